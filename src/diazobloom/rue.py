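"""Resource use efficiency (RUE) and its regression on diazotroph proportion.

RUE is the natural log of the weight ratio of chlorophyll a to a total
nutrient: RUE_P = ln(Chl a / TP), RUE_N = ln(Chl a / TN). Both are z-scored
before regression so the slopes of the two responses are directly
comparable. The regression is semiparametric,

    z(RUE) ~ s(lat, lon) + beta * asin(sqrt(proportion)),

with the geographic smooth absorbing the strong spatial pattern of nutrient
limitation and ``beta`` the quantity of interest. The smooth is a
thin-plate-type radial basis (default 30 knots) with a ridge penalty chosen
by generalized cross-validation; with ``smooth=False`` the model collapses
to ordinary least squares with linear lat/lon adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from .data import SampleTable

__all__ = ["RueFit", "compute_rue", "fit_rue", "compare_slopes", "RUERegression"]


def compute_rue(samples: SampleTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample RUE and z-scored RUE.

    Each RUE column is defined over its own complete positive pair
    (chl_a & tp for rue_p, chl_a & tn for rue_n) and missing elsewhere;
    z-scores (sample sd) are computed over the non-missing rows of each
    column. Rows with non-positive chl/nutrient values are treated as
    missing with a warning.
    """
    df = samples.data if isinstance(samples, SampleTable) else samples
    out = pd.DataFrame(index=df.index)
    n_bad = 0
    for col, nutrient in [("rue_p", "tp"), ("rue_n", "tn")]:
        chl, nut = df["chl_a"], df[nutrient]
        ok = chl.notna() & nut.notna() & (chl > 0) & (nut > 0)
        n_bad += int((chl.notna() & nut.notna() & ~ok).sum())
        rue = pd.Series(np.nan, index=df.index)
        rue[ok] = np.log(chl[ok] / nut[ok])
        out[col] = rue
        z = (rue - rue.mean()) / rue.std(ddof=1)
        out["z_" + col] = z
    if n_bad:
        warnings.warn(f"{n_bad} row(s) with non-positive chl/nutrient dropped from RUE")
    return out


@dataclass
class RueFit:
    """Slope of z(RUE) per unit arcsine-sqrt proportion, with inference."""

    slope: float
    se: float
    p: float
    n: int
    smooth_df: float
    method: str = "tprs-gcv"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _tp_basis(coords: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Thin-plate radial basis phi(r) = r^2 log r, phi(0) = 0."""
    d = np.linalg.norm(coords[:, None, :] - knots[None, :, :], axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(d > 0, d**2 * np.log(d), 0.0)
    return phi


class RUERegression(RegressorMixin, BaseEstimator):
    """Semiparametric regression of z(RUE) on diazotroph proportion.

    Parameters
    ----------
    smooth : bool
        Include the penalized spatial term; ``False`` gives plain OLS with
        linear lat/lon adjustment.
    basis_size : int
        Number of radial-basis knots for the spatial smooth.
    alphas : array-like
        Ridge-penalty grid searched by GCV.

    ``fit(X, y)`` expects ``X`` with columns (lat, lon, proportion) —
    proportion in [0, 1], arcsine-sqrt transformed internally — and ``y``
    the z-scored RUE. Fitted attributes: ``slope_``, ``se_``, ``pvalue_``,
    ``n_``, ``smooth_df_``.
    """

    def __init__(self, smooth: bool = True, basis_size: int = 30, alphas=None):
        self.smooth = smooth
        self.basis_size = basis_size
        self.alphas = alphas

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
        X, y = X[ok], y[ok]
        n = len(y)
        if n < 30:
            raise ValueError(f"need >= 30 complete cases, got {n}")
        lat, lon, prop = X[:, 0], X[:, 1], X[:, 2]
        if np.any((prop < 0) | (prop > 1)):
            raise ValueError("proportion outside [0, 1]")
        g = np.arcsin(np.sqrt(prop))
        if g.std() < 1e-10:
            raise ValueError("rank-deficient design: proportion is constant")

        coords = X[:, :2].copy()
        coords = (coords - coords.mean(0)) / coords.std(0)
        # parametric (unpenalized) part: intercept, lat, lon, g — slope last
        P = np.column_stack([np.ones(n), coords, g])
        if self.smooth:
            Z = self._smooth_basis(coords)
            D = np.column_stack([P, Z])
            pen = np.zeros(D.shape[1])
            pen[P.shape[1]:] = 1.0
            S = np.diag(pen)
            alphas = (
                np.logspace(-4, 5, 28) if self.alphas is None else np.asarray(self.alphas)
            )
            best = None
            DtD = D.T @ D
            Dty = D.T @ y
            for a in alphas:
                A = DtD + a * S
                try:
                    beta = np.linalg.solve(A, Dty)
                except np.linalg.LinAlgError:
                    continue
                hat_diag_tr = np.trace(np.linalg.solve(A, DtD))
                resid = y - D @ beta
                rss = float(resid @ resid)
                edf = hat_diag_tr
                if n - edf <= 1:
                    continue
                gcv = n * rss / (n - edf) ** 2
                if best is None or gcv < best[0]:
                    best = (gcv, a, beta, rss, edf)
            if best is None:
                raise np.linalg.LinAlgError("no admissible penalty found")
            _, alpha, beta, rss, edf = best
            A = DtD + alpha * S
            Ainv = np.linalg.inv(A)
            sigma2 = rss / (n - edf)
            cov = Ainv @ DtD @ Ainv * sigma2
            self.alpha_ = float(alpha)
            # spatial-term edf: total edf minus intercept and the linear slope
            self.smooth_df_ = float(edf - 2.0)
            self._D_cols = D.shape[1]
            self.coef_ = beta
            slope_idx = P.shape[1] - 1
        else:
            D = P
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ beta
            rss = float(resid @ resid)
            edf = D.shape[1]
            sigma2 = rss / (n - edf)
            cov = np.linalg.inv(D.T @ D) * sigma2
            self.alpha_ = 0.0
            self.smooth_df_ = 0.0
            self.coef_ = beta
            slope_idx = P.shape[1] - 1

        self.slope_ = float(beta[slope_idx])
        self.se_ = float(np.sqrt(cov[slope_idx, slope_idx]))
        z = self.slope_ / self.se_
        self.pvalue_ = float(2 * norm.sf(abs(z)))
        self.n_ = n
        self._coords_mean = X[:, :2].mean(0)
        self._coords_std = X[:, :2].std(0)
        return self

    def _smooth_basis(self, coords: np.ndarray) -> np.ndarray:
        uniq = np.unique(coords, axis=0)
        k = min(self.basis_size, len(uniq))
        # deterministic spread: evenly spaced indices of lexicographically
        # sorted unique coordinates
        order = np.lexsort((uniq[:, 1], uniq[:, 0]))
        idx = np.linspace(0, len(uniq) - 1, k).round().astype(int)
        self.knots_ = uniq[order][idx]
        return _tp_basis(coords, self.knots_)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        coords = (X[:, :2] - self._coords_mean) / self._coords_std
        g = np.arcsin(np.sqrt(np.clip(X[:, 2], 0, 1)))
        P = np.column_stack([np.ones(len(X)), coords, g])
        if self.smooth:
            Z = _tp_basis(coords, self.knots_)
            D = np.column_stack([P, Z])
        else:
            D = P
        return D @ self.coef_

    def result_(self) -> RueFit:
        return RueFit(
            slope=self.slope_,
            se=self.se_,
            p=self.pvalue_,
            n=self.n_,
            smooth_df=self.smooth_df_,
            method="tprs-gcv" if self.smooth else "ols",
        )


def fit_rue(rue_z, proportion, lat, lon, smooth: bool = True, basis_size: int = 30) -> RueFit:
    """Fit z(RUE) ~ s(lat, lon) + beta * asin(sqrt(proportion)); return the slope."""
    X = np.column_stack([np.asarray(lat, float), np.asarray(lon, float),
                         np.asarray(proportion, float)])
    est = RUERegression(smooth=smooth, basis_size=basis_size)
    est.fit(X, np.asarray(rue_z, float))
    return est.result_()


def compare_slopes(fit_a: RueFit, fit_b: RueFit) -> tuple[float, float]:
    """Wald comparison of two slopes assuming independent fits.

    z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2), two-sided p. The
    independence assumption is an approximation when both slopes come from
    the same samples.
    """
    z = (fit_a.slope - fit_b.slope) / np.sqrt(fit_a.se**2 + fit_b.se**2)
    p = float(2 * norm.sf(abs(z)))
    return float(z), p
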