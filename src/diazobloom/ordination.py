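"""Community ordination and distance-based variance partitioning.

Three complementary routes from a community matrix to a "how much does the
diazotroph proportion explain" number, each with a permutation test:

* NMDS on Bray-Curtis dissimilarities with a posteriori vector fitting of
  the proportion (R^2 of the variable on the ordination coordinates, p by
  permuting the variable; 999 permutations by default);
* (partial) constrained correspondence analysis — the chi-square
  standardized matrix is projected (row-weighted) onto the constraint
  space, optionally after residualizing out conditioning covariates;
  constrained fraction = constrained / total inertia;
* PERMANOVA on the distance matrix (McArdle-Anderson sums of squares via
  the Gower-centered inner-product matrix), for continuous or categorical
  covariates.

All permutation p-values use the (1 + hits) / (1 + n_perm) convention and
are therefore never zero. The NMDS numerical engine is delegated to
scikit-learn's isotonic MDS; the statistical assessment around it is the
point here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS

from .data import CommunityMatrix

__all__ = [
    "OrdinationResult",
    "VectorFit",
    "CcaResult",
    "PermanovaResult",
    "bray_curtis",
    "nmds",
    "fit_external_vector",
    "cca",
    "permanova",
    "NMDS",
    "EnvironmentalVectorFit",
    "CCA",
    "PERMANOVA",
]


def bray_curtis(matrix) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix (symmetric, zero diagonal, [0, 1]).

    A pair of all-zero rows has undefined dissimilarity; it is set to 0 and
    flagged with a warning.
    """
    X = matrix.biomass if isinstance(matrix, CommunityMatrix) else np.asarray(matrix, float)
    if (X < 0).any():
        raise ValueError("negative abundances")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(X, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero row pair(s): dissimilarity set to 0")
        d = np.nan_to_num(d, nan=0.0)
    return d


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    method: str = "nmds"
    degenerate: bool = False


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling of a precomputed distance matrix.

    Thin contract wrapper over sklearn's isotonic MDS: best-stress
    configuration over ``n_restarts`` random starts, deterministic under
    ``seed``. Fitted attributes: ``embedding_``, ``stress_``.
    """

    def __init__(self, k: int = 2, n_restarts: int = 4, seed: int | None = 0,
                 max_iter: int = 300):
        self.k = k
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_iter = max_iter

    def fit(self, dist, y=None):
        D = np.asarray(dist, dtype=float)
        n = D.shape[0]
        if n < 4:
            raise ValueError("need >= 4 samples")
        off = D[~np.eye(n, dtype=bool)]
        self.degenerate_ = bool(np.allclose(off, off[0]))
        if self.degenerate_:
            warnings.warn("degenerate all-equal distances; configuration arbitrary")
        eng = MDS(
            n_components=self.k,
            metric_mds=False,
            dissimilarity="precomputed",
            n_init=self.n_restarts,
            random_state=self.seed,
            max_iter=self.max_iter,
            normalized_stress=True,
        )
        self.embedding_ = eng.fit_transform(D)
        self.stress_ = float(eng.stress_)
        return self

    def fit_transform(self, dist, y=None):
        self.fit(dist)
        return self.embedding_

    def result_(self) -> OrdinationResult:
        return OrdinationResult(self.embedding_, self.stress_, "nmds", self.degenerate_)


def nmds(dist, k: int = 2, n_restarts: int = 4, seed: int | None = 0) -> OrdinationResult:
    """Best-stress NMDS configuration over random restarts."""
    est = NMDS(k=k, n_restarts=n_restarts, seed=seed)
    est.fit(dist)
    return est.result_()


@dataclass
class VectorFit:
    direction: np.ndarray
    r2: float
    p: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        row = {f"axis{i + 1}": v for i, v in enumerate(self.direction)}
        row.update(r2=self.r2, p=self.p, n_perm=self.n_perm)
        return pd.DataFrame([row])


def _vector_r2(coords: np.ndarray, v: np.ndarray) -> tuple[float, np.ndarray]:
    X = np.column_stack([np.ones(len(v)), coords])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ beta
    tss = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss
    return r2, beta[1:]


class EnvironmentalVectorFit(BaseEstimator):
    """A posteriori fit of an external variable onto an ordination plane.

    R^2 is the coefficient of determination of the least-squares regression
    of the variable on the ordination coordinates; the direction is the
    normalized coefficient vector; significance by permuting the variable
    across samples.
    """

    def __init__(self, n_perm: int = 999, seed: int | None = 0):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, coords, variable):
        coords = np.asarray(coords, dtype=float)
        v = np.asarray(variable, dtype=float)
        if len(v) != len(coords):
            raise ValueError("variable length does not match samples")
        if not np.isfinite(v).all():
            raise ValueError("variable contains non-finite values")
        if v.std() == 0:
            raise ValueError("constant variable cannot be fitted")
        r2, coef = _vector_r2(coords, v)
        norm = np.linalg.norm(coef)
        self.direction_ = coef / norm if norm > 0 else coef
        self.r2_ = r2
        rng = np.random.default_rng(self.seed)
        hits = 0
        for _ in range(self.n_perm):
            r2p, _ = _vector_r2(coords, rng.permutation(v))
            hits += r2p >= r2
        self.pvalue_ = (1 + hits) / (1 + self.n_perm)
        return self

    def result_(self) -> VectorFit:
        return VectorFit(self.direction_, self.r2_, self.pvalue_, self.n_perm)


def fit_external_vector(ordination, variable, n_perm: int = 999, seed: int | None = 0) -> VectorFit:
    coords = ordination.coordinates if isinstance(ordination, OrdinationResult) else ordination
    est = EnvironmentalVectorFit(n_perm=n_perm, seed=seed)
    est.fit(coords, variable)
    return est.result_()


@dataclass
class CcaResult:
    total_inertia: float
    constrained_inertia: float
    conditioned_inertia: float
    constrained_fraction: float
    p: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _chi_square_matrix(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square standardized community matrix Q and row weights r."""
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise ValueError("community matrix needs positive row and column sums")
    E = np.outer(r, c)
    return (P - E) / np.sqrt(E), r

def _weighted_design(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-weight-centred design scaled by sqrt(r), ready for projection."""
    Xc = X - (r[:, None] * X).sum(axis=0) / r.sum()
    return np.sqrt(r)[:, None] * Xc


def _project(Q: np.ndarray, Xs: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Xs, Q, rcond=None)
    return Xs @ beta


class CCA(BaseEstimator):
    """(Partial) constrained correspondence analysis inertia partition.

    ``fit(Y, constraints, conditions=None)`` computes total inertia of the
    chi-square standardized matrix, the inertia captured by the row-weighted
    projection onto the constraint space (after residualizing constraints
    and community on the conditions, if given) and a permutation p-value
    obtained by permuting the (residualized) constraint rows.
    """

    def __init__(self, n_perm: int = 199, seed: int | None = 0):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, Y, constraints, conditions=None):
        Y = Y.biomass if isinstance(Y, CommunityMatrix) else np.asarray(Y, dtype=float)
        X = np.atleast_2d(np.asarray(constraints, dtype=float))
        if X.shape[0] == 1 and X.shape[1] == Y.shape[0]:
            X = X.T
        if not np.isfinite(X).all():
            raise ValueError("constraint columns must be finite")
        Q, r = _chi_square_matrix(Y)
        self.total_inertia_ = float((Q**2).sum())

        cond_inertia = 0.0
        if conditions is not None:
            Z = np.atleast_2d(np.asarray(conditions, dtype=float))
            if Z.shape[0] == 1 and Z.shape[1] == Y.shape[0]:
                Z = Z.T
            Zs = _weighted_design(Z, r)
            fit_z = _project(Q, Zs)
            cond_inertia = float((fit_z**2).sum())
            Q = Q - fit_z
            Xs = _weighted_design(X, r)
            Xs = Xs - _project(Xs, Zs)
        else:
            Xs = _weighted_design(X, r)

        fitted = _project(Q, Xs)
        obs = float((fitted**2).sum())
        if conditions is not None and obs < 1e-12 and np.abs(Xs).max() < 1e-10:
            warnings.warn("constraints collinear with conditions; fraction ~ 0")
        self.constrained_inertia_ = obs
        # residual inertia, computed from the residual matrix itself so that
        # the Pythagorean decomposition is checkable, not true by definition
        self.unconstrained_inertia_ = float(((Q - fitted) ** 2).sum())
        self.conditioned_inertia_ = cond_inertia
        self.constrained_fraction_ = obs / self.total_inertia_

        rng = np.random.default_rng(self.seed)
        hits = 0
        for _ in range(self.n_perm):
            perm = rng.permutation(Xs.shape[0])
            stat = float((_project(Q, Xs[perm]) ** 2).sum())
            hits += stat >= obs
        self.pvalue_ = (1 + hits) / (1 + self.n_perm)
        return self

    def result_(self) -> CcaResult:
        return CcaResult(
            self.total_inertia_,
            self.constrained_inertia_,
            self.conditioned_inertia_,
            self.constrained_fraction_,
            self.pvalue_,
            self.n_perm,
        )


def cca(community, constraints, conditions=None, n_perm: int = 199, seed: int | None = 0) -> CcaResult:
    est = CCA(n_perm=n_perm, seed=seed)
    est.fit(community, constraints, conditions=conditions)
    return est.result_()


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p: float
    df_model: int
    df_resid: int
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _design_matrix(covariate) -> np.ndarray:
    cov = np.asarray(covariate)
    if cov.dtype.kind in "OUS" or cov.dtype.kind == "b":
        dummies = pd.get_dummies(pd.Series(cov), drop_first=True).to_numpy(float)
        if dummies.shape[1] == 0:
            raise ValueError("constant covariate: degenerate design")
        return dummies
    cov = cov.astype(float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if np.allclose(cov.std(axis=0), 0):
        raise ValueError("constant covariate: degenerate design")
    return cov


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = len(A)
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _permanova_f(G: np.ndarray, X: np.ndarray) -> tuple[float, float, int, int]:
    n = len(G)
    Xc = X - X.mean(axis=0)
    # hat matrix of the centred design; G is double-centred so the
    # intercept direction contributes nothing
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum()) if s.size else 0
    if rank == 0:
        raise ValueError("constant covariate: degenerate design")
    U = U[:, :rank]
    ss_total = float(np.trace(G))
    ss_model = float(np.einsum("ij,jk,ik->", U.T, G, U.T))
    df_m = rank
    df_r = n - rank - 1
    f = (ss_model / df_m) / ((ss_total - ss_model) / df_r)
    r2 = ss_model / ss_total
    return f, r2, df_m, df_r


class PERMANOVA(BaseEstimator):
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the McArdle-Anderson sums of squares of the Gower-centered
    inner-product matrix by the hat matrix of the covariate design;
    significance by permuting the covariate rows.
    """

    def __init__(self, n_perm: int = 999, seed: int | None = 0):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, dist, covariate):
        D = np.asarray(dist, dtype=float)
        n = D.shape[0]
        if n < 3:
            raise ValueError("need >= 3 samples")
        X = _design_matrix(covariate)
        if len(X) != n:
            raise ValueError("covariate length does not match distance matrix")
        G = _gower_center(D)
        f, r2, df_m, df_r = _permanova_f(G, X)
        self.pseudo_f_, self.r2_ = f, r2
        self.df_model_, self.df_resid_ = df_m, df_r
        rng = np.random.default_rng(self.seed)
        hits = 0
        for _ in range(self.n_perm):
            perm = rng.permutation(n)
            fp, *_ = _permanova_f(G, X[perm])
            hits += fp >= f
        self.pvalue_ = (1 + hits) / (1 + self.n_perm)
        return self

    def result_(self) -> PermanovaResult:
        return PermanovaResult(
            self.r2_, self.pseudo_f_, self.pvalue_, self.df_model_, self.df_resid_, self.n_perm
        )


def permanova(dist, covariate, n_perm: int = 999, seed: int | None = 0) -> PermanovaResult:
    est = PERMANOVA(n_perm=n_perm, seed=seed)
    est.fit(dist, covariate)
    return est.result_()
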