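"""Distance-based Moran's eigenvector maps for a 1-D transect and the
environment-vs-space variance decomposition built on them.

The transect is not looped: geographic distance is the absolute difference
of cumulative along-channel positions.  dbMEM construction follows the
classical recipe -- truncate the geographic distance matrix at the largest
nearest-neighbour gap, replace all farther pairs by four times that
threshold, take the principal coordinates of the truncated matrix, and
keep eigenvectors with positive eigenvalue.  Each retained eigenvector is
annotated with Moran's I under within-threshold adjacency weights;
eigenvectors with negative Moran's I (negative spatial autocorrelation)
are excluded from the spatial candidate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta import pcoa
from .containers import DistanceMatrix, ValidationError

log = logging.getLogger("fluvimyco")

__all__ = [
    "DbMemModel", "dbmem", "morans_i", "dbrda_r2", "forward_select",
    "scalogram_split", "varpart", "VarpartResult", "geographic_distance",
]


def geographic_distance(channel_km, ids=None) -> DistanceMatrix:
    """1-D along-channel distance matrix |km_i - km_j|."""
    if isinstance(channel_km, pd.Series):
        ids = ids or list(channel_km.index)
        channel_km = channel_km.to_numpy()
    x = np.asarray(channel_km, dtype=float)
    D = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(D, ids=ids or list(map(str, range(len(x)))))


# ---------------------------------------------------------------------------
# dbMEM
# ---------------------------------------------------------------------------

@dataclass
class DbMemModel:
    eigenvectors: pd.DataFrame         # sites x MEMk, positive eigenvalues only
    eigenvalues: np.ndarray
    morans_i: pd.Series                # per retained eigenvector
    truncation_threshold: float
    adjacency: np.ndarray
    selected: list[str] = field(default_factory=list)
    submodel: dict[str, str] = field(default_factory=dict)

    @property
    def candidates(self) -> pd.DataFrame:
        """Eigenvectors with positive Moran's I (positive autocorrelation)."""
        keep = self.morans_i.index[self.morans_i > 0]
        return self.eigenvectors[list(keep)]


def dbmem(channel_km, ids=None) -> DbMemModel:
    """Distance-based Moran's eigenvector maps of a 1-D transect."""
    if isinstance(channel_km, pd.Series):
        ids = ids or list(channel_km.index)
        channel_km = channel_km.to_numpy()
    x = np.asarray(channel_km, dtype=float)
    n = len(x)
    if n < 4:
        raise ValidationError("dbMEM needs at least 4 positions")
    if len(np.unique(x)) != n:
        raise ValidationError("duplicate along-channel positions")
    ids = ids or [f"s{i}" for i in range(n)]

    D = np.abs(x[:, None] - x[None, :])
    sorted_x = np.sort(x)
    threshold = float(np.max(np.diff(sorted_x)))
    trunc = D.copy()
    trunc[D > threshold] = 4.0 * threshold
    np.fill_diagonal(trunc, 0.0)

    ordn = pcoa(DistanceMatrix(trunc, ids=ids))
    n_pos = ordn.coordinates.shape[1]
    # unit-norm eigenvectors (principal coordinates rescaled): orthonormal
    vecs = ordn.coordinates.to_numpy() / np.sqrt(ordn.eigenvalues[:n_pos])
    cols = [f"MEM{k + 1}" for k in range(n_pos)]
    eig = pd.DataFrame(vecs, index=ids, columns=cols)

    W = ((D <= threshold) & (D > 0)).astype(float)
    mi = pd.Series({c: morans_i(eig[c].to_numpy(), W) for c in cols})
    return DbMemModel(eigenvectors=eig, eigenvalues=ordn.eigenvalues[:n_pos],
                      morans_i=mi, truncation_threshold=threshold, adjacency=W)


def morans_i(values, weights) -> float:
    """Moran's I = (n / sum W) * sum_ij w_ij (x_i - m)(x_j - m) / sum (x_i - m)^2."""
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    if np.any(np.diag(W) != 0) or not np.allclose(W, W.T):
        raise ValidationError("weights must be symmetric with zero diagonal")
    if W.sum() == 0:
        raise ValidationError("all-zero weights")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValidationError("constant vector has no spatial autocorrelation")
    n = len(x)
    return float(n / W.sum() * (z @ W @ z) / denom)


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

def _response_axes(d: DistanceMatrix) -> np.ndarray:
    """Positive-eigenvalue principal coordinates (centered)."""
    return pcoa(d).coordinates.to_numpy()


def _drop_collinear(X: np.ndarray, names=None) -> tuple[np.ndarray, list]:
    names = list(names) if names is not None else list(range(X.shape[1]))
    keep_idx, kept = [], []
    for j in range(X.shape[1]):
        trial = X[:, keep_idx + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) == len(keep_idx) + 2:
            keep_idx.append(j)
            kept.append(names[j])
        else:
            log.warning("dropping collinear predictor column %r", names[j])
    return X[:, keep_idx], kept


def _rss(Y: np.ndarray, X: np.ndarray | None) -> float:
    """Residual sum of squares of Y on [1, X] (total SS when X is None)."""
    Yc = Y - Y.mean(axis=0)
    if X is None or X.shape[1] == 0:
        return float(np.sum(Yc ** 2))
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    resid = Yc - Xc @ beta
    return float(np.sum(resid ** 2))


def dbrda_r2(d: DistanceMatrix, predictors) -> tuple[float, float]:
    """Distance-based redundancy R^2 and Ezekiel-adjusted R^2.

    The response is the positive-eigenvalue principal-coordinate space of
    ``d``; R^2 is the fraction of its total sum of squares captured by an
    OLS fit on the predictors.  adjusted R^2 = 1 - (1 - R^2)(n-1)/(n-p-1).
    """
    X, names = _as_matrix(predictors)
    Y = _response_axes(d)
    n = Y.shape[0]
    X, kept = _drop_collinear(X, names)
    p = X.shape[1]
    if n <= p + 1:
        raise ValidationError(f"too many predictors ({p}) for {n} samples")
    tss = _rss(Y, None)
    rss = _rss(Y, X)
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return float(r2), float(adj)


def _as_matrix(predictors) -> tuple[np.ndarray, list]:
    if isinstance(predictors, pd.DataFrame):
        return predictors.to_numpy(dtype=float), list(predictors.columns)
    arr = np.asarray(predictors, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, list(range(arr.shape[1]))


def forward_select(d: DistanceMatrix, candidates, alpha: float = 0.05,
                   n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Greedy dbRDA forward selection with the double stopping rule.

    At each step the candidate with the best partial pseudo-F enters if its
    permutation p-value is <= ``alpha`` and the running adjusted R^2 has
    not yet exceeded that of the full-candidate model.  Returns the
    selection path (variable, pseudo_f, p, adj_r2_after) in entry order.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    X, names = _as_matrix(candidates)
    if X.shape[1] == 0:
        raise ValidationError("no candidate predictors")
    Y = _response_axes(d)
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    tss = _rss(Y, None)
    _, adj_full = dbrda_r2(d, candidates)

    selected: list[int] = []
    rows = []
    while len(selected) < X.shape[1] and len(selected) < n - 2:
        remaining = [j for j in range(X.shape[1]) if j not in selected]
        best_j, best_f = None, -np.inf
        rss_red = _rss(Y, X[:, selected] if selected else None)
        for j in remaining:
            Xj = X[:, selected + [j]]
            if np.linalg.matrix_rank(Xj - Xj.mean(axis=0)) < len(selected) + 1:
                continue
            rss_j = _rss(Y, Xj)
            df_resid = n - len(selected) - 2
            f = (rss_red - rss_j) / (rss_j / df_resid)
            if f > best_f:
                best_f, best_j = f, j
        if best_j is None:
            break
        # permutation test: permute response rows under the reduced model
        hits = 0
        Xfull = X[:, selected + [best_j]]
        df_resid = n - len(selected) - 2
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Yp = Y[perm]
            rss_red_p = _rss(Yp, X[:, selected] if selected else None)
            rss_p = _rss(Yp, Xfull)
            f_p = (rss_red_p - rss_p) / (rss_p / df_resid)
            if f_p >= best_f:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        if p > alpha:
            break
        r2_new = 1.0 - _rss(Y, Xfull) / tss
        adj_new = 1.0 - (1.0 - r2_new) * (n - 1) / (n - len(selected) - 2)
        if adj_new > adj_full and alpha < 1:
            break
        selected.append(best_j)
        rows.append({"variable": names[best_j], "pseudo_f": float(best_f),
                     "p": float(p), "adj_r2_after": float(adj_new)})
    return pd.DataFrame(rows, columns=["variable", "pseudo_f", "p", "adj_r2_after"])


# ---------------------------------------------------------------------------
# Scalogram submodels
# ---------------------------------------------------------------------------

def scalogram_split(morans: pd.Series) -> dict[str, str]:
    """Partition selected eigenvectors into broad vs small scale.

    Eigenvectors are taken in order and split at the largest drop in
    Moran's I; everything before the gap is ``broad``, the rest ``small``.
    Exact ties in the drops fall back to the midpoint, with a warning.
    """
    morans = pd.Series(morans)
    if len(morans) < 2:
        raise ValidationError("scalogram split needs at least 2 eigenvectors")
    vals = morans.to_numpy(dtype=float)
    drops = vals[:-1] - vals[1:]
    best = float(drops.max())
    where = np.flatnonzero(np.isclose(drops, best))
    if len(where) > 1:
        cut = len(vals) // 2
        log.warning("scalogram drops tie; splitting at the midpoint (%d)", cut)
    else:
        cut = int(where[0]) + 1
    return {name: ("broad" if i < cut else "small")
            for i, name in enumerate(morans.index)}


# ---------------------------------------------------------------------------
# Variation partitioning
# ---------------------------------------------------------------------------

@dataclass
class VarpartResult:
    """Adjusted-R^2 decomposition: a (env unique), b (shared), c (space
    unique), d (unexplained); a+b+c+d = 1 by construction, individual
    fractions may be negative."""

    frac_env_unique: float
    frac_shared: float
    frac_spat_unique: float
    frac_unexplained: float

    def as_dict(self) -> dict[str, float]:
        return {"a_env_unique": self.frac_env_unique,
                "b_shared": self.frac_shared,
                "c_spat_unique": self.frac_spat_unique,
                "d_unexplained": self.frac_unexplained}


def varpart(d: DistanceMatrix, env, spat) -> VarpartResult:
    """Two-block variation partitioning by dbRDA adjusted R^2."""
    Xe, ne = _as_matrix(env)
    Xs, ns = _as_matrix(spat)
    both = np.column_stack([Xe, Xs])
    _, adj_e = dbrda_r2(d, Xe)
    _, adj_s = dbrda_r2(d, Xs)
    _, adj_es = dbrda_r2(d, both)
    a = adj_es - adj_s
    c = adj_es - adj_e
    b = adj_e + adj_s - adj_es
    u = 1.0 - adj_es
    return VarpartResult(float(a), float(b), float(c), float(u))
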