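"""Phylogeny-aware distances, ordination and permutation tests.

The distance of record is the generalized UniFrac

    d_alpha(k, m) = sum_b L_b (p_b + q_b)^alpha |p_b - q_b| / (p_b + q_b)
                    ---------------------------------------------------
                    sum_b L_b (p_b + q_b)^alpha

over branches b with p_b + q_b > 0, where p_b, q_b are the proportions of
community k resp. m subtended by branch b and L_b its length.  alpha
moderates the weight of high-abundance branches; alpha = 1 recovers
weighted-normalized UniFrac.

PERMANOVA follows the classical pseudo-F decomposition of squared
dissimilarities with whole-row label permutation; PCoA reports negative
eigenvalues rather than silently correcting them (a Cailliez correction is
available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .containers import DistanceMatrix, EnvTable, OtuTable, PhyloTree, ValidationError
from .diversity import zscore

log = logging.getLogger("fluvimyco")

__all__ = [
    "gunifrac", "bray_curtis", "pcoa", "OrdinationResult",
    "permanova", "pairwise_permanova", "PermanovaResult",
    "envfit_axes", "collinearity_screen",
    "simprof_cluster", "SimprofResult", "anosim_r",
    "distance_decay", "DistanceDecayResult",
    "branch_proportions",
]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def branch_proportions(table: OtuTable, tree: PhyloTree
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample branch-subtended abundance proportions.

    Returns ``(P, L)`` where ``P[s, b]`` is the proportion of community s
    subtended by branch b and ``L[b]`` the branch length, over every branch
    of the tree below the root.
    """
    otu_index = {o: i for i, o in enumerate(table.otu_ids)}
    missing = set(table.otu_ids) - set(tree.tip_labels)
    if missing:
        raise ValidationError(f"table OTUs absent from tree: {sorted(missing)}")
    rel = table.relative_abundance().to_numpy()

    lengths, masks = [], []
    # postorder accumulation of tip membership under each branch
    tip_sets: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(otu_index))
            idx = otu_index.get(node.name)
            if idx is not None:
                vec[idx] = 1.0
            tip_sets[id(node)] = vec
        else:
            vec = np.zeros(len(otu_index))
            for child in node.children:
                vec += tip_sets[id(child)]
            tip_sets[id(node)] = vec
        if node.parent is not None:  # every branch below the root
            lengths.append(node.length or 0.0)
            masks.append(tip_sets[id(node)])
    L = np.asarray(lengths)
    M = np.asarray(masks)            # branches x otus
    P = rel @ M.T                    # samples x branches
    return P, L


def gunifrac(table: OtuTable, tree: PhyloTree, alpha: float = 0.5
             ) -> DistanceMatrix:
    """Generalized UniFrac distance between all sample pairs (in [0, 1])."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    P, L = branch_proportions(table, tree)
    n = P.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, q = P[i], P[j]
            tot = p + q
            nz = tot > 0
            w = L[nz] * tot[nz] ** alpha
            num = float(np.sum(w * np.abs(p[nz] - q[nz]) / tot[nz]))
            den = float(np.sum(w))
            out[i, j] = out[j, i] = 0.0 if den == 0 else num / den
    return DistanceMatrix(out, ids=table.sample_ids)


def bray_curtis(matrix, ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y) between rows."""
    if isinstance(matrix, OtuTable):
        ids = matrix.sample_ids
        matrix = matrix.counts
    if isinstance(matrix, pd.DataFrame):
        ids = ids or list(matrix.index)
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if (matrix < 0).any():
        raise ValidationError("negative entries in Bray-Curtis input")
    if (matrix.sum(axis=1) == 0).sum() >= 2:
        raise ValidationError("two all-zero rows make Bray-Curtis undefined")
    return DistanceMatrix(squareform(pdist(matrix, metric="braycurtis")),
                          ids=ids or list(map(str, range(len(matrix)))))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Principal-coordinates decomposition of a dissimilarity matrix.

    ``eigenvalues`` are all n eigenvalues in descending order (negative
    ones included); ``coordinates`` span the positive axes, scaled so
    squared coordinate distances reproduce the input when the matrix is
    Euclidean; ``prop_explained`` normalizes over positive eigenvalues.
    """

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    prop_explained: np.ndarray
    ids: list[str] = field(default_factory=list)


def pcoa(d: DistanceMatrix, cailliez: bool = False) -> OrdinationResult:
    """Eigen-decomposition of the double-centered matrix -1/2 J D^2 J."""
    D = d.data
    n = D.shape[0]
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    if cailliez:
        D = _cailliez(D)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    prop = evals[pos] / evals[pos].sum()
    return OrdinationResult(
        eigenvalues=evals,
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=cols),
        prop_explained=prop,
        ids=list(d.ids),
    )


def _cailliez(D: np.ndarray) -> np.ndarray:
    """Smallest additive constant making D Euclidean (Cailliez 1983)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ (D ** 2) @ J
    d2 = -0.5 * J @ D @ J
    B = np.block([[np.zeros((n, n)), 2 * d1], [-np.eye(n), -4 * d2]])
    c = float(np.max(np.real(np.linalg.eigvals(B))))
    if c <= 0:
        return D
    out = D + c
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_perm: int


def _permanova_ss(d2: np.ndarray, groups: np.ndarray, labels) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2, groups, labels) -> tuple[float, float]:
    n, k = d2.shape[0], len(labels)
    ss_total, ss_within = _permanova_ss(d2, groups, labels)
    ss_between = ss_total - ss_within
    if ss_total <= 0:          # all points identical: no variance to explain
        return 0.0, 0.0
    if ss_within <= 0:
        return np.inf, 1.0
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def permanova(d: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)) with sums of squared
    dissimilarities; the p-value counts whole-row label permutations with
    F >= F_obs, with the +1 continuity convention.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    groups = np.asarray(pd.Series(groups).reindex(list(d.ids))
                        if isinstance(groups, pd.Series) else groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    sizes = [int((groups == g).sum()) for g in labels]
    if min(sizes) < 2:
        raise ValidationError("every group needs at least 2 samples")
    d2 = d.data ** 2
    f_obs, r2 = _pseudo_f(d2, groups, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        f_perm, _ = _pseudo_f(d2, perm, labels)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def pairwise_permanova(d: DistanceMatrix, groups, n_perm: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA on every unordered group pair, BH-adjusted across pairs."""
    groups = pd.Series(groups, index=list(d.ids)
                       if not isinstance(groups, pd.Series) else groups.index)
    groups = groups.reindex(list(d.ids))
    labels = sorted(groups.unique().tolist())
    rng = np.random.default_rng(seed)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            keep = groups.index[groups.isin([a, b])]
            sub = d.filter(list(keep))
            res = permanova(sub, groups.loc[list(sub.ids)].to_numpy(),
                            n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
            rows.append({"group_a": a, "group_b": b, "pseudo_f": res.pseudo_f,
                         "r_squared": res.r_squared, "p": res.p_value})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Environment fitting & screening
# ---------------------------------------------------------------------------

def envfit_axes(ordination: OrdinationResult, env: EnvTable,
                p_thresh: float = 0.005, r2_thresh: float = 0.5,
                score_thresh: float = 0.7) -> pd.DataFrame:
    """Correlate each environmental variable with the first two axes.

    Per variable: Pearson r against each axis, a fitted-vector R^2 (OLS of
    the variable on both axis scores), unit-normalized direction cosines
    ("scores"), BH-adjusted per-axis p-values, and a pass flag per axis
    requiring p_adj < ``p_thresh``, R^2 > ``r2_thresh`` and
    |score| > ``score_thresh``.
    """
    axes = ordination.coordinates.iloc[:, :2]
    data = env.data.loc[axes.index]
    rows = []
    for var in data.columns:
        y = data[var].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ValidationError(f"constant environmental variable {var!r}")
        r1, p1 = stats.pearsonr(y, axes.iloc[:, 0])
        r2_, p2 = stats.pearsonr(y, axes.iloc[:, 1])
        X = np.column_stack([np.ones(len(y)), axes.to_numpy()])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2_fit = 1.0 - resid.var() / y.var()
        direction = np.array([r1, r2_])
        norm = np.linalg.norm(direction)
        score = direction / norm if norm > 0 else direction
        rows.append({"variable": var, "r_axis1": r1, "r_axis2": r2_,
                     "score_axis1": score[0], "score_axis2": score[1],
                     "r2": r2_fit, "p_axis1": p1, "p_axis2": p2})
    out = pd.DataFrame(rows).set_index("variable")
    flat = multipletests(
        np.concatenate([out["p_axis1"], out["p_axis2"]]), method="fdr_bh")[1]
    out["p_adj_axis1"] = flat[: len(out)]
    out["p_adj_axis2"] = flat[len(out):]
    for ax in (1, 2):
        out[f"flag_axis{ax}"] = (
            (out[f"p_adj_axis{ax}"] < p_thresh)
            & (out["r2"] > r2_thresh)
            & (out[f"score_axis{ax}"].abs() > score_thresh)
        )
    return out


def collinearity_screen(env: EnvTable, p_thresh: float = 0.05,
                        r2_thresh: float = 0.5) -> pd.DataFrame:
    """Spearman collinearity screen over all variable pairs with BH-FDR.

    A pair is flagged when the adjusted p is below ``p_thresh`` and the
    squared rank correlation exceeds ``r2_thresh``.
    """
    data = env.data
    if data.shape[0] < 4:
        raise ValidationError("collinearity screen needs at least 4 samples")
    sd = data.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValidationError(
            f"constant environmental columns: {sd.index[sd == 0].tolist()}")
    rows = []
    cols = list(data.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rho, p = stats.spearmanr(data[a], data[b])
            rows.append({"var_a": a, "var_b": b, "rho": rho,
                         "rho2": rho ** 2, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["flagged"] = (out["p_adj"] < p_thresh) & (out["rho2"] > r2_thresh)
    return out


# ---------------------------------------------------------------------------
# Environmental clustering (k-means + similarity profile test)
# ---------------------------------------------------------------------------

def anosim_r(d: np.ndarray, groups: np.ndarray) -> float:
    """ANOSIM R: (mean between-group rank - mean within-group rank) / (M/2)."""
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(d[iu])
    same = (groups[iu[0]] == groups[iu[1]])
    if same.all() or not same.any():
        return 0.0
    rb = ranks[~same].mean()
    rw = ranks[same].mean()
    m = len(ranks)
    return float((rb - rw) / (m / 2.0))


@dataclass
class SimprofResult:
    k: int
    labels: pd.Series
    anosim_r: float
    pi: float
    p_value: float
    significant: bool
    n_perm: int


def simprof_cluster(env: EnvTable, k_range=(2, 10), n_perm: int = 999,
                    alpha: float = 0.05, seed: int | None = None,
                    n_restarts: int = 50) -> SimprofResult:
    """k-means environmental clustering with a similarity-profile check.

    Profiles are z-scored Euclidean; k-means is run for every k in
    ``k_range`` (fixed seed, ``n_restarts`` restarts) and the partition
    with maximal ANOSIM R is kept.  SIMPROF's pi statistic -- the summed
    absolute departure of the ordered dissimilarities from their
    column-permutation null mean -- decides whether any structure is
    significant at ``alpha``.
    """
    Z = zscore(env).to_numpy()
    n = Z.shape[0]
    kmin, kmax = k_range
    if not (2 <= kmin <= kmax <= n - 1):
        raise ValidationError(f"k_range must lie within [2, {n - 1}]")
    rng = np.random.default_rng(seed)
    D = squareform(pdist(Z))

    best = None
    for k in range(kmin, kmax + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=int(rng.integers(2 ** 31)))
        lab = km.fit_predict(Z)
        if len(np.unique(lab)) < 2:
            continue
        r = anosim_r(D, lab)
        if best is None or r > best[1]:
            best = (k, r, lab)
    k, r, labels = best

    # similarity profile: ordered pairwise dissimilarities vs a null in
    # which every variable column is permuted independently
    obs_profile = np.sort(D[np.triu_indices(n, 1)])

    def null_profile():
        Zp = np.column_stack([rng.permutation(Z[:, j]) for j in range(Z.shape[1])])
        Dp = pdist(Zp)
        return np.sort(Dp)

    null_mean = np.mean([null_profile() for _ in range(n_perm)], axis=0)
    pi_obs = float(np.abs(obs_profile - null_mean).sum())
    hits = 0
    for _ in range(n_perm):
        pi_null = float(np.abs(null_profile() - null_mean).sum())
        if pi_null >= pi_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return SimprofResult(k=int(k), labels=pd.Series(labels, index=env.sample_ids,
                                                    name="cluster"),
                         anosim_r=float(r), pi=pi_obs, p_value=float(p),
                         significant=p <= alpha, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Distance decay
# ---------------------------------------------------------------------------

@dataclass
class DistanceDecayResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int


def distance_decay(d_comm: DistanceMatrix, d_geo: DistanceMatrix
                   ) -> DistanceDecayResult:
    """OLS of community dissimilarity on geographic distance over all pairs."""
    if list(d_comm.ids) != list(d_geo.ids):
        if set(d_comm.ids) != set(d_geo.ids):
            raise ValidationError("mismatched sample ids in distance decay")
        d_geo = d_geo.filter(list(d_comm.ids))
    n = len(d_comm.ids)
    if n < 3:
        raise ValidationError("distance decay needs at least 3 samples")
    iu = np.triu_indices(n, 1)
    y, x = d_comm.data[iu], d_geo.data[iu]
    res = stats.linregress(x, y)
    return DistanceDecayResult(slope=float(res.slope),
                               intercept=float(res.intercept),
                               r_squared=float(res.rvalue ** 2),
                               p_value=float(res.pvalue),
                               n_pairs=len(y))
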