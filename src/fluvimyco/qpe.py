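"""Quantitative process estimates: phylogenetic and compositional null
models that partition pairwise community turnover into five assembly
processes.

For a sample pair the abundance-weighted beta mean-nearest-taxon distance

    bMNTD(k, m) = 0.5 * [ sum_{i in k} f_ik min_{j in m} d_ij
                        + sum_{j in m} f_jm min_{i in k} d_ij ]

(f = relative abundance, d = patristic distance) is standardized against a
null that reshuffles OTU labels across the tips of the whole tree, giving
the beta nearest-taxon index bNTI in units of null SDs.  |bNTI| > 2 signals
selection (variable if > 2, homogenizing if < -2).  Pairs without a
selection signal are split by the Raup-Crick-standardized Bray-Curtis
deviation RC_bray in [-1, 1]: > 0.95 dispersal limitation, < -0.95
homogenizing dispersal, otherwise undominated turnover (e.g. drift).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, OtuTable, PhyloTree, ValidationError
from .diversity import tukey_hsd

log = logging.getLogger("fluvimyco")

__all__ = [
    "bmntd", "bnti", "rc_bray", "classify_processes", "process_fractions",
    "compare_process_prevalence", "run_qpe", "QpeResult", "PROCESSES",
]

PROCESSES = ["variable_selection", "homogenizing_selection",
             "dispersal_limitation", "homogenizing_dispersal", "undominated"]

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# beta-MNTD and beta-NTI
# ---------------------------------------------------------------------------

def _aligned_patristic(table: OtuTable, tree: PhyloTree) -> np.ndarray:
    pat = tree.patristic()
    missing = set(table.otu_ids) - set(pat.ids)
    if missing:
        raise ValidationError(f"table OTUs absent from tree: {sorted(missing)}")
    return pat.filter(table.otu_ids).data


def _bmntd_matrix(freq: np.ndarray, supports: list[np.ndarray],
                  D: np.ndarray, perm: np.ndarray | None = None) -> np.ndarray:
    """All-pairs weighted bMNTD; ``perm`` optionally relabels tips."""
    n = freq.shape[0]
    idx = [perm[s] if perm is not None else s for s in supports]
    # min patristic distance from every taxon to each community's members
    dmin = [D[:, cols].min(axis=1) for cols in idx]
    out = np.zeros((n, n))
    for k in range(n):
        fk, ik = freq[k], idx[k]
        for m in range(k + 1, n):
            fm, im = freq[m], idx[m]
            v = 0.5 * (fk[supports[k]] @ dmin[m][ik]
                       + fm[supports[m]] @ dmin[k][im])
            out[k, m] = out[m, k] = v
    return out


def _prep(table: OtuTable) -> tuple[np.ndarray, list[np.ndarray]]:
    freq = table.relative_abundance().to_numpy()
    supports = [np.flatnonzero(row > 0) for row in freq]
    if any(len(s) == 0 for s in supports):
        raise ValidationError("empty sample")
    return freq, supports


def bmntd(table: OtuTable, tree: PhyloTree, weighted: bool = True
          ) -> DistanceMatrix:
    """Abundance-weighted (or unweighted) beta mean nearest taxon distance."""
    D = _aligned_patristic(table, tree)
    freq, supports = _prep(table)
    if not weighted:
        freq = np.zeros_like(freq)
        for i, s in enumerate(supports):
            freq[i, s] = 1.0 / len(s)
    return DistanceMatrix(_bmntd_matrix(freq, supports, D), ids=table.sample_ids)


def bnti(table: OtuTable, tree: PhyloTree, n_null: int = 999,
         seed: int | None = None, weighted: bool = True
         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """beta nearest taxon index: (obs - mean null) / sd null per sample pair.

    The null reshuffles OTU identities across all tree tips ``n_null``
    times.  Returns (bnti, degenerate): pairs whose null SD collapses (all
    shuffles equivalent, e.g. on a star tree) carry bNTI 0 and a True
    degeneracy flag rather than NaN.
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    D = _aligned_patristic(table, tree)
    freq, supports = _prep(table)
    if not weighted:
        freq = np.zeros_like(freq)
        for i, s in enumerate(supports):
            freq[i, s] = 1.0 / len(s)
    obs = _bmntd_matrix(freq, supports, D)
    rng = np.random.default_rng(seed)
    n_taxa = D.shape[0]
    nulls = np.empty((n_null,) + obs.shape)
    for r in range(n_null):
        perm = rng.permutation(n_taxa)
        nulls[r] = _bmntd_matrix(freq, supports, D, perm=perm)
    mu = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    degenerate = sd < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, (obs - mu) / np.where(degenerate, 1.0, sd))
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(degenerate, False)
    ids = table.sample_ids
    return (pd.DataFrame(z, index=ids, columns=ids),
            pd.DataFrame(degenerate, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# Raup-Crick Bray-Curtis
# ---------------------------------------------------------------------------

def rc_bray(table: OtuTable, n_null: int = 999, seed: int | None = None
            ) -> pd.DataFrame:
    """Raup-Crick-standardized Bray-Curtis deviation per sample pair.

    Null communities preserve each sample's observed richness and total
    abundance: taxa enter by weighted sampling without replacement with
    probability proportional to occupancy (number of samples occupied),
    receive one individual each, and the remaining individuals are
    assigned multinomially with probability proportional to regional
    relative abundance.  RC = 2 * ((#{null < obs} + 0.5 #{null = obs}) /
    n_null - 0.5), bounded in [-1, 1].
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    counts = table.counts.to_numpy()
    n, t = counts.shape
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    if regional.sum() == 0:
        raise ValidationError("empty regional pool")
    p_member = occupancy / occupancy.sum()
    p_abund = regional / regional.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)

    rng = np.random.default_rng(seed)
    nulls = np.zeros((n, n_null, t))
    taxa = np.arange(t)
    for s in range(n):
        S, J = int(richness[s]), int(totals[s])
        for r in range(n_null):
            chosen = rng.choice(taxa, size=S, replace=False, p=p_member)
            comm = np.zeros(t)
            comm[chosen] = 1.0
            if J > S:
                w = p_abund[chosen]
                wsum = w.sum()
                w = np.full(S, 1.0 / S) if wsum == 0 else w / wsum
                comm[chosen] += rng.multinomial(J - S, w)
            nulls[s, r] = comm

    def _bc(x, y):
        denom = (x + y).sum(axis=-1)
        return np.abs(x - y).sum(axis=-1) / denom

    ids = table.sample_ids
    out = np.zeros((n, n))
    for k in range(n):
        for m in range(k + 1, n):
            obs = float(_bc(counts[k].astype(float), counts[m].astype(float)))
            null_bc = _bc(nulls[k], nulls[m])
            below = int((null_bc < obs - 1e-12).sum())
            ties = int((np.abs(null_bc - obs) <= 1e-12).sum())
            rc = 2.0 * ((below + 0.5 * ties) / n_null - 0.5)
            out[k, m] = out[m, k] = rc
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Classification & summaries
# ---------------------------------------------------------------------------

def classify_processes(bnti_df: pd.DataFrame, rc_df: pd.DataFrame
                       ) -> pd.DataFrame:
    """Five-way process label per unordered sample pair.

    bNTI > 2 -> variable selection; bNTI < -2 -> homogenizing selection;
    otherwise RC > 0.95 -> dispersal limitation, RC < -0.95 ->
    homogenizing dispersal, else undominated.
    """
    ids = list(bnti_df.index)
    if list(rc_df.index) != ids or list(rc_df.columns) != ids:
        if set(rc_df.index) != set(ids):
            raise ValidationError("bNTI and RC matrices cover different samples")
        rc_df = rc_df.loc[ids, ids]
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            z = float(bnti_df.loc[a, b])
            rc = float(rc_df.loc[a, b])
            if z > BNTI_THRESHOLD:
                label = "variable_selection"
            elif z < -BNTI_THRESHOLD:
                label = "homogenizing_selection"
            elif rc > RC_THRESHOLD:
                label = "dispersal_limitation"
            elif rc < -RC_THRESHOLD:
                label = "homogenizing_dispersal"
            else:
                label = "undominated"
            rows.append({"sample_a": a, "sample_b": b, "bnti": z,
                         "rc_bray": rc, "process": label})
    return pd.DataFrame(rows)


def process_fractions(labels: pd.DataFrame, groups) -> pd.DataFrame:
    """Percentage of within-group sample pairs per process, per group."""
    groups = pd.Series(groups)
    rows = {}
    for g in sorted(groups.unique()):
        members = set(groups.index[groups == g])
        if len(members) < 2:
            log.warning("group %r has fewer than 2 samples; skipped", g)
            continue
        within = labels[labels["sample_a"].isin(members)
                        & labels["sample_b"].isin(members)]
        frac = within["process"].value_counts(normalize=True) * 100.0
        rows[g] = frac.reindex(PROCESSES, fill_value=0.0)
    return pd.DataFrame(rows).T


def compare_process_prevalence(labels: pd.DataFrame, groups) -> pd.DataFrame:
    """Tukey HSD on per-sample process prevalences between groups.

    A sample's prevalence of a process is the fraction of its within-group
    pairs carrying that process; prevalences are compared across groups
    per process.
    """
    groups = pd.Series(groups)
    counts = groups.value_counts()
    usable = counts.index[counts >= 3]
    if len(usable) < 2:
        raise ValidationError("need at least 2 groups with >= 3 samples")
    per_sample = []
    for g in usable:
        members = set(groups.index[groups == g])
        within = labels[labels["sample_a"].isin(members)
                        & labels["sample_b"].isin(members)]
        for s in sorted(members):
            mine = within[(within["sample_a"] == s) | (within["sample_b"] == s)]
            if len(mine) == 0:
                continue
            for proc in PROCESSES:
                per_sample.append({
                    "sample": s, "group": g, "process": proc,
                    "prevalence": float((mine["process"] == proc).mean())})
    prev = pd.DataFrame(per_sample)
    out = []
    for proc in PROCESSES:
        sub = prev[prev["process"] == proc]
        if sub["prevalence"].nunique() > 1:
            hsd = tukey_hsd(sub["prevalence"].to_numpy(), sub["group"].to_numpy())
        else:
            gl = sorted(usable)
            hsd = pd.DataFrame([{"group_a": a, "group_b": b,
                                 "difference": 0.0, "p": 1.0}
                                for i, a in enumerate(gl) for b in gl[i + 1:]])
        hsd.insert(0, "process", proc)
        out.append(hsd)
    return pd.concat(out, ignore_index=True)


@dataclass
class QpeResult:
    bnti: pd.DataFrame
    degenerate: pd.DataFrame
    rc_bray: pd.DataFrame
    labels: pd.DataFrame
    fractions: pd.DataFrame
    n_null: int
    seed: int | None


def run_qpe(table: OtuTable, tree: PhyloTree, groups=None, n_null: int = 999,
        seed: int | None = None, weighted: bool = True) -> QpeResult:
    """Run the full five-process inference on one dataset."""
    z, degen = bnti(table, tree, n_null=n_null, seed=seed, weighted=weighted)
    rc = rc_bray(table, n_null=n_null,
                 seed=None if seed is None else seed + 1)
    labels = classify_processes(z, rc)
    if groups is None:
        groups = pd.Series("all", index=table.sample_ids)
    else:
        groups = pd.Series(groups, index=table.sample_ids
                           if not isinstance(groups, pd.Series) else groups.index)
    fractions = process_fractions(labels, groups)
    return QpeResult(bnti=z, degenerate=degen, rc_bray=rc, labels=labels,
                     fractions=fractions, n_null=n_null, seed=seed)
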