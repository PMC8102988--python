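"""Count transforms, alpha-diversity, rarefaction, abundant-OTU subsetting,
water-type assignment and group tests.

Conventions pinned here: Shannon entropy in nats; Chao1 in its
bias-corrected form (defined even when doubletons are absent); Faith's PD
root-inclusive (the stem from the subtree to the tree root counts); the
brackish interval is closed, [0.5, 30] PSU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .containers import EnvTable, OtuTable, PhyloTree, ValidationError

__all__ = [
    "hellinger", "zscore", "chao1", "shannon", "faith_pd",
    "alpha_diversity_table", "rarefaction_curve", "abundant_otus",
    "water_type", "water_types", "tukey_hsd", "group_frequency_test",
]

PSU_FRESH_MAX = 0.5
PSU_MARINE_MIN = 30.0


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def hellinger(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of relative abundance, rows unit-norm."""
    counts = table.counts if isinstance(table, OtuTable) else table
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("zero row sum in Hellinger transform")
    return np.sqrt(counts.div(totals, axis=0))


def zscore(env: EnvTable | pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sd 1 with the n-1 denominator)."""
    data = env.data if isinstance(env, EnvTable) else env
    sd = data.std(axis=0, ddof=1)
    if (sd == 0).any() or sd.isna().any():
        const = sd.index[(sd == 0) | sd.isna()].tolist()
        raise ValidationError(f"constant environmental columns: {const}")
    return (data - data.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _as_counts(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.size == 0 or arr.sum() == 0:
        raise ValidationError("empty sample")
    if (arr < 0).any():
        raise ValidationError("negative counts")
    return arr


def chao1(sample_counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = _as_counts(sample_counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(sample_counts) -> float:
    """Shannon entropy, natural log, over nonzero proportions."""
    counts = _as_counts(sample_counts)
    return float(stats.entropy(counts[counts > 0]))


def faith_pd(sample_counts, otu_ids, tree: PhyloTree) -> float:
    """Faith's phylogenetic diversity, root-inclusive.

    Sum of branch lengths of the minimal subtree spanning the present
    tips and the root of ``tree``.
    """
    counts = np.asarray(sample_counts)
    if counts.sum() == 0:
        raise ValidationError("empty sample")
    present = [o for o, c in zip(otu_ids, counts) if c > 0]
    missing = set(present) - set(tree.tip_labels)
    if missing:
        raise ValidationError(f"taxa absent from tree: {sorted(missing)}")
    return float(_skbio_faith_pd(counts, taxa=list(otu_ids), tree=tree.tree))


def alpha_diversity_table(table: OtuTable, tree: PhyloTree | None = None
                          ) -> pd.DataFrame:
    """Chao1, Shannon and (when a tree is given) Faith's PD per sample."""
    rows = {}
    for sid in table.sample_ids:
        counts = table.counts.loc[sid].to_numpy()
        row = {"chao1": chao1(counts), "shannon": shannon(counts)}
        if tree is not None:
            row["faith_pd"] = faith_pd(counts, table.otu_ids, tree)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curve(sample_counts, depths) -> pd.Series:
    """Analytic expected richness per subsampling depth.

    E[S_d] = sum_i (1 - C(N - N_i, d) / C(N, d)), evaluated with log-gamma
    for numerical stability; monotone nondecreasing and concave in d.
    """
    counts = _as_counts(sample_counts)
    counts = counts[counts > 0]
    total = int(counts.sum())
    depths = np.asarray(depths, dtype=int)
    if (depths < 1).any() or (depths > total).any():
        raise ValidationError(f"depths must lie in [1, {total}]")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expected = []
    for d in depths:
        keep = (total - counts) >= d
        log_p_absent = np.full(counts.shape, -np.inf)
        log_p_absent[keep] = log_comb(total - counts[keep], d) - log_comb(total, d)
        expected.append(float(np.sum(1.0 - np.exp(log_p_absent))))
    return pd.Series(expected, index=depths, name="expected_richness")


# ---------------------------------------------------------------------------
# Abundant subcommunity & water types
# ---------------------------------------------------------------------------

def abundant_otus(table: OtuTable, coverage: float = 0.9) -> OtuTable:
    """Smallest OTU set whose cumulative relative abundance reaches ``coverage``.

    OTUs ranked by descending total relative abundance; ties broken by OTU
    identifier.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValidationError("coverage must lie in (0, 1]")
    share = table.counts.sum(axis=0) / table.counts.to_numpy().sum()
    order = share.sort_values(ascending=False, kind="mergesort")
    order = order[order > 0]
    # stable re-sort on (share desc, id asc) for the tie rule
    order = order.iloc[np.lexsort((order.index.astype(str), -order.to_numpy()))]
    cum = order.cumsum()
    k = int(np.searchsorted(cum.to_numpy(), coverage - 1e-12) + 1)
    k = min(k, len(order))
    keep = sorted(order.index[:k], key=lambda o: table.otu_ids.index(o))
    return table.subset(otus=keep)


def water_type(salinity_psu: float) -> str:
    """fresh < 0.5 PSU; brackish in [0.5, 30]; marine > 30."""
    if salinity_psu < 0:
        raise ValidationError("negative salinity")
    if salinity_psu < PSU_FRESH_MAX:
        return "fresh"
    if salinity_psu <= PSU_MARINE_MIN:
        return "brackish"
    return "marine"


def water_types(env: EnvTable, column: str = "salinity") -> pd.Series:
    return env.data[column].map(water_type).rename("water_type")


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def tukey_hsd(values, groups) -> pd.DataFrame:
    """Tukey honestly-significant-difference test across group means.

    Returns a long-format table (group_a, group_b, difference, p) based on
    the studentized range distribution; symmetric in group order.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValidationError("tukey_hsd needs at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        small = [g for g, s in zip(labels, samples) if len(s) < 2]
        raise ValidationError(f"groups with fewer than 2 values: {small}")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.tukey_hsd(*samples)
    rows = []
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                rows.append({"group_a": a, "group_b": b,
                             "difference": float(res.statistic[i, j]),
                             "p": float(res.pvalue[i, j])})
    return pd.DataFrame(rows)


@dataclass
class GroupFrequencyResult:
    frequencies: pd.DataFrame  # taxon group x water type occurrence freq
    abundances: pd.DataFrame   # taxon group x water type mean rel. abundance
    tests: pd.DataFrame        # long: taxon_group, group_a, group_b, p (per mode)


def group_frequency_test(table: OtuTable, sample_groups,
                         taxon_groups: pd.Series | None = None,
                         on: str = "occurrence") -> GroupFrequencyResult:
    """Distribution of taxon groups (e.g. basal lineages) over water types.

    For every taxon group: its occurrence frequency (fraction of samples in
    which any member OTU is present) and mean relative abundance per water
    type, plus all pairwise Tukey HSD p-values on the per-sample values.
    ``on`` selects which per-sample value feeds the test: ``occurrence``
    (presence/absence, default) or ``abundance`` (summed relative
    abundance).
    """
    if taxon_groups is None:
        taxon_groups = table.taxon_group
    if taxon_groups is None:
        raise ValidationError("no taxon-group labels available")
    if on not in ("occurrence", "abundance"):
        raise ValueError(f"unknown mode {on!r}")
    sample_groups = pd.Series(sample_groups, index=table.sample_ids
                              if not isinstance(sample_groups, pd.Series)
                              else sample_groups.index)
    sample_groups = sample_groups.reindex(table.sample_ids)
    counts_per_group = sample_groups.value_counts()
    small = counts_per_group[counts_per_group < 2].index.tolist()
    if small:
        raise ValidationError(f"sample groups with fewer than 2 samples: {small}")

    rel = table.relative_abundance()
    freq_rows, abun_rows, test_rows = {}, {}, []
    for tg in sorted(pd.unique(taxon_groups.dropna())):
        members = taxon_groups.index[taxon_groups == tg]
        present = (table.counts[members] > 0).any(axis=1).astype(float)
        tot_rel = rel[members].sum(axis=1)
        freq_rows[tg] = present.groupby(sample_groups).mean()
        abun_rows[tg] = tot_rel.groupby(sample_groups).mean()
        values = present if on == "occurrence" else tot_rel
        if values.nunique() > 1:
            hsd = tukey_hsd(values.to_numpy(), sample_groups.to_numpy())
        else:  # identical values in every sample: no effect by construction
            labels = sorted(counts_per_group.index)
            hsd = pd.DataFrame([{"group_a": a, "group_b": b,
                                 "difference": 0.0, "p": 1.0}
                                for i, a in enumerate(labels)
                                for b in labels[i + 1:]])
        hsd.insert(0, "taxon_group", tg)
        test_rows.append(hsd)
    return GroupFrequencyResult(
        frequencies=pd.DataFrame(freq_rows).T,
        abundances=pd.DataFrame(abun_rows).T,
        tests=pd.concat(test_rows, ignore_index=True),
    )
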