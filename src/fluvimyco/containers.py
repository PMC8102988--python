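"""Core in-memory containers for the transect analysis.

Three thin, validated wrappers are defined here: an OTU count table
(samples x OTUs), a per-sample environmental table carrying the
along-channel coordinate, and a rooted phylogeny.  Pairwise distances are
held in :class:`skbio.DistanceMatrix`, which already enforces symmetry and
a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = ["OtuTable", "EnvTable", "PhyloTree", "DistanceMatrix", "ValidationError"]


class ValidationError(ValueError):
    """An input violated a container invariant."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class OtuTable:
    """Nonnegative integer OTU counts, samples as rows.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer counts, index = sample identifiers, columns = OTU
        identifiers.
    taxon_group : pandas.Series, optional
        A phylum/clade label per OTU (used by the water-type frequency
        tests); indexed by OTU identifier.
    """

    counts: pd.DataFrame
    taxon_group: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.size == 0:
            raise ValidationError("empty OTU table")
        _check_unique(self.counts.index, "sample ids")
        _check_unique(self.counts.columns, "OTU ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric counts in OTU table")
        if np.isnan(arr.astype(float)).any():
            raise ValidationError("NaN counts in OTU table")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"OTU {self.counts.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr.astype(float))):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr.astype(float))))[0]
            raise ValidationError(
                f"non-integer count at sample {self.counts.index[i]!r}, "
                f"OTU {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total counts: {empty}")
        if self.taxon_group is not None:
            self.taxon_group = self.taxon_group.reindex(self.counts.columns)

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by per-sample totals (rows sum to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def subset(self, samples=None, otus=None) -> "OtuTable":
        counts = self.counts
        if samples is not None:
            counts = counts.loc[list(samples)]
        if otus is not None:
            counts = counts[list(otus)]
        tg = None
        if self.taxon_group is not None:
            tg = self.taxon_group.reindex(counts.columns)
        return OtuTable(counts.copy(), tg)


@dataclass
class EnvTable:
    """Per-sample environmental variables plus the along-channel position.

    ``data`` holds the named real-valued columns (salinity in PSU,
    temperature in degC, pH, nutrients in uM, chlorophyll a in ug/L, DOC,
    depth in m, ...); ``channel_km`` is the cumulative water-channel
    coordinate of each station in km.
    """

    data: pd.DataFrame
    channel_km: pd.Series

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise ValidationError("empty environmental table")
        _check_unique(self.data.index, "sample ids")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric environmental data: {exc}")
        self.channel_km = pd.Series(self.channel_km, dtype=float).reindex(self.data.index)
        if self.channel_km.isna().any() or not np.isfinite(self.channel_km).all():
            raise ValidationError("channel_km must be finite for every sample")
        all_nan = [c for c in self.data.columns if self.data[c].isna().all()]
        if all_nan:
            raise ValidationError(f"environmental columns with no data: {all_nan}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, samples) -> "EnvTable":
        samples = list(samples)
        return EnvTable(self.data.loc[samples].copy(), self.channel_km.loc[samples].copy())

    def to_frame(self) -> pd.DataFrame:
        """Variables plus a trailing ``channel_km`` column (the TSV layout)."""
        out = self.data.copy()
        out["channel_km"] = self.channel_km
        return out


class PhyloTree:
    """A rooted phylogeny with nonnegative branch lengths and unique tips.

    Wraps a :class:`skbio.TreeNode`; supplies tip labels in a deterministic
    (postorder) order, cached patristic distances and pruning.
    """

    def __init__(self, tree: TreeNode):
        self._tree = tree
        self._patristic: DistanceMatrix | None = None
        self._validate()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = TreeNode.read(StringIO(newick))
        except Exception as exc:  # skbio raises several parser error types
            raise ValidationError(f"unparseable newick: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        tips = [t.name for t in self._tree.tips()]
        if len(tips) < 2:
            raise ValidationError("tree must have at least 2 tips")
        if any(t is None for t in tips):
            raise ValidationError("unnamed tip in tree")
        _check_unique(tips, "tree tips")
        for node in self._tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise ValidationError(f"negative branch length at node {node.name!r}")
        self._tips = tips

    # -- accessors -------------------------------------------------------
    @property
    def tree(self) -> TreeNode:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def total_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self._tree.traverse(include_self=False)))

    def patristic(self) -> DistanceMatrix:
        """Tip-to-tip path-length (patristic) distance matrix."""
        if self._patristic is None:
            self._patristic = self._tree.tip_tip_distances()
        return self._patristic

    def prune_to(self, tip_names) -> "PhyloTree":
        keep = set(tip_names)
        missing = keep - set(self._tips)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        return PhyloTree(self._tree.shear(keep))

    def to_newick(self) -> str:
        buf = StringIO()
        self._tree.write(buf)
        return buf.getvalue()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips>"
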