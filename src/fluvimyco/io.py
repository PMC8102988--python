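"""Readers, writers, input alignment and run configuration.

All tabular formats are plain TSV (UTF-8, header row, first column =
identifier); trees are standard newick with branch lengths.  The canonical
OTU-table orientation is samples-as-rows; a flag accepts the transposed
dialect.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix, TreeNode

from .containers import EnvTable, OtuTable, PhyloTree, ValidationError

log = logging.getLogger("fluvimyco")

__all__ = [
    "read_otu_table", "write_otu_table",
    "read_env_table", "write_env_table",
    "read_tree", "write_tree",
    "read_distance_matrix", "write_distance_matrix",
    "align_inputs", "Config", "load_config", "save_config",
]

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

def read_otu_table(path, orientation: str = "samples_rows",
                   taxon_group_path=None) -> OtuTable:
    """Read a TSV OTU count table and validate it.

    ``orientation`` is ``samples_rows`` (canonical) or ``otus_rows`` (the
    transposed dialect, normalized on load).  ``taxon_group_path`` may name
    a two-column TSV mapping OTU id to a clade label.
    """
    if orientation not in ("samples_rows", "otus_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.size == 0:
        raise ValidationError(f"empty OTU table: {path}")
    if orientation == "otus_rows":
        df = df.T
    tg = None
    if taxon_group_path is not None:
        tg_df = pd.read_csv(taxon_group_path, sep="\t", index_col=0)
        tg = tg_df.iloc[:, 0]
    return OtuTable(df, tg)


def write_otu_table(table: OtuTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")
    if table.taxon_group is not None:
        tg_path = Path(path).with_suffix(".taxon_groups.tsv")
        table.taxon_group.rename("taxon_group").to_csv(
            tg_path, sep="\t", index_label="otu_id")


# ---------------------------------------------------------------------------
# Environmental table
# ---------------------------------------------------------------------------

def read_env_table(path, impute: str | None = None) -> EnvTable:
    """Read the per-sample environmental TSV (must carry ``channel_km``).

    Missing cells are an error unless ``impute='median'`` is requested
    explicitly, in which case column medians fill the gaps and every filled
    cell is logged.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if "channel_km" not in df.columns:
        raise ValidationError(f"env table {path} lacks a 'channel_km' column")
    km = df.pop("channel_km")
    if df.isna().any().any():
        bad = [(str(i), str(c)) for i, c in zip(*np.where(df.isna().to_numpy()))]
        cells = [(df.index[int(i)], df.columns[int(c)]) for i, c in bad]
        if impute == "median":
            for sid, col in cells:
                df.loc[sid, col] = df[col].median()
                log.warning("imputed env cell (%s, %s) with column median", sid, col)
        else:
            raise ValidationError(f"missing environmental values at {cells}")
    return EnvTable(df, km)


def write_env_table(env: EnvTable, path) -> None:
    env.to_frame().to_csv(path, sep="\t", index_label="sample_id",
                          float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def read_tree(path) -> PhyloTree:
    try:
        tree = TreeNode.read(str(path))
    except Exception as exc:
        raise ValidationError(f"unparseable newick file {path}: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick())


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_data_frame().to_csv(path, sep="\t", index_label="sample_id",
                              float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_inputs(table: OtuTable, tree: PhyloTree, env: EnvTable
                 ) -> tuple[OtuTable, PhyloTree, EnvTable]:
    """Restrict all three inputs to their shared samples and OTUs.

    The OTU table keeps OTUs present as tree tips and samples present in
    the environmental table; the tree is pruned to the retained OTUs; row
    and column orderings are harmonized (table order wins).  Dropped
    identifiers are logged.  Idempotent.
    """
    shared_samples = [s for s in table.sample_ids if s in set(env.sample_ids)]
    if not shared_samples:
        raise ValidationError("no samples shared between OTU table and env table")
    tips = set(tree.tip_labels)
    shared_otus = [o for o in table.otu_ids if o in tips]
    if not shared_otus:
        raise ValidationError("no OTUs shared between OTU table and tree tips")

    dropped_samples = sorted(set(table.sample_ids) - set(shared_samples))
    dropped_env = sorted(set(env.sample_ids) - set(shared_samples))
    dropped_otus = sorted(set(table.otu_ids) - set(shared_otus))
    dropped_tips = sorted(tips - set(shared_otus))
    for what, ids in [("table samples", dropped_samples), ("env samples", dropped_env),
                      ("table OTUs", dropped_otus), ("tree tips", dropped_tips)]:
        if ids:
            log.info("align_inputs dropped %d %s: %s", len(ids), what, ids[:10])

    table2 = table.subset(samples=shared_samples, otus=shared_otus)
    env2 = env.subset(shared_samples)
    tree2 = tree.prune_to(shared_otus) if dropped_tips else tree
    return table2, tree2, env2


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Run configuration with documented defaults.

    permutations: label permutations for every permutation test (>= 1).
    n_null: null-model replicates for the assembly nulls (>= 99).
    seed: global seed; per-stage seeds are derived from it.
    gunifrac_alpha: moderation exponent of the generalized UniFrac.
    coverage: cumulative relative-abundance cut for the abundant-OTU subset.
    """

    otu_table: str | None = None
    tree: str | None = None
    env_table: str | None = None
    taxon_groups: str | None = None
    orientation: str = "samples_rows"
    outdir: str = "results"
    permutations: int = 999
    n_null: int = 999
    seed: int = 42
    gunifrac_alpha: float = 0.5
    gunifrac_on_hellinger: bool = False
    coverage: float = 0.9
    impute_missing: bool = False
    cailliez: bool = False

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValidationError("permutations must be >= 1")
        if self.n_null < 99:
            raise ValidationError("n_null must be >= 99")
        if not 0.0 <= self.gunifrac_alpha <= 1.0:
            raise ValidationError("gunifrac_alpha must lie in [0, 1]")
        if not 0.0 < self.coverage <= 1.0:
            raise ValidationError("coverage must lie in (0, 1]")
        if self.orientation not in ("samples_rows", "otus_rows"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")


def load_config(path=None, **overrides) -> Config:
    """Load a YAML config file; unknown keys are rejected, defaults filled."""
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} is not a mapping")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = set(Config.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return Config(**values)


def save_config(config: Config, path) -> None:
    """Echo the effective settings to ``path`` (round-trips via load_config)."""
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
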