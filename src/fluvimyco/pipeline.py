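"""End-to-end orchestration of the transect analysis with provenance.

Stages run in the workflow order of the underlying survey analysis:
load -> transform (+collinearity screen) -> ordination (GUniFrac PCoA,
PERMANOVA, environment fitting) -> environmental clustering -> alpha
diversity -> distance decay -> spatial (dbMEM, forward selection,
variation partitioning) -> qpe -> water-type tests.  Every stage writes
its outputs before the next starts; a single global seed fans out to
per-stage seeds through a stable hash, so adding a stage never perturbs
the others.  Outputs are plain TSV/JSON and byte-identical across reruns
of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beta, diversity, qpe as qpe_mod, spatial
from .containers import ValidationError
from .io import (Config, FLOAT_FMT, align_inputs, read_distance_matrix,
                 read_env_table, read_otu_table, read_tree, save_config,
                 write_distance_matrix, write_env_table, write_otu_table,
                 write_tree)

log = logging.getLogger("fluvimyco")

__all__ = ["STAGES", "RunManifest", "run_all", "run_stage", "stage_seed"]

STAGES = ["load", "transform", "ordination", "env_clustering", "alpha",
          "distance_decay", "spatial", "qpe", "water_types"]

# files each stage needs from earlier stages (dependency -> producing stage)
_STAGE_DEPS: dict[str, dict[str, str]] = {
    "load": {},
    "transform": {"aligned_otu_table.tsv": "load", "aligned_env_table.tsv": "load"},
    "ordination": {"aligned_otu_table.tsv": "load", "aligned_tree.nwk": "load",
                   "aligned_env_table.tsv": "load"},
    "env_clustering": {"aligned_env_table.tsv": "load"},
    "alpha": {"aligned_otu_table.tsv": "load", "aligned_tree.nwk": "load"},
    "distance_decay": {"gunifrac.tsv": "ordination", "aligned_env_table.tsv": "load"},
    "spatial": {"gunifrac.tsv": "ordination", "aligned_env_table.tsv": "load",
                "dbmem_eigenvectors.tsv": "spatial:self"},
    "qpe": {"aligned_otu_table.tsv": "load", "aligned_tree.nwk": "load",
            "aligned_env_table.tsv": "load"},
    "water_types": {"aligned_otu_table.tsv": "load", "aligned_env_table.tsv": "load"},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from (seed, stage name)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunManifest:
    config_hash: str
    input_digests: dict[str, str]
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, status: str, outputs: list[str]) -> None:
        self.stages.append({"name": name, "status": status,
                            "outputs": sorted(outputs)})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class DependencyError(RuntimeError):
    pass


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _config_hash(config: Config) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path, index_label="sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def _load_aligned(outdir: Path, config: Config):
    table = read_otu_table(outdir / "aligned_otu_table.tsv")
    tg_path = outdir / "aligned_otu_table.taxon_groups.tsv"
    if tg_path.exists():
        table = read_otu_table(outdir / "aligned_otu_table.tsv",
                               taxon_group_path=tg_path)
    tree = read_tree(outdir / "aligned_tree.nwk")
    env = read_env_table(outdir / "aligned_env_table.tsv")
    return table, tree, env


# ---------------------------------------------------------------------------
# Stage implementations (each returns the list of files it wrote)
# ---------------------------------------------------------------------------

def _stage_load(config: Config, outdir: Path) -> list[str]:
    table = read_otu_table(config.otu_table, orientation=config.orientation,
                           taxon_group_path=config.taxon_groups)
    tree = read_tree(config.tree)
    env = read_env_table(config.env_table,
                         impute="median" if config.impute_missing else None)
    table, tree, env = align_inputs(table, tree, env)
    write_otu_table(table, outdir / "aligned_otu_table.tsv")
    write_tree(tree, outdir / "aligned_tree.nwk")
    write_env_table(env, outdir / "aligned_env_table.tsv")
    out = ["aligned_otu_table.tsv", "aligned_tree.nwk", "aligned_env_table.tsv"]
    if table.taxon_group is not None:
        out.append("aligned_otu_table.taxon_groups.tsv")
    return out


def _stage_transform(config: Config, outdir: Path) -> list[str]:
    table, _, env = _load_aligned(outdir, config)
    _write_tsv(diversity.hellinger(table), outdir / "hellinger.tsv")
    _write_tsv(diversity.zscore(env), outdir / "env_zscore.tsv")
    screen = beta.collinearity_screen(env)
    screen.to_csv(outdir / "collinearity.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)
    return ["hellinger.tsv", "env_zscore.tsv", "collinearity.tsv"]


def _stage_ordination(config: Config, outdir: Path) -> list[str]:
    table, tree, env = _load_aligned(outdir, config)
    seed = stage_seed(config.seed, "ordination")
    if config.gunifrac_on_hellinger:
        hel = diversity.hellinger(table)
        scaled = (hel ** 2 * 10 ** 9).round().astype(np.int64)
        gu_table = type(table)(scaled)
    else:
        gu_table = table
    dm = beta.gunifrac(gu_table, tree, alpha=config.gunifrac_alpha)
    write_distance_matrix(dm, outdir / "gunifrac.tsv")
    ordn = beta.pcoa(dm, cailliez=config.cailliez)
    _write_tsv(ordn.coordinates, outdir / "pcoa_coordinates.tsv")
    _write_json({"eigenvalues": [float(v) for v in ordn.eigenvalues],
                 "prop_explained": [float(v) for v in ordn.prop_explained]},
                outdir / "pcoa_eigenvalues.json")
    groups = diversity.water_types(env)
    res = beta.permanova(dm, groups, n_perm=config.permutations, seed=seed)
    payload = {"pseudo_f": res.pseudo_f, "r_squared": res.r_squared,
               "p_value": res.p_value, "n_perm": res.n_perm, "seed": seed,
               "grouping": "water_type"}
    _write_json(payload, outdir / "permanova.json")
    if groups.nunique() >= 3:
        pw = beta.pairwise_permanova(dm, groups, n_perm=config.permutations,
                                     seed=seed)
        pw.to_csv(outdir / "pairwise_permanova.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)
    fit = beta.envfit_axes(ordn, env)
    fit.to_csv(outdir / "envfit.tsv", sep="\t", float_format=FLOAT_FMT)
    out = ["gunifrac.tsv", "pcoa_coordinates.tsv", "pcoa_eigenvalues.json",
           "permanova.json", "envfit.tsv"]
    if groups.nunique() >= 3:
        out.append("pairwise_permanova.tsv")
    return out


def _stage_env_clustering(config: Config, outdir: Path) -> list[str]:
    _, _, env = _load_aligned(outdir, config)
    seed = stage_seed(config.seed, "env_clustering")
    res = beta.simprof_cluster(env, n_perm=config.permutations, seed=seed)
    res.labels.to_csv(outdir / "env_clusters.tsv", sep="\t",
                      index_label="sample_id")
    _write_json({"k": res.k, "anosim_r": res.anosim_r, "pi": res.pi,
                 "p_value": res.p_value, "significant": bool(res.significant),
                 "n_perm": res.n_perm, "seed": seed},
                outdir / "simprof.json")
    return ["env_clusters.tsv", "simprof.json"]


def _stage_alpha(config: Config, outdir: Path) -> list[str]:
    table, tree, env = _load_aligned(outdir, config)
    alpha = diversity.alpha_diversity_table(table, tree)
    _write_tsv(alpha, outdir / "alpha_diversity.tsv")
    groups = diversity.water_types(env)
    out = ["alpha_diversity.tsv"]
    if groups.value_counts().min() >= 2 and groups.nunique() >= 2:
        tests = []
        for metric in alpha.columns:
            t = diversity.tukey_hsd(alpha[metric].to_numpy(), groups.to_numpy())
            t.insert(0, "metric", metric)
            tests.append(t)
        pd.concat(tests, ignore_index=True).to_csv(
            outdir / "alpha_tukey.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT)
        out.append("alpha_tukey.tsv")
    return out


def _stage_distance_decay(config: Config, outdir: Path) -> list[str]:
    _, _, env = _load_aligned(outdir, config)
    dm = read_distance_matrix(outdir / "gunifrac.tsv")
    geo = spatial.geographic_distance(env.channel_km)
    res = beta.distance_decay(dm, geo)
    _write_json({"slope": res.slope, "intercept": res.intercept,
                 "r_squared": res.r_squared, "p_value": res.p_value,
                 "n_pairs": res.n_pairs}, outdir / "distance_decay.json")
    return ["distance_decay.json"]


def _stage_spatial(config: Config, outdir: Path) -> list[str]:
    _, _, env = _load_aligned(outdir, config)
    dm = read_distance_matrix(outdir / "gunifrac.tsv")
    seed = stage_seed(config.seed, "spatial")
    model = spatial.dbmem(env.channel_km)
    _write_tsv(model.eigenvectors, outdir / "dbmem_eigenvectors.tsv")
    scal = pd.DataFrame({"morans_i": model.morans_i,
                         "eigenvalue": model.eigenvalues[:len(model.morans_i)]})
    _write_tsv(scal, outdir / "scalogram.tsv", index_label="eigenvector")

    sel = spatial.forward_select(dm, model.candidates, n_perm=config.permutations,
                                 seed=seed)
    sel.to_csv(outdir / "forward_selection_space.tsv", sep="\t", index=False,
               float_format=FLOAT_FMT)
    model.selected = sel["variable"].tolist()

    envz = diversity.zscore(env)
    screen = beta.collinearity_screen(env)
    drop = set()
    for _, row in screen[screen["flagged"]].iterrows():
        # of each collinear pair keep the first variable, drop the second
        if row["var_a"] not in drop:
            drop.add(row["var_b"])
    env_candidates = envz[[c for c in envz.columns if c not in drop]]
    sel_env = spatial.forward_select(dm, env_candidates,
                                     n_perm=config.permutations, seed=seed + 1)
    sel_env.to_csv(outdir / "forward_selection_env.tsv", sep="\t", index=False,
                   float_format=FLOAT_FMT)

    outputs = ["dbmem_eigenvectors.tsv", "scalogram.tsv",
               "forward_selection_space.tsv", "forward_selection_env.tsv"]

    spat_sel = model.selected or list(model.candidates.columns[:2])
    env_sel = (sel_env["variable"].tolist()
               or list(env_candidates.columns[:2]))
    if len(spat_sel) >= 2:
        model.submodel = spatial.scalogram_split(model.morans_i[spat_sel])
        _write_json(model.submodel, outdir / "scalogram_submodels.json")
        outputs.append("scalogram_submodels.json")
        submodels = {
            "broad": [k for k, v in model.submodel.items() if v == "broad"],
            "small": [k for k, v in model.submodel.items() if v == "small"],
        }
    else:
        submodels = {"all": spat_sel}
    vp_out = {}
    for name, mems in submodels.items():
        if not mems:
            continue
        vp = spatial.varpart(dm, env_candidates[env_sel],
                             model.eigenvectors[mems])
        vp_out[name] = vp.as_dict()
    _write_json({"submodels": vp_out, "env_model": env_sel,
                 "spatial_selected": spat_sel}, outdir / "varpart.json")
    outputs.append("varpart.json")
    return outputs


def _stage_qpe(config: Config, outdir: Path) -> list[str]:
    table, tree, env = _load_aligned(outdir, config)
    seed = stage_seed(config.seed, "qpe")
    groups = diversity.water_types(env)
    res = qpe_mod.run_qpe(table, tree, groups=groups, n_null=config.n_null,
                      seed=seed)
    _write_tsv(res.bnti, outdir / "bnti.tsv")
    _write_tsv(res.rc_bray, outdir / "rcbray.tsv")
    res.labels.to_csv(outdir / "process_labels.tsv", sep="\t", index=False,
                      float_format=FLOAT_FMT)
    _write_tsv(res.fractions, outdir / "process_fractions.tsv",
               index_label="group")
    _write_json({"n_null": res.n_null, "seed": seed,
                 "degenerate_pairs": int(res.degenerate.to_numpy().sum() // 2)},
                outdir / "qpe_summary.json")
    out = ["bnti.tsv", "rcbray.tsv", "process_labels.tsv",
           "process_fractions.tsv", "qpe_summary.json"]
    if (groups.value_counts() >= 3).sum() >= 2:
        comp = qpe_mod.compare_process_prevalence(res.labels, groups)
        comp.to_csv(outdir / "process_prevalence_tests.tsv", sep="\t",
                    index=False, float_format=FLOAT_FMT)
        out.append("process_prevalence_tests.tsv")
    return out


def _stage_water_types(config: Config, outdir: Path) -> list[str]:
    table, tree, env = _load_aligned(outdir, config)
    wt = diversity.water_types(env)
    wt.to_csv(outdir / "water_types.tsv", sep="\t", index_label="sample_id")
    out = ["water_types.tsv"]
    taxon_groups = table.taxon_group
    if taxon_groups is not None and wt.value_counts().min() >= 2:
        res = diversity.group_frequency_test(table, wt, taxon_groups)
        _write_tsv(res.frequencies, outdir / "lineage_frequencies.tsv",
                   index_label="taxon_group")
        res.tests.to_csv(outdir / "lineage_tests.tsv", sep="\t", index=False,
                         float_format=FLOAT_FMT)
        out += ["lineage_frequencies.tsv", "lineage_tests.tsv"]
    return out


_STAGE_FUNCS = {
    "load": _stage_load,
    "transform": _stage_transform,
    "ordination": _stage_ordination,
    "env_clustering": _stage_env_clustering,
    "alpha": _stage_alpha,
    "distance_decay": _stage_distance_decay,
    "spatial": _stage_spatial,
    "qpe": _stage_qpe,
    "water_types": _stage_water_types,
}


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def _check_deps(name: str, outdir: Path) -> None:
    for fname, producer in _STAGE_DEPS.get(name, {}).items():
        if producer.endswith(":self"):
            continue
        if not (outdir / fname).exists():
            raise DependencyError(
                f"stage {name!r} needs {fname!r}; run stage {producer!r} first")


def run_stage(name: str, config: Config) -> list[str]:
    """Run one stage in isolation (dependencies must exist in outdir)."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; valid stages: {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_deps(name, outdir)
    return _STAGE_FUNCS[name](config, outdir)


def run_all(config: Config) -> RunManifest:
    """Execute every stage in order, writing a reproducible manifest.

    Any stage error aborts the run; the partial manifest (with the failed
    stage marked) is still written to ``<outdir>/manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config_echo.yaml")
    digests = {}
    for key in ("otu_table", "tree", "env_table", "taxon_groups"):
        path = getattr(config, key)
        if path:
            digests[key] = _digest(path)
    manifest = RunManifest(config_hash=_config_hash(config),
                           input_digests=digests, seed=config.seed)
    for name in STAGES:
        try:
            outputs = run_stage(name, config)
        except Exception as exc:
            manifest.record(name, f"failed: {exc}", [])
            manifest.write(outdir / "manifest.json")
            raise StageError(name, exc) from exc
        manifest.record(name, "completed", outputs)
        log.info("stage %s completed (%d outputs)", name, len(outputs))
    manifest.write(outdir / "manifest.json")
    return manifest
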