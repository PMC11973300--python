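"""Orchestrate the full RMP / GCN-RMP / FACS-QMP / spike-QMP comparison.

One call runs, for every requested taxonomic rank and unit system: taxon
filtering, paired differential-abundance tests with BH correction and
fold changes, alpha-diversity, generalized-UniFrac distances with
PERMANOVA, and a cross-system discordance table listing taxa whose
significance calls disagree between unit systems — the core deliverable
when contrasting relative and absolute profiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from qmp import gcn as gcn_mod
from qmp import quantify, stats
from qmp.simulate import StudyBundle
from qmp.tables_io import (
    CountTable, StudyDesign, ValidationError,
    read_cell_counts, read_count_table, read_design, read_gcn_table,
    read_newick, read_taxonomy, write_results,
)

logger = logging.getLogger("qmp")

UNIT_SYSTEMS = ("rmp", "rmp_gcn", "facs", "spike")


@dataclass
class RunConfig:
    """Paths and knobs for one end-to-end run."""

    counts_path: str | Path
    taxonomy_path: str | Path
    gcn_path: str | Path
    facs_path: str | Path
    design_path: str | Path
    spike_yaml: str | Path
    tree_path: str | Path | None = None
    ranks: tuple[str, ...] = ("phylum", "family", "genus")
    unit_systems: tuple[str, ...] = UNIT_SYSTEMS
    prevalence_min: float = 0.30
    relab_min: float = 0.0025
    comparisons: tuple[tuple[str, str], ...] | None = None  # None: d0 vs later
    unifrac_alpha: float = 0.5
    n_perm: int = 999
    seed: int = 0
    output_dir: str | Path = "results/run"

    def __post_init__(self) -> None:
        for t in (self.prevalence_min, self.relab_min):
            if not 0 <= t <= 1:
                raise ValidationError("filter thresholds must lie in [0, 1]")
        unknown = set(self.unit_systems) - set(UNIT_SYSTEMS)
        if unknown:
            raise ValidationError(f"unknown unit systems {sorted(unknown)}")


@dataclass
class StudyResults:
    """In-memory results of one run, keyed the way they are written."""

    abundances: dict[tuple[str, str], pd.DataFrame]  # (rank, unit) -> matrix
    diff_tests: pd.DataFrame
    diversity: pd.DataFrame
    permanova: pd.DataFrame | None
    discordance: pd.DataFrame
    filtered_taxa: dict[str, list[str]]
    totals: dict[str, pd.Series]
    log: list[str] = field(default_factory=list)


def load_bundle_from_paths(cfg: RunConfig) -> StudyBundle:
    counts = read_count_table(cfg.counts_path)
    taxonomy = read_taxonomy(cfg.taxonomy_path)
    gcn = read_gcn_table(cfg.gcn_path)
    facs = read_cell_counts(cfg.facs_path)
    design = read_design(cfg.design_path)
    spike_cfg = quantify.SpikeConfig.from_yaml(cfg.spike_yaml)
    tree = read_newick(cfg.tree_path) if cfg.tree_path else None
    chain = quantify.DilutionChain()
    return StudyBundle(counts, taxonomy, gcn, facs, design, spike_cfg,
                       tree, truth=None, chain=chain)


def _comparisons(design: StudyDesign,
                 requested: tuple[tuple[str, str], ...] | None) -> list[tuple[str, str]]:
    if requested:
        return list(requested)
    tps = list(pd.unique(design.data["timepoint"]))
    return [(tps[0], t) for t in tps[1:]]


def compute_unit_totals(bundle: StudyBundle, bio: CountTable,
                        spike_reads: pd.Series,
                        systems: tuple[str, ...]) -> dict[str, pd.Series]:
    """Per-sample totals for the absolute unit systems."""
    totals: dict[str, pd.Series] = {}
    if "facs" in systems:
        totals["facs"] = quantify.cell_counts_from_table(bundle.facs, chain=bundle.chain)
    if "spike" in systems:
        if bundle.spike_cfg is None:
            raise ValidationError("spike unit system requested but no spike config")
        copies = quantify.spike_copies_per_gram(
            bio.totals(), spike_reads, bundle.spike_cfg)
        totals["spike"] = quantify.harmonize_to_reference(copies, bundle.spike_cfg)
    return totals


def run_study(bundle: StudyBundle, cfg: RunConfig) -> StudyResults:
    """Execute the full comparison on an in-memory bundle."""
    log: list[str] = [f"seed={cfg.seed}", f"prevalence_min={cfg.prevalence_min}",
                      f"relab_min={cfg.relab_min}", f"n_perm={cfg.n_perm}"]
    bio, spike_reads = quantify.strip_spikes(bundle.counts, bundle.spike_cfg)
    corrected = gcn_mod.correct_gcn(bio, bundle.gcn)
    totals = compute_unit_totals(bundle, bio, spike_reads, cfg.unit_systems)
    for name, t in totals.items():
        log.append(f"{name}_total_median={t.median():.4g}")

    comparisons = _comparisons(bundle.design, cfg.comparisons)
    groups = {
        f"{g}:{tp}": list(sub.index)
        for (g, tp), sub in bundle.design.data.groupby(["group", "timepoint"])
    }

    abundances: dict[tuple[str, str], pd.DataFrame] = {}
    filtered: dict[str, list[str]] = {}
    tests = []
    for rank in cfg.ranks:
        raw_rank = gcn_mod.aggregate_rank(bio.data, bundle.taxonomy, rank)
        cor_rank = gcn_mod.aggregate_rank(corrected.data, bundle.taxonomy, rank)
        rel_raw = quantify.total_sum_scaling(raw_rank)
        rel_cor = quantify.total_sum_scaling(cor_rank)
        keep = stats.filter_taxa(rel_cor, groups, cfg.prevalence_min, cfg.relab_min)
        filtered[rank] = keep
        log.append(f"rank={rank}: {len(keep)}/{rel_cor.shape[1]} taxa retained")
        mats = {"rmp": rel_raw, "rmp_gcn": rel_cor}
        for sysname in ("facs", "spike"):
            if sysname in cfg.unit_systems:
                mats[sysname] = quantify.integrate_cell_counts(rel_cor, totals[sysname])
        for sysname in cfg.unit_systems:
            mat = mats[sysname][keep]
            abundances[(rank, sysname)] = mat
            for t0, t1 in comparisons:
                pairs = bundle.design.paired_samples(t0, t1)
                pairs = pairs[pairs["sample_t0"].isin(mat.index)
                              & pairs["sample_t1"].isin(mat.index)]
                res = stats.paired_taxon_tests(
                    mat, pairs, comparison=f"{t0}_vs_{t1}", unit=sysname)
                res.insert(0, "rank", rank)
                tests.append(res)
    diff_tests = pd.concat(tests, ignore_index=True) if tests else pd.DataFrame()

    # alpha diversity on GCN-corrected ASV-level fractions
    rel_asv = quantify.total_sum_scaling(corrected.data)
    diversity = pd.DataFrame({
        "richness": rel_asv.gt(0).sum(axis=1),
        "shannon_effective": [stats.shannon_effective(r) for _, r in rel_asv.iterrows()],
    })
    diversity.index.name = "sample_id"

    perm_table = None
    if bundle.tree is not None:
        dm = stats.unifrac_distance_matrix(bundle.tree, rel_asv, alpha=cfg.unifrac_alpha)
        tp = bundle.design.data["timepoint"].reindex(dm.index)
        rows = []
        whole = stats.permanova(dm, tp, n_perm=cfg.n_perm, seed=cfg.seed)
        rows.append({"comparison": "all_timepoints", "pseudo_F": whole.pseudo_f,
                     "R2": whole.r_squared, "p": whole.p_value})
        if tp.nunique() > 2:
            pw = stats.pairwise_permanova(dm, tp, n_perm=cfg.n_perm, seed=cfg.seed)
            for _, r in pw.iterrows():
                rows.append({"comparison": f"{r['group_a']}_vs_{r['group_b']}",
                             "pseudo_F": r["pseudo_F"], "R2": r["R2"], "p": r["p"]})
        perm_table = pd.DataFrame(rows)

    discordance = summarize_discordance(diff_tests)
    return StudyResults(abundances, diff_tests, diversity, perm_table,
                        discordance, filtered, totals, log)


def summarize_discordance(diff_tests: pd.DataFrame,
                          flag_col: str = "significant_p") -> pd.DataFrame:
    """Cross-system comparison of significance calls.

    One row per (rank, comparison, taxon): the significance flag and fold
    change under every unit system, plus a label — "concordant" when all
    systems agree, otherwise the set of systems that flag the taxon
    (e.g. "facs-only").
    """
    if diff_tests.empty:
        return pd.DataFrame()
    systems = list(diff_tests["unit"].unique())
    if len(systems) < 2:
        raise ValidationError("discordance summary needs >= 2 unit systems")
    wide_sig = diff_tests.pivot_table(
        index=["rank", "comparison", "taxon"], columns="unit",
        values=flag_col, aggfunc="first")
    wide_fc = diff_tests.pivot_table(
        index=["rank", "comparison", "taxon"], columns="unit",
        values="fold_change", aggfunc="first")
    if wide_sig.isna().any().any():
        raise ValidationError("unit systems were run on mismatched taxa sets")
    out = pd.concat(
        {"significant": wide_sig.astype(bool), "fold_change": wide_fc}, axis=1)
    labels = []
    for _, row in wide_sig.iterrows():
        flagged = [s for s in systems if bool(row[s])]
        if len(flagged) == 0 or len(flagged) == len(systems):
            labels.append("concordant")
        elif len(flagged) == 1:
            labels.append(f"{flagged[0]}-only")
        else:
            labels.append("+".join(sorted(flagged)))
    out["label"] = labels
    return out


def write_study_results(results: StudyResults, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {
        "differential_abundance": results.diff_tests,
        "diversity": results.diversity,
        "discordance": results.discordance,
    }
    if results.permanova is not None:
        tables["permanova"] = results.permanova
    for (rank, unit), mat in results.abundances.items():
        tables[f"abundance_{rank}_{unit}"] = mat
    paths = write_results(tables, outdir)
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(results.log) + "\n")
    return {p.stem: p for p in paths} | {"run_log": log_path}


def run_study_from_config(cfg: RunConfig) -> StudyResults:
    """Load inputs from paths, run, and write the results directory."""
    bundle = load_bundle_from_paths(cfg)
    results = run_study(bundle, cfg)
    write_study_results(results, cfg.output_dir)
    return results
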