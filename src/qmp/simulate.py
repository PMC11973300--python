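"""Synthetic study generator with known ground truth.

Emulates a small antibiotic-perturbation trial: per-subject faecal
communities with log-normal taxon and total-load variation (day-0 totals
spanning roughly 7e7 to 2.5e8 cells per gram, as seen in piglet faeces),
a treatment that multiplies the absolute abundance of chosen taxa by a
true fold change, amplicon sequencing with 16S gene-copy-number bias and
synthetic spike-in standards sampled multinomially at fixed depth, and
noisy triplicate flow-cytometry totals.

Everything the real pipeline consumes (counts incl. spikes, taxonomy,
GCN table, FACS triplicates, design, spike config, tree) is produced,
alongside the generating truth, so recovery of known fold changes — and
the directional artifacts of purely relative profiling — can be asserted
exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from qmp.quantify import DilutionChain, SpikeConfig
from qmp.tables_io import CountTable, GcnTable, StudyDesign, TaxonomyMap, RANKS, ValidationError

# GCN distribution over {1..9}: ~27% of taxa multi-copy, most of those
# with 2-5 copies, a thin tail up to 9 (as in gut 16S surveys).
DEFAULT_GCN_PROBS: dict[int, float] = {
    1: 0.731, 2: 0.080, 3: 0.070, 4: 0.050, 5: 0.040,
    6: 0.012, 7: 0.000, 8: 0.009, 9: 0.008,
}


@dataclass
class CommunitySpec:
    """Generating conditions for one synthetic trial.

    Defaults mirror the study scale: 6 subjects sampled before (d0) and
    one day after (d1) treatment, a community whose dominant taxon holds
    ~35% of cells and is knocked down to a true fold change of 0.3, total
    loads centred on 9.15e7 cells/g with ~0.35 log-sd across subjects,
    30k reads per sample, a 5% spike read fraction at the mean load, and
    15% CV flow-cytometry noise.
    """

    n_subjects: int = 6
    timepoints: tuple[str, ...] = ("d0", "d1")
    n_taxa: int = 60
    genera_per_family: int = 5
    families_per_phylum: int = 4
    base_total_cells_per_g: float = 9.15e7
    taxon_log_sd: float = 1.5
    dominant_share: float = 0.35
    total_load_log_sd: float = 0.35
    subject_taxon_log_sd: float = 0.15
    effect_fc: float = 0.3
    n_affected: int = 1
    affect_dominant: bool = True
    gcn_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_GCN_PROBS))
    read_depth: int = 30_000
    n_spikes: int = 13
    spike_fraction_target: float = 0.05
    sample_mass_g: float = 0.5
    facs_mass_g: float = 0.1
    facs_cv: float = 0.15
    group_label: str = "treated"

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValidationError("spec needs at least one taxon")
        if self.effect_fc <= 0:
            raise ValidationError("true fold changes must be positive")
        if self.read_depth <= 0:
            raise ValidationError("read depth must be positive")

    def taxon_ids(self) -> list[str]:
        return [f"ASV_{i:03d}" for i in range(1, self.n_taxa + 1)]

    def spike_ids(self) -> list[str]:
        return [f"SPIKE_{i:02d}" for i in range(1, self.n_spikes + 1)]


@dataclass
class GroundTruth:
    """True cells/g per (sample, taxon), plus the generating parameters."""

    abundance: pd.DataFrame          # samples x taxa, cells per gram
    design: StudyDesign
    true_fc: pd.Series               # taxon -> true fold change
    gcn: GcnTable
    base_fractions: pd.Series

    def totals(self) -> pd.Series:
        return self.abundance.sum(axis=1)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv ** 2)))


def make_taxonomy(spec: CommunitySpec) -> TaxonomyMap:
    """Deterministic nested template: every ASV its own genus, genera
    grouped into families, families into phyla."""
    rows = {}
    for i, taxon in enumerate(spec.taxon_ids()):
        genus = i
        family = genus // spec.genera_per_family
        phylum = family // spec.families_per_phylum
        rows[taxon] = [
            "Bacteria", f"Phylum_{phylum + 1:02d}", f"Class_{phylum + 1:02d}",
            f"Order_{family + 1:02d}", f"Family_{family + 1:02d}",
            f"Genus_{genus + 1:03d}",
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "taxon_id"
    return TaxonomyMap(df)


def make_tree(spec: CommunitySpec) -> TreeNode:
    """Rooted tree following the taxonomy nesting, unit branch lengths."""
    taxonomy = make_taxonomy(spec).data
    phyla: dict[str, dict[str, list[str]]] = {}
    for taxon, row in taxonomy.iterrows():
        phyla.setdefault(row["phylum"], {}).setdefault(row["family"], []).append(taxon)
    parts = []
    for fam_map in phyla.values():
        fams = [
            "(" + ",".join(f"{t}:1" for t in tips) + "):1"
            for tips in fam_map.values()
        ]
        parts.append("(" + ",".join(fams) + "):1" if len(fams) > 1 else fams[0])
    newick = "(" + ",".join(parts) + ");"
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


def simulate_community(spec: CommunitySpec, seed: int) -> GroundTruth:
    """Draw true absolute trajectories for every subject and timepoint."""
    rng = np.random.default_rng(seed)
    taxa = spec.taxon_ids()

    # baseline composition: heavy-tailed fractions with a pinned dominant taxon
    raw = rng.lognormal(0.0, spec.taxon_log_sd, size=spec.n_taxa)
    fractions = raw / raw.sum()
    if spec.dominant_share > 0 and spec.n_taxa > 1:
        rest = 1.0 - spec.dominant_share
        others = fractions[1:] / fractions[1:].sum() * rest
        fractions = np.concatenate([[spec.dominant_share], others])
    base_fractions = pd.Series(fractions, index=taxa)

    # treatment effect
    fc = pd.Series(1.0, index=taxa)
    if spec.n_affected > 0:
        if spec.affect_dominant:
            affected = list(base_fractions.sort_values(ascending=False).index[: spec.n_affected])
        else:
            affected = list(rng.choice(taxa, size=spec.n_affected, replace=False))
        fc[affected] = spec.effect_fc

    gcn_values = np.array(list(spec.gcn_probs.keys()))
    gcn_probs = np.array(list(spec.gcn_probs.values()), dtype=float)
    gcn = pd.Series(
        rng.choice(gcn_values, size=spec.n_taxa, p=gcn_probs / gcn_probs.sum()),
        index=taxa, dtype=float,
    )

    loads = rng.lognormal(0.0, spec.total_load_log_sd, size=spec.n_subjects)
    rows, design_rows = {}, {}
    for s in range(spec.n_subjects):
        subject = f"S{s + 1}"
        for ti, tp in enumerate(spec.timepoints):
            sample = f"{subject}_{tp}"
            effect = fc.values if ti > 0 else np.ones(spec.n_taxa)
            noise = rng.lognormal(0.0, spec.subject_taxon_log_sd, size=spec.n_taxa)
            rows[sample] = (
                base_fractions.values * spec.base_total_cells_per_g
                * loads[s] * effect * noise
            )
            design_rows[sample] = [subject, tp, spec.group_label]
    abundance = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    abundance.index.name = "sample_id"
    design = StudyDesign(pd.DataFrame.from_dict(
        design_rows, orient="index", columns=["subject", "timepoint", "group"]))
    return GroundTruth(abundance, design, fc, GcnTable(gcn), base_fractions)


def spike_copies_for_target(truth: GroundTruth, spec: CommunitySpec) -> float:
    """Spike copies per sample giving the target expected spike read
    fraction at the cohort-mean biological 16S load."""
    bio_copies = (truth.abundance * truth.gcn.data).sum(axis=1) * spec.sample_mass_g
    mean_bio = float(bio_copies.mean())
    t = spec.spike_fraction_target
    return t / (1.0 - t) * mean_bio


def simulate_sequencing(truth: GroundTruth, spec: CommunitySpec, seed: int,
                        spike_copies: float | None = None
                        ) -> tuple[CountTable, SpikeConfig]:
    """Multinomial reads at fixed depth with GCN bias and spike-ins.

    Read probabilities for biological taxa are proportional to
    true cells/g x GCN x sample mass (total 16S copies in the tube); the
    constant spike pool contributes its own copies, so the spike read
    share falls as the biological load rises — the premise that makes
    spike reads a load estimator.
    """
    rng = np.random.default_rng(seed)
    if spike_copies is None:
        spike_copies = spike_copies_for_target(truth, spec)
    taxa, spikes = list(truth.abundance.columns), spec.spike_ids()
    per_spike = spike_copies / max(spec.n_spikes, 1)
    counts = {}
    for sample, row in truth.abundance.iterrows():
        bio = row.values * truth.gcn.data.values * spec.sample_mass_g
        weights = np.concatenate([bio, np.full(spec.n_spikes, per_spike)])
        total = weights.sum()
        if total <= 0:
            raise ValidationError(f"sample {sample!r} has zero total copies")
        counts[sample] = rng.multinomial(spec.read_depth, weights / total)
    df = pd.DataFrame.from_dict(counts, orient="index", columns=taxa + spikes)
    df.index.name = "sample_id"
    reference = truth.abundance.index[0]
    cfg = SpikeConfig(
        spike_taxon_ids=tuple(spikes),
        spike_copies_added=float(spike_copies),
        sample_mass_g={s: spec.sample_mass_g for s in truth.abundance.index},
        reference_sample_id=str(reference),
        reference_facs_count=float("nan"),  # filled once FACS is simulated
    )
    return CountTable(df.astype(float), unit="reads"), cfg


def simulate_facs(truth: GroundTruth, spec: CommunitySpec, seed: int,
                  chain: DilutionChain | None = None) -> pd.DataFrame:
    """Noisy triplicate cytometer events per sample.

    Each 0.1-g aliquot reports events consistent with the true total
    times independent log-normal noise of the configured CV, pushed
    backwards through the dilution chain.
    """
    rng = np.random.default_rng(seed)
    chain = chain or DilutionChain()
    sigma = _lognormal_sigma(spec.facs_cv)
    rows = {}
    for sample, total in truth.totals().items():
        noise = rng.lognormal(0.0, sigma, size=3) if sigma > 0 else np.ones(3)
        events = [
            chain.cells_per_gram_to_events(total * z, spec.facs_mass_g)
            for z in noise
        ]
        rows[sample] = events + [spec.facs_mass_g]
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["event_rep1", "event_rep2", "event_rep3", "mass_g"])
    df.index.name = "sample_id"
    return df


@dataclass
class StudyBundle:
    """Everything the analysis pipeline consumes, plus the truth."""

    counts: CountTable               # incl. spike columns
    taxonomy: TaxonomyMap
    gcn: GcnTable
    facs: pd.DataFrame
    design: StudyDesign
    spike_cfg: SpikeConfig
    tree: TreeNode
    truth: GroundTruth
    chain: DilutionChain


def simulate_study(spec: CommunitySpec, seed: int) -> StudyBundle:
    """Run the three generators with independent substreams of ``seed``
    and anchor the spike reference to its simulated FACS count."""
    ss = np.random.SeedSequence(seed)
    s_comm, s_seq, s_facs = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(3))
    truth = simulate_community(spec, s_comm)
    counts, cfg = simulate_sequencing(truth, spec, s_seq)
    chain = DilutionChain()
    facs = simulate_facs(truth, spec, s_facs, chain=chain)
    from qmp.quantify import cell_counts_from_table
    facs_totals = cell_counts_from_table(facs, chain=chain)
    cfg.reference_facs_count = float(facs_totals[cfg.reference_sample_id])
    return StudyBundle(counts, make_taxonomy(spec), truth.gcn, facs,
                       truth.design, cfg, make_tree(spec), truth, chain)


def write_bundle(bundle: StudyBundle, outdir) -> dict[str, Path]:
    """Write the full input bundle (and truth) as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _tsv(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t")
        paths[name] = p

    _tsv("counts", bundle.counts.data.rename_axis("sample_id"))
    lineage = bundle.taxonomy.data.apply(lambda r: ";".join(r), axis=1)
    _tsv("taxonomy", lineage.rename("lineage").to_frame())
    _tsv("gcn", bundle.gcn.data.rename("gcn").rename_axis("taxon_id").to_frame())
    _tsv("facs", bundle.facs)
    _tsv("design", bundle.design.data.rename_axis("sample_id"))
    _tsv("truth_abundance", bundle.truth.abundance)
    _tsv("truth_fold_change", bundle.truth.true_fc.rename("true_fc")
         .rename_axis("taxon_id").to_frame())
    spike_path = outdir / "spike.yaml"
    bundle.spike_cfg.to_yaml(spike_path)
    paths["spike"] = spike_path
    tree_path = outdir / "tree.nwk"
    bundle.tree.write(str(tree_path))
    paths["tree"] = tree_path
    return paths
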