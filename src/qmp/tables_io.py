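"""Typed I/O for every tabular and tree artifact the pipeline touches.

All tables are TSV. Count tables are normalized to samples-in-rows; a
dialect flag accepts the taxa-in-rows orientation that DADA2 exports
commonly use. Validation is strict and names the offending record.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("qmp")

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

COUNT_UNITS = ("reads", "gcn_corrected_reads")


class ValidationError(ValueError):
    """An input table violates one of its declared invariants."""


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative read counts.

    ``unit`` records whether the counts are raw sequencer reads or have
    already been divided by per-taxon 16S gene copy numbers. ``provenance``
    accumulates a human-readable list of corrections applied.
    """

    data: pd.DataFrame  # rows = samples, columns = taxa
    unit: str = "reads"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit not in COUNT_UNITS:
            raise ValidationError(f"unknown count unit {self.unit!r}")
        self.data.index.name = "sample_id"
        self.data.columns.name = "taxon_id"
        _check_unique(self.data.index, "sample_id")
        _check_unique(self.data.columns, "taxon_id")
        neg = self.data.lt(0)
        if neg.any().any():
            s = self.data.index[neg.any(axis=1)][0]
            t = self.data.columns[neg.any(axis=0)][0]
            raise ValidationError(
                f"negative count at sample {s!r}, taxon {t!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.data.sum(axis=1)


@dataclass
class TaxonomyMap:
    """taxon_id -> ranked lineage (domain..genus).

    Empty ranks are filled with a deterministic placeholder,
    ``"unknown <deepest known name>"``, so that aggregation buckets are
    stable functions of the known part of the lineage.
    """

    data: pd.DataFrame  # index = taxon_id, columns = RANKS

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "taxon_id")
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValidationError(f"taxonomy missing ranks {missing}")

    def name_at(self, taxon_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}")
        return str(self.data.at[taxon_id, rank])

    def covers(self, taxon_ids) -> list[str]:
        """Return the taxa from ``taxon_ids`` absent from the map."""
        return [t for t in taxon_ids if t not in self.data.index]


@dataclass
class GcnTable:
    """taxon_id -> predicted 16S rRNA gene copy number (integer >= 1)."""

    data: pd.Series  # index = taxon_id, values = gcn

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "taxon_id")
        bad = self.data[self.data < 1]
        if len(bad):
            raise ValidationError(
                f"GCN < 1 for taxon {bad.index[0]!r} (value {bad.iloc[0]})"
            )

    def get(self, taxon_id: str, default: float | None = None) -> float:
        if taxon_id in self.data.index:
            return float(self.data[taxon_id])
        if default is None:
            raise KeyError(taxon_id)
        return float(default)


@dataclass
class StudyDesign:
    """sample_id -> (subject, timepoint, group); defines pairing."""

    data: pd.DataFrame  # index = sample_id; columns subject, timepoint, group

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample_id")
        for col in ("subject", "timepoint", "group"):
            if col not in self.data.columns:
                raise ValidationError(f"design missing column {col!r}")
        dup = self.data.duplicated(subset=["subject", "timepoint"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise ValidationError(
                "duplicate (subject, timepoint) pair "
                f"({row['subject']!r}, {row['timepoint']!r})"
            )

    def samples_for(self, timepoint: str) -> pd.Series:
        """subject -> sample_id at the given timepoint."""
        sub = self.data[self.data["timepoint"] == timepoint]
        return pd.Series(sub.index.values, index=sub["subject"].values)

    def paired_samples(self, t0: str, t1: str) -> pd.DataFrame:
        """Subjects sampled at both timepoints, with their sample ids."""
        a, b = self.samples_for(t0), self.samples_for(t1)
        shared = sorted(set(a.index) & set(b.index))
        return pd.DataFrame(
            {"sample_t0": a[shared].values, "sample_t1": b[shared].values},
            index=pd.Index(shared, name="subject"),
        )

    def groups(self) -> dict[str, list[str]]:
        return {
            g: list(sub.index) for g, sub in self.data.groupby("group")
        }


def _check_unique(index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValidationError(f"duplicate {what}: {dup!r}")


# ---------------------------------------------------------------------------
# readers


def read_count_table(path, orientation: str = "samples_as_rows",
                     unit: str = "reads") -> CountTable:
    """Read a TSV count table.

    ``orientation='taxa_as_rows'`` transposes on read so that in-memory
    tables are always samples x taxa.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if orientation == "taxa_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountTable(df.astype(float), unit=unit)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column TSV: taxon_id, semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise ValidationError("taxonomy file needs taxon_id and lineage columns")
    taxon_col, lineage_col = df.columns[0], df.columns[1]
    _check_unique(pd.Index(df[taxon_col]), "taxon_id")
    rows = {}
    for _, rec in df.iterrows():
        rows[rec[taxon_col]] = resolve_lineage(rec[lineage_col])
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    out.index.name = "taxon_id"
    return TaxonomyMap(out)


def resolve_lineage(lineage: str) -> list[str]:
    """Expand a ';'-delimited lineage into all six ranks with placeholders.

    Empty ranks below the deepest named one become
    ``"unknown <deepest known name>"``; a lineage with no parsable rank at
    all is an error.
    """
    parts = [p.strip() for p in lineage.split(";")]
    parts = (parts + [""] * len(RANKS))[: len(RANKS)]
    if not any(parts):
        raise ValidationError(f"lineage with zero parsable ranks: {lineage!r}")
    filled, deepest = [], None
    for name in parts:
        if name:
            deepest = name
            filled.append(name)
        else:
            filled.append(f"unknown {deepest}" if deepest else "unknown")
    return filled


def read_gcn_table(path) -> GcnTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    return GcnTable(s)


def read_design(path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return StudyDesign(df)


def read_cell_counts(path) -> pd.DataFrame:
    """Read FACS triplicates: sample_id, event_rep1..3, mass_g."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    need = {"event_rep1", "event_rep2", "event_rep3", "mass_g"}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"cell-count table missing columns {sorted(missing)}")
    return df


def read_newick(path) -> TreeNode:
    """Read a rooted newick tree; leaf labels must be unique."""
    # underscores in leaf labels are kept verbatim (taxon ids use them)
    try:
        tree = TreeNode.read(str(path), format="newick",
                             convert_underscores=False)
    except Exception as exc:  # skbio raises several parse error types
        raise ValidationError(f"unparsable newick file {path}: {exc}") from exc
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate leaf labels in tree")
    return tree


def check_tree_covers(tree: TreeNode, taxon_ids) -> list[str]:
    """Leaves present in the count table but missing from the tree."""
    leaves = {t.name for t in tree.tips()}
    missing = [t for t in taxon_ids if t not in leaves]
    extra = leaves - set(taxon_ids)
    if extra:
        logger.warning("tree has %d leaves absent from the count table", len(extra))
    return missing


# ---------------------------------------------------------------------------
# writers


def write_count_table(ct: CountTable, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if ct.provenance:
            fh.write("# corrections: " + "; ".join(ct.provenance) + "\n")
        ct.data.to_csv(fh, sep="\t")
    return path


def write_results(tables: dict[str, pd.DataFrame], report_dir) -> list[Path]:
    """Write each result DataFrame as ``<name>.tsv`` with stable columns."""
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = report_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=True)
        paths.append(p)
    return paths


def roundtrip_equal(df: pd.DataFrame) -> bool:
    """Value-identity of a write->read cycle (used by invariant tests)."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t")
    buf.seek(0)
    back = pd.read_csv(buf, sep="\t", index_col=0,
                       float_precision="round_trip")
    return (
        list(back.index) == list(df.index)
        and list(back.columns) == list(df.columns)
        and bool((back.values == df.values.astype(float)).all())
    )
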