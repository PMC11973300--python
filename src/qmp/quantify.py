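"""Conversion of counts into the three abundance unit systems.

* relative fractions (RMP) via total sum scaling,
* cells per gram faeces (FACS-QMP): fractions times the flow-cytometry
  total of the sample,
* cell-number equivalents per gram (spike-QMP): the biological/spike read
  ratio scaled so a chosen reference sample matches its FACS count.

Within a sample these systems only rescale — taxon ratios are preserved —
which is exactly why between-sample comparisons can disagree: the fold
change of a taxon in cells/g factorizes as (relative fold change) x
(total-load fold change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from qmp.tables_io import CountTable, ValidationError

logger = logging.getLogger("qmp")


@dataclass
class DilutionChain:
    """Explicit volume bookkeeping from faecal aliquot to cytometer.

    The default mirrors a protocol with an extra fixation/wash step:
    0.1 g homogenized in 10 mL saline; 500 uL suspension fixed in 3
    volumes of buffer (500 -> 2000 uL); pellet resuspended back in
    500 uL; ``analyzed_volume_ul`` is the volume the cytometer actually
    counts events in. Everything is configuration, not protocol-locked.
    """

    suspension_volume_ul: float = 10_000.0
    steps: tuple[tuple[float, float], ...] = ((500.0, 2000.0), (2000.0, 500.0))
    analyzed_volume_ul: float = 10.0

    def events_to_cells_per_gram(self, mean_events: float, mass_g: float) -> float:
        if self.analyzed_volume_ul <= 0:
            raise ValidationError("analyzed volume must be positive")
        if mass_g <= 0:
            raise ValidationError("sample mass must be positive")
        mult = 1.0
        for vin, vout in self.steps:
            if vin <= 0 or vout <= 0:
                raise ValidationError("dilution step volumes must be positive")
            mult *= vout / vin
        mult *= self.suspension_volume_ul / self.analyzed_volume_ul
        return mean_events * mult / mass_g

    def cells_per_gram_to_events(self, cells_per_gram: float, mass_g: float) -> float:
        """Inverse map, used by the simulator's forward model."""
        unit = self.events_to_cells_per_gram(1.0, mass_g)
        return cells_per_gram / unit


@dataclass
class CellCountRecord:
    """Flow-cytometry triplicate for one sample."""

    sample_id: str
    triplicate_events: tuple[float, ...]
    mass_g: float
    chain: DilutionChain = field(default_factory=DilutionChain)

    def cv(self) -> float:
        ev = np.asarray([e for e in self.triplicate_events if not np.isnan(e)])
        m = ev.mean()
        return float(ev.std(ddof=1) / m) if len(ev) > 1 and m > 0 else 0.0


@dataclass
class SpikeConfig:
    """Spike-in bookkeeping: which taxa are synthetic standards, how many
    16S copies were added per sample, sample masses, and the reference
    sample whose FACS count anchors cell-number equivalents."""

    spike_taxon_ids: tuple[str, ...]
    spike_copies_added: float
    sample_mass_g: dict[str, float]
    reference_sample_id: str
    reference_facs_count: float

    def __post_init__(self) -> None:
        if self.spike_taxon_ids and self.spike_copies_added <= 0:
            raise ValidationError("spike_copies_added must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SpikeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            spike_taxon_ids=tuple(raw["spike_taxon_ids"]),
            spike_copies_added=float(raw["spike_copies_added"]),
            sample_mass_g={str(k): float(v) for k, v in raw["sample_mass_g"].items()},
            reference_sample_id=str(raw["reference_sample_id"]),
            reference_facs_count=float(raw["reference_facs_count"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "spike_taxon_ids": list(self.spike_taxon_ids),
                    "spike_copies_added": self.spike_copies_added,
                    "sample_mass_g": self.sample_mass_g,
                    "reference_sample_id": self.reference_sample_id,
                    "reference_facs_count": self.reference_facs_count,
                },
                fh,
            )


# ---------------------------------------------------------------------------
# operations


def total_sum_scaling(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Within-sample relative fractions; rows sum to 1."""
    df = counts.data if isinstance(counts, CountTable) else counts
    totals = df.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValidationError(f"sample {empty.index[0]!r} has zero total count")
    return df.div(totals, axis=0)


def facs_cells_per_gram(record: CellCountRecord, cv_warn: float = 0.25) -> float:
    """Convert triplicate cytometer events into cells per gram faeces.

    Mean of the available replicates, multiplied through the dilution
    chain, divided by sample mass. A triplicate coefficient of variation
    above ``cv_warn`` is logged as a quality warning.
    """
    ev = np.asarray(record.triplicate_events, dtype=float)
    ev = ev[~np.isnan(ev)]
    if len(ev) == 0:
        raise ValidationError(f"sample {record.sample_id!r} has no FACS replicates")
    if len(ev) < 3:
        logger.warning("sample %s: only %d FACS replicates; using their mean",
                       record.sample_id, len(ev))
    if record.cv() > cv_warn:
        logger.warning("sample %s: triplicate CV %.1f%% exceeds %.0f%%",
                       record.sample_id, 100 * record.cv(), 100 * cv_warn)
    return record.chain.events_to_cells_per_gram(float(ev.mean()), record.mass_g)


def cell_counts_from_table(df: pd.DataFrame,
                           chain: DilutionChain | None = None) -> pd.Series:
    """Per-sample cells/g from a FACS triplicate table."""
    chain = chain or DilutionChain()
    out = {}
    for sample_id, row in df.iterrows():
        rec = CellCountRecord(
            sample_id=str(sample_id),
            triplicate_events=(row["event_rep1"], row["event_rep2"], row["event_rep3"]),
            mass_g=float(row["mass_g"]),
            chain=chain,
        )
        out[str(sample_id)] = facs_cells_per_gram(rec)
    return pd.Series(out, name="cells_per_gram")


def integrate_cell_counts(rel: pd.DataFrame, totals: pd.Series,
                          on_missing: str = "warn") -> pd.DataFrame:
    """Scale relative fractions by per-sample total cell counts.

    Rows of the result sum to the sample's total; samples without a total
    are dropped with a warning (``on_missing='error'`` raises instead).
    """
    missing = [s for s in rel.index if s not in totals.index]
    if missing:
        if on_missing == "error":
            raise ValidationError(f"samples without FACS totals: {missing}")
        logger.warning("dropping %d samples without FACS totals: %s",
                       len(missing), missing[:5])
        rel = rel.drop(index=missing)
    return rel.mul(totals.reindex(rel.index), axis=0)


def strip_spikes(counts: CountTable, cfg: SpikeConfig) -> tuple[CountTable, pd.Series]:
    """Split a count table into biological taxa and a per-sample spike tally."""
    present = [t for t in cfg.spike_taxon_ids if t in counts.data.columns]
    absent = set(cfg.spike_taxon_ids) - set(present)
    if absent:
        logger.warning("declared spike taxa absent from table: %s", sorted(absent))
    spike_reads = counts.data[present].sum(axis=1) if present else pd.Series(
        0.0, index=counts.data.index)
    bio = counts.data.drop(columns=present)
    return (
        CountTable(bio, unit=counts.unit,
                   provenance=counts.provenance + ["spikes_removed"]),
        spike_reads.rename("spike_reads"),
    )


def spike_copies_per_gram(biological_reads: pd.Series, spike_reads: pd.Series,
                          cfg: SpikeConfig) -> pd.Series:
    """Total 16S copies per gram from the biological/spike read ratio.

    copies/g(s) = bio_reads(s)/spike_reads(s) * copies_added / mass_g(s).
    Samples with zero spike reads are unquantifiable (NaN, logged).
    """
    out = {}
    for s in biological_reads.index:
        sp = float(spike_reads.get(s, 0.0))
        if sp <= 0:
            logger.warning("sample %s: zero spike reads, unquantifiable", s)
            out[s] = np.nan
            continue
        mass = cfg.sample_mass_g[str(s)]
        if mass <= 0:
            raise ValidationError(f"sample {s!r} has non-positive mass")
        out[s] = float(biological_reads[s]) / sp * cfg.spike_copies_added / mass
    return pd.Series(out, name="copies_per_gram")


def harmonize_to_reference(spike_values: pd.Series, cfg: SpikeConfig) -> pd.Series:
    """Rescale spike-derived copies/g into cell-number equivalents/g.

    The scale factor maps the reference sample exactly onto its FACS
    count; every other sample is multiplied by the same factor, so the
    result is invariant to the (arbitrary) value of spike_copies_added.
    """
    ref = cfg.reference_sample_id
    if ref not in spike_values.index or not np.isfinite(spike_values[ref]):
        raise ValidationError(f"reference sample {ref!r} has no spike-derived value")
    factor = cfg.reference_facs_count / float(spike_values[ref])
    out = (spike_values * factor).rename("cell_equivalents_per_gram")
    out[ref] = cfg.reference_facs_count  # exact by construction, no ulp drift
    return out
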