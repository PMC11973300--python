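"""16S rRNA gene copy-number (GCN) correction and rank aggregation.

Genomes carry 1 to ~15 copies of the 16S rRNA gene, so taxa with many
copies appear overrepresented in amplicon reads. Correction divides each
ASV's read count by its predicted copy number; it is applied at ASV level
*before* aggregating to phylum/family/genus, because a per-genus copy
number would be ill-defined. Corrected counts stay real-valued —
re-rounding would break per-sample conservation and bias small taxa.
"""

from __future__ import annotations

import logging

import pandas as pd

from qmp.tables_io import CountTable, GcnTable, TaxonomyMap, RANKS, ValidationError

logger = logging.getLogger("qmp")


def correct_gcn(counts: CountTable, gcn: GcnTable,
                missing_default: float = 1.0) -> CountTable:
    """Divide read counts by per-taxon gene copy number.

    Taxa absent from the GCN table fall back to ``missing_default``
    (default 1: no correction, conservative) with a logged warning.
    """
    if counts.unit != "reads":
        raise ValidationError(
            f"correct_gcn expects raw reads, got unit {counts.unit!r}"
        )
    divisors = pd.Series(
        [gcn.get(t, default=missing_default) for t in counts.taxon_ids],
        index=counts.data.columns, dtype=float,
    )
    missing = [t for t in counts.taxon_ids if t not in gcn.data.index]
    if missing:
        logger.warning(
            "%d taxa missing from GCN table; using default %.3g: %s",
            len(missing), missing_default, ", ".join(missing[:5]),
        )
    out = counts.data.div(divisors, axis=1)
    return CountTable(
        out, unit="gcn_corrected_reads",
        provenance=counts.provenance + ["gcn_correction"],
    )


def aggregate_rank(data: pd.DataFrame, taxonomy: TaxonomyMap,
                   rank: str) -> pd.DataFrame:
    """Sum ASV-level columns into rank-level buckets.

    Works on any samples x taxa frame (counts or abundances); per-sample
    totals are conserved. Bucket names come from the taxonomy, including
    its deterministic "unknown <parent>" placeholders.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    missing = taxonomy.covers(data.columns)
    if missing:
        raise ValidationError(
            f"taxa without taxonomy rows: {missing[:5]}"
        )
    buckets = [taxonomy.name_at(t, rank) for t in data.columns]
    out = data.T.groupby(pd.Index(buckets, name=rank)).sum().T
    return out


def aggregate_count_table(counts: CountTable, taxonomy: TaxonomyMap,
                          rank: str) -> CountTable:
    out = aggregate_rank(counts.data, taxonomy, rank)
    return CountTable(out, unit=counts.unit,
                      provenance=counts.provenance + [f"aggregated:{rank}"])


def multi_copy_fraction(gcn: GcnTable) -> tuple[int, int, float]:
    """(taxa with GCN > 1, total taxa, percentage with GCN > 1)."""
    n_multi = int((gcn.data > 1).sum())
    n_total = int(len(gcn.data))
    return n_multi, n_total, 100.0 * n_multi / n_total
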