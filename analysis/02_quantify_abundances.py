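#!/usr/bin/env python
"""Convert the simulated counts into the three abundance unit systems.

Reads the bundle written by 01, strips spike reads, applies GCN
correction, and writes relative fractions (RMP), FACS-anchored cells/g,
and spike-derived cell-number equivalents/g, reporting the per-sample
totals each absolute system implies.
"""

import argparse
from pathlib import Path

import pandas as pd

from qmp.gcn import correct_gcn
from qmp.quantify import (
    SpikeConfig, cell_counts_from_table, harmonize_to_reference,
    integrate_cell_counts, spike_copies_per_gram, strip_spikes,
    total_sum_scaling,
)
from qmp.tables_io import read_cell_counts, read_count_table, read_gcn_table

parser = argparse.ArgumentParser()
parser.add_argument("--bundle", type=Path, default=Path("results/bundle"))
parser.add_argument("--out", type=Path, default=Path("results/abundances"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

counts = read_count_table(args.bundle / "counts.tsv")
cfg = SpikeConfig.from_yaml(args.bundle / "spike.yaml")
bio, spike_reads = strip_spikes(counts, cfg)
corrected = correct_gcn(bio, read_gcn_table(args.bundle / "gcn.tsv"))
rel = total_sum_scaling(corrected)

facs_totals = cell_counts_from_table(read_cell_counts(args.bundle / "facs.tsv"))
spike_totals = harmonize_to_reference(
    spike_copies_per_gram(bio.totals(), spike_reads, cfg), cfg)

tables = {
    "relative": rel,
    "facs_cells_per_gram": integrate_cell_counts(rel, facs_totals),
    "spike_cell_equivalents": integrate_cell_counts(rel, spike_totals),
}
for name, df in tables.items():
    df.to_csv(args.out / f"{name}.tsv", sep="\t")

print(f"spike read fraction: {(spike_reads / counts.totals()).mean():.1%} of reads")
comparison = pd.DataFrame({"facs": facs_totals, "spike": spike_totals})
comparison["ratio"] = comparison["spike"] / comparison["facs"]
print("per-sample totals (cells/g) by method:")
print(comparison.to_string(float_format=lambda v: f"{v:.3g}"))
print(f"wrote {len(tables)} abundance tables to {args.out}")
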