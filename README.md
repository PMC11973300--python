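# qmp — quantitative microbiome profiling

Standard 16S rRNA gene amplicon sequencing yields *compositional* data:
each sample's taxon counts are only interpretable as fractions of that
sample's total reads. When an antibiotic truly reduces a dominant taxon,
every resistant taxon's *relative* abundance must rise, so relative
microbiome profiling (RMP) misreports both the direction and magnitude
of community changes. This package implements quantitative microbiome
profiling (QMP) for small longitudinal animal or human trials — the
setting where faecal samples are collected per subject before and after
a perturbation — and quantifies exactly how much RMP gets wrong.

It provides, as a library plus numbered analysis drivers:

- **16S gene copy-number (GCN) correction** — read counts divided by the
  per-ASV predicted copy number (1–9+ copies per genome), applied at ASV
  level before aggregation to phylum/family/genus;
- **three abundance unit systems** over the same counts:
  - *RMP*: total sum scaling, `rel(s,t) = n(s,t) / Σ_t n(s,t)`;
  - *FACS-QMP*: `abs(s,t) = rel(s,t) · C(s)` with `C(s)` the
    flow-cytometry total cell count (cells per gram faeces), so
    `Σ_t abs(s,t) = C(s)` exactly;
  - *spike-QMP*: total 16S copies/g from the biological/spike read
    ratio, `copies/g = (n_bio/n_spike) · copies_added / mass`, rescaled
    into cell-number equivalents so a chosen reference sample matches
    its FACS count;
- **the statistical surface** used to compare them: prevalence (≥30% in a
  group) and abundance (≥0.25% somewhere) filters, paired Wilcoxon
  signed-rank tests with Benjamini–Hochberg correction, fold changes of
  group means, Fisher's exact prevalence tests, species richness and
  Shannon effective diversity, generalized UniFrac
  `d = Σ_b L_b (p+q)^α |p−q|/(p+q) / Σ_b L_b (p+q)^α`, and a seeded
  PERMANOVA;
- **a synthetic-trial generator** with known ground truth: log-normal
  subject and taxon variation, a multiplicative treatment effect,
  multinomial read sampling with GCN bias and spike-ins, and noisy
  triplicate FACS totals — so every stage, and the RMP artifact itself,
  is testable without any external data.

## Worked example

```
python analysis/01_simulate_study.py --seed 1
python analysis/03_compare_unit_systems.py --seed 1
python analysis/04_artifact_recovery.py --seed 1
```

The first script simulates six subjects at d0/d1 whose dominant taxon
(35% of cells) truly drops to a fold change of 0.3, and prints:

```
d0 total loads (cells/g): 7.56e+07 - 1.45e+08
perturbed taxon: ASV_001 (baseline share 35%, true FC 0.3)
```

The comparison step then reports, per rank and unit system, how many
taxa each system calls significantly changed (paired Wilcoxon, p ≤ 0.05):

```
unit    facs  rmp  rmp_gcn  spike
rank
family     1    9       12      2
genus      1   13       20      3
phylum     1    3        3      1
```

Only one genus truly changed: the FACS-anchored system finds exactly it,
while the relative systems flag 13–20 genera — the compositional
artifact. The recovery driver repeats the whole chain over 50 seeds:

```
RMP flagged >=1 unperturbed taxon as increased in 100% of trials
FACS-QMP median FC estimate: 0.305 (median |error| 0.022); detected in 100% of trials
PERMANOVA under random labels: p <= 0.05 in 6.5% of 200 repeats
```

i.e. QMP recovers the planted fold change of 0.3 almost exactly, and
the permutation test is calibrated.

A `qmp` console command exposes the same steps
(`qmp simulate`, `qmp quantify --mode {rmp,facs,spike}`, `qmp run`,
`qmp summarize`).

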