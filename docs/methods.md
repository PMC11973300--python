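# Methods

## The problem and the three unit systems

Amplicon counts are compositional: sequencing depth is arbitrary, so a
sample's counts carry information only about within-sample ratios.
Between-sample statements ("taxon X increased after treatment") require
an absolute anchor. The package compares three unit systems computed
from the same ASV table:

1. **Relative fractions (RMP).** Total sum scaling. Within-sample ratios
   are preserved; between-sample fold changes are confounded by total
   load: for any taxon, FC(cells/g) = FC(relative) × FC(total). This
   identity (asserted as a property test) is the entire mechanism of the
   directional artifact — if total load falls, unchanged taxa appear to
   rise relatively.
2. **FACS-anchored absolute abundance.** Each sample's fractions are
   multiplied by its flow-cytometry total (cells per gram faeces), so
   taxon values sum exactly to the measured total. No re-normalization
   is ever applied after this integration; absolute tables are tested
   as-is.
3. **Spike-in cell-number equivalents.** A constant pool of synthetic
   16S genes (13 distinguishable sequences) is added per sample before
   DNA extraction. The biological/spike read ratio times copies added,
   divided by sample mass, estimates total 16S copies/g — a relative
   load scale. It is made comparable to FACS by one global factor chosen
   so a designated reference sample equals its FACS count; the factor is
   defined constructively (reference FACS ÷ reference spike value),
   which makes the result invariant to the arbitrary internal scale of
   "copies added" and maps the reference exactly (enforced to the last
   ulp in code).

## GCN correction

Genomes carry 1–15 16S rRNA gene copies; multi-copy taxa are
overrepresented in reads. Correction divides ASV counts by the predicted
copy number **before** rank aggregation (a per-genus copy number would
be ill-defined), keeps real-valued results (re-rounding would break
per-sample conservation and bias rare taxa), and falls back to GCN = 1
with a logged warning for taxa without a prediction — a deliberately
conservative default: dividing by a guessed mean would silently rescale
unknown taxa. GCN prediction itself (phylogenetic placement) is out of
scope; predictions are consumed as a table. Whether spike reads should
be GCN-corrected is moot here: each spike plasmid carries one artificial
gene, so their copy number is 1 by construction.

## Flow-cytometry conversion model

Protocols report events, not cells/g; the conversion is explicit volume
bookkeeping: cells/g = mean(triplicate events) × Π(volume_out/volume_in
over dilution steps) × (suspension volume / analyzed volume) / sample
mass. The chain is configuration, not hard-coded (defaults: 0.1 g in
10 mL saline; 500 µL + 3 volumes fixative; pellet resuspended in
500 µL), because fixation/washing steps vary between protocols.
Triplicates are combined by arithmetic mean; a missing aliquot drops to
the mean of the remaining two with a warning; a triplicate CV above 25%
is logged as a quality flag. Samples without a FACS total are excluded
from the FACS unit system with a warning (configurable to a hard error).

## Filtering and testing

Taxa enter testing iff prevalence ≥ 30% in at least one
(group, timepoint) stratum **and** relative abundance ≥ 0.25% in at
least one sample; boundary values are retained. Serial comparisons are
subject-paired (baseline vs each later timepoint): two-sided Wilcoxon
signed-rank, exact null for ≤ 25 non-zero tie-free differences, normal
approximation otherwise; all-zero differences give p = 1 with a warning.
Fisher's exact test is provided as a presence/absence (prevalence) 2×2
per group pair — the only well-defined reading for continuous
abundances; this interpretation is a documented assumption. BH families
are one per (rank, unit system, comparison) panel; both p ≤ 0.05 and
q ≤ 0.05 flags are emitted. Fold changes are later/earlier ratios of
group means, reported to 2 decimals in outputs, undefined (NaN) for a
zero baseline.

Richness counts taxa above a detection threshold (default: any positive
abundance — the 0.25% display filter is a filter, not a richness
parameter); Shannon effective diversity is exp(−Σ p ln p). These are
standard α-diversity measures and generalized UniFrac is a β-diversity
distance; field usage occasionally swaps the two labels, and the package
follows the standard semantics.

Generalized UniFrac weights each branch by (p+q)^α (α = 0.5 default,
α = 1 recovers the weighted-UniFrac normalization); branches with
p + q = 0 are skipped, and taxa with nonzero abundance missing from the
tree are an error, not a silent drop. PERMANOVA computes pseudo-F from
between/within sums of squared distances and permutes labels freely (no
strata), p = (hits + 1)/(n_perm + 1) with n_perm = 999 by default; the
seed is mandatory in configuration so runs are reproducible. Pairwise
mode runs all group pairs with BH across pairs. scipy/statsmodels stand
behind the univariate tests and BH; both are verified against exhaustive
enumeration oracles in the test suite, and pseudo-F is cross-checked
against an independent implementation.

## Synthetic trial generator

What it emulates, per sample (subject × timepoint):

- per-taxon baseline cells/g: heavy-tailed fractions (log-normal,
  log-sd 1.5 across taxa) of a subject total; the dominant taxon's share
  is pinned (default 35%) because the artifact's size is governed by the
  perturbed taxon's share of total load;
- subject totals: 9.15×10⁷ cells/g × log-normal(sd 0.35), reproducing a
  ~2–3.5× spread of day-0 loads across six subjects;
- treatment: multiplicative fold change (default 0.3) on the affected
  taxa at post-baseline timepoints; independent log-normal (sd 0.15)
  subject × taxon × timepoint noise; treatment never changes GCN;
- sequencing: read probabilities ∝ cells/g × GCN × mass for biological
  taxa plus a constant spike pool sized to a 5% expected spike read
  fraction at the cohort-mean load; multinomial at fixed depth 30,000
  (depth variation is a config option; multinomial, not Poisson, keeps
  depth exact);
- FACS: triplicate events = true total × log-normal noise (CV 0.15 — a
  configuration choice; published protocols do not quantify this), sent
  backwards through the same dilution chain the analysis inverts.

Problem sizes used throughout (6 subjects, 60 taxa, 30k reads, 50-seed
Monte-Carlo, 200×999 PERMANOVA permutations) are the package's default
study scale: large enough that the artifact and its correction are
unambiguous, small enough to iterate on freely.

What it does **not** model: chimeras, primer and DNA-extraction bias,
compositional interactions between taxa, overdispersion beyond the
log-normal × multinomial hierarchy, or copy-number variation within a
taxon. Passing tests therefore demonstrate the algebra and inference
machinery under the stated generative model, not robustness to every
real-world artifact — on real data, extraction efficiency and staining
variability add error the generator does not represent.

## Numerical choices and degenerate inputs

- Corrected counts and all abundance matrices are float64 throughout;
  row-sum conservation is asserted at 1e-6 relative (observed ~1e-16).
- Validation is strict and names the offending record: negative counts,
  duplicate identifiers, empty samples, GCN < 1, singleton PERMANOVA
  groups, unparsable trees.
- Taxonomy placeholders are deterministic: an empty rank becomes
  "unknown <deepest known name>", so aggregation buckets are stable.
- Zero spike reads make a sample unquantifiable (NaN + warning) rather
  than infinite.
- Tables are TSV, samples in rows; a dialect flag accepts taxa-in-rows
  input. Newick leaf labels keep underscores verbatim.

## Known limitations

- The spike-QMP reference anchoring propagates any error in the
  reference sample's FACS count multiplicatively to every sample; the
  package reports per-sample FACS/spike total ratios so this can be
  inspected.
- The exact Wilcoxon null is bypassed in favour of the normal
  approximation when tied |differences| occur, slightly conservative at
  n = 6.
- PERMANOVA permutes freely; repeated-measures designs would need
  within-subject restricted permutations, which are not implemented.
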