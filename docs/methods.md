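# Methods

## The measurement being modelled

A hydroxamate assay (HAMA) screen presents a panel of amino-acid
substrates to an adenylation domain under direct competition and reports
one hydroxamate concentration (µM) per substrate per well.  The default
panel has N = 19 substrates: 17 proteinogenic amino acids plus d-Phe and
d-Val, with l-Leu-d7, l-Phe-d5 and l-Val-d8 supplied as deuterated
standards so that isobaric/enantiomeric pairs can be distinguished by
mass.  Screens run in 96-well plates; each plate carries 4 wild-type
(parent enzyme) and 4 negative-control (disrupted A-domain) wells and is
treated as one batch.

## Normalization chain

Protein expression varies strongly between wells and batches, so absolute
hydroxamate totals are only meaningful relative to the in-batch wild-type
control.  The pipeline:

1. averages technical replicates per (variant, batch) — unweighted
   arithmetic mean per substrate;
2. divides by the batch wild-type total: `A_rel = total_mutant /
   total_WT`.  The wild-type reference is the replicate-weighted mean of
   all wild-type wells in the batch (a median option exists for
   robustness).  Because mutant and reference share the batch, the
   multiplicative batch effect cancels exactly — `A_rel` is invariant to
   rescaling all concentrations of a batch by any c > 0;
3. merges identical mutants screened in more than one library by a
   replicate-weighted mean of their batch-normalized profiles, so the
   merged profile equals the plain mean over all underlying wells;
4. applies the activity floor: mutants whose total falls below 1% of the
   wild type are flagged and their fraction vector set to zero; all
   others carry a unit-sum substrate-fraction vector `p`;
5. applies the trace filter: mutants below 0.2 µM total hydroxamates are
   excluded from promiscuity ranking (too close to the detection limit).
   Both thresholds are inclusive on the kept side (kept iff total ≥
   threshold), reading "less than X" literally as the excluded set.

Missing concentration cells are read as 0 µM with a warning — in MRM
quantification an absent signal means below the limit of detection — and
a strict mode rejects them instead.  Negative-control wells are unused by
default; an optional step subtracts the per-batch mean NEG signal
(floored at 0) when chemical background is suspected.  Wells that failed
sequencing can be dropped via an explicit exclusion list rather than any
imputation.

## Promiscuity metrics

With `p` the substrate-fraction vector, promiscuity is the Shannon
entropy `P = −Σ pᵢ ln pᵢ` (nats, 0·ln 0 := 0) and the promiscuity index
is the normalized entropy

    I = P / ln N,

which is 0 exactly for an indicator profile (perfectly specific) and 1
exactly for the uniform profile (perfectly promiscuous); the logarithm
base cancels in the ratio.  `I_rel = I / I_WT` is > 1 for mutants more
promiscuous than the wild type.  Ranking by `I` breaks ties by higher
total activity, then lexicographic label, for determinism.

## Specificity divergence and significance

The change of a mutant's profile relative to the wild type is the
Jensen–Shannon distance with base-2 logarithms:

    M = (P + Q) / 2
    JSD(P, Q) = sqrt( D(P‖M)/2 + D(Q‖M)/2 ),   D(X‖Y) = Σ xᵢ log2(xᵢ/yᵢ)

This form is symmetric, bounded in [0, 1] with the bound attained for
disjoint-support profiles, and a metric (the square-rooted base-2 form);
a config flag returns the divergence without the root for comparison.
Mutants must retain ≥ 1% of wild-type activity (inclusive) to enter the
JSD analysis at all.

Significance uses an empirical null: on each plate, the JSD is computed
for every unordered pair of wild-type wells and the 95th percentile of
those pair distances is the plate's threshold.  When a single global line
is needed the per-plate thresholds are pooled by their maximum — the
conservative choice, since a call must then beat the noisiest plate.
Note an intentional asymmetry: mutant profiles are replicate-averaged
before comparison against the (also averaged) wild-type reference, while
the null is built from single-well pairs.  Averaging shrinks noise, so
the pipeline's false-call rate under a pure-noise null sits at or below
the nominal 5%; the calibration test in the suite verifies ≈5% exactly at
the statistically matched level (single-well pairs on both sides) and
conservatism (≤ nominal) at the pipeline level.

## Position designability

Per mutated position the analysis reports the mean JSD of the (up to)
three most divergent eligible mutants — with fewer than three eligible,
the available ones are averaged and flagged rather than dropping the
position — together with the entropy of the activity distribution at the
position: relative activities are binned on log10(A_rel), clipped to
[−3, 1] (zeros land in the lowest bin), in 10 equal-width bins, and the
normalized histogram's Shannon entropy is reported in nats.  The log
scale matches the orders-of-magnitude span of mutant activities; bin
count and range are configurable and are the main sensitivity knob of
this statistic, since no canonical histogram specification exists.
Positions are annotated as first shell (the 8 canonical specificity-code
residues: 660, 663, 702, 726, 728, 752, 760, 761) or second shell, and
mutations carry BLOSUM62 substitution scores (matrix configurable) as a
measure of chemical drasticness.  A position is called significant when
its top-3 mean JSD exceeds the pooled wild-type null threshold.

## Library design statistics

Degenerate codons are expanded against the standard genetic code from
their IUPAC letters (NNK → 32 codons, 20 amino acids, one amber stop);
combinatorial library sizes are products of per-site residue-set sizes;
oligo pools mix in proportion to the codon count each oligo contributes,
keeping codons equiprobable.  Colony coverage at n screened colonies is
reported two ways, because the informal "X% coverage" phrase admits both
readings: the expected fraction of amino acids observed, mean over
residues a of 1 − (1 − k_a/32)^n (the screening heuristic; 96.7% for NNK
at n = 92), and the probability of observing every amino acid, computed
exactly by inclusion–exclusion over the missed-residue sets grouped by
codon multiplicity (49.6% at n = 92).  Colony draws are uniform over
codons — equimolar degenerate oligos approximate codon-uniform sampling —
with no organism-specific codon-usage weighting.

## Synthetic screens

The generator emulates the screen the analysis is designed for, with all
randomness flowing from one seed:

- colonies per library are drawn by NNK codon sampling, so replicate
  counts per mutant are multinomial over amino-acid codon frequencies,
  stop-codon clones (labelled e.g. `G728*`) are inactive, and synonymous
  clones are relabelled `WT` (they are chemically the parent enzyme);
- non-planted mutant profiles are Dirichlet draws with concentration
  vector `dirichlet_alpha × p_WT` (default α = 50, keeping most mutants
  near the parent profile, as observed for most single substitutions);
  planted switches override profile and activity multiplier;
- true totals are `wt_total × Lognormal(0, σ)` with σ = 1.0 (≈2 decades
  of activity spread) and an independent completely-inactive probability
  of 0.3 (≈ the one-third of point mutants that typically fall below 1%
  of wild type);
- observations multiply in a per-plate batch factor Lognormal(0, 0.3),
  mean-one per-channel lognormal noise with CV 0.2 (typical plate-assay
  technical variation), and censor channels below the 0.02 µM detection
  limit to 0 — censoring to zero, not truncation, mirrors MRM behaviour;
- plates hold 88 library wells + 4 WT + 4 NEG; the default screen is 15
  positions × 92 colonies (1380 colonies + controls on 16 plates), and
  the parent profile is a multispecific enzyme with major Phe/Met/Leu and
  side Trp/Tyr activities, total 10 µM.

What the generator does *not* emulate: chromatography and ionization
artefacts, substrate-specific detection sensitivity, plate-position
(edge) effects, pipetting covariance between channels, and sequencing
errors.  Passing recovery tests therefore demonstrates that the
statistics behave correctly under the assumed noise model, not that the
model captures every failure mode of real LC-MS/MS screens.

## Numerical choices and degenerate inputs

Probability vectors are validated to unit sum within 1e-6; entropy uses
masked 0·ln 0 = 0; JS divergences are clipped to [0, 1] against float
round-off before the square root; −0.0 results are normalized to 0.0.
Inactive profiles yield all-zero fraction vectors and are flagged, never
NaN; positions with zero eligible mutants get a NaN top-3 JSD and a flag
rather than an exception; a batch without a wild-type control raises a
missing-reference error naming the batch.  Metrics CSVs are written with
17 significant digits and read back with round-trip float parsing, so
write→read is bit-exact.

## Problem sizes

The test suite simulates full-scale screens (15 × 92 colonies) where the
end-to-end behaviour is under test and 2–3-position screens elsewhere;
the null-calibration test uses a 300-well reference pool and 2,000 test
pairs, and Monte-Carlo coverage checks use 10,000 replicates.  The whole
suite runs in a few seconds on one CPU.

## Known limitations

- The promiscuity index uses the unweighted normalized entropy; it does
  not down-weight chemically similar substrates.
- The significance threshold is a wild-type *reproducibility* null; it
  does not control a family-wise error rate across 285 mutants.
- `A_rel` inherits any systematic difference between on-bead plate
  expression and the wild-type control's expression within the batch;
  only multiplicative batch effects cancel.
- The activity-entropy statistic depends on its histogram specification;
  compare positions only under a fixed configuration.
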