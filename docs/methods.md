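# Methods

## Model

A DNA sequence over {A, C, G, T} of length N is represented by its
cumulative base frequencies: a_n is the fraction of A among positions
1..n (counts divided by n, not by N — this is what keeps every
coordinate inside [−1, 1]), and likewise c_n, g_n, t_n. The Z-curve
coordinates are

    x_n = (a_n + g_n) − (c_n + t_n)
    y_n = (a_n + c_n) − (g_n + t_n)
    z_n = (a_n + t_n) − (g_n + c_n)

The map is invertible: a_n = (x_n + y_n + z_n + 1)/4 and cyclic
variants recover the frequencies, cumulative counts follow by
multiplying by n, and successive count differences identify each base.
`inverse_zcurve` implements this and rejects curves whose implied
counts are not integers or do not change by exactly one unit step per
position. Useful identities: x_n + y_n + z_n = 4·a_n − 1, and each
coordinate is bounded by ±1.

The set-level model (ZCM) applies the same arithmetic to the
position-wise arithmetic mean of the member sequences' cumulative
frequencies; it is invariant to duplication and reordering of the set.

The position weight matrix holds log-odds M_in = log(q′_in / b_i),
with q′_in = (count_in + α) / (m + 4α) the Laplace-smoothed frequency
of base i at position n over m sequences. The combined ZCMM model
weights each mean frequency by the matching PWM entry inside the
Z-curve arithmetic:

    X_n = (M_nA·a_nm + M_nG·g_nm) − (M_nC·c_nm + M_nT·t_nm)
    Y_n = (M_nA·a_nm + M_nC·c_nm) − (M_nG·g_nm + M_nT·t_nm)
    Z_n = (M_nA·a_nm + M_nT·t_nm) − (M_nG·g_nm + M_nC·c_nm)

Exact identities used as tests: a unit PWM (all entries 1) reproduces
the ZCM curve; an all-zero PWM annihilates all coordinates; q′ = b
gives M = 0 exactly.

Classification features are the per-position Euclidean distances
between a query's own Z-curve and the nucleosome-set ZCMM,
Ed_n = √((x_n−X_n)² + (y_n−Y_n)² + (z_n−Z_n)²), giving N features per
sequence. Alternative featurizations are provided for ablation:
distances to both class models (2N features, positive model first),
the raw flattened Z-curve (3N), and the per-position PWM log-odds of
the query's own bases (N). The single-model distance is the default
because the method is defined around a model of the *nucleosomal* set;
the dual-model variant is a strictly richer option kept behind a flag.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `pseudocount` α | 1.0 | per-base, per-column Laplace smoothing of PWM frequencies; α = 0 allowed only when all counts are positive (log 0 otherwise) |
| `background` | `"from-set"` | PWM background b_i: base frequencies pooled over the training set; `"uniform"` (0.25 each) or an explicit 4-vector (e.g. genome-wide frequencies) are alternatives |
| `log_base` | natural | base of the PWM log-odds; base 2 only rescales the features, and the SVM grid absorbs scale |
| `gamma`, `cost` | 2⁻⁷, 8 | RBF-SVM kernel width and soft-margin penalty; tune with `grid_search` over the usual log-2 lattice (γ ∈ 2^{−15..1}, C ∈ 2^{−5..11}) |
| `scale_features` | on | zero-mean/unit-variance scaling fitted on training folds; RBF kernels need comparable feature scales |
| `k`, `seed` | 10, 42 | stratified cross-validation folds and the seed controlling fold assignment and SVM tie-breaking |
| `window`, `step` | model N, 1 bp | sliding-window size (must equal the model length) and stride for occupancy profiling |

Base rows are ordered A, C, G, T in every 4×N matrix, and positions
are 1-based in all serialized output; the model archive records both.

## Cross-validation protocol

Folds are stratified (per-fold class counts within one sequence of
proportionality) and seeded. Within each fold the ZCM, PWM, ZCMM and
the feature scaler are fitted on the nine training parts only and then
applied to the held-out part, so nothing about the held-out sequences
reaches the models they are scored against; a `refit_per_fold=False`
switch fits the models once on all data for comparison with protocols
that do not isolate folds. The per-fold model state is hashed so
leakage-freedom is testable: permuting a held-out fold leaves that
fold's training-model hash bit-identical. Grid search maximizes mean
CV accuracy, breaking ties toward smaller cost, then smaller gamma
(smaller cost = stronger regularization, the more conservative model).

Metrics are computed in the miss-rate parameterization
(Sn = 1 − FN/N⁺, Sp = 1 − FP/N⁻, Acc, and
MCC = [1 − (FN/N⁺ + FP/N⁻)] / √[(1 + (FP−FN)/N⁺)(1 + (FN−FP)/N⁻)]),
which is algebraically the textbook confusion-matrix MCC — asserted
against that oracle to 1e-10 in the tests rather than assumed. A zero
MCC denominator (one-class predictions) returns 0 with a warning. AUC
is the tie-corrected Mann–Whitney statistic P(s⁺ > s⁻) + ½P(tie),
checked against a brute-force all-pairs oracle; reports expose
per-fold, mean and maximum AUC since both mean and per-fold-maximum
conventions appear in the literature. The ranking score is the SVM
decision-function value (probability calibration would add a
cross-validation inside each fold for little benefit here).

## Occupancy profiling

Every window of the model length (stride `step`, windows never
spanning record boundaries) is scored by the classifier's decision
function; a base's occupancy is the mean score of all windows covering
it, and bases covered by no valid window (record ends; neighborhoods
where every window contains an ambiguous base) are missing (NaN).
This per-base mean is the simplest aggregation consistent with a
continuous occupancy track, and it is invariant to step refinement for
a constant scorer — a property test. Tracks are written as fixedStep
wiggle (1-based, format-mandated) and bedGraph (0-based half-open,
format-mandated); both writers have matching readers and round-trip
coordinates and repr-precision scores exactly. Track similarity is
Pearson correlation over the intersection of covered bases with
pairwise NaN exclusion; constant tracks are an error (undefined r).

## Synthetic data: what it does and does not emulate

The generator draws the positive class from a position-specific base
distribution with (i) a GC content `gc_pos` and (ii) a phased A/T
boost: at every 10th position the A/T probability mass moves toward 1
by the fraction `periodic_strength` (columns renormalized by
construction). Negatives are i.i.d. at `gc_neg`. Defaults — 500
sequences per class, 147 bp, GC 0.60 vs 0.40, boost 0.5, seed 7 —
define the "strong" condition: the two signals are exactly what the
ZCM (cumulative composition) and PWM (positional preference) encode,
so a correct implementation must learn them (calibration target: mean
CV accuracy ≥ 0.90, AUC ≥ 0.95). The null condition (equal GC, no
periodicity) makes the classes identically distributed, pinning CV
accuracy to 0.5 ± 0.05. The 20-point GC gap is deliberately generous
compared with real nucleosome/linker composition differences; passing
these calibrations demonstrates that the pipeline's plumbing and
protocol are sound, not that real-genome accuracy would match —
real sequences carry correlated dinucleotide structure, repeats and
context the i.i.d.-per-position generator does not model. Toy genomes
alternate i.i.d. spacers (default GC 0.40, 200–500 bp, linker-like) with
positive-class plants and report ground-truth intervals; all
randomness flows from one seed and never touches global state.

## Numerical and design notes

- Cumulative frequencies divide by the position index n (per-position
  normalization); this is forced by the ±1 coordinate bound.
- The Z-curve round trip tolerates 1e-6 absolute error when checking
  that implied counts are integers — float error at N ≤ a few thousand
  is orders of magnitude below the 0.5 decision margin.
- Ambiguous bases: model-facing FASTA input either drops offending
  records with a warning (default) or rejects the file; genome records
  keep them and the profiler skips affected windows. Soft-masked
  (lowercase) bases are uppercased, never dropped.
- The model archive is a single versioned JSON file; floats serialize
  at full repr precision so save/load round trips are bit-exact. The
  classifier archive embeds the fitted scikit-learn pipeline as
  base64 so the whole predictor stays one text artifact.
- Wilcoxon rank-sum comparison of two fitted coordinate models
  (`compare_models`) reports two-sided p-values per axis and pooled
  over the three axes; identical models give p = 1 by construction.
- Whether features were scaled before SVM training in prior work is
  not determinable; scaling is a documented default, not a claim.

## Problem sizes

Default test and reproduction runs use 500–1000 sequences per class at
147 bp, 10-fold CV, and ~10 kb toy genomes profiled at a 5-bp stride —
sizes chosen so the complete suite runs in well under a minute on one
core while leaving every statistical check comfortably powered.

## Known limitations

- The i.i.d.-per-position generator cannot stand in for benchmark
  corpora; reported calibration numbers characterize the pipeline, not
  biological predictive performance.
- Only the RBF kernel is supported, matching the method's definition.
- No peak calling on occupancy profiles, and no redundancy filtering
  of input sets (an upstream concern).
- `compare_models` treats positions as independent samples for the
  rank-sum test; positions of a cumulative-frequency curve are in fact
  autocorrelated, so its p-values are descriptive rather than strictly
  calibrated.
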