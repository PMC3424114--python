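# Methods

## Problem and model

Given a protein chain of length N, the task is a per-residue binary
classification: does residue *i* contact ATP? Each residue is represented by
the window of w = 17 residues centered on it (8 to each side). Two feature
families are used:

* **LogisticPSSM** — the 17 × 20 slice of the PSI-BLAST profile after the
  elementwise logistic map `ns = 1/(1+e^(−s))`, flattened position-major to
  340 dimensions. The logistic map is applied to the *log-odds* block of the
  ASCII matrix (not the percentage block): log-odds are signed and roughly
  centered at 0, so the logistic sends them into (0, 1) with 0 ↦ 0.5.
* **Bi-profile blocks** — for each categorical track (amino-acid identity,
  3-state secondary structure H/E/C, 2-state disorder D/O, 2-state
  accessibility e/b), position-wise symbol posteriors are estimated from the
  positive and negative training windows and each window is encoded as the
  2w = 34 posteriors of its own symbols under both tables. The raw one-hot
  amino-acid encoding is never materialized: bi-profile sampling of the
  amino-acid track is exactly the bi-profile of that sparse encoding, so the
  34-D Bipro-aa block subsumes it.

Feature blocks are concatenated in a fixed order (LogisticPSSM, Bipro-aa,
Bipro-ss, Bipro-dis, Bipro-sa) and the fusion signature (names + dims)
travels with every trained model; prediction refuses a mismatched signature.

The classifier is an RBF-kernel SVM. No feature rescaling is applied: both
feature families already live in [0, 1], and keeping the encoders and the
classifier decoupled makes encodings reusable.

## Estimation details

**Posterior tables.** `table[i, a] = (count(a at i) + κ) / (n + κ·|A|)` with
pseudocount κ (default 1, selectable 0 for the plain frequency estimate).
κ = 1 was chosen because small training folds routinely miss symbols at some
positions and a hard zero posterior is brittle downstream; κ = 0 reproduces
the plain estimator for exactness tests. The alphabet of every track
includes the terminal padding symbol '□' as a first-class state, so windows
at chain ends encode without special-casing; the amino-acid alphabet also
carries an 'X' state into which nonstandard letters (X, B, Z, U, O) fold.

**Leakage control.** Bi-profile tables are label-dependent, so they are
fitted per cross-validation fold on training chains only. The fold driver
(`fit_fold_encoders`) hard-fails (LeakageError) if any supplied window
belongs to a non-training chain. Folds are assigned at the chain level
(seeded shuffle, round-robin), so all windows of a chain travel together;
k = number of chains gives leave-one-out over chains.

**Class imbalance.** Training sets contain all positives plus
min(r·|pos|, |neg|) negatives drawn uniformly without replacement (default
r = 1). Test folds are never subsampled: evaluation reflects the deployment
imbalance. Metrics are therefore reported at the balanced ROC point — the
threshold where FPR = FNR, located by linear interpolation between the two
adjacent empirical ROC points straddling the line TPR = 1 − FPR. The
interpolated equal error rate is exact to 1e−9 by construction; confusion
counts (and Sens/Spec/Prec/Acc) come from the nearest realizable threshold,
ties resolved toward higher sensitivity. Score ties are grouped into single
ROC steps, making the trapezoidal AUC equal to the Mann–Whitney statistic
with ties counted half.

**Grid search.** Default grids C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, …, 2³}
(the standard coarse log₂ grid), selection by mean stratified inner-CV AUC
(inner_folds = 3), exact ties broken toward smaller C then smaller γ, winner
refit on the full training set. AUC rather than accuracy is the selection
criterion because training sets at r > 1 are imbalanced. Class weighting is
off by default (imbalance is handled by subsampling); `class_weight=
"balanced"` is available for experiments.

## Parsers and dialects

PSI-BLAST ASCII matrices (first 20-column log-odds block, fixed column order
A R N D C Q E G H I L K M F P S T W Y V), PSIPRED `.ss2` (state letter
authoritative, probabilities retained, sum-to-1 deviations > 0.05 warn),
DISOPRED per-residue output (probability binarized at 0.5 with ties →
disordered — the upstream tool emits probabilities but the feature is
two-state, and 0.5 is the tool's own decision boundary), and SSpro-style
accessibility strings (e/E exposed; b/B/− buried). All parsers tolerate
Windows line endings and trailing blanks and check length/residue
consistency against the chain when given one. A canonical per-chain TSV
"profile bundle" (position, residue, 20 profile columns, ss, disorder,
access) is the package's own interchange format.

## Synthetic data: what it emulates and what it does not

The generator produces chains (uniform residues), binding positions (a fixed
fraction per chain, optionally with minimum spacing), integer-rounded
Gaussian profile scores, and class-conditionally sampled categorical tracks,
all written in the external dialects above so the real parsers are always
exercised.

Default conditions (chosen once, as realistic for nucleotide-binding chain
sets): 30 chains of 60–120 residues; binding fraction 0.05; profile scores
N(0, 2²) rounded to integers, with a +2 mean shift on the G/K/S/T columns
(the Walker-A/P-loop residues) for residues within ±2 of a binding position
— conservation around a binding motif extends over its neighborhood, as in
real profiles; disorder rates 2.0 % (binding) vs 8.1 % (non-binding);
buried rates 75.3 % vs 58.5 %; C/H/E rates 49.6/26.0/24.4 % vs
41.7/40.3/18.0 %. These categorical contrasts are the ones observed in real
protein–ATP interface surveys.

What the generator does **not** emulate: residue-composition structure
(sequences are uniform), autocorrelation of secondary-structure segments
(states are i.i.d. per residue rather than forming runs), homology between
chains, and the position-dependent gradients real binding neighborhoods show
(class rates switch only at binding residues). Passing tests therefore
demonstrate correctness and calibration of the machinery — parameter
recovery, chance-level behavior without signal, the benefit of fusing an
independent signal — not real-data accuracy. Headline performance on real
ATP datasets requires external profile generation and is out of scope.

## Problem sizes and numerical choices

Test and acceptance experiments use deliberately modest sizes: pipeline
checks run 14–30 chains with 5 chain-level folds and reduced SVM grids
(2–9 (C, γ) pairs), which keeps every experiment in seconds while leaving
thousands of pooled test windows; null-calibration runs use binding fraction
0.3 so the AUC's sampling error (~0.013) sits well inside the ±0.05 band;
recovery checks use ≥500 positive windows so 3 binomial standard errors is a
meaningful bound. The fusion-benefit experiment injects a moderate profile
shift (+1) and a strong secondary-structure contrast so the marginal value
of the fused block is identifiable over five seeds.

Degenerate inputs: even window widths, unnormalized profiles entering the
windower, double logistic normalization, empty positive/negative sets,
single-class training labels, non-finite features, and out-of-alphabet
symbols all raise typed errors rather than propagating silently. Extreme
raw scores are clipped to the open interval (0, 1) after the logistic to
preserve the normalized-profile invariant at float precision.

## Known limitations

* Chains shorter than the window are allowed (padding covers them) but warn
  at generation time; prediction quality near termini rests entirely on the
  neutral-padding assumption.
* The equal-error operating point is computed on pooled cross-validation
  scores; per-fold thresholds would differ slightly.
* `SVC` training is O(n²)–O(n³); for training sets beyond ~10⁴ windows a
  linear or approximate kernel would be needed.
* The bi-profile encoder treats positions independently; correlations
  between window positions are left to the SVM kernel.
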