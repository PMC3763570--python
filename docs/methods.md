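# Methods

## Model

Each protein is represented by `20 + λR` descriptors built from a
row-stochastic `L × 20` profile `A` and `R` z-normalized amino-acid property
scales `h(r, ·)`:

* profile: softmax of the PSI-BLAST log-odds rows, or one-hot rows when no
  PSSM exists (degenerate residue codes X, B, Z, U, O, J get uniform rows —
  the zero-information choice that keeps sequence and profile lengths equal);
* positional specific physicochemical property (PSPCP):
  `d_{i,r} = Σ_j A_{i→j} h(r,j)`, the expected property value of position `i`
  under its substitution distribution;
* composition `f_j = (1/L) Σ_i A_{i→j}` (20 values, unit sum) and
  pseudofactors `u_{k,r} = mean_i d_{i,r} d_{i+k,r}` for lags `k = 1…λ`;
* final vector `q = [f, w·u] / (Σf + wΣu)`, pseudo block laid out
  property-major (`q_{20+(r−1)λ+k} = w·u_{k,r}/Z`).

The classifier is a one-vs-one RBF-SVM (libsvm via scikit-learn) on these
vectors, with hard labels only; the evaluation metrics (per-class accuracy,
per-class MCC, overall accuracy) need nothing beyond a confusion matrix.

### Assumptions and interpretation choices

* **Log-odds block.** The first 20 integer columns of the ascii PSSM (the
  signed log-odds block) feed the softmax, not the weighted-percentage
  block; only the former is signed, which is what the exponential
  standardization presumes.
* **Property normalization.** The spread `s(r)` is the population standard
  deviation over the 20 amino acids (divide by 20, then square root), making
  `h` a standard z-score with unit spread. Scales with zero spread are
  rejected by name rather than propagating NaN.
* **Residue order.** All arrays index amino acids in the PSI-BLAST column
  order `A R N D C Q E G H I L K M F P S T W Y V`. Property scales published
  in alphabetical order are remapped on load; this avoids a silent
  permutation bug at the profile/property interface.
* **Sign of the pseudofactors.** `u_{k,r}` is a raw product of signed
  z-score mixtures and can be negative; the classic squared-difference
  correlation factors of older pseudo-composition variants are not used.
  Consequently single descriptors can be negative and, in pathological
  cases, the shared denominator `Z = Σf + wΣu` can reach zero or below —
  that case raises an explicit error. Only the sum-to-1 identity is
  guaranteed; nonnegativity is available as an opt-in diagnostic.
* **No feature rescaling before the SVM.** Descriptors already share the
  sum-to-1 normalization; no extra standardization is applied, keeping the
  representation exactly the `q` vector.
* **MCC convention.** A vanishing MCC denominator (degenerate predictor or
  class) yields 0; a class absent from the truth yields NaN accuracy with a
  warning, never a silent 0.
* **Hold-out splits.** Unstratified uniform draws of `round(0.8·N)` training
  rows, 20 repeats by default; a draw whose training set misses a class is
  redrawn with a logged warning (bounded retries). The across-repeat spread
  is the population standard deviation. Per-repeat seeds are spawned from
  the master seed and recorded in the report.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `w` | 0.15 | weight of the sequence-order block, in (0, 1) |
| `λ` | 11 | autocorrelation depth; must be < every sequence length |
| `R` | 9 | bundled AAindex property scales |
| `γ` | 0.125 | RBF kernel width (CLI default operating point) |
| `C` | 8 | SVM soft-margin cost |

`w = 0.15, λ = 11, γ = 0.125, C = 8` is the calibrated operating point for
real-PSSM descriptor scales and is the CLI default. The calibration grids
are `w ∈ {0.05, …, 1.00}` (step 0.05; note 1.00 is inside the enumeration
convention although user-facing configs require `w < 1` strictly — the
calibration loop therefore assembles descriptors directly) and
`λ ∈ {2, …, 20}`, 380 combinations, with a nested libsvm-style power-of-two
grid `γ ∈ 2^{−15..3}`, `C ∈ 2^{−5..15}`. Ties break toward the simplest
model: smallest `λ`, then `w`, then `C`, then `γ`. Within one `λ` the
per-protein composition and pseudofactors are computed once and re-weighted
for each `w`; this is algebraically identical to recomputation because `w`
enters only as a scalar on the pseudo block and in the denominator.

## Synthetic data

The generator produces labeled sequences with matching integer-valued
ascii PSSMs and exercises exactly the two channels the descriptors read:

* **Composition channel:** class `c` tilts residue usage toward the residue
  subset `{j : j mod n_classes = c}` with logit amplitude
  `0.5 × signal_strength`.
* **Order channel ("echo"):** with probability
  `β = 0.8·(1 − exp(−signal/2))` a residue repeats the residue `p` positions
  back (period `p` class-specific; defaults 2, 3, 4, …). Copying a draw from
  the usage distribution preserves the marginal composition exactly, so the
  echo induces property autocorrelation at lags that are multiples of `p`
  and nothing below — order information invisible to composition and to any
  `λ < p`. Period 0 selects the *diffuse* control: echoes copy a uniformly
  random earlier position, matching the overall dependence level (and hence
  the composition-variance inflation that any dependency causes) while
  concentrating at no lag.
* **PSSMs:** each row is `round(2·(log π_i − mean log π_i) + ε)` clipped to
  `[−10, 10]`, where `π_i` mixes the realized residue (weight 0.7) with the
  class usage background — every row has the same shape regardless of echo
  status, so profile sharpness itself carries no label information — and
  `ε ~ N(0, (2/(1+signal))²)`. At `signal_strength = 0` all classes are
  exchangeable by construction.

Presets: *easy* (3 balanced classes × 20 sequences, lengths 30–60,
signal 4.0), *null* (same geometry, signal 0), and an imbalanced
3-class variant with per-class counts proportional to 661:177:145 to
exercise imbalanced-metric paths. The presets are evaluated at their own
SVM operating point `γ = 8, C = 8`: synthetic descriptors are much more
tightly clustered than real-PSSM descriptors, so the flat real-data kernel
width (`γ = 0.125`) under-resolves them; the preset width was fixed during
generator design, before the recovery thresholds were frozen, and is not
exposed as a CLI default.

What passing the synthetic suite shows: the descriptor pipeline recovers
composition signal, recovers order signal exactly when `λ` reaches the
generating lag, and finds nothing in the exchangeable null. What it does not
show: performance on real proteins — the generator has no homology
structure, no targeting signals, no length/composition confounds, and its
PSSMs are noise-perturbed copies of the generating distribution rather than
alignment-derived profiles.

## Numerical choices

* Softmax with per-row maximum subtraction; agrees with the naive formula to
  1e-12 wherever the latter is finite, and stays finite for arbitrarily
  large integer scores.
* Property z-scores reject spreads below `1e-12·max(1, |mean|)` as constant.
* Feature TSVs are written at 17 significant digits and parsed with
  round-trip float precision, so persisted matrices are bit-exact.
* The SVM wrapper pins its internal random state; jackknife and calibration
  are deterministic end-to-end, and the training fingerprint (SHA-256 over
  the matrix and labels) makes retrain identity checkable.
* Problem sizes in the bundled checks (60-sequence presets, reduced
  calibration grids, 100-instance oracle sweeps) keep the whole suite in the
  seconds range while still exercising every code path; the full 380-point
  calibration on a real dataset is expensive and is meant to be driven
  through the CLI's grid-subsetting flags.

## Known limitations

* The bundled AAindex values are embedded constants transcribed from the
  AAindex1 release; custom tables can be supplied per file to override them.
* Dataset construction from UniProt (redundancy filtering, fragment
  removal) is out of scope; the package consumes already-curated FASTA plus
  PSSM inputs and does not run PSI-BLAST itself (a helper prints the
  appropriate command line).
* Calibrating directly on jackknife accuracy is an optimistic protocol
  (the selection set and the evaluation set coincide); it is reproduced
  faithfully here, and any unbiased estimate should come from the held-out
  protocol or external data.
* No class weighting is applied despite possible strong class imbalance;
  per-class MCC is the metric to watch in that regime.
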