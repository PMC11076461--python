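# Methods

This note documents the models, conventions and numerical choices behind
`eegmst`, and what the synthetic-data validation does and does not show.

## Preprocessing

Recordings are channels × samples matrices in µV with unique labels and a
sampling rate; the default montage is the 55-channel set used throughout
(a 64-channel equidistant layout minus nine rejected channels). The
pipeline applies, in order: optional 49.5–50.5 Hz notch (off by default —
the generator produces no line noise), common average reference, zero-phase
band-pass, epoching.

- **Filters.** 4th-order Butterworth (SOS form) applied forward–backward,
  giving an effective 8th-order zero-phase response. The one-way order is a
  conventional EEG default that remains stable down to the 0.5 Hz delta
  edge; scipy's default odd-reflection padding suppresses startup
  transients. Band edges at or above Nyquist are rejected.
- **Resampling** uses polyphase filtering (`resample_poly`) with the rate
  ratio expressed as a rational; content above the target Nyquist is
  attenuated, never aliased.
- **Epoching** takes the first `n_epochs` consecutive non-overlapping
  segments (7 × 8 s by default) and demeans each epoch per channel.
  Segments are always cut *after* filtering the continuous signal, so
  filter transients never sit inside epochs; a test asserts the
  filter-then-cut identity. Real studies select artifact-free epochs by
  inspection; the generator's data are clean, so the deterministic
  first-seven rule is the documented equivalent.

## Connectivity estimators

Both estimators operate per epoch on band-filtered data and are averaged
across epochs per subject. Band routing defaults to wPLI for delta and
theta and AEC-c for alpha through high gamma, and is configurable.

- **wPLI** is computed from Hilbert analytic signals, with per-sample
  cross-spectral terms within each epoch:
  `|mean(Im(z_i conj(z_j)))| / mean(|Im(z_i conj(z_j))|)`.
  When the imaginary cross-spectrum is numerically zero (relative threshold
  1e-12) the estimator is formally 0/0; the implemented convention returns
  0, since pure zero-lag coupling carries no lag evidence. This also fixes
  wPLI of a channel paired with a scaled copy of itself at 0. wPLI is
  invariant to positive rescaling of either channel.
- **AEC-c.** Pairwise symmetric orthogonalization in the time domain:
  both series demeaned, β = ⟨x,y⟩/⟨x,x⟩, residual y − βx. Envelopes are
  analytic-signal magnitudes with no extra smoothing or downsampling (the
  fewest-moving-parts choice; the envelope model is isolated behind
  `analytic_signal` so it can be revisited). The two regression directions
  are Pearson-correlated and averaged; a numerically zero residual or a
  constant envelope contributes 0 (logged). The signed correlation is kept
  — no rectification — and the sign convention is stamped into output
  metadata. Negative values are legal MST inputs and simply rank below all
  positive weights.
- The matrix-level AEC-c uses the linearity of the analytic-signal
  transform (`H(y − βx) = H(y) − βH(x)`) to reuse per-channel analytic
  signals across all pairs; a test pins it to the definitional pairwise
  estimator at 1e-10.

## Spanning-tree metrics

The per-epoch matrix is converted to distances `1 − w` and Kruskal's MST is
extracted (equivalently, the maximum-total-connectivity spanning tree; the
tree depends only on the weight ranking). Ties are broken deterministically
by inserting edges in ascending lexicographic label order under a stable
sort — with continuous estimates, ties are measure-zero anyway.

Metrics per tree of N nodes: normalized diameter (longest path in edges
/ (N−1)); leaf fraction (degree-1 nodes / N); maximum degree, raw and
/(N−1) — both are reported because normalization conventions differ across
tools; group statistics default to the normalized variant; betweenness
centrality normalized by (N−1)(N−2)/2; its global, anterior (20 frontal
channels) and posterior (19 parieto-occipital channels) means; and degree
assortativity as the Pearson correlation of endpoint degrees over the
doubled edge list. Assortativity is undefined when all endpoint degrees are
equal (e.g. a 2-node tree); such epochs return an explicit `None`, are
excluded from the across-epoch mean and counted in the log — never coerced
to 0. Metrics are computed per epoch and averaged (not: average the
matrices, then one tree), so epoch-level topology variability is retained.

All four analytic metrics are verified against brute-force path-enumeration
/ correlation oracles over every labeled tree up to 6 nodes and ~8,500
Prüfer-sampled trees on 7–8 nodes, at 1e-12; MST optimality is verified
against exhaustive enumeration of all 1296 spanning trees on 6 nodes.

## Group statistics

Welch t-tests (unequal variances, Welch–Satterthwaite df, two-sided p)
compare the two groups per measure × band, from raw values or from printed
summary statistics. Effect sizes are Cohen's d with the pooled-SD
denominator and a 95% CI from the large-sample variance approximation
Var(d) ≈ (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)). The published study's printed d
values are not exactly recoverable from its printed t and n under any
common t-to-d conversion (they were evidently computed from raw data), so
the implemented variant is documented here rather than pinned numerically.
Benjamini–Hochberg step-up adjustment is applied over exactly the declared
family — by default the 6 global measures × 6 bands = 36 tests — while
regional betweenness rows are exploratory and carry uncorrected p only.
Note BH is not idempotent: re-adjusting an adjusted vector inflates it
again; the invariants that do hold (adjusted ≥ raw, ≤ 1, monotone in
sorted order) are property-tested. Re-applying the adjustment to the
published family's 4-decimal p-values reproduces the printed corrected
values 0.0153, 0.0270 and 0.0474 within ±0.0005; the two smallest ranks
depend on digits beyond the printed precision and are not pinned.

## Synthetic cohort generator

The generator emulates the statistical structure the estimators assume,
over a known coupling tree — it is an explicit stand-in for real EEG, not a
biophysical model.

Per channel, a narrowband carrier is built from band-pass-filtered white
noise whose envelope is normalized to a constant (flatten → refilter × 2 →
flatten). This keeps ≥95% of carrier power in-band (the tested floor is 70%) while making the channel envelope equal its slow modulator exactly.
Coupling propagates along the tree from the lowest-index root: a child's
analytic carrier is `k·e^{-iΔ}` times its parent's plus a `√(1−k²)`
independent remainder, re-normalized (magnitude normalization preserves
phase, so the imposed lag survives). The lag is applied as an analytic
rotation, which imposes Δ exactly at every frequency — an exact wPLI
target, rather than the approximate one a fractional-sample delay gives at
band center. Slow envelopes are log-normal: per-channel Gaussian processes
(frequency-domain low-pass at 0.7 Hz — time-domain filtering at such
cutoffs leaves multi-second edge transients — unit variance, σ = 0.5)
propagate along the tree with an AR coefficient chosen by inverting the
Gaussian-to-log-normal correlation map, so coupled pairs hit the requested
envelope correlation analytically (verified within ±0.02 empirically,
against a ±0.1 contract). Volume conduction is a scalar zero-lag mixing
between montage-adjacent channels (coefficient 0–0.5); 1/f-power noise is
added per channel at the requested SNR, and the output is scaled to a
~10 µV working range.

Defaults represent a plausible resting-state regime: phase lag π/4,
phase-coupling strength 0.7, envelope correlation 0.5, leakage 0.2,
SNR 2, 7 × 8 s epochs at 512 Hz over the 55-channel montage. Subject seeds
derive from `SeedSequence(cohort_seed, group_index, subject_index)`, so
cohorts are bit-reproducible file-for-file and any subject can be
regenerated in isolation.

What passing tests on this generator do **not** show: robustness to ocular
or muscle artifacts, mains interference, electrode drift, realistic
head-volume conduction (a scalar adjacency mixing stands in for it),
nonstationarity beyond the slow modulators, or the epoch-selection biases
of visual artifact rejection. Conclusions about real EEG require real EEG.

## Scale of the validation runs

The cohort-level parameter-recovery check simulates 10 replicate cohorts of
20 star- vs 20 path-coupled subjects (full 55-channel montage, alpha band,
AEC-c routing) and requires the correct direction on leaf fraction, max
degree and diameter plus Welch p < 0.05 on leaf fraction in ≥90% of
replicates; the acceptance script runs one such cohort. Estimator null
levels are averaged over 20 seeds at the full 7 × 4096-sample record
length, where the wPLI null (positive by construction, ~1/√N_eff with
N_eff ≈ bandwidth × duration) sits near 0.06; per-epoch estimates have a
correspondingly higher floor (~0.15 in alpha), which is why the epoch-mean
null contract is 0.2 rather than 0.1.

## Known limitations

- AEC-c envelopes are unsmoothed analytic magnitudes; with 8-s epochs and a
  0.7 Hz modulator the per-epoch envelope correlation has few effective
  samples, so single-epoch estimates are noisy and only the across-epoch
  (and across-subject) aggregates are stable.
- The wPLI realization forms cross-terms per sample from Hilbert analytic
  signals; a whole-epoch Fourier cross-spectral realization would weight
  frequencies differently. The choice matches band-limited practice but is
  a convention, not a theorem.
- `welch_t_from_summary` inherits the rounding of printed summaries; its
  agreement contract (±0.005 on t) reflects that.
- EDF input/output is not supported; recordings travel in the plain-text
  dialect only.
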