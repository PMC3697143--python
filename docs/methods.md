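# Methods

## Model and assumptions

At each voxel the S repeated BOLD runs are modelled as
`s(t) = mu + r(t) * a(t) + eps(t)`, `t = 1..T`: a per-run constant baseline,
plus the matrix convolution of R deterministic binary stimulus trains with
an R×S bank of impulse responses, plus noise that is assumed only to be
stationary with zero mean — no white-noise or AR-order assumption is made.
The stimulus trains are shared by all voxels; the impulse responses and the
noise are voxel-specific.

All inference happens in the frequency domain, where the convolution
becomes a product and the Fourier coefficients at distinct frequencies are
asymptotically independent complex Gaussians for stationary noise.  The
estimand is the hemodynamic transfer function (HTF) `A(λ)`, i.e. the
Fourier transform of the impulse-response bank; no parametric form is ever
imposed on it by the analysis.

## Spectral estimation

- **Transform.** Unnormalized forward DFT, coefficients kept only at
  `k = 0..floor(T/2)` (real data; the negative half-line is redundant).
  The test statistics are ratios invariant to any global scaling, so the
  convention matters only for inspecting intermediate values; the
  periodogram keeps its classical `(2πT)⁻¹` factor for that reason.
- **Bands.** Uniform bands of `2m+1` consecutive frequencies centered at
  consecutive multiples of `2m+1`, so they tile the axis without gaps.
  The zero-centered band is always discarded (it carries baselines, drift
  and slow motion artifacts; discarding it is the model's high-pass filter
  and also removes `mu` exactly, so no detrending or demeaning is done).
  Bands whose top index would pass the Nyquist index `floor(T/2)` are
  dropped; a band may touch Nyquist exactly.  This boundary convention is a
  choice — for the reference design (T=156, m=6) it yields five bands
  centered at k = 13, 26, 39, 52, 65 with top index 71 ≤ 78.
- **Cross-spectra.** Arithmetic mean of cross-periodograms over each band's
  members.  `f̂_rr` is computed once per band (stimuli carry no spatial
  dependency); `f̂_rs` and `f̂_ss` per voxel.  No tapering or weighting: the
  unweighted band average is the minimum-mean-square-error choice for
  deterministic inputs, and keeps `Â` identical to the stacked-frequency
  complex least-squares solution (verified against that oracle in the
  tests).

## Testing

For a contrast pair (B: b×R over stimuli, C: c×S over runs) the null
`B A(λ) Cᵀ = 0` is tested per band with

- `E = B Â Cᵀ`, `V = B f̂_rr⁻¹ Bᵀ`, `H = (2m+1) Eᴴ V⁻¹ E`,
- `G = (2m+1)(f̂_ss − f̂_sr f̂_rr⁻¹ f̂_rs)`, `G_c = C G Cᵀ`,
- `U = det(G_c)/det(G_c + H)`, and Rao's approximation
  `F = (h/bc)(U^{−1/d} − 1) ~ F(2bc, 2h)` with
  `d = sqrt((b²c²−4)/(b²+c²−5))` (or `d = 1` exactly when `b²+c² = 5`) and
  `h = [2m+1 − R − (c−b+1)/2]·d − bc/2 + 1`.

The `h` formula's grouping is typographically ambiguous in its printed
source; the grouping above is adopted because it uniquely reproduces both
reference df pairs — (4, 20) for b=1, c=2 and (2, 22) for b=1, c=1 at
R=2, m=6 — and gives d=2, h=18 (df (12, 36)) for the omnibus test.  For
R = S = 1 the machinery collapses to
`F = h·|f̂_rs|²/(f̂_rr f̂_ss − |f̂_rs|²)`, the explained-to-unexplained band
variance ratio (a tested identity).

Under white Gaussian noise the DFT coefficients are exactly independent
complex Gaussians across frequencies, so the null F distribution is exact,
not merely asymptotic; the test suite verifies rejection-rate and
Kolmogorov–Smirnov calibration against F(2bc, 2h) over 5000 simulated
voxels.

### Numerical choices

- Determinants of Hermitian matrices are taken as real after asserting the
  imaginary residue is below 1e−9 of magnitude; `G` and `H` are
  re-symmetrized as `(M + Mᴴ)/2` after assembly.
- `f̂_rr` and `V` inversions are guarded by a condition-number bound
  (default 1e8, configurable): a near-singular stimulus design is an error
  naming the offending band, never a silent NaN.
- Estimability requires `2m+1 ≥ R + c + 1` so the residual degrees of
  freedom stay positive; violation is a configuration error.
- Degenerate voxels (singular residual matrix, e.g. identically zero data)
  are flagged per voxel with NaN statistics and a `degenerate` mask plus a
  warning — the batch API never raises for one bad voxel, and never emits a
  silent p-value for it.
- Results are independent of voxel evaluation order (everything is
  vectorized; no accumulation across voxels).

## Masking hierarchy

1. Omnibus (B = C = I) p maps, one per band, thresholded at P = .001 and
   OR-combined into the omnibus mask.
2. The stimulus-by-state interaction is tested inside it; significant
   voxels form an exclusion mask.  The interaction gate threshold is not
   separately specified by the reference procedure; it defaults to the
   same .001 and is configurable.
3. Multivariate state/stimulus effects are tested inside
   (omnibus AND NOT interaction).
4. Multivariate simple effects are gated by the rejections of the specific
   stage-3 test named for them (configurable; the union-of-stage-3 rule is
   not the default).  Univariate simple effects are deliberately gated by
   the omnibus mask only.

Every stage records a pass/fail/not-reached status per voxel in an audit
table.  The multi-P-level display ladder defaults to
[.05, .01, .005, .001, .0005, .0001]; band p-values are combined by the
minimum across bands before binning (the most significant band drives the
label).  The exact published form of this display algorithm is available
only as an unreproduced figure, so the rule here is a documented
reconstruction from the prose description.  No further multiplicity
correction (e.g. FDR) is applied — out of scope by design.

## Synthetic data

The generator draws from the forward model exactly:

- **Schedules.** 2 s presentations, ISI uniform on [0, 8] s (continuous
  time, onsets floored to the containing TR bin, origin at acquisition
  start), types assigned uniformly at random — the event-related protocol
  of the reference design, at T = 156, TR = 2 s by default.  The ISI
  distribution is pluggable.
- **Responses.** Double-gamma impulse responses sampled at TR (peak 6 s,
  undershoot 16 s, 1:6 undershoot ratio, unit peak), scaled per
  (stimulus × run) cell.  The parametric HRF lives only in the simulator
  as ground truth; the analysis never sees it.  A non-parallel amplitude
  profile plants an interaction; a run-varying but stimulus-parallel
  profile plants a state effect.
- **Noise.** AR(1) with phi = 0.3 and unit innovation SD by default
  (stationary initialization), reflecting BOLD autocorrelation; white
  noise for exact null calibration.  Baseline 100 per run (arbitrary
  units; removed exactly by the zero-band discard).
- **Convolution boundary.** Truncation at T, no circular wraparound; the
  resulting leakage is part of what band averaging absorbs.
- A frequency-domain constructor (`simulate_band_constant_dataset`) builds
  data whose true HTF is exactly constant within each band — the reference
  input for recovery tests, where the noise-free estimate must match the
  truth to machine-level precision and the error must shrink monotonically
  with the noise scale (shared noise realizations make this deterministic,
  since `Â` is linear in the data).

What the simulator does **not** emulate: physiological (cardiac/
respiratory) noise, scanner drift fields, motion, spatial noise
correlation induced by smoothing.  Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness to
every artifact of real acquisitions — on real data the zero-band discard
and band averaging are the only defenses provided here.

Test problem sizes (a few thousand voxels at T = 156; toy grids of order
10×10 for pipeline checks) are chosen so the whole suite runs in seconds
while keeping Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

- Single-subject inference only; no between-subject or group extension.
- No modelling of the HTF's profile across bands (few bands exist at
  TR = 2 s); each band is tested marginally.
- The omnibus-gated hierarchy controls false positives procedurally, not
  at a stated family-wise or FDR level.
- Onset binning floors to the containing TR; sub-TR timing is not
  represented.
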