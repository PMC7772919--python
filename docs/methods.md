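# Methods

## Problem and model

An ECG excerpt x[t], sampled at fs = 250 Hz for 14 s (N = 3500), is
min-max normalized to x_N[t] ∈ [0, 1] so that excerpts of different
amplitude are scored on a common scale. A known artificial baseline wander
w[t] is added, y = x_N + w, and the detrender must recover x_N. Because w
is known, the error of any candidate method is measurable exactly — this is
the point of the semi-synthetic design, and also its limit: conclusions
transfer to real wander only to the extent that real wander resembles the
modeled trends.

### The transform

The detrender is built on the Maximal Overlap Discrete Wavelet Transform.
For a scaling/wavelet filter pair (g, h) rescaled by 1/√2, the pyramid is

    W_j[t] = Σ_l h_l · V_{j−1}[(t − 2^{j−1} l) mod N],
    V_j[t] = Σ_l g_l · V_{j−1}[(t − 2^{j−1} l) mod N],      V_0 = x,

for j = 1..J; the inverse uses the adjoint (forward-shifted) recursion with
the same filters. Properties the package tests and relies on:

* **Exact inversion** — imodwt(modwt(x)) = x to ~1e-12 relative, every
  wavelet, any N ≥ 2^J.
* **Energy partition** — Σ_j ‖W_j‖² + ‖V_J‖² = ‖x‖², which licenses reading
  ‖W_j‖² as "energy in band j".
* **Shift equivariance** — circularly shifting the input shifts every
  coefficient vector, unlike the decimated DWT.

Boundary handling is circular (periodic). Detail level j nominally spans
(fs/2^(j+1), fs/2^j] Hz; V_J holds everything below fs/2^(J+1) including DC.

### Detrending and scoring

`lvA-B` keeps details A..B, zeroes all others *and the scaling vector V_J*
(keeping V_J would leave the trend's DC component in place and no
configuration could detrend at all; an explicit `keep_scaling` flag exists
for inspection work). After inversion the first and last 2 s are dropped —
circular convolution wraps the record ends, and 2 s covers the reach of the
longest upsampled filter at the levels that matter — and the retained 10 s
(M = 2500 samples) are min-max renormalized. The score is
MSE = Σ (x_N − x′)²/M against the clean excerpt trimmed to the same window
but *not* renormalized: its scale is the ground truth. Normalizing over the
trimmed window (rather than the full 14 s before trimming) is a design
choice; it perturbs MSEs in the third decimal and is applied uniformly.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| fs | 250 Hz | QT-Database native rate; study condition |
| duration_s | 14 s | excerpt length; gives N = 3500 |
| J | 11 | floor(log2 3500); deepest feasible level, band 0.061–0.122 Hz |
| trim_s | 2 s | boundary guard per end; M = 2500 |
| level ranges | lv1-7, lv1-8, lv2-8, lv3-8, lv1-9, lv3-9 | the comparison set; arbitrary `A:B` accepted |
| trend suite | 10 sinusoids 0.05–0.50 Hz step 0.05, amplitude 1, phase 0; step (amp 1, onset 7 s); spike (amp 1, onset 7 s, width 1 sample) | uniform frequency grid over the stated range; onsets mid-record; all config-overridable |
| heart rate | 60 bpm, ±5% R-R jitter | synthetic cohort default |

Trend amplitudes are expressed on the normalized-ECG scale (a unit
sinusoid spans the whole signal range — a severe wander). This mirrors
adding a ±1 excursion trend to a [0, 1] signal and makes the step/spike
pathologies visible.

## Filter banks

The 14 scaling filters are frozen constants in the unit-energy convention
(Σg = √2, Σg² = 1), stored in the standard published-table ordering; the
wavelet filter is the quadrature mirror g'[k] = (−1)^k g[L−1−k]. Three
deliberate departures from verbatim toolbox tables, all documented in
`filters.py`:

* **dmey** — the conventional 62-tap FIR Meyer approximation is not exactly
  orthogonal (even-shift defect ~1.4e-3), which would cap round-trip
  accuracy near 1e-2. We store the nearest exactly-orthonormal 62-tap
  filter (constraint projection; max tap change 8.1e-4).
* **sym4/sym6/sym10, fk4** — published digits carry 1e-12…1e-9 residuals in
  the same identities; projected likewise (tap changes below the tables'
  own rounding error).
* **sym3 ≡ db3** — one shared table, so the pair ties bit-for-bit
  downstream, as the mathematics says it must.

## Synthetic ECG generator

Each beat is five Gaussian bumps (P, Q, R, S, T) at fixed offsets from the
R time; R-R intervals are 60/HR scaled by seeded uniform jitter, and each
bump's amplitude gets a 2% seeded wobble so beats are not carbon copies.
This emulates what the benchmark needs — a normalized, trend-free,
morphologically plausible beat train with R dominant and T second — and
nothing more. It has no respiration coupling, muscle/electrode noise,
arrhythmia, or realistic spectral tails; passing grids on it demonstrate
the *mechanism* (trend bands zeroed ⇒ trend removed, retained bands ⇒ ECG
preserved), not clinical performance. Real-data runs use the WFDB path.

## Numerical choices

* Tolerances: round-trip and partition identities asserted at 1e-9/1e-8
  relative (measured ~1e-15); filter identities at 1e-10/1e-8 (measured
  ~1e-16).
* Impulse localization is the global argmax of |level-1 reconstruction|,
  smallest index on ties; no threshold, so a spike-free input returns the
  steepest QRS transition.
* Grid cells that fail (e.g. a constant post-trim reconstruction, which
  renormalization rejects) are recorded with an error string and NaN MSE,
  never dropped; summaries exclude and count them.
* Argmin ties in summaries are resolved at 1e-12 and reported as sets.
* The MODWT of each contaminated record is computed once per wavelet and
  shared across level ranges; modular index matrices are cached by
  (N, taps, level).

## Known limitations and edge behaviors

* **Spike pathology (reproduced on purpose):** a 1-sample spike is
  high-frequency content; low-level-preserving ranges cannot remove it, the
  residual spike becomes the post-detrend maximum, and min-max
  renormalization compresses the true ECG — inflating MSE far beyond the
  spike's own energy. `robust=True` (quantile rescaling) sidesteps this but
  is off by default because the benchmark scores the literal procedure.
* **Step trends** are removed except within ~0.5 s of the onset; a sharp
  edge cannot be synthesized from low-frequency levels alone.
* Level-selective detrending is **not idempotent**: synthesis∘zero∘analysis
  is not a projection for a redundant transform (transition-band gains in
  (0, 1) get squared on a second pass; measured ~11% relative RMS change).
  Linearity and complement-exactness hold instead and are tested.
* The extracted "trend" of a composite record contains the ECG's own
  sub-band content (notably its DC level) in addition to the injected
  wander; the wander-attributable part is recovered by linearity.
* db1 at 0.5 Hz is the worst attenuation cell (~96% energy removed):
  Haar's wide skirts leak the highest trend frequency into level 7.
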