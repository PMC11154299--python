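# Methods

## Electrode–tissue interface model

The recording chain is modeled as a voltage divider: the neural source
drives the amplifier input through the electrode impedance `Z(jω)`
while the shunt capacitance `C_s` (wires, connectors, amplifier input;
default 3 nF, overridable) pulls the node to ground,

    H(jω) = 1 / (jω·C_s·Z(jω) + 1).

Amplifier input impedance is treated as infinite and cable resistance
as negligible. Because every electrode model here has `Re Z ≥ 0` and
`Im Z ≤ 0` over the measurement band, `jωC_s·Z` has non-negative real
part and `|H| ≤ 1` everywhere — the divider can only attenuate.

Two circuit topologies are provided:

* **uncoated** (bare gold): `Z = Rs + [jωCdl + 1/(RCT + Z_Q)]⁻¹` with
  the constant phase element `Z_Q = 1/(Q(jω)^n)`, `0 < n ≤ 1`. `n = 1`
  reduces the CPE to an ideal capacitor; `n < 1` captures surface
  roughness/porosity.
* **coated** (PEDOT:PSS on gold): the volumetric capacitance of the
  polymer suppresses charge transfer (RCT → very large), so the
  faradaic branch is a semi-infinite Warburg diffusion element
  `Z_W = σ(1−j)/√ω`: `Z = Rs + [jωCdl + 1/Z_W]⁻¹`.

The series-vs-parallel structure of these expressions is a modeling
decision: the literal series sum `Rs + 1/(jωCdl) + 1/(RCT + Q)` is
dimensionally inconsistent (it adds an impedance to a capacitance), so
the package adopts the standard Randles reading — `Cdl` in parallel
with the faradaic branch — for both topologies, and exposes
`coated_form="series"` (`Rs + 1/(jωCdl) + Z_W`) as an alternative for
the coated circuit. Sign convention is engineering (`+jωt`):
capacitive impedances have negative imaginary part.

Canonical presets (`au`, `au_pedot`) carry the fitted mean element
values for 125 µm gold wire electrodes before and after PEDOT:PSS
coating: Rs = 3 kΩ both; Cdl = 1.036 nF → 1.73 µF; RCT = 12.24 kΩ
(uncoated only); Q = 10.97 nF with n = 0.890 (uncoated only);
σ = 10.24 kΩ·s⁻⁰·⁵ (coated only). Alternate `_reported` presets store
a second, mutually inconsistent set of values quoted alongside the
canonical ones (Rs = 2 kΩ, Cdl = 6 nF → 1.32 µF, RCT = 1 µΩ,
σ = 11 Ω·s⁻⁰·⁵); they are kept for reference and are used nowhere as
defaults. Frequency grids default to 50 log-spaced points per decade
over 1 Hz–10 kHz, the usual EIS measurement span. The −3 dB cut-off of
a transfer curve is located by log-linear interpolation between grid
points, which carries a bias of order 0.2% on the default grid.

## Circuit fitting

`fit_circuit` minimizes `Σ_k w_k |Z_model(f_k) − Z_data(f_k)|²` with
scipy's trust-region-reflective least squares. Choices that matter:

* **Weighting** defaults to `modulus` (`w_k = 1/|Z_data|²`). EIS
  spectra span decades in magnitude; unit weights would make the fit a
  low-frequency fit. `unit` and `proportional` (separate 1/|Re Z|,
  1/|Im Z| weights) are available.
* **Parameterization**: positive parameters in log10 space (scale-free
  steps, positivity for free); `n` bounded in (0, 1], fittable or
  pinned via `fix_n`.
* **Multi-start**: after the first solve, unless the residual is at
  the noiseless floor, the fit is retried from the data-driven initial
  guess and from 8 deterministic ×10±1 perturbations (round-robin per
  parameter), keeping the best. This is seedless and reproducible, and
  it removes the one local minimum observed in practice (Rs → 0 with
  the CPE absorbing the series resistance). Tolerances: `xtol = ftol =
  gtol = 1e-14`, at most 2000·(p+1) function evaluations per start.
  Non-convergence is reported in the result, never raised.

The heuristic initial guess reads Rs from the high-frequency real
part, Cdl from the most capacitive (most negative phase) point, RCT
from the low-frequency modulus excess over Rs, and σ from the
low-frequency modulus. On spectra limited to 1 Hz–10 kHz the RCT
plateau of the canonical uncoated circuit is never reached, so the RCT
guess is orders of magnitude high; this is inherent to the band, not a
defect, and the multi-start fit recovers RCT regardless.

## Filter bank

Each of the eight bands (δ 0.5–3.5, θ 3.5–8, α 8–15, β 15–30, γ 30–80,
high-γ 80–120, R 120–200, FR 200–600 Hz) is an analytic band-pass
kernel applied by convolution (reflect padding; band signal = 2·Re of
the analytic output, so an in-band tone is reconstructed at unit
gain). The kernel magnitude response is a Gaussian on the
*log-frequency* axis centered at the geometric mean of the band edges
and −3 dB at both edges. A Gaussian on the linear axis (a classical
Gabor atom) cannot hit both edges of an octave-spanning band
symmetrically; the log-Gabor parameterization is the natural
realization of "symmetric on a log axis" and keeps relative bandwidth
consistent across bands. Time-domain coefficients are obtained by
inverse FFT of the one-sided response and truncated at the exp(−8)
envelope level (the 4σ point of a Gaussian). Kernel widths and lengths
are package choices; no particular widths are prescribed by the band
table itself.

The background signal (3.5–200 Hz) is reconstructed as the **sum of
the θ…R band outputs** rather than by one wide kernel, reusing the
bank and matching the band-table definition of background.

Spectrograms for segmentation use Morlet-style Gaussian-windowed
exponentials on a linear grid (default 200–600 Hz in 5 Hz steps,
`n_cycles = 6`, window truncated at 4σ_t, unit peak response per
frequency).

## FR detection, segmentation, validation

* **Detection** (automatic stand-in for visual pre-selection): the
  FR-band analytic envelope must exceed `k = 3` times the robust RMS
  (1.4826 × median absolute deviation) of the whole FR-band record for
  ≥ 6 ms; runs closer than 10 ms are merged; windows are padded by
  ±50 ms. All thresholds are config keys.
* **Segmentation**: within a window the FR-band spectrogram is
  smoothed with a 2-D Gaussian (σ = 1 time bin × 1 frequency bin) and
  flooded by marker-based watershed (markers = regional maxima,
  negated magnitude as relief). The catchment basin containing the
  global peak defines the event; onset/offset are the first/last time
  bins whose in-basin magnitude reaches 50% of the basin peak. The
  smoothing scale and the 50% extent rule are this package's concrete
  reconstruction of a procedure that is usually described only
  pictorially.
* **Validation**: an event is a true FR iff (i) at least 4 local
  maxima of the FR-band signal inside the segment exceed twice the
  background amplitude, (ii) the peak FR-band envelope is at least
  twice the background amplitude, and (iii) the event is not a
  harmonic of ripple-band activity. "Background amplitude" is
  operationalized as the robust RMS of the background-band signal over
  the full record. The harmonic check flags events whose peak
  frequency lies within ±10 Hz of 2× or 3× the concurrent R-band
  spectral peak *and* whose R-band peak power exceeds the FR peak
  power; the spectral slice is widened to at least 32 ms for usable
  frequency resolution.
* **Energies**: `E_band = Σ_{i=onset}^{offset} x_band[i]²` over the
  segmented extent, per channel, in the FR and background bands.
  Doubling an amplitude exactly quadruples the energy, which is why a
  four-fold energy ratio and a 6.02 dB gain gap are the same
  statement.
* **Comparison**: per-event energies of the two channels are paired
  by event id and compared with a one-tailed paired t-test on log10
  energies (direction fixed: coated > uncoated). Log energies are used
  because event energies are approximately log-normally distributed
  and are conventionally displayed on a log scale. Degenerate
  zero-variance cases return t = 0, p = 0.5 (identical inputs) rather
  than NaN.

Conventions throughout: half-open sample intervals `[onset, offset)`,
0-based indices, times in seconds (serialized at 6 decimals).

## Synthetic data

The generator emulates the two-electrode in vivo configuration: one
neural signal seen through two different electrode transfer functions.

* **Background**: Gaussian noise spectrally shaped to `1/f^β`
  (β ∈ [0, 2], default 1), scaled to a total RMS of 50 µV — a typical
  LFP background scale in arbitrary-but-consistent volts.
* **FR bursts**: sinusoid at 200–600 Hz under a Gaussian (FWHM =
  n_cycles/freq) or Tukey envelope, n_cycles ≥ 4. Ground-truth
  onset/offset are the envelope half-maximum crossings.
* **Channels**: the shared neural signal is filtered in the frequency
  domain by each channel's `H(jω)` (1 s reflect padding against
  circular artifacts), then thermal noise is added with RMS
  `√(4·k_B·T·R_eff·fs/2)`, `R_eff` = median `Re Z` over 1 Hz–1 kHz
  (T = 310 K), plus white amplifier noise (default 1 µV RMS). The
  thermal-noise formula is the package's own concrete choice for a
  mechanism usually invoked only qualitatively.
* **`paper_like` scenario** (the default study conditions): 60 s at
  fs = 2048 Hz, β = 1, 20 events uniform in 220–550 Hz and 4–12
  cycles, channel A = `au`, channel B = `au_pedot`, C_s = 3 nF both.
  Event amplitudes are drawn uniformly from 120–300 µV (2.4–6× the
  background RMS): the validity criterion itself requires a true FR to
  be at least twice the background amplitude, so smaller bursts would
  by definition not be classifiable events. Recording, detection and
  statistics problem sizes in the test suite (10–60 s records, 8–20
  events, 100 segmentation trials, 55 pairs for the significance
  check) are the package's chosen desk-scale study sizes.

All randomness uses `numpy.random.default_rng` (PCG64); one seed per
`RecordingSpec` drives background, events and noise in a fixed stream
order, so a fixed spec is bit-reproducible across platforms.

What the generator does **not** emulate: spike-like artifacts and
"false ripple" filter ringing, non-stationary background, electrode
drift and scar-tissue dynamics, or any biophysical FR generation
mechanism. Passing tests therefore demonstrate correctness of the
measurement chain (filters, segmentation, energies, statistics) under
controlled conditions, not detector performance on real iEEG.

## Degenerate inputs and numerical notes

* Impedance spectra must be strictly increasing in frequency; readers
  sort and validate. Fitting is invariant to input row order.
* `H` at exactly 0 Hz is defined as 1 (the divider limit for every
  passive model here).
* All-zero candidate windows raise a no-event error that the pipeline
  skips; degenerate segments (< 4 samples) validate as invalid rather
  than raising.
* Watershed ties and plateau maxima follow scikit-image's
  deterministic labeling, so segmentation is reproducible for fixed
  input.
* Event energies are computed on the Gabor band outputs (not on
  raw-signal slices), consistent with the filter-bank definition of
  the bands; the t-test uses log10 energies.

## Known limitations

* The model family is deliberately small: no finite-length or porous
  Warburg variants, no inductive elements, no Kramers–Kronig validity
  testing, no multi-spectrum global fitting.
* The uncoated transfer function approaches unity extremely slowly at
  low frequency (`ωZ ~ ω^(1−n)` with n = 0.890), so "DC gain = 1" is
  only visible far below the measurement band.
* With the canonical presets and C_s = 3 nF the model predicts a
  ~3.7 dB inter-electrode gap in the middle of the FR band; measured
  in vivo gaps can be larger, and the divider model with a single
  lumped shunt is only as good as the C_s estimate.
* RCT of the uncoated circuit is weakly identified by 1 Hz–10 kHz
  spectra; fits recover it on noiseless data, but on noisy data its
  uncertainty is large.
* EDF files can be read (via mne) but not written; the native
  interchange format is raw float32 + JSON sidecar.
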