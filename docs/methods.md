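# Methods

This note records the models, parameter choices and known limitations of
the package, in the spirit of a methods supplement: everything stated here
is computed by the test suite or the acceptance script, not asserted.

## 1. Signal model

Each recording site of the MEA reports a voltage time series whose
one-sided power spectral density S_V(f) (V²/Hz) is modelled as the sum of
three independent sources:

    S_V(f) = A_pink / f^α  +  S_white · (1 + ε_sensor)  +  ΔS_V(f)

* **1/f^α background** (α = 1 by default) from the acquisition
  electronics; it dominates below ~10 kHz and is excluded from analysis.
* **White floor** S_white with a fixed per-sensor relative offset
  ε_sensor ~ N(0, σ_sensor); a sensor's floor is a device property, so a
  culture recording and its bare calibration share the same offsets.
* **Adhesion noise** ΔS_V, present only under cells: the Johnson–Nyquist
  noise of the cell–chip cleft resistance,
  ΔS_V = 4·k_B·T·Σ_cells(fraction·R_J)·B(f), where `fraction` is the part
  of the sensor's area each cell covers and B(f) is the plateau shape.

Because the sources are independent their powers add, which is what
justifies recovering ΔS_V by subtracting the bare-sensor spectrum
bin-wise. On PSD-type inputs this subtraction is exact by construction;
on time-series inputs it carries Welch estimation error only.

**Plateau shape B(f).** The cleft is resistive, so ΔS_V is flat over the
analysis band (100–450 kHz). Only in-band flatness is physically
constrained; the out-of-band shape is a modelling choice and is taken as
a raised cosine in log-frequency falling from 1 to 0 over one octave
beyond each band edge. A continuous roll-off avoids spectral
discontinuities that would bias Welch estimates at the band edges.

**Units.** Internally everything is SI (V²/Hz, Hz, K, Ω). The µV²/Hz and
MΩ figures appear only at presentation boundaries (1 µV²/Hz = 1e-12
V²/Hz). This removes the 10^-12 scaling-bug class by construction.

**Temperature.** Recordings default to 310.15 K (37 °C incubation). The
conversion ΔS_V = 0.027 µV²/Hz → R_cleft = 1.58 MΩ holds at this
temperature (room temperature would give 1.64 MΩ). k_B is the exact SI
value and is not configurable.

## 2. Default parameters

| Parameter | Default | Why |
|---|---|---|
| S_white | 5e-15 V²/Hz (0.005 µV²/Hz) | background floor well below the 0.01–0.03 µV²/Hz plateau range, so cells are detectable but not trivially so |
| A_pink | 5e-11 V² | equals the white floor at 10 kHz, making 1/f dominant below 10 kHz and negligible at 300 kHz |
| α | 1 | canonical flicker-noise exponent |
| σ_sensor | 0.05 | few-percent sensor-to-sensor gain spread typical of matched CMOS front-ends |
| band | 100–450 kHz | resistive-plateau band; 300 kHz (band middle) is the single analysis frequency |
| estimator_averages | 100 | per-bin gamma sampling with shape k = 100 emulates the χ²-like fluctuation of a k-average PSD estimate (~10% rel. SD per bin) |
| T | 310.15 K | incubation temperature |
| R_J | 1.58 ± 0.25 MΩ | cleft resistance whose plateau is 0.027 µV²/Hz at 37 °C |
| Welch | Hann, 4096 samples, 50% overlap, no detrend | ≥100 averages per second at 1 MHz; 244 Hz bins resolve the 1–450 kHz range; no detrending keeps the Parseval contract exact |

The background amplitudes are simulator choices, not measured chip
values; they are recorded in every simulation manifest.

## 3. Synthetic layouts and ground truth

Cells are ellipses placed in continuous (µm) coordinates and rasterized
onto the sensor grid at its physical pitch (5.6 × 6.5 µm by default) with
4×4 sub-sensor sampling. Footprints never overlap (checked on a
sub-sensor occupancy raster), but neighbouring cells may share a boundary
sensor's area, as confluent cultures do. The signal at a sensor is
weighted by the covered-area fraction.

**Ground-truth label.** A sensor counts as cell-covered when the total
covered fraction is ≥ 0.5, attributed to the dominant cell. For an
isolated cell this is equivalent to "the sensor centre lies inside the
footprint"; at confluence it also counts sensors straddling two touching
cells, which carry an unambiguous cellular signal.

**Placement.** Sparse layouts use random sequential placement. Because
random placement jams near ~50% occupancy, confluent targets are packed
on a jittered lattice with sizes drawn near the lattice pitch, and any
remaining shortfall is filled with progressively smaller cells (down to
single-cell scale) — the spatial statistics of a culture approaching
confluence, not of a hard-sphere gas.

**Footprint scale.** Epithelial cancer cells on collagen grow as
multi-cell clusters, and fibroblasts are large (~40 µm); covered-area
studies therefore default to cluster-scale footprints (80 ± 20 µm).
Isolated ~15 µm footprints (2–3 sensors across at this pitch) sit at the
segmentation resolution limit — see the limitations in section 6 below.

**Dynamics.** Trajectories over the 0/24/48/72 h schedule come in three
kinds. *Static* repeats the layout. *Detachment* removes each cell per
interval with probability 1 − e^(−r·Δt). *Proliferation* adds daughter
footprints adjacent to surviving parents, tracking the exponential
footprint-area target A₀·e^(r·t); a daughter's size is drawn once (drawing
per placement attempt would select small cells), and daughters shrink
stepwise when no pocket fits, emulating in-fill near confluence. The
presets r = ln 2 / 72 h (growth) and r = ln 1.8 / 72 h (decay) reproduce a
2.0× rise and a 1.8-fold decline of covered area at 72 h; the detachment
fold fluctuates per chip (few clusters, Bernoulli removal), so fold-change
summaries average n = 4 simulated chips.

**Time series.** Gaussian series are spectrally shaped: a white complex
spectrum is scaled by √(target PSD) on the FFT bins and inverse
transformed. The DC bin is zeroed. The expected Welch estimate equals the
target, and the one-sided PSD integrates to the series variance
(verified to <2%).

## 4. Imaging pipeline

Processing order is fixed: percentile clip → 8-bit grayscale → Gaussian
blur → Otsu threshold → morphological opening, closing, minimum-size
filter → 8-connected components.

* Grayscale maps the [P1, P99] range of the zero-clamped ΔS_V map at
  300 kHz linearly onto 0–255; the mapping is scale-invariant, and a
  constant (e.g. empty) map renders all-zero.
* Negative ΔS_V values are kept in the raw map — they are needed for
  unbiased means — and clamped only for imaging, which also stabilizes
  the Otsu histogram.
* Blur: 5×5 kernel, σ = 1 px, reflective borders; suppresses
  single-sensor errors.
* Otsu is implemented as the exhaustive between-class-variance scan over
  all 256 gray levels (ties take the lowest level); cells are the bright
  class, which by construction of the `> t` partition has the higher mean
  gray. A constant image yields an empty mask.
* Morphology: 3×3 square opening then closing with edge-replicated
  borders (so border objects are not eroded by the implicit zero
  background), then removal of components below 4 sensors (≈ one 15 µm
  cell at this pitch). All parameters are config-exposed.
* The analysis frequency is looked up at the nearest grid bin, no
  interpolation; an exact midpoint resolves to the lower bin.
* A per-sensor k·σ rule against the bare-calibration statistics
  (`detect_cells_threshold`, default k = 3) is provided alongside the
  Otsu pipeline; at plateau-to-background-SD ratios ≥ 5 both classify
  sensors with > 0.95 balanced accuracy.
* Overlay onto micrographs consumes a user-supplied 2×3 affine transform;
  no automatic registration is attempted.

Covered area is exactly 100 · (mask-true sensors) / (total sensors).

## 5. Quantification and statistics

Mean ΔS_V per chip uses the **raw** (unclamped) values over mask-true
sensors to avoid positive bias. Fold changes report ratio ≥ 1 with an
explicit direction label ("increase" t₁/t₀, "decline" t₀/t₁), since
"x-fold" is ambiguous in either direction. CCK-8 viability is
(sample − blank)/(control − blank)·100, unbounded above for proliferating
controls. Group comparisons are unpaired t-tests per timepoint, one-way
ANOVA across time, or two-way fixed-effects ANOVA
(condition + time + interaction) via statsmodels, annotated with the
four-level star scheme (ns, * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001,
**** ≤ 0.0001) and no multiple-testing correction. Two identical
zero-variance groups are defined to give p = 1 (scipy returns NaN there);
zero-variance groups with different means give p = 0.

The plateau flatness statistic is max |log10(ΔS_V/band mean)| over in-band
bins; a spectrum is flagged resistive below 0.15 (configurable — there is
no field-standard criterion). A 1/f spectrum across the band fails this
flag by a wide margin.

## 6. Problem sizes and what the tests do (and do not) show

Simulations run on a 64×96 grid at the chip's physical pitch (≈ 6,100
sensors, ~0.42 × 0.54 mm) — large enough for tens of cluster-scale
objects while keeping the full suite and the acceptance script in the
tens of seconds. The spectral round trip uses 1 s at 1 MHz sampling.

Passing tests demonstrate: exact Eq. arithmetic; an unbiased spectral
path (synthesis → Welch → subtraction recovers 4k_BT·R_J within 5–10%);
segmentation whose covered area tracks ground truth within ±3 pp on
cluster-scale layouts from 10% to 60% coverage; and preset dynamics that
reproduce the 2× / 1.8-fold 72 h calibration targets.

They do **not** show:

* accuracy on isolated single ~15 µm cells. At ~6 µm pitch such
  footprints span 2–3 sensors; the blur halo and the low Otsu threshold
  that a heavy zero-background histogram induces inflate the detected
  area by several pp (a dedicated test documents the positive bias).
  Real HT-29 on collagen forms clusters, which is the regime validated.
* robustness to spatially correlated noise, amplifier transfer functions
  or ADC quantization — the simulator deliberately omits electronics
  modelling beyond the 1/f + white background.
* the sub-10 kHz region, excluded as setup-dominated.
* any biology: detachment/proliferation presets are phenomenological
  calibrations, not mechanistic models of 5-FU action.

## 7. Other design decisions

* The chip's stated active area (1.6 × 2.5 mm) is not exactly
  rows·pitch × cols·pitch for either axis pairing; the model stores the
  exact n·pitch extent (1.664 × 2.150 mm) and leaves rounding to
  presentation, without attempting to reconcile the two.
* The cytoplasmic-resistivity analysis of the core-coat conductor model
  (ρ_cyt ≈ 800–950 Ω cm) is out of scope: the governing equations live in
  prior interface-physics literature and are not reimplemented here.
* Recording I/O uses a small documented HDF5 schema (`/values`,
  `/freq_grid` or sampling metadata, JSON attribute blocks for geometry
  and recording metadata); per-sensor scalar maps export as
  (row, col, value) CSV. No proprietary acquisition formats are read.
* The acquisition software's exact PSD estimator is unknown; Welch with
  the documented defaults is a stated substitute, not a reproduction.
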