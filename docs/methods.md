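# Methods

This note documents the models behind each subsystem of the digital
twin, the parameters that matter, the numerical choices, and what the
synthetic plants do and do not capture about real cultures.

## Stimulation waveform

A burst-mode rectangular pulse train is synthesized on a uniform sample
grid (default 10 kHz, resolving 4 ms pulses with 40 samples and edges to
0.1 ms). Each burst carries ⌊f·T_burst⌋ pulses at period 1/f, the first
starting at the burst's start; the signal sits at baseline during the
rest interval. One burst+rest cycle is sampled and then tiled, which
makes burst periodicity exact by construction; the cumulative edge drift
this introduces is below half a sample period per cycle.

Voltage convention: the default dialect is a two-level signal symmetric
about 0 V — +V_pp/2 during a pulse, −V_pp/2 otherwise — so a "40 V_pp"
protocol swings ±20 V. Oscilloscope captures of such signals constrain
amplitude and timing but not the DC reference, so a monopolar 0→V_pp
dialect is provided as a configuration alternative. Pulse width is
measured as the median high-interval duration, robust to a corrupted
pulse and accurate to one sample period.

## Lipid-droplet plant

Droplet radii follow a linear rate law with clamping:
r ← max(r_min, r ± rate·dt), growing at 0.4 px/h under insulin and
shrinking at 0.6 px/h under adrenaline (r_min = 1 px). Linearity is the
minimal model that yields the observed monotone rise under lipogenic and
fall under lipolytic stimulation; no biophysical rate law is implied.
The growth/shrink defaults are set so that, with the default feedback
field (150 non-overlapping droplets of 5–9 px radius in a 320×240 frame),
one hour of stimulation moves the index by roughly 0.44/0.66 percentage
points — comfortably straddling the 0.3 pp switching threshold so the
closed loop is exercised within a 13 h run.

Clusters drift at constant velocity (direction fixed per cluster by the
seed) with optional Poisson-distributed jump events, reproducing the
disturbance in which whole clusters leave the field of view. Jump draws
are keyed on the quantized simulation time, so the disturbance sequence
depends only on the schedule, not on call granularity.

Rendering: droplets are bright disks (intensity 150) with a 2 px dark
rim (intensity 40) over a smooth textured background (mean 100, sd 8),
plus optional additive Gaussian noise, clipped to 8 bit. The rim band is
centered on the droplet radius so the thinned contour traces the true
circumference; drawing the rim strictly inside the radius instead biases
the index low by ~30% at r = 5 px. The background texture is fixed per
plant seed and per-frame noise is seeded from (seed, time), so a fixed
schedule reproduces a bit-identical image stack.

Absolute droplet sizes, optical magnification, and intensity calibration
are free parameters of the twin: only relative changes in the index are
meaningful, as in the physical system.

## LD monitor

Default pipeline: 3×3 median filter → morphological gradient with a
disk(2) structuring element → global Otsu threshold → Zhang–Suen
thinning. The gradient step makes the foreground the droplet boundary
band (consistent with the index's circumference interpretation) and
renders the index exactly invariant to uniform brightness offsets. The
disk(2) element is load-bearing: a disk(1) gradient leaves the rim's
inner and outer edge responses disconnected and thinning then produces
two concentric loops per droplet (~1.4× the true circumference), while
disk(2) merges them into one annulus whose skeleton sits at the rim
center. A plain-intensity Otsu dialect ("intensity") is provided; it
extracts filled droplet bodies rather than boundaries.

Thinning iterates scikit-image's Zhang–Suen implementation together with
a pruning pass to a fixpoint, which makes the operation idempotent by
construction. The parallel Zhang–Suen pass occasionally leaves 2×2
staircase blocks at contour junctions; pruning deletes a simple pixel
(one 8-connected foreground component in its neighborhood and one
4-adjacent background component) from each block, falling back to a
global component-count check at junction clumps. In the rare degenerate
case where two fused rims share a single-pixel wall and no deletion
preserves topology exactly, strict 1-px width is preferred and one rim
is opened by a single pixel — a one-part-in-10³ effect on a pixel-count
index. Featureless frames (gradient range < 10 intensity units) binarize
to all-background rather than thresholding noise.

Accuracy: on rasterized circles of radius 5–40 px the index falls ~9%
below the analytic 2πr/area because the 8-connected digital contour
counts diagonal steps as single pixels; this systematic deficit is well
inside the ±15% verification band and cancels in all relative
comparisons. Over random droplet fields the index correlates with the
analytic circumference density at Pearson ≥ 0.98.

## Feedback controller

Bang-bang rule with threshold θ (default 0.3, interpreted as absolute
percentage points of the index; a relative-percent dialect is available).
Strict inequality: a deviation of exactly θ does not switch. On each
switch the reference is replaced by the index at the switch (default
"on_switch" mode). The alternative "previous_frame" mode re-references
to the immediately preceding frame at every step; it rejects slow
drifts entirely, so a creeping disturbance never switches — the two
modes are genuinely different policies and both are kept selectable.
The initial stimulant defaults to insulin. Imaging cadence in closed
loop is 1 h; the controller acts on the newest frame with no actuation
delay, and the active stimulant is held constant within each interval.

## Contraction imaging

Dense optical flow uses scikit-image's iterative Lucas–Kanade
(`optical_flow_ilk`, radius 15, 10 warp iterations, Gaussian weighting),
which in validation recovers radial warps of 0.5–5 px with mean-magnitude
error under ~5%. A block-matching fallback assigns each tile the
phase-correlation shift (Hann-windowed, mean-removed, unnormalized FFT
correlation — the normalized variant is unreliable on smooth textures).
The representative displacement is the mean flow **magnitude** over all
pixels: a radial contraction has a near-zero mean signed vector, so
averaging magnitudes avoids cancellation; a signed interpretation can be
recovered from the returned field if needed.

The synthetic movie warps a Gaussian-filtered random texture radially
toward the frame center by the commanded displacement during each
burst's frames (uniform magnitude outside an 8 px linear core, so the
mean applied displacement ≈ the commanded peak) and releases it between
bursts. The ground-truth trace holds the mean displacement change
actually applied per frame pair; flow therefore spikes at burst onset
and release. Default schedule mirrors the electrical protocol (1 s
on / 4 s off); capture rounds default to 5 s at 5 fps in the orchestrated
experiment, a scaled-down stand-in for the 25 s imaging rounds that
preserves one full contraction cycle per round.

The generator does not emulate cell-scale deformation heterogeneity,
focus drift, or photobleaching; passing recovery tests demonstrates the
flow pipeline's correctness on idealized motion, not robustness to
microscope artifacts.

## Fluidics

**Sampling.** The four-phase cycle (circulating 180 s, sampling 10 s,
drainage 30 s, waiting) runs only at scheduled times (default 0, 3, 6,
12, 18, 24 h); off-schedule calls are logged no-ops. The aliquot volume
is π·(d/2)²·L from the valve-to-valve tube segment; the defaults
(d = 1.6 mm, L = 19.89 mm) give 39.996 µL ≈ 40 µL. The virtual biosensor
enforces a 40 µL minimum read volume with 0.1% relative tolerance so the
default geometry's aliquot is accepted; sensor noise is multiplicative
Gaussian, clipped at zero, deterministic per seed.

**Mixing.** The dish is an 8-compartment ring (10 mL total). Per 1 s
sub-step each compartment passes fraction f = Q·dt/V of its contents to
the next compartment (Q = 2 mL/min circulation) and fraction g·dt to each
neighbour (g = 0.05 /s exchange). The update matrix is doubly stochastic:
dye mass is conserved exactly and the coefficient of variation never
increases. Pure advection at 2 mL/min alone would need ~35 min to
homogenize (slowest circulant eigenmode |λ| ≈ 0.998 per second); the
exchange term represents the turbulent/diffusive mixing the pump jet
induces, and g = 0.05 /s was chosen from the eigenvalue decay rate so a
single-compartment bolus reaches CV < 5% in ≈ 90 s, comfortably inside
the 180 s circulating phase. Arbitrary `dt` is integrated in ≤ 1 s
sub-steps.

**Metabolites.** Control lactate is linear, L_c(t) = L₀ + k·t (defaults
L₀ = 1 mM, k = 0.5 mM/h — arbitrary scale, as only ratios are anchored).
Stimulation multiplies it: L_s = L_c·(1 + e(t_s)) with the power law
e(t_s) = E₂₄·(t_s/24 h)^α, where α = ln(E₆/E₂₄)/ln(6/24) ≈ 0.447 is fixed
by the anchors e(6 h) = 0.14 and e(24 h) = 0.26 and t_s is time inside
the stimulation window. The law is monotone in stimulation time with
e(0) = 0. Glucose declines linearly (5.5 mM initial, 0.1 mM/h uptake,
floored at zero) and is identical in both arms. In the 24 h total-system
experiment, where stimulation runs only from 12 h and the observed excess
is smaller, the excess law is rescaled at run time so that the full
12 h stimulation window yields 7% (scale ≈ 0.367); the two experiment
variants differ in culture state and this per-experiment calibration
constant is the twin's way of representing that difference.

## Orchestration and determinism

`RunConfig` + seed fully determine every emitted table; `RunRecord.digest()`
hashes the canonical CSV text of all tables so re-runs can be compared
bit-exactly. Sub-seeds for sensors and movie rounds are derived with
`numpy.random.SeedSequence`, never shared. The feedback experiment uses a
240×320 frame with 150 droplets (see the plant section); the renderer's
stand-alone default is 480×640. CSV schemas are fixed:
`index.csv (frame_id, time_h, index_percent)`,
`events.csv (time_h, from, to, index_percent)`,
`actions.csv (frame_id, time_h, action)`,
`aliquots.csv (time_h, volume_ul, lactate_mM, glucose_mM, container_id)`,
`displacement.csv (round_h, frame_pair, time_s, mean_px)`.

## Known limitations

- Droplet kinetics are linear and noise-free by default; real lipolysis
  saturates and fluctuates. The twin's purpose is exercising the control
  loop, not predicting adipocyte physiology.
- The closed-loop band property holds for the default calibrated field;
  much sparser fields move less than the threshold per hour and the
  controller (correctly) never switches.
- Overlapping droplets merge contours, so the index under-counts dense
  fields; the default generators keep droplets separated.
- The mixing model is a 1-D ring, not a hydrodynamic simulation; its
  exchange constant is calibrated, not derived.
- Optical-flow accuracy degrades beyond ~6 px/frame displacements with
  the default iLK parameters; the synthetic protocol stays within this
  range, as does the physical system's frame rate.
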