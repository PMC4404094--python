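# Methods

## The measurement model

A bird of mass m walking over the platform applies a vertical force
F(t) = m(g + a(t)), where a(t) is its centre-of-mass (CoM) vertical
acceleration, g = 9.8 m/s². The instrument records F through the
platform-on-load-cells assembly (a lightly damped second-order oscillator
with unit static gain), adds the empty-bridge offset F₀, and digitizes at
200 Hz. Integrating Newton's second law over a window [t₁, t₂],

    m[v(t₂) − v(t₁)] = ∫ [F − F₀ − mg] dt,

leads to the two-stage estimator implemented in `weight.py`:

* **W₁** — trapezoidal mean of the net force over the window, divided by the
  calibration gain. Its error is m·Δv/(t₂−t₁): small when the window is long
  and when its endpoints sit at the same gait phase (equal v).
* **W₂ = W₁(1 + a/g)** — the trend slope *a* of the reconstructed velocity
  v(t) = (g/W₁)∫[F − F₀ − W₁]dt measures the relative error of W₁ and removes
  it to first order.

Two structural properties of this estimator are worth making explicit, since
both are verified numerically in the suite and shaped the design:

1. **The correction cannot repair an offset error.** Because W₁ is the mean
   of the same integrand over the same window, ∫[F − F₀ − W₁]dt ≡ 0
   regardless of any error δ in F₀; the reconstructed velocity is pinned to
   zero at both window ends and carries no trace of δ. An offset error passes
   straight into W₂ (δ/gain kilograms). This is why F₀ is re-estimated for
   every crossing and why the offset estimate's precision budget (below) is
   the tightest in the chain.
2. **The trend fit has a small deterministic bias for windows anchored at
   force peaks.** The force peaks where dv/dt is largest, i.e. where v rises
   through zero; a window spanning whole gait periods anchored there makes
   the velocity oscillation an odd function about each period's centre, and
   an ordinary least-squares slope picks up a bias ≈ 0.32·α/(f²T²) in units
   of g (α the gait force amplitude as a fraction of body weight, f the step
   rate, T the window length). At penguin stepping rates (~5 steps/s, one
   step ≈ 0.2 s — the same figure that sets the peak-detection bin width) and
   windows of 2–4 s this is 0.01–0.05% and is the floor of the method's
   accuracy; at much slower stepping it would grow quadratically. This bias
   is a property of the estimator, not of the simulator.

## Processing chain and its parameters

Per crossing (defaults in `config.py`, all overridable by YAML):

1. **Peaks** — bins of 0.2 s (≈ one step), maximum per bin, validated by
   re-binning with the grid shifted ±0.025 s. A sample qualifies under a grid
   if its *value* equals its bin's maximum: quantized records tie freely, and
   requiring the same argmax index under all three grids would spuriously
   reject peaks in flat (empty-bridge) stretches that the empty filter needs
   to see. Ties within a base bin break to the earliest sample.
2. **Empty filter** — from the first peak below F₀-provisional + 0.5 kg, the
   bird has left; that peak and all later ones are dropped. The provisional
   baseline is the 1st percentile of wgt1, so kg-denominated thresholds
   survive offset drift.
3. **Overload filter** — from the first peak above the multiple-penguin
   level, more than one bird is aboard. The level must clear the strongest
   single-bird transient: hop landings reach ≈1.8× body weight after the
   oscillator overshoot, so the default (8.5 kg) suits a ≤4.5 kg-bird
   installation and the 2–8 kg study ensemble uses full scale (15.5 kg).
   Entry/exit hops are ordinary single-bird features; a threshold below them
   would truncate every record at its first peak.
4. **Window** — second to second-to-last surviving peak (hop transients
   excluded); fewer than four peaks → flagged unmeasurable record.
5. **Offset** — mean wgt1 over the longest ≥0.25 s run where wgt1 is below
   F₀-provisional + 0.5 kg and (when a per-deployment channel map is
   available) the two channels agree to 12 raw units; a still empty platform
   loads both cells in a fixed ratio, so agreement rules out a stationary
   bird. Fallback: nearest prior crossing's offset, then nearest following.
6. **W₁, v(t), trend, W₂** as above; quadrature is the trapezoid rule
   (second-order at 200 Hz, deterministic), the trend is the centred-sums
   least-squares slope. The dimensionless correction (1 + a/g) is applied to
   the calibrated weight; velocity is computed in raw force units, which
   cancel.
7. **Calibration** — gain is the through-origin least-squares slope of net
   (offset-subtracted) plateau readings on applied mass, pooled over all
   weekly placements of 2/4/5/7/9 kg standard masses on both cells; plateau
   readings discard the first 2 s of ringing. The land-vs-sea slope
   difference is reported as a diagnostic only.
8. **Direction** — (i) wgt2 at the second peak minus wgt2 at the
   second-to-last peak against a ±60 raw dead band; (ii) mean wgt2 over the
   first 0.25 s against a 200/300 raw dead band. Agreement → confident call;
   one definite call → kept but flagged low-confidence; opposite calls →
   conflict. The installation's geometry (which cell feeds wgt2) is a config
   switch so a mirrored build flips cleanly.
9. **Trips** — per tag, each outward crossing pairs with the next inward one
   (a newer outward replaces a pending one), bounded by a 14-day maximum;
   meal proxy = weight in − weight out. Unknown-direction crossings stay in
   summaries but never pair.

## The simulator

The generator (`simulator.py`) works in the velocity domain so that force and
velocity are a single consistent object. The CoM velocity of a crossing is a
continuous quasi-periodic oscillation
v(t) = A(t)·[cos 2πφ + (β/2)·cos(4πφ + ψ)] with per-step period jitter (10%)
in the phase rate φ̇, per-step amplitude draws (±15%) smoothly interpolated
into the envelope A(t), and a random-phase second harmonic (force ratio β).
Each gait bout starts and ends at a zero of v (phase k + ¼), so landings,
pauses, push-offs and turn-arounds join without velocity discontinuities —
a discontinuous v would imply infinite force. Entry and exit hops are
raised-cosine acceleration bumps carrying the hop impulse. The applied force
is m(g + a) with a the analytic derivative of v; the *discrete* ground-truth
velocity is the cumulative trapezoid of the sampled acceleration, which makes
the impulse identity ∫(F − mg)dt = m·Δv hold on the grid to machine
precision (the simulated world is the sampled one). An earlier construction
with independently drawn per-step pulses put a velocity discontinuity at
every step boundary and leaked a systematic artefact into the trend
regression; physical continuity of v removes it.

The instrument model: second-order oscillator (default 30 Hz, damping ratio
0.15 — the published account gives no numbers, only "settles in a couple of
seconds", which these defaults reproduce; both configurable), discretized by
a bilinear transform prewarped at the resonance so the sampled system rings
at the configured frequency. The reaction splits between the cells by the
lever rule along the bird's path; each cell share passes through the
oscillator, is scaled (main: 32 raw/kg; auxiliary: 120 raw/kg + 100 offset),
dithered with Gaussian noise (0.5 raw main, 3 raw aux) and quantized (9-bit
main, 7-bit auxiliary over full scale). Clipping is flagged, never silent.
Scenario scripting covers single crossings, sequential and overlapping
two-bird records, turn-arounds, pauses, offset drift across a deployment and
calibration placements, all deterministic under a seed.

**Why these defaults.**

* *Main-channel range*: 9-bit ADC at 32 raw/kg → ≈16 kg full scale, sized so
  the strongest transient of the 2–8 kg study population (hop landing
  ≈ 1.8 × 8 kg) stays on scale. A macaroni-colony installation (birds ≤6 kg,
  range "just under 10 kg") corresponds to gain ≈ 51.
* *Main-channel noise 0.5 raw*: an a-priori error budget. One raw unit is
  ≈31 g, so the offset must be recovered to ~0.1 raw for W₂'s 0.1% target;
  sub-LSB electronic noise dithers the quantizer, making the mean over an
  empty stretch unbiased with standard error ≈ 0.5/√N raw (≈0.03 raw over a
  2 s tail).
* *Auxiliary scale 120 raw/kg + 100 offset*: chosen so the conventional
  direction thresholds (60/200/300 raw) are meaningful across 2–8 kg birds;
  the published account leaves this channel's numeric scale ambiguous.
* *Stepping 4.5–5.5 Hz, gait amplitude 0.2–0.5 of body weight*: one step
  ≈ 0.2 s; the second-harmonic ratio 0.2–0.4 reflects the asymmetric rise
  and fall of a real stance force.
* *Ensemble durations 3.5–5.0 s aboard* (speed 0.16–0.23 m/s over the 0.8 m
  platform): the accuracy study targets the long, steady, repetitive records
  on which the second approximation's headline accuracy is premised — the
  trend-bias floor above shrinks as 1/T². Short or hurried crossings are
  exercised separately (filters, flags, quality tiers), not in the accuracy
  ensemble.

## What the simulator does and does not emulate

It reproduces the features the algorithm must survive: quasi-periodic
stepping with jitter, hop transients, bridge ringing, position-dependent cell
sharing, coarse quantization, channel noise, offset drift, pauses,
turn-arounds, two-bird records and RFID reads. It does not attempt
biomechanically faithful penguin gait (no double-support force sharing, no
lateral waddle coupling), 2-D platform dynamics, partial support at the
platform edges (a bird standing half on the ground), fur-seal interference,
or temperature effects on the load cells. Passing the recovery tests
therefore shows the estimator is correct and numerically robust under the
stated physics — not that field records of real birds meet these accuracy
figures; the field-scale checks (manual dynamometer comparisons,
manual-vs-automatic window audits) are supported as analysis modes
(`validate_against_manual`, `compare_windows`) but need real data.

## Numerical choices, degenerate inputs, limitations

* g is fixed at 9.8 m/s²; trapezoid quadrature throughout; ties in peak
  detection break to the earliest sample; the window requires ≥4 surviving
  peaks and ≥2 samples.
* Records are never dropped silently: unreadable files, too-few-peaks,
  missing offsets and nonpositive mean forces all come back as flagged rows.
* Clock correction is affine through one or two anchor events (the logger has
  no real-time clock); with two anchors both map exactly and event order is
  preserved.
* Trip pairing across midnight or multi-day trips is bounded by a
  configurable 14-day maximum — an operational convention, flagged in the
  output schema, not derived from data.
* Known limitations: the trend-bias floor grows as α/(f²T²), so very slow
  steppers on short windows are intrinsically less accurate than the headline
  figure; the overload filter cannot separate two light birds from one heavy
  one by level alone; direction calls for birds that turn round mid-platform
  are deliberately low-confidence or unknown rather than guessed.
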