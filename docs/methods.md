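# Methods

## The model

The mosquito drinking apparatus is represented as a series network: food
source → feeding canal (tube 1) → cibarial pump (CP) → pharynx (tube 2,
containing a backflow valve) → pharyngeal pump (PP) → esophagus (tube 3,
with a no-backflow valve) → gut.  The working fluid is a sugar/contrast
solution (ρ = 1100 kg/m³, μ = 3.0 mPa·s, σ = 0.077 N/m).

**Regime screening.**  With the literature bound U ≤ 1 cm/s on canal
velocity, Re = ρUD/μ ≈ 0.09 in the narrowest tube, and the Womersley number
α = (ρD²/μT)^½ < 0.1 for all tubes at the continuous-mode period.  Flow is
therefore laminar and quasi-steady: each tube obeys the Hagen–Poiseuille
relation Δp_i = K_i Q_i with impedance κ(L, D) = 128 μL/(πD⁴), and entrance
effects (l_e ≈ 0.6 Re D ≤ 3 μm) are negligible.

**Pumps.**  Each pump lumen is a prolate spheroid of fixed semi-major axis
b = L/2 and oscillating semi-minor axis a(t), volume V = (4π/3) a² b.
Pressure inside a pump is spatially uniform (quasi-static pump
assumption — the model's largest idealization: it neglects losses inside
the pumps).  Continuous mode drives a(t) as a raised cosine of period T_C =
233.5 ms with the PP delayed 83.5 ms; burst mode is a single 1−cos stroke
per pump inside a 703 ms period (CP 0.4–662 ms, PP 153–646 ms), resting at
the minimum height outside the stroke.  Both waveforms are C¹ everywhere;
volume rates are evaluated from the closed-form derivative, never finite
differences, because the instantaneous solution is linear in V̇ and
derivative noise would contaminate the pressure peaks.

**Instantaneous solve.**  Mass conservation in each pump
(V̇_CP = Q₁ − Q₂, V̇_PP = Q₂ − Q₃) plus the three tube laws give a linear
5×5 system in (Q₁, Q₂, Q₃, p_CP, p_PP) whose closed form is evaluated
directly.  Valves make K₂ and K₃ direction-dependent: under backflow
(Q₂ < 0) a 20 μm section of the pharynx constricts to 5 μm; reverse
esophageal flow (Q₃ < 0) multiplies K₃ by 10⁶ (a finite stand-in for a
sealed valve that keeps the solve well posed).  The sign-consistent branch
is found by enumerating the four (sign Q₂, sign Q₃) combinations in the
fixed order (+,+), (+,−), (−,+), (−,−) and accepting the first whose
solution reproduces its assumed signs; Q = 0 counts as forward.  If two
branches are consistent at a crossing instant the forward-most wins (logged
at debug level); if none is, the solver raises with diagnostics rather than
guessing.  Because the kinematics are exactly periodic and the system is
memoryless, one period with no spin-up *is* the periodic solution.

**Power.**  Each pump delivers P_β = −(p_β − p_hemo) V̇_β to the fluid;
summing the per-tube dissipations Q_i Δp_i recovers the same total exactly
(used as an internal identity check at 10⁻⁶ relative).  Muscles cannot
absorb work from the fluid, so the cycle-average expended power rectifies
first: P_γ = ⟨max(0, P_CP) + max(0, P_PP)⟩.  On the default configuration
rectification changes the average by < 3% (2.98% continuous, 0.16% burst).
p_hemo is a configuration value (default: atmospheric), not a constant.

**Knockouts.**  A pump is removed by substituting a static tube of its
length and resting height, κ(L_β, H_min).  With the PP removed the
pharynx–knockout–esophagus path carries a single series flow, so one sign
resolves both valves; with the CP removed the esophageal valve keeps its
own sign.  Comparisons report signed percentage changes of time-averaged
flow, instantaneous peak canal flow ("peak" is taken as the instantaneous
maximum; no other published definition exists), maximum proboscis pressure
drop, and rectified average power, on identical grids.

**Capillarity.**  If air reaches the canal tip, the meniscus opposes
suction with a Laplace jump Δp_m = 2σ/R; a mode can re-prime the canal only
if min_t (p_CP − p_atm) < −Δp_m.  Default R = 25 μm: the source text
defines R as the canal radius (12.5 μm), but its printed −6.2 kPa threshold
equals 2σ/D₁; the default reproduces the printed number and R is
configurable.  (The related "< 3 Pa in a 7 mm droplet" figure is not
reproducible from 2σ/R ≈ 44 Pa and is not used anywhere.)

## Numerical choices

- Internal units are SI throughout (values span ~10⁻¹⁹–10¹⁸ across
  quantities); nL/s, kPa, nW appear only at I/O boundaries.
- Default grid: 2000 steps per period (4000 in the acceptance script).
  Doubling the grid moves the headline metrics by < 10⁻⁶ relative — far
  below the ±5% reproduction tolerance — because the trapezoidal average
  with periodic closure (equivalently, the plain sample mean on a uniform
  [0, T) grid) is spectrally accurate for smooth periodic integrands.
- Time averages use that periodic trapezoid; maxima (Δp_γ) are grid maxima
  of smooth curves, accurate to O(Δt²).
- The unknown-field-rejecting configuration (pydantic, `extra="forbid"`)
  exists because a silent typo among 25 parameters is the dominant failure
  mode of a model like this.

## Known model inconsistencies in the source values

The published pump-volume table prints a PP burst maximum of 7.96 nL, but
the spheroid volume at the published burst height (a = 128 μm, b = 163 μm)
is 11.18 nL, and only the larger value is consistent with the published
16 nL/s burst intake.  `volume_table` computes everything from the spheroid
formula and therefore reports 11.18 nL; the CP "relative change 2.5" cell
arises from rounded volumes (0.30/0.12) — the unrounded ratio is 2.39.

## Trace analysis

The pipeline emulates how pump kinematics are read off x-ray video ROI
intensities (absorption is linear in contrast mass, so intensity tracks
pump volume): 3-point moving-average smoothing (endpoints use shrunken
windows), per-bout min/max normalization, stroke detection, classification,
timing table.

- **Detection** finds prominence-filtered local maxima and minima
  (`scipy.signal.find_peaks`).  The prominence threshold is 0.1 of a
  *robust* amplitude estimate, 2√2 × MAD (exact for a raised cosine),
  rather than 0.1 of the range: embedded ~17× bursts would otherwise
  inflate the range and mask the continuous strokes.  For a pure normalized
  continuous trace the two definitions coincide.
- **Onset refinement.**  When a pump rests between strokes the raw flanking
  minimum sits at a noise-selected point on the flat gap; the stroke
  boundary is therefore refined to the last sample within 5% of the stroke
  height above the minimum.  Without this, start/end estimates carry a
  plateau-length bias (up to ~1.5 frames on the measured mean timings).
- **Classification.**  A stroke is a burst if its un-normalized amplitude
  exceeds 3× the median stroke amplitude of the recording; with fewer than
  3 strokes there is no median context and an absolute fallback (3× a
  robust baseline amplitude) applies, so an isolated large event is still
  recognized.  The CP's burst stroke is only ~2.4× its continuous stroke,
  so at the default threshold CP bursts are found via their detected
  amplitude exceeding the smoothing-attenuated continuous median — the PP
  channel (17×) is the reliable burst indicator and is the one the tests
  pin down.
- **Timing table.**  Each cibarial stroke pairs with the next-starting
  pharyngeal stroke; the cycle runs from CP start to PP end; cycle
  frequency is the reciprocal of the CP start-to-start interval.  Grand
  summaries average per specimen first; with a single specimen the SD is
  across cycles.

## Synthetic traces

The generator states the observed world: 30 fps sampling; continuous bouts
as per-pump stroke trains (defaults: back-to-back 233.5 ms strokes, PP
delayed 83.5 ms; the "measured-means" recipe uses 241/226 ms strokes every
274 ms, reproducing the 318 ms measured total cycle and the −44 ms
inter-cycle overlap); burst events with the measured stroke windows; a PP
burst intensity amplitude 17× the continuous one (the ROI-level figure —
the full anatomical volume ratio is ~109× and would only make bursts easier
to classify); additive Gaussian noise with sd 0.05 of the continuous stroke
amplitude (the real noise process is uncharacterized; 5% is what the
published traces visually suggest); optional linear drift.  Intensity is an
affine image of the spheroid volume trajectory, and every stroke is
recorded in a ground-truth table with exact times, amplitudes, mode labels,
and flags marking which stroke boundaries are sharp (stroke-to-stroke
junctions) versus plateau-adjacent.

What a green recovery test establishes: the detector finds every generated
stroke, localizes sharp boundaries and peaks to one frame, recovers mean
cycle timing to one frame, and never misses a PP burst across 50 seeded
replicates at the default noise.  What it does not establish: robustness to
real-data pathologies the generator omits — occlusion, motion of the ROI,
non-Gaussian or correlated noise, amplitude drift within a bout, or
frame-rate limits (at 30 fps, pumping above ~8 Hz approaches Nyquist and
timing recovery degrades; the frequency-sweep test samples at 90 fps for
that reason).

## Limitations

- No pump-internal pressure gradients or losses (quasi-static pumps); the
  power outputs are lower bounds on muscular expenditure.
- No free-surface dynamics inside the simulation; capillarity enters only
  as the separate threshold analysis.
- Newtonian fluid only — blood rheology, host blood pressure, and drinking
  ecology are out of scope.
- Valve dynamics are instantaneous two-state impedances; no hysteresis or
  finite closing time.
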