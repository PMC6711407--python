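# Methods

`circwave` couples a four-chamber heart model to a one-dimensional
arterial/venous tree in a closed loop and asks what the augmentation index of
the resulting aortic pressure waveform actually measures.  The two
experimental dials are the left-ventricular sarcomere shortening velocity
v_s,LV (cardiac contractility) and the vessel-wall stiffness coefficient k
(arterial stiffness); every pulse-wave index is then read off the simulated
steady-state beat exactly as a clinical pipeline would read it off a
measured one.

## Cardiac mechanics

Each wall is a representative sarcomere in a modified Hill arrangement: a
contractile element (length `L_si`) in series with a series-elastic element
(`L_se`, relaxed length `L_se_iso` = 0.04 um), in parallel with a passive
exponential element loaded by the total length `L_s = L_si + L_se`.  The
contractile element obeys

    dL_si/dt = v_s (L_se - L_se_iso) / L_se_iso,

and the active stress is

    sigma_act = S_act · C · (L_si - L_si,ref) · L_se / L_se_iso.

Because the stress carries the factor `L_se/L_se_iso`, rapid wall shortening
(which pulls `L_se` below its relaxed length) depresses stress linearly in
the shortening rate, with zero-stress intercept exactly at `dL_s/dt = -v_s`:
a linear force–velocity relation whose unloaded-velocity parameter is the
contractility dial (7 um/s for the reference LV, 3 um/s in the reduced-
shortening scenarios).  `L_se_iso` is a fixed wall parameter: the dynamics
relax `L_se` to `L_se_iso` whenever activation is low, so the value captured
at the onset of isovolumic contraction equals the constant at every
steady-state beat.

The mechanical activation C(t, L_s) is a phenomenological single twitch:
saturating rise `1 - exp(-(t/t_rise)^2)`, sigmoidal decay centred at the
twitch duration, a monotone sarcomere-length gate (Frank–Starling), and a
length-dependent duration `t_dur = t_dur0 (1 + 0.4 (L_s - L_s,ref))`
evaluated at the instantaneous length, which deactivates earlier when the
wall has shortened.  Defaults (ventricles): t_rise = 115 ms,
t_decay = 45 ms, t_dur0 = 375 ms; atria: a weaker (c_max = 0.25), shorter
(120 ms) twitch starting 170 ms before the ventricles.

Cavity mechanics use a one-fiber model with homogeneous myofiber stress:

    p_cav = (sigma_f / 3) · ln(1 + V_wall / V_cav),

and the kinematic map from cavity volume to sarcomere length uses the
exactly work-conjugate strain
`eps(z) = (1/3)[z ln(1+1/z) + ln(1+z)]`, `z = V_cav/V_wall`, so that fiber
work `V_wall · sigma · d(eps)` equals pump work `p · dV` identically; this
keeps PV-loop stroke work and fiber energetics consistent by construction.
The four chambers sit inside a pericardial sac whose external pressure rises
as `p_ref (V_heart/V_ref)^8` (V_ref = 950 ml, p_ref = 0.5 mmHg), negligible
at normal volumes and a firm constraint under dilation.

Wall defaults (LV/RV/LA/RA): wall volumes 180/45/25/25 ml, active stress
scales 130/120/60/60 kPa/um, reference cavity volumes 70/70/50/50 ml at
L_s,ref = 2.0 um, L_si,ref = 1.51 um, passive exponential
(50 Pa, 10 um^-1) above a 1.8 um slack length.  The LV wall volume and
stress scale were calibrated so the reference simulation hits the published
operating pressures (~127/60 mmHg aortic) and so the slow-stiff corner of
the parameter sweep retains enough contractile reserve to reach the
homeostatic targets.

## Vascular network

Every vessel segment is an elastic tube obeying

    p_trans(A) = p0 [ (1+b)(A/A0)^(1+k/3) - b (1 + A0/A) ],

with b = 0.02 preventing collapse (the law diverges to -inf as A -> 0) and
wave speed `c^2 = (A/rho) dp/dA`, which reduces to
`c^2 = (1+k/3) p/rho` in the b -> 0 power-law limit — k = 8 at
92 mmHg gives c = 6.54 m/s, the aortic operating point.  The printed form of
this law in the original description is typographically ambiguous in how the
b-terms group; the grouping above is the one that restores the power law as
b -> 0, is strictly increasing, and diverges at collapse.  It evaluates to
`p0 (1-b)` at A = A0, a 2% offset we accept.

The systemic tree contains merged-bilateral segments: ascending aorta
(8 cm, 8.0 cm^2... in SI 8.0e-4 m^2), descending (20 cm, 3.6e-4) and
abdominal aorta (10 cm, 2.4e-4) with k = 8; carotid (16 cm, k = 16),
subclavian (5 cm, k = 14), brachial (42 cm, k = 18) and femoral
(30 cm, k = 20) arteries — the "elastic taper" — plus a short splanchnic
stub (14 cm, k = 14) carrying the trunk circulation, without which all
cardiac output would have to leave through the limb and head vessels.  The
venous tree mirrors the arterial one (vena cava k = 8, same taper, 2.5x
lumen areas, p0 = 8 mmHg).  Arterial p0 is the mean-pressure operating
point (92 mmHg; the raised-p0 sensitivity levels 102/112 mmHg re-target the
pressure controller accordingly).  The carotid and femoral measurement
sites are the distal segment ends; the PWV travel distance is the
aorta-to-femoral minus aorta-to-carotid path difference (0.44 m).

Four arteriovenous beds (head 20%, arm 15%, trunk 35%, leg 30% of systemic
conductance) each consist of a characteristic-impedance entry matched to
the terminal artery, a resistive core (the control-loop actuator), and a
storage compliance between them with time constant r_core · C = 0.27 s.
The storage element stands for the distal small arteries, so its compliance
stiffens with delta_k by the same `(1+k/3)` factor as the named segments.
Wave propagation is linear (no convective acceleration): an explicit
staggered-grid scheme advances cell areas (mass, in flux form — volume
conservation is exact by construction) and face flows (momentum with
Poiseuille friction, blood viscosity 3.5 mPa s) at dt ~ 0.15 ms on
~1.5 cm cells, comfortably below the CFL bound, with a runtime check that
aborts on violation.  Junction nodes carry no volume; each step solves the
node pressure in closed form such that the updated member flows sum exactly
to zero, making the junction pressure single-valued and junction mass
conservation exact.

Valves are pressure-gated orifices (effective areas 5–8 cm^2) with blood
inertance over a 30 mm effective length and Bernoulli resistance; a smooth
opening state (6 ms relaxation) avoids flow discontinuities that would
corrupt second-derivative landmark detection.  The pulmonary circuit is
lumped (artery and vein compliances, 3.0e-8 and 1.2e-7 m^3/Pa, joined by a
1.1e7 Pa s/m^3 resistance), since only systemic waves are analyzed.

## Homeostatic control and steady state

After each beat the controller scales the bed core resistances toward the
target ratio MAP/CO = 92 mmHg / 5.1 l/min and infuses or withdraws
circulating volume in proportion to the cardiac-output and pressure errors
(damped proportional control, infusion capped at 40 ml/s).  Steady state
requires, for three consecutive beats: both targets within 0.5%,
beat-to-beat aortic-pressure RMS difference below 0.5% of pulse pressure,
beat-to-beat MAP drift below 0.04%, and residual infusion below 0.5% of
target flow.  The controller is then frozen and one further beat is
recorded for analysis, so the analysis beat conserves total blood volume
exactly and is stationary to ~0.05% if integrated further.  Everything is
deterministic — there is no random number anywhere in the simulator — so
identical configurations give bit-identical traces.

A limitation surfaced by the sweep: at vs,LV = 2 um/s combined with strong
stiffening (delta_k >= ~6) the one-fiber LV saturates — past a certain
dilation the geometric factor ln(1 + V_wall/V_cav) falls as fast as
Frank–Starling recruits stress — and the targets are unreachable.  Those
cells are reported as non-converged and excluded from pooled statistics,
per the sweep contract.

## Waveform analysis

All landmark detectors work on the 1 ms output grid after zero-phase
low-pass smoothing (2nd-order Butterworth, applied forward-backward).  Two
bandwidths are used deliberately:

* **morphology** (25 Hz default): inflection point and ejection corners,
  where anti-ringing smoothing matters more than localization;
* **transit timing** (60 Hz, with a two-stage search that first localizes
  the foot at 25 Hz and then sharpens within one smoothing period, and a
  narrow parabolic sub-sample refinement): heavier smoothing biases the
  detected foot up the pressure upstroke by amounts that differ between
  sites with different upstroke steepness, which biases foot-to-foot
  transit times; the sharp detector agrees with a pressure-minimum transit
  oracle to ~0.1 m/s.  When the high-frequency residual of a record exceeds
  0.3% of pulse height (noisy data), the PWV detector falls back to the
  25 Hz bandwidth, which is the only one with usable curvature SNR.

The foot is the maximum of the second derivative.  The inflection point is
the first upward (negative-to-positive) zero-crossing of the second
derivative after the foot's acceleration lobe and before end-systole: the
re-acceleration where the reflected compression wave arrives.  (A plain
"first zero-crossing" cannot be meant literally, since any rise to a
maximum crosses zero downward; the upward crossing is the convention that
can also be legitimately absent, propagated as a missing value.)  AIx and
AIx' follow their definitions from p_dia, p_i, p_sys; when both are defined
they satisfy AIx' = 100·AIx/(100-AIx) identically.

Ejection duration brackets the aortic-valve flow lobe with the
second-derivative maxima on either side of the peak, searched only where
the smoothed flow is below 10% of its peak: the onset/end corners live at
the baseline, and the restriction prevents interior deceleration knees
(reflected-wave loading) from masquerading as the end of ejection.  Stroke
work is the signed shoelace area of the (V, p) loop (positive
counterclockwise, i.e. ejecting), in joules.  Peak systolic strain rate is
the most negative derivative of LV fiber strain within the ejection window
(shortening negative), with a guard band against filter edge transients.

Wave separation uses the water-hammer relations on sample increments,
`dp_fw,bw = (dp ± rho·c·dU)/2`, cumulated from zero with the measured
pressure at t = 0 as the reconstruction offset; amplitudes are max - min of
each component over the beat and the reflection index is
100·p̂_bw/p̂_fw.  The wave speed is estimated from the slope of the
early-systolic PU loop (foot to 30% of ejection duration, least squares)
divided by blood density (1050 kg/m^3), or can be supplied externally for
validation.

## Synthetic ground-truth waveforms

The `synthetic` module generates every waveform family the analysis
operations consume, with machine-precision truth: forward/backward pairs
that satisfy the water-hammer identity exactly; pressure beats built from
quintic smoothsteps whose maximal curvature (the foot) and upward
zero-crossing (the inflection) are placed analytically; rectangle/ellipse
PV loops with closed-form areas; and exactly time-shifted site pairs for
PWV, with optional seeded Gaussian noise (default off).  These fixtures
emulate landmark geometry, not physiology: they contain no heart-artery
feedback, so tests passing on them validate the detectors' contracts, not
the simulator — the simulator is tested against its own invariants
(conservation, periodicity, determinism, scenario orderings) and the
published operating points.

## Numerical and protocol choices

* Solver step 0.15 ms (rounded so an integer number of steps and of 1 ms
  output samples fits the 60/72 s beat), cell size 1.5 cm; halving both
  moves the scenario indices by well under their reporting precision.
* The acceptance sweep uses vs,LV 2–10 um/s step 1 and delta_k -2–14 step 2
  (a uniformly coarsened version of the full step-1 grid; 81 cells), and
  the regression pools all converged cells with a defined AIx.
* Scatter spreads use 2-point AIx bins and 2 mmHg backward-amplitude bins.
* OLS with classical standard errors and two-sided p-values; 0.05
  significance.

## Known limitations

* The AIx–ejection-duration regression slope computes to ~0.29 %/ms on this
  model, below the ~0.43 %/ms of the original study: the
  arterial-stiffness direction alone reproduces ~0.43, but reduced vs,LV
  prolongs ejection more here (vslow t_ej ~299 ms vs ~274 ms) at a similar
  AIx gain, diluting the pooled slope.  This traces to the operating point
  of the linear force–velocity relation, not to the analysis pipeline.
* Every sweep cell of the shipped model has a defined (sometimes weak,
  late) systolic inflection; the published sweep reports an undefined
  region at high vs,LV and low stiffness.
* Single representative segments per vessel (no within-segment taper), no
  wall viscoelasticity, no baroreflex or heart-rate variability, lumped
  pulmonary circuit — all outside the intended scope.
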