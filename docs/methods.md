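# Methods

`pahva` implements a desk-scale analysis chain for ventricular–arterial
physiology in pediatric pulmonary arterial hypertension (PAH): clinical
data harmonization, a closed-loop lumped-parameter (0D) cardiopulmonary
circulation, fixed-point calibration to hemodynamic targets, myocardial
constitutive laws with ESPVR/Ea coupling metrics, and rank-based
disease-severity stratification. This note records the models, their
assumptions, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Clinical data model and harmonization

A patient bundle holds 40-phase phase-contrast MRI flow waveforms (AAo,
DTA, MPA, LPA, RPA), 30-phase cine-MRI ventricular volume waveforms, and
catheter pressure waveforms, plus scalar demographics and catheterization
metrics. Units are fixed package-wide: mmHg, ml, ml/s, s; material
stiffness in kPa (1 mmHg = 0.133322 kPa; 1 mmHg·ml = 1.33322·10⁻⁴ J).

Real acquisitions are mutually inconsistent: MRI and catheterization are
days apart under different sedation, cine (breath-held) stroke volumes
exceed phase-contrast (free-breathing) stroke volumes by ~20%, and the
pressure and volume clocks are misaligned even after ECG referencing.
Three harmonization steps address this:

**PV-loop alignment.** Catheter pressure is down-sampled to 30 phases
(periodic linear interpolation) and cyclically shifted over ±7 phase
increments of T/30; for each shift an ellipse is fitted to the 30 (V, P)
points by the direct least-squares conic method with the ellipse
constraint (solved in the numerically stable partitioned form, on
centered/scaled coordinates), and the shift giving the largest fitted
ellipse area wins. Ties within 10⁻⁹ relative go to the smallest |shift|,
so peak pressure stays near minimum volume. A genuinely physiological
loop traverses pressure and volume in near-quadrature, and for loops
synthesized that way the criterion recovers planted shifts exactly
(15/15 over the full ±7 range). Two caveats are inherent to the
criterion, not to this implementation: (i) for points on a *rotated*
ellipse the area maximum sits at the quadrature phase rather than at
zero shift, and (ii) on realistic simulated loops the optimum carries a
small patient-specific offset, so shift recovery on full bundles is
exact only relative to the uncorrupted bundle's own optimum. The fit is
performed in raw (mmHg, ml) coordinates; z-scoring would change the
area ranking and is deliberately not applied.

**Volume-waveform adjustment.** The ejection limb of the cine volume
waveform is rebuilt from the flow integral: systole is the contiguous
run where flow exceeds 5% of peak (edge samples included so the window
starts at flow onset), the cumulative integral is scaled by
s = SV_cine/SV_PC-MRI, and V(t) = EDV − s·∫q dt on that window. The
ejection window is snapped *down* to the 30-phase grid with the scale
referenced to the snapped window end, which makes EDV and SV exactly
conserved and reduces to the identity when the flow already matches the
cine systole. The filling limb is the cine waveform, remapped onto the
remaining phases.

**Elastance construction.** Clinical elastance is E_i = P_i/V_i on the
aligned loop (no unloaded-volume offset by default; a v0 argument
exists). The analytic waveform is the two-Hill form
E(t) = k·[g₁/(1+g₁)]·[1/(1+g₂)] + E_min with g₁ = (t/τ₁)^m1,
g₂ = (t/τ₂)^m2 and k chosen so the cycle maximum equals E_max − E_min
(k is found by a 2049-point grid plus bounded scalar refinement,
accurate to ~10⁻⁹ relative). Fitting uses bounded nonlinear least
squares over (E_max, E_min, m1, m2, τ₁, Δτ = τ₂−τ₁ > 0) from a fixed
five-point multi-start grid; noiseless self-generated series are
recovered to machine precision, and constant series yield a flagged
degenerate fit. Time is kept in absolute seconds (not normalized by
cycle length).

## Closed-loop 0D circulation

The network has four elastance chambers, four valves, aortic and
pulmonary root R–C segments, arterial Windkessel beds with a
configurable number of outlets (default two per side), and systemic and
pulmonary venous Windkessels closing the loop. Every storage element is
a volume state (16 states at the defaults), so total blood volume is
conserved *identically*: each branch flow enters one compartment's rate
with + and another's with −, and the integrator's update is linear in
the right-hand side, leaving only float rounding (measured drift ~10⁻¹⁴
relative over 20 cycles).

Chamber pressure is P = E(t)·(V − V0)·(1 − ks·Q_out): a time-varying
elastance with a flow-dependent source resistance that flattens the
ejection waveform (ks in s/ml, default 2·10⁻⁴). Ventricles use the
two-Hill elastance; atria use a single raised-cosine bump timed late in
the cycle (onset 0.80 T, width 0.17 T) — atrial parameters are
configuration, not fitted. Elastances are tabulated on a 4096-point
cycle grid and linearly interpolated inside the right-hand side.

Valves: mitral and tricuspid are smooth diodes,
q = [ΔP + √(ΔP² + w²)]/(2R) with w = 10⁻³ mmHg, strictly non-negative.
Aortic and pulmonary valves are dynamically controlled resistors in
series with an inductor: R(ΔP) blends logistically (width 1 mmHg) from
R_open to 5·10³·R_open as the gradient reverses. This reproduces
post-systolic flow reversal and small non-zero diastolic flow; both the
closing factor and the width are exposed. The exact functional form of
the published dynamic valve is not reproduced here; the logistic blend
is a declared smooth surrogate.

The image-resolved central arteries are replaced by the root R–C
segments, so central/peripheral resistance and compliance splits remain
computable (central R and C versus parallel-combined / summed
peripheral Windkessels). The venous Windkessel's proximal resistance is
lumped in series with its distal resistance on the atrial side of the
venous capacitor — this avoids a junction node when arterial beds have
several outlets and is the one topology simplification. Blood density
(1.06 g/cm³) and viscosity (4 mPa·s) ride along in the parameter set;
the 0D equations do not use viscosity.

Integration is stiff-capable (BDF; the closed valve introduces ~10⁻⁵ s
time constants), rtol 10⁻⁶ / atol 10⁻⁸, run cycle by cycle until the
relative change in cycle-mean node pressures and ventricular stroke
volumes between consecutive cycles falls below 10⁻³ (cold start ~12
cycles, ≈0.4 s/cycle). Warm starts from a previous final state cut this
to a few cycles and are used throughout calibration. A non-periodic run
is returned flagged, not raised.

The default parameter set is a healthy-adult-like fixture (systemic
~110/70 mmHg, pulmonary ~21/10 mmHg, EF ~56%, CO ~5 L/min at 75 bpm)
documented in `circulation.default_params`; PAH patients are derived
from it by the synthetic-data module.

## Calibration

Relative errors are |data − model|/|data|·100, and a stage converges
when every target is below tolerance (default 10%).

**Arterial family (three stages).** Stage 1 imposes the measured AAo
and MPA flows on open-loop root+Windkessel beds and iterates
RT^{n+1} = RT^n + (P̄ − P̄ⁿ)/Q̄ⁿ for total peripheral resistance and a
pulse-pressure ratio update for total compliance, distributing both
proportionally over outlets (preserving each outlet's proximal:distal
split). Stage 2 replaces the flow sources with elastance chambers
filling from a constant-pressure reservoir; the preload pressure is
updated by P^{n+1} = Pⁿ·average(Q̄/Q̄ⁿ, P̄/P̄ⁿ), and the
source-resistance coefficient ks is chosen from a small grid by
minimizing the L2 discrepancy S = Σ(data − sim)² of the 40-phase inflow
waveform. Stage 3 closes the loop, carries all parameters forward, and
re-tunes resistances, compliances, and initial venous pressures until
mean/systolic/diastolic pressures at MPA and the systemic node plus
AAo/MPA mean flows are all within tolerance.

One orientation matters: pulse pressure *decreases* with compliance, so
the stable compliance iteration is C^{n+1} = Cⁿ·(PP_sim/PP_target);
the target/sim orientation amplifies the error (if PP·C ≈ SV, the map
C ↦ C²·PP_t/SV has derivative 2 at its fixed point). The standalone
`update_total_C` exposes the conventional target/sim form with its
frozen examples; every iteration loop uses the stable orientation.
Oscillation (error increasing three consecutive iterations) halves the
update exponent; a floor at 0.05·RT prevents sign flips.

On synthetic patients whose targets come from their own ground-truth
simulation, the full three-stage pipeline converges below 10% on all
eight targets from Windkessels mis-scaled by 0.6–1.5×, and at a 5%
tolerance recovers total R within ~7% and total C within ~12% of truth
(total R and C are the identifiable combinations; individual outlet
parameters are not).

**Ventricular family (coordinate descent).** One sweep = one warm-started
simulation plus a damped multiplicative update of every mapped
parameter: venous resting volumes → EDV (additive, 2 ml per ml of EDV
defect, clipped at ±60 ml, with the blood added directly to the venous
compartment state so the warm start stays consistent), arterial
resistances → mean pressures, compliances → pulse pressures (stable
orientation), peak elastance → ESV, diastolic elastance → EDP. All
ratios are clipped to [0.8, 1.25] per sweep (damping exponent 0.7,
halved on oscillation). End-systolic pressure targets are matched
through the afterload and contractility updates jointly, as in the
published mapping. Activation-timing targets are not in the default
sweep: the 0D ventricle's timing lives in the two-Hill parameters,
which are fitted upstream from the aligned PV loop. EDP is measured as
the minimum pressure over the near-EDV volume plateau — the volume
maximum is flat through isovolumetric contraction, and reading pressure
at argmax(V) can catch the systolic upstroke. Recovery tests converge
in ~5 sweeps from 0.7–1.5× perturbations of all mapped parameters.

## Myocardial material laws and coupling metrics

Active stress is Pₐ = T_ref·[Ca₀²/(Ca₀² + ECa₅₀²)]·C(t)·e_f ⊗ e_f0 with
activation C(t) = ½(1 − cos πt/t₀) for t < t_t and
C(t_t)·exp(−(t − t_t)/τ) afterwards (decaying relaxation), and
length-dependent calcium sensitivity
ECa₅₀ = (Ca₀)_max/√(exp(B(l − l₀)) − 1), undefined at or below the
zero-tension sarcomere length l₀ (a literal printed-form variant is
available behind a flag; no shipped number depends on the choice).
Passive stress derives from the transversely isotropic Fung energy
W = c/2·(e^Q − 1), Q = b_ff E_ff² + b_xx(E_ss² + E_nn² + E_sn² + E_ns²)
+ b_fx(E_fn² + E_nf² + E_fs² + E_sf²), giving S_ij = c·e^Q·b_ij·E_ij
componentwise; the analytic stress matches central finite differences of
W to better than 10⁻⁶ kPa on random strains. Default constants
(c = 0.2 kPa, b_ff = 29.9, b_xx = 13.3, b_fx = 26.6; T_ref = 80 kPa,
B = 4.75 /µm, l₀ = 1.58 µm) are illustrative mid-range myocardium
values.

Organ-level mechanics are reduced to a thick-walled incompressible
sphere: midwall radius and thickness follow from cavity and (constant)
wall volume, circumferential stretch λ = r_m/r_m,ref gives equibiaxial
in-plane Green strain with the radial component from incompressibility,
sarcomere length maps as l = l_ref·λ (l_ref = 1.85 µm), and cavity
pressure is the Laplace equilibrium P = 2σh/r_m with σ the total
(passive + active) circumferential fiber stress. This surrogate
exercises the constitutive laws exactly at material points and organ
behavior only qualitatively — fiber architecture, regional wall motion,
and septal interaction are outside its reach.

ESPVR is estimated exactly as in the virtual-preload protocol: the
venous resting volume upstream of the chamber is swept over a grid,
each closed loop is run to periodicity, the end-systolic point is read
at the instant of peak elastance, and a line is regressed through the
(V_es, P_es) points. In the pure-elastance limit (ks = 0) the slope
equals E_max and the intercept −E_max·V0 analytically; the
implementation agrees to ~3·10⁻⁵ relative. Ea = P_es/SV, and the
coupling ratio is ESPVR/Ea. For the isolated sphere ventricle, end
systole is taken at the start of relaxation (t_t) and preload is swept
via the filling-reservoir pressure.

Vessel-wall metrics: linearized stiffness
E = 1.5·ΔP·R_i²·R_o/((R_o² − R_i²)·ΔR) with ΔP converted to kPa and the
15% wall-thickness rule h = 0.15·r_dias applied outward
(R_o = 1.15·R_i); radii from luminal areas assume a circular lumen.
Pulse wave velocity per segment is the Moens–Korteweg speed
c = √(E·h/(2ρR_i)) — a material wave-speed surrogate, since the
published estimator for path PWV is not stated — and paths aggregate as
total length over summed transit times.

## Stratification

Spearman's ρ is Pearson correlation of midranks (tie-robust), with a
closed-form fast path 1 − 6Σd²/(n(n²−1)) for untied data (numerically
exact at ρ = ±1). With eight subjects, p-values enumerate all
8! = 40320 orderings (two-sided by default; the published p-values are
consistent with one-sided enumeration); a t-approximation with n−2
degrees of freedom serves larger n. Benjamini–Hochberg selection at
Q = 0.10 compares sorted p-values to i·Q/m and is cross-checked against
an independent implementation in tests. Rows with heavy ties in the
printed inputs do not reproduce the published coefficients from rounded
values under any tie convention; the six tie-free rows reproduce to
±0.001 and are the test surface. The MPA diastolic pressure column is
derived as systolic − pulse.

## Synthetic patients

A virtual patient is the ground-truth circulation of a latent severity
s ∈ [0, 1]: pulmonary Windkessel resistance ×(1 + 7s^1.2), compliance
÷(1 + 2s), RV peak elastance ×(1 + 1.3s), LV peak elastance ×(1 − 0.25s),
pulmonary vessel-site distensibility ÷(1 + 2.5s), cycle length uniform
in 0.7–0.9 s, all with ~5% seeded log-normal jitter. Across s = 0→1
this spans mean pulmonary pressures ≈15–85 mmHg and reproduces the sign
pattern of the severity-correlated metrics (pulmonary pressures,
resistance and RV contractility up; pulmonary compliance and LV
contractility down). Measurement corruption then applies, in order:
phase sampling (40-phase flows, 30-phase volumes, 120-phase cath
pressures re-referenced to the volume R-peak clock), cine SV inflation
(+20% about EDV, the breath-hold effect), a planted cyclic pressure
shift in T/30 increments (±7), a catheter heart-period rescale, and
multiplicative Gaussian noise (defaults 2% pressures, 4% flows, 5%
volumes; the publication gives no noise model, these are plausible
acquisition levels). All randomness flows through one seeded generator;
identical seeds give identical bundles.

What the synthetic cohort does *not* emulate: imaging geometry and
segmentation variability, ventricular-volume truncation below the
tricuspid plane, respiratory modulation, beat-to-beat variability, and
multi-day physiological drift between MRI and cath. Passing the
end-to-end test therefore shows that the pipeline inverts its own
corruption model and recovers a planted monotone disease process — not
that it would recover clinical severity from real data.

The end-to-end replica runs eight patients through
generation → corruption → harmonization → stage-1 Windkessel
calibration → metric extraction → stratification, in ~1 minute. Under
zero noise it recovers the planted severity ranking with ρ = 1.0 on the
afterload metrics and flags 13/13 metrics significant at the 10% FDR.

## Problem sizes and runtime

Default test problem sizes: 30/40-phase waveforms as acquired; 16-state
circulation, 120–200 output samples per cycle; calibration recovery on
3 patients; end-to-end cohort of 8. The full test suite runs in ~9
minutes and the acceptance script in ~6 on one CPU.

## Known limitations

- The 0D central segment cannot resolve wave travel; PWV here is a
  material property, never compared against waveform-transit estimates.
- The sphere ventricle has no fiber architecture or regional mechanics;
  ESPVR from it is qualitative (monotone in T_ref) rather than
  quantitative.
- Calibration identifiability: only total R and C per side are well
  determined; outlet-level parameters inherit the initial split.
- The permutation p-value is exact only for n ≤ 9; beyond that the
  t-approximation is used.
- Tied-metric Spearman rows cannot be validated against the published
  table from printed precision.
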