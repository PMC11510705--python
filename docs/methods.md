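# Methods

`bpfray` analyses the opening/closing ("fraying") of a terminal base pair —
the motivating system is the dA-rU pair at the end of a DNA-RNA hybrid
duplex — from two per-frame trajectory observables: the RMSD of the
terminal nucleotides relative to a reference structure, and the backbone
torsion ζ (the C3′(i)–O3′(i)–P(i+1)–O5′(i+1) dihedral). Units are ns, Å,
degrees, kcal/mol and eu (cal mol⁻¹ K⁻¹) throughout; kB =
1.987204×10⁻³ kcal/(mol·K).

## State model

Three conformational states are defined by rectangular windows in the
(RMSD, ζ) plane:

| state      | ζ window (deg)   | RMSD (Å)     |
|------------|------------------|--------------|
| closed     | [−100, −50]      | ≤ 2          |
| transition | [−100, −50]      | > 2          |
| open       | [0, 100]         | [2, 13.5]    |

The closed ζ window and the 2 Å RMSD boundary are the observed values for
this system; the open ζ window is chosen symmetric about the observed
≈ 50° centre and is configurable. Frames falling outside all windows are
assigned the label of the temporally nearest assigned frame (ties to the
preceding frame).

Each frame owns one step-width interval centred on its timestamp, so n
frames at step Δ span exactly n·Δ ns. Residences in the two basins
alternate and tile the trajectory: a *successful* crossing (closed→ts→open
or a direct label change) splits the trajectory at the midpoint of the
crossing interval. *Failed* excursions — ctc (closed→ts→closed) and oto
(open→ts→open) — are nested inside residences, do not terminate them and
are tallied separately. This bookkeeping makes p_cl + p_op = 1 with the
transition-state occupancy overlapping the residences, and it preserves
the identity p = τ_ave·N/τ per state, which is the only arithmetic
consistent with the reference occupancy table this package ships
(`bpfray.reference_data`). Dwell filters (`min_excursion_frames`,
`min_residence_frames`) default to 1, i.e. no suppression.

## Thermodynamics

The closing free energy is ΔG_close(T) = −kB·T·ln(p_cl/p_op). Two fits
extract ΔH and ΔS:

* **Gibbs**: OLS of ΔG on T; intercept ΔH, slope −ΔS.
* **van't Hoff**: OLS of ln(p_op/p_cl) on 1/T; slope −ΔH_open/kB,
  intercept ΔS_open/kB.

Both are unweighted (no per-point uncertainties are available from a
single trajectory per temperature) and coincide exactly whenever the
populations derive from temperature-independent ΔH and ΔS. The melting
temperature is T_m = ΔH/ΔS. The package's primary sign convention is
**closing** (ΔH, ΔS < 0 for a stable pair); the literal evaluation of
−kBT ln(p_op/p_cl) has the opposite sign, so every report carries an
explicit convention tag and the opposite convention is available by flag.

Sampling uncertainty matters here: with mean dwells of ~25 ns and p ≈ 0.5,
a 4000 ns trajectory contains only ~78 complete open/close cycles, so the
per-temperature ΔG carries ≈ 0.12 kcal/mol of Monte-Carlo error and the
extrapolated intercept ΔH ≈ 2 kcal/mol (the 370–400 K window is narrow and
far from T = 0). The end-to-end recovery test therefore uses 800 µs of
synthetic trajectory per temperature (frame step 50 ps), power-sized so
that sd(ΔH) ≈ 0.14 kcal/mol and sd(ΔS) ≈ 0.4 eu.

## Kinetics

Rates are reciprocal mean lifetimes (k− = 1/τ_cl opening, k+ = 1/τ_op
closing) and the mean transition-path times are identified with the mean
failed-excursion durations, t_tp(o→c) = τ_ctc and t_tp(c→o) = τ_oto (the
durations of successful crossing intervals are additionally recorded by
the segmentation for comparison). In the diffusive picture,

    t_residence = 2π/(β·D*·ω*·ω_basin) · exp(β·ΔG‡)        (Kramers)
    t_tp        = ln(2·e^γ·β·ΔG‡)/(β·D*·ω*²)               (Szabo)

with γ = 0.5772156649. The ratio t_residence/t_tp is independent of D*, so
fitting ratios across temperatures identifies β·ΔG‡ and the curvature
ratio ω*/ω_basin only — absolute curvatures and D* are not identifiable
and are never reported as fitted values.

The closed-side barrier ΔGc is modelled as temperature-independent; the
fit runs on log-ratios (scale stability) with a grid search over
ΔGc ∈ [1, 15] kcal/mol followed by bounded scalar refinement, the
curvature ratio being profiled out exactly at each candidate. The
open-side barrier is modelled as purely entropic, ΔGo = T·ΔS_open, which
makes β·ΔGo constant and the model exactly flat in temperature — ΔS_open
and ω*/ωo are then not jointly identifiable from ratios alone. The open
side fit therefore accepts a pinned ΔS_open (typically the thermodynamic
fit's −ΔS_close); without one it still runs the prescribed grid fit but
flags the result non-identifiable.

An exponential-dwell diagnostic (`dwell_time_distribution_check`) audits
the memoryless two-state assumption: ML rate = 1/mean plus a
Kolmogorov–Smirnov distance against the fitted exponential (a diagnostic,
not a calibrated p-value, since the rate is fitted from the same sample).

## Synthetic generators

**Hidden-state Markov generator.** Alternating closed/open residences with
exponential durations; failed excursions are Poisson-placed within
residences (overlaps dropped) with exponential durations; per-frame
emissions are truncated normals / uniforms confined to the state windows
(closed RMSD ≈ 0.7 ± 0.25 Å, ζ ≈ −75 ± 10°; open RMSD uniform on
[2, 13.5] Å, ζ ≈ 50 ± 15°; transition RMSD ≈ 3 ± 1 Å with closed-like ζ).
Default lifetimes, excursion rates and the 2 ps frame step reproduce the
reference statistics at 370–400 K; `markov_config_from_thermo` instead
fixes the open lifetime (observed to be nearly temperature-flat) and sets
τ_cl/τ_op = exp(−βΔG_close). What the generator does *not* emulate:
emission autocorrelation within a state, non-exponential dwells,
temperature-dependent emission shapes, and any coupling between RMSD and ζ
beyond the shared state — so passing tests validate the bookkeeping and
estimators, not force-field realism.

**Langevin double well.** Overdamped Euler–Maruyama dynamics
dx = −βD·U′(x)dt + √(2D·dt)·ξ on U(x) = h[(x/a)² − 1]², with analytic
curvatures U″(±a) = 8h/a² and |U″(0)| = 4h/a². A configuration is rejected
unless the maximal drift displacement per step is below 0.1·a. Residences
and transition paths are logged in the integration loop: a transition path
runs from the last exit out of one basin region to the first arrival in
the other. The basin/transition boundaries sit at ±a/√2 by default: the
Szabo expression is derived for absorbing boundaries where the parabolic
barrier has dropped by the full barrier height (√(2ΔG/ω*²) = a/√2 here);
boundaries at ±a/2 would probe an effective drop of only h/2 and bias the
comparison by ~25% at βh ≈ 4–6. The fraction is configurable and recorded.
At βh ∈ {4, 5, 6} measured mean residences agree with the Kramers form
within ~10% (the exact double-integral MFPT, used as an independent test
oracle, shows Kramers itself is 8–12% low there) and measured
transition-path times with the Szabo form within ~20%; both are asymptotic
results, and the acceptance band is 25%.

A monotone map sends the well coordinate to (RMSD, ζ) for end-to-end runs
through the classifier; the RMSD ramp rises before the ζ ramp so frames
leaving the closed basin first appear transition-like, as in the physical
system.

## Numerical choices and degenerate inputs

* Torsions use the IUPAC atan2 form; collinear triples raise a
  degenerate-geometry error; output in (−180, 180] with the −180 boundary
  folded onto +180. Angle wrapping leaves in-range values bit-identical.
* Superposition RMSD uses the Kabsch solution (SVD); it is off by default
  because the motivating trajectories restrain all but the terminal
  nucleotides, fixing the laboratory frame.
* Trajectories with zero successful crossings segment into a single
  residence with a warning flag rather than an error.
* A state never visited reports its mean lifetime as absent, not zero.
* Barrier fits outside the grid, with fewer than two temperatures, or with
  non-positive ratios raise fit errors with diagnostics.

## Limitations

* The rule-based classifier has no notion of emission overlap; if state
  windows overlap or emissions leak across a boundary, frames are
  mislabelled silently (the generators validate their emission supports
  against the windows to prevent this in tests).
* ΔH/ΔS extraction from a 30 K window is an extrapolation; quoted standard
  errors are conditional on the linear model.
* The Szabo comparison is boundary-convention-dependent; only the default
  convention is validated.
* Reported transition-path times inherit the identification
  t_tp = mean failed-excursion duration; alternative definitions (durations
  of successful crossings) are recorded in the segmentation but not fitted.
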