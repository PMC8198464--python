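# Methods

This note documents the models behind `langmuir-workbench`: what the
synthetic generators emulate, how each analysis stage works, the numerical
choices that matter, and what the closed-loop tests do and do not
demonstrate about real trough data.

## The reference isotherm model

No closed-form equation of state describes a DPPC π–A isotherm through the
LE–LC coexistence region, so the generator uses a piecewise construction
chosen for analytic tractability — every knot, tangent and shift has a
closed form, which is what makes the analysis chain testable against exact
oracles:

- **Gas region** (A above the lift-off area `A_lift`): π = 0.
- **Liquid-expanded branch** (`A_C ≤ A ≤ A_lift`):
  `π(A) = π_C·((A_lift − A)/(A_lift − A_C))²` — a quadratic that rises from
  zero slope at lift-off to slope `−2π_C/(A_lift − A_C)` at the plateau
  onset. Its tangent at `A_C` crosses π = 0 at
  `A_C + (A_lift − A_C)/2` (0.895 nm² for the default DPPC set).
- **Coexistence plateau**: linear from `(A_C, π_C)` to
  `(A_end, π_C + δ)`, where the tilt δ models the loss of plateau
  horizontality seen in mixed films.
- **Condensed branch**: linear with slope `k_LC` up to the collapse
  pressure.

Binary nanoparticle/phospholipid films are expressed as horizontal
displacements of this curve: a uniform LE-branch expansion `ΔA_LE` below
the plateau onset, a signed condensed-branch shift `ΔA_LC` above the
plateau end, blended linearly across the plateau. Positive `ΔA_LE` models
nanoparticles occupying interfacial area early in compression; the sign of
`ΔA_LC` distinguishes material squeezed out at high pressure (negative)
from material retained in the film (positive).

Default parameter sets (`presets.py`): pure DPPC has
`A_lift = 1.02 nm²`, `A_C = 0.77 nm²`, `π_C = 5 mN·m⁻¹`,
`A_end = 0.55 nm²`, `δ = 0.5 mN·m⁻¹`, `k_LC = 250 mN·m⁻¹·nm⁻²`, collapse at
55 mN·m⁻¹. The binary films at weight fraction X_W = 0.36 use
`ΔA_LE = 0.19 nm²`, onset 12 mN·m⁻¹, `ΔA_LC = −0.05 nm²` (starch coating)
and `ΔA_LE = 0.14 nm²`, onset 10 mN·m⁻¹, `ΔA_LC = +0.05 nm²` (aminated
starch). The onset area/pressure and LE expansions are the calibration
anchors of the package; lift-off, plateau end, slopes, collapse and the
`ΔA_LC` magnitudes are free model choices of plausible magnitude, with the
`ΔA_LC` signs fixed by the squeeze-out-versus-retention distinction.

A consequence of anchoring the condensed branch at each film's own plateau
exit: the high-pressure shift between a binary film and pure DPPC at equal
pressure is `ΔA_LC + (π′_C,b − π_C,a)/k_LC` (−0.022 nm² for the starch
film at 30 mN·m⁻¹), not `ΔA_LC` itself. The tests assert this analytic
value.

Sampling defaults are 400 points over the grid from 5% above lift-off to
the collapse cut, with Gaussian pressure noise of sd 0.05 mN·m⁻¹ —
instrument noise levels and sampling density are stated choices (a Wilhelmy
balance resolves 0.01 mN·m⁻¹; 0.05 is deliberately pessimistic), not
values inferred from any particular instrument.

## Isotherm analysis

**Differentiation.** `Cₛ⁻¹ = −A·dπ/dA` uses the three-point Lagrange
derivative on the raw (possibly irregular) area grid, exact for local
quadratics, with two-point one-sided differences at the boundaries. Spline
differentiation was rejected because splines oscillate at the plateau
knots, which are genuine slope discontinuities of the underlying model.

**Smoothing.** Noisy isotherms are smoothed before differentiation with
Savitzky–Golay-type local polynomial least squares (default window 11,
order 3; window 21 recommended at noise sd 0.05). It is implemented
directly (rather than via a uniform-grid convolution filter) so irregular
grids work and endpoints are handled by shifting the full window inside
the series, preserving exact reproduction of polynomials up to the fit
order.

**Phase classification** follows Davies–Rideal with the convention: lower
bound inclusive, solid strictly above 250 mN·m⁻¹ (so 250 itself is LC),
and negative moduli flagged `unstable/artifact` rather than classified.

**Transition detection.** The LE and LC packing maxima are found as the
two most prominent peaks of `Cₛ⁻¹(π)` (scipy `find_peaks`, absolute
prominence floor 5 mN·m⁻¹ — small enough to keep a weak LE maximum, large
enough to reject smoothed-noise spikes). The coexistence interval is the
region between them where the modulus stays below 50 mN·m⁻¹
(configurable). Entry and exit are first located as half-prominence level
crossings scanning outward from the dip — a level crossing on a steep
flank moves by at most the knot-smearing width under noise, whereas an
argmax on the flat LE branch can jump anywhere — and then refined by
intersecting straight-line fits of the π–A branches a few points away from
the crossing on each side (`knot_gap`, default 3 points; half the
smoothing window after smoothing, since the filter smears the slope break
over that scale). Defining π′_C/π″_C on the modulus curve rather than as
curvature sign changes of π(A) is more robust to noise: curvature is a
second derivative, one differentiation noisier again. A plateau whose
refined rise π″_C − π′_C is below 0.5 mN·m⁻¹ is reported as the single
point (A_C, π_C), matching how a horizontal plateau is read off a plot.
A monotone modulus curve (no interior dip) yields a report with the
transition fields absent rather than an error.

Closed-loop accuracy: over a 36-set parameter grid the noise-free
recovery of (A_C, π_C, π′_C) is within 0.06%; at noise sd 0.05 mN·m⁻¹
with window-21 smoothing it is within ~2% (tested bound 5%).

**Extrapolated area.** `A_EXT` fits a least-squares line over the first
(largest-area) contiguous run of points with pressure inside
`[0.3, 0.9]·π̂`, where π̂ is the plateau-onset estimate (from transition
detection when not supplied), and extrapolates to π = 0. The window is the
operational definition of the "first linear slope" and is configurable;
because it scales with each film's own onset pressure, A_EXT *differences*
between films generated with equal LE-branch shape are window-independent
and equal the generator's `ΔA_LE` exactly. On the quadratic LE branch the
default window yields the chord value (0.929 nm² for default DPPC); a
narrow window anchored just below the onset approaches the tangent value
0.895 nm². Fits with fewer than 5 points or R² < 0.98 carry a
low-confidence flag; a non-negative slope is an error.

**Inverse lookup / shifts.** `isotherm_shift` inverts each isotherm by
linear interpolation on its monotone-rising branch. Pressures falling on a
plateau — three or more consecutive segments with |dπ/dA| below
5 mN·m⁻¹·nm⁻² — raise an error naming the plateau bounds, since the
inverse is ill-conditioned there.

**Area normalisation.** `mean_molecular_area` counts only phospholipid
molecules: `A = A_trough / (V·c·(1 − X_W)/M · N_A)`. Nanoparticle mass
reduces the molecule count via (1 − X_W) and nothing else.

## Dilatational rheology

The defining relation is `δπ = −E·δA/A` with `E = E′ + iE″`: an ideally
elastic film (pressure exactly antiphase with area) has phase lag 0 and
`E″ = 0`; a perfectly viscous film has `E′ = 0` and lag π/2. Moduli are
extracted by least-squares regression of both the relative area
`x = (A − Ā)/Ā` and the pressure onto `{1, sin 2πft, cos 2πft}` at the
known barrier frequency. Least squares was chosen over FFT because it is
exact for non-integer cycle counts and short records and needs no
windowing; the frequency is trusted from the instrument metadata, with an
optional bounded search (±5%) minimising the residual for metadata drift.
The amplitude convention is peak (half peak-to-peak), so the protocol's
"1% amplitude" means u = 0.01.

Records containing rest intervals between oscillation bursts are split at
sampling gaps larger than 5× the median step; each burst is demodulated
separately — discarding its first cycle as a transient when at least four
cycles remain — and moduli are averaged across bursts with their sd
reported. Traces must keep at least 3 full cycles and 8 samples per cycle.
A relative area amplitude below 10⁻⁴ means no forcing (error); a phase lag
beyond π/2 is warned about as non-physical.

Noise-free recovery is exact to numerical precision (tested at 10⁻⁸
relative over E′ ∈ [10, 120], E″ ∈ [0, 30], f ∈ [20, 140] mHz); at noise
sd 0.05 mN·m⁻¹ the estimator is unbiased with per-trace scatter
~0.3 mN·m⁻¹ at u = 0.01 and 10 cycles.

## Penetration kinetics

`Δπ(t) = π^PE(t) − π^R(t)` on the union of both sample grids inside their
overlap (linear interpolation, no extrapolation, overlap ≥ 80% of the
shorter trace). No smoothing is applied before differencing: the
simultaneous reference already cancels the common evaporation drift, which
the generator reproduces by giving both troughs the same drift ramp but
independent sensor noise. The endpoint Δπ at 6 h (360 min) is the primary
summary, read by interpolation from the raw series. The
exponential-saturation fit `Δπ_max(1 − e^{−kt})` (bounded nonlinear least
squares, initialised from the final value and the time to half-final) is a
derived convenience, not a mechanistic model — no diffusion-limited
(Ward–Tordai) adsorption theory is implied. Series ending below zero are
in the extraction regime (phospholipid pulled out of the film) and are
summarised by their minimum instead; an all-zero series is flagged
degenerate. The calibrated defaults (Δπ_max = 4.32 and 7.3 mN·m⁻¹,
k = 0.01 min⁻¹) put the 6 h endpoints at 4.20 and 7.10 mN·m⁻¹.

## Owens–Wendt surface energy

With `x = √γ_d`, `y = √γ_p` the per-liquid Young equations become linear:
`γ_L(1 + cos θ)/2 = x·√(γ_L^d) + y·√(γ_L^p)`. Two liquids give an exact
2×2 solve; more than two are combined by least squares on the same
linearisation. The default probe-liquid table (glycerin 63.4 = 37.0 + 26.4,
diiodomethane 50.8 = 50.8 + 0, mJ·m⁻²) carries standard literature
components and is user-editable — a different liquid table rescales the
solved components, so the table is part of the result's provenance.
Dispersively proportional liquids make the system singular (error naming
the liquids). Negative roots — infeasible geometry, typically from noise —
are clamped to zero and flagged rather than raised, so batch runs
complete. Uncertainties come from a seeded parametric bootstrap (default
2000 resamples) over the drop angles, because the square of a near-zero
root is strongly non-Gaussian and first-order propagation would misstate
it. `γ_s = γ_d + γ_p` holds exactly by construction.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the instrument outputs — knot
locations, linear-response harmonics, saturating kinetics, Young angles —
with independent Gaussian noise. They do not emulate baseline drift within
a record, barrier-speed artefacts, film-leakage relaxation, nonlinear
(higher-harmonic) rheology, BAM-visible domain textures, or angle
hysteresis. Passing closed-loop tests therefore demonstrates that the
analysis chain is correct and unbiased under the stated noise model, not
that it is robust to every instrumental pathology; the smoothing window,
coexistence threshold, prominence floor and fit windows are exposed
precisely so they can be re-tuned on real traces.

## Problem sizes

Default scenario sizes — 400-point isotherms, 10-cycle oscillation bursts
at 64 samples per cycle, 361-point kinetics series, 10 drops per liquid,
2000 bootstrap resamples — match the scale of the corresponding laboratory
records; the full test suite and the reproduction script each run in a few
seconds on one CPU core.
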