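# Methods

This note documents the physical models, the numerical choices and the
limits of validity of the `foilyield` package. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Decay data and gamma-line policy

Half-lives are stored with their original unit (s/h/d) and an
uncertainty; every derived quantity uses the decay constant
λ = ln2/t½ in h⁻¹, always recomputed from the stored half-life (the two
can never drift apart). The packaged registry covers ⁴⁷Sc, ⁴⁶Sc, ⁴⁴ᵐSc,
⁴⁴ᵍSc, ⁴³Sc, ⁴⁸V and the ⁵⁷Ni monitor product.

Only γ lines flagged *usable* quantify activities. Two lines ship
flagged off: the 1120.5 keV line of ⁴⁶Sc (interferes with ambient ²¹⁴Bi
background, so the 889.3 keV line alone is used) and the 1157.0 keV
line of ⁴⁴ᵐSc (coincides with the ⁴⁴ᵍSc 1157 keV line; the 271.3 keV
transition is used instead).

The ⁴⁴ᵐSc → ⁴⁴ᵍSc isomeric-transition branching is not measurable from
the package's inputs; it ships as a configurable constant, default
0.988 (evaluated decay-scheme value). The purity results are
insensitive to it: a ±1% change moves the RNP targets by far less than
their tolerance because the feeding term is at most a ~7% correction to
the ⁴⁴ᵍSc activity once the directly produced ⁴⁴ᵍSc has decayed.

⁴⁶Sc is handled as a single (cumulative) product: its 18.75 s isomer
decays to the ground state within any realistic cooling time.

## Reaction thresholds

Excitation fits are anchored to zero at the reaction threshold. The
shipped thresholds are computed from atomic-mass-evaluation mass
excesses with the exact relativistic two-body threshold formula, taking
for each product the lowest-energy open exit channel:

| product | channel | threshold (MeV) |
|---------|---------------|------|
| Sc-47 | (p,2p) | 11.687 |
| Sc-46 | (p,³He) | 14.677 |
| Sc-44g | (p,αn) | 14.173 |
| Sc-44m | (p,αn) | 14.450 |
| Sc-43 | (p,⁶He) | 23.084 |
| V-48 | (p,n) | 4.897 |

They are overridable through the thresholds CSV for users who prefer,
e.g., the multi-nucleon-emission channel that actually dominates.

## Stopping power and energy bookkeeping

Proton mass stopping powers use the Bethe formula in the
heavy-projectile limit (T_max ≈ 2mₑc²β²γ²), without shell, Barkas or
density corrections, with fixed mean excitation energies (Ti 233 eV,
Al 166 eV, Ni 311 eV; Kapton and dry air via Bragg-rule additivity over
their elements). Validity window 1–100 MeV; the package tests it
against an independently evaluated full-relativistic Bethe reference
for Ti, Al and Ni over 10–70 MeV (agreement within 3%, typically
≪ 1%). Above ~10 MeV the neglected corrections are at the percent
level and are absorbed by the yield tolerances; the model is *not*
meant for dosimetry or for energies near the Bragg peak.

Energy degradation through a foil integrates dE/dX with a midpoint rule
over areal density, step 1 mg/cm² or 1/100 of the foil, whichever is
finer (halving the step moves exit energies by well under 1 keV). The
mid-foil energy — the energy a cross-section point is quoted at — is
the energy after exactly half the areal density. Per-foil energy spread
uses the non-relativistic Bohr straggling variance
σ² = 0.1569·(Z/A)·X MeV² (X in g/cm²), combined in quadrature with the
±500 keV cyclotron extraction uncertainty and accumulated layer by
layer. For the shipped 70 → 18 MeV example stack the deepest foil's
combined uncertainty is 784 keV, consistent with the sub-MeV scale
expected for such stacks. Lateral spread, nuclear attenuation of the
beam and the asymmetry of the straggling distribution are out of scope.

The air gap between the vacuum window and the stack is modelled as one
more layer of dry air at its measured length; its contribution is a few
tens of keV.

## Activity extraction and uncertainty budget

The EOB activity of one counted peak is

A = C·λ·(t_real/t_live) / (ε·I_γ·e^(−λt_c)·(1−e^(−λt_real))),

with decay during the acquisition computed over the real time and the
live/real ratio applied as a multiplicative dead-time correction —
standard practice while the dead fraction stays below 10%, which the
measurement type enforces as an invariant. Repeated acquisitions of the
same foil/product combine by inverse-variance weighting after
individual decay correction.

The monitor excitation curve (natNi(p,x)⁵⁷Ni, 13 recommended points
between 22.4 and 67.9 MeV) is interpolated with a shape-preserving
piecewise cubic (PCHIP — no overshoot between points); its relative
uncertainty (≤ 5%) is interpolated linearly. Queries outside the
tabulated span are a hard error rather than an extrapolation. ⁵⁷Ni
recoils caught by the downstream Al foil (~1% of the monitor activity)
are added back before the flux is formed. The beam current is assumed
constant over the 1–1.5 h runs.

Cross-sections are rescaled by the enrichment fraction (0.9932) to
refer to a 100% enriched ⁴⁸Ti target; production from the residual
0.68% of other Ti isotopes is neglected. Relative uncertainties
(counting statistics, efficiency, γ intensity, monitor cross-section,
areal density) are treated as independent and summed in quadrature; the
budget helper reports them sorted so the dominant term (normally the
monitor's ≤ 5%) is visible.

## Excitation fits and thick-target yields

An excitation function is a PCHIP interpolant through the threshold
anchor (σ = 0) and the measured points, clipped at zero, with constant
(flagged) extrapolation above the last point. Cells of the measured
table reported *below detection* enter the fit as zero cross-section at
their foil energy: the curve must not invent production where the
experiment saw none. This is conservative — real sub-detection
cross-sections are small but nonzero — and is the main reason computed
yields sit slightly below published ones for products whose rise was
only partially sampled. A side effect is a small nonzero tail where the
interpolant rises between the last below-detection energy and the first
detection (e.g. a sub-MBq ⁴⁶Sc yield for a 30 MeV scenario, where the
published table prints a blank).

The thick-target EOB activity integrates σ(E)/S(E) by the trapezoid
rule on a 0.02 MeV grid (halving the step changes results by < 0.1%)
from the reaction threshold — the target is taken thick enough to
degrade the beam below threshold — to the entry energy, times
(I/e)·(N_A/M)·(1−e^(−λt_irr)) with M = 47.948 g/mol. Yields treat every
product independently: isomer feeding during the irradiation itself is
neglected (it matters at the sub-percent level for ⁴⁴ᵍSc over 24–80 h
and keeps the 80 h/24 h yield ratio exactly equal to the closed-form
saturation-factor ratio, which the tests verify to < 0.5%).

Yield computations here use only the measured points shipped with the
package; the published planning study fitted those together with
additional literature data. The acceptance band for reproducing the
published yield table (±20%) reflects that difference in inputs, and
the observed deviations (≤ 19%, mostly ≤ 10%) sit inside it.

## Purity evolution

Post-EOB, every activity decays exponentially except ⁴⁴ᵍSc, which obeys
the two-member Bateman solution with isomeric feeding:

A_g(t) = A_g(0)·e^(−λg t) + b·(λg/(λg−λm))·A_m(0)·(e^(−λm t) − e^(−λg t)),

with the λg → λm degenerate case handled by its limiting form. The
implementation is verified against direct high-accuracy integration of
the decay ODEs to 1e-8 relative and against the nuclei-conservation
integral ∫A_g dt = N_g(0) + b·N_m(0).

RNP(t) is the ⁴⁷Sc fraction of total scandium activity; ⁴⁸V is a
different element (removed chemically) and never enters the
denominator. `time_to_rnp` scans a 1 h grid and refines the first
crossing by root bracketing, returning "never" when the purity stays
below target over the whole horizon — the generic outcome whenever
⁴⁶Sc is present, since λ(⁴⁶Sc) < λ(⁴⁷Sc) makes the purity → 0 as
t → ∞. `max_rnp` does a 1 h grid search refined by bounded
golden-section; for ⁴⁶Sc-free sets the purity is monotone increasing
and the supremum is reported at the horizon end with a flag. The
default horizon is 5 000 h (~60 ⁴⁷Sc half-lives), wide enough to
bracket the ~1 500 h purity crossing with margin.

## Synthetic campaigns

The simulator's default conditions mirror the experimental ones: ~120
nA beam (7.5·10¹¹ p/s), 1 h irradiation, 500 µg/cm² ⁴⁸Ti deposits with
5% areal-density uncertainty, 25 µm Ni monitors, 10 µm Al catchers
(collecting a fixed 1% recoil share), 500 µm Al degraders, counting at
a geometry giving ~10⁻³ peak efficiency with 3% dead time, 2%
efficiency uncertainty. True excitation curves follow the measured
data, so synthetic campaigns resemble the real one.

The only sampled noise is Poisson counting statistics; areal-density,
efficiency and monitor uncertainties enter the quoted uncertainty as
fixed systematic terms, mirroring the quadrature treatment of the real
analysis. Two consequences, verified by the tests: a noise-free
campaign inverts to the truth at machine precision (the forward and
inverse paths share the energy bookkeeping and monitor curve, so this
checks the algebra, not the physics); and the 1σ/3σ coverage of the
recovered cross-sections is far above the nominal 68%/99.7%
(over-coverage by construction, since the quoted uncertainty contains
systematics that are never sampled). What passing these tests does
*not* show: robustness to efficiency-calibration bias, γ-interference,
current-profile variation or peak-fitting pathologies, none of which
the simulator models (peak areas are taken as inputs throughout).

## Degenerate inputs and tie-breaks

Zero-thickness layers are legal and act as the identity; a beam
stopping inside a foil raises a ranged-out error naming the layer.
Duplicate energies in a fit, thresholds at or above the first point,
non-positive half-lives, dead fractions ≥ 10%, out-of-range monitor
energies and all-zero activity sets are rejected with typed errors.
Blank table cells always serialize as empty strings, never 0, so
"below detection" and "measured zero" stay distinguishable on disk.
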