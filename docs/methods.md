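# Methods

## Scope and data model

The package analyses *outputs* of quantum-chemistry workflows on
metal–chelator complexes: Cartesian geometries (XYZ), tables of
energy-decomposition (EDA) terms, exchange free energies, and sampled
one-dimensional electron-density profiles.  It computes none of these
inputs; producing them (DFT optimization, wavefunction EDA, 3-D density
analysis) is a separate concern.  Where real inputs are unavailable, the
synthetic module generates statistically controlled stand-ins with the
generating truth attached.

## Donor perception and classification

Bonds between non-metal atoms are perceived by the covalent-radius
criterion d(i,j) ≤ s·(r_i + r_j) with s = 1.3 and the Cordero radii frozen
in-repo.  The metal is excluded from the covalent graph; its coordination
sphere is instead every O/N within a cutoff of 3.1 Å (configurable),
chosen to cover the longest inner-sphere contacts reported for
nine/ten-coordinate La³⁺ complexes (~2.71 Å) with margin while excluding
second-sphere atoms.

Donor classes are assigned by first-match rules on the covalent
environment (rings = 5/6-membered cycles of a minimum cycle basis):

* O: water (≥ 2 H neighbours) → carboxylate (its C carries exactly one
  other O, terminal) → amide (on a C that also bonds N) → phenolate
  (single neighbour, a ring C) → ether (two C, no H);
* N: pyridine (two heavy neighbours, N and both neighbours ring members)
  → amide (bonded to a carbonyl C) → amine (three σ-neighbours, not in a
  ring).

A donor matching no rule is kept as `other` with a logged warning, never
dropped.  These rules are heuristics: they assume organic chelator
chemistry and will misname exotic donors; they are deliberately simple,
documented, and testable.

Pairing of equivalent donors across the two metal analogues defaults to
matching by atom index (paired optimizations normally share ordering; an
element mismatch at any index is a hard error).  Rank-order matching
within each donor class is the fallback and warns.

## Gaussian analysis of Δd and the ionic radius

The pooled differences Δd = d(cmp) − d(ref) are fitted with one or two
Gaussian components.  The default route is unbinned maximum likelihood —
it requires no bin-width choice and is exactly reproducible; binned least
squares at 0.01 Å is provided for histogram-figure parity.  Two-component
fits use EM initialized by a deterministic median split (seed-free);
centers are reported ascending; a width collapsing below 1e-4 Å or
coincident centers raise a singular-component error rather than returning
an arbitrary answer.  Center standard errors come from the observed
information (analytic σ/√n for one component; a central-difference
Hessian of the log-likelihood for two).

The radius transfer is r_est = r_ref + center with r_ref = 1.216 Å
(Shannon, La³⁺ at CN 9).  The quoted ± is the fitted component *width* —
the physical scatter of the distance differences — while the much smaller
standard error of the center is reported separately.  The component count
is a user input; no AIC/BIC selection is attempted.

## Bond-path critical points

A profile is a strictly increasing position grid (Å from the metal
nucleus) with positive densities.  The critical point is the interior
grid minimum refined by a parabola through the minimum and its two
neighbours; an endpoint minimum is an error, a plateau returns its
midpoint with a warning.  Quadratic refinement was chosen over splines
because its error has a simple bound (≈ h²/λ for decay length λ) that can
be checked against an analytic oracle.

The promolecular test bed superposes two unrelaxed exponential atomic
densities ρ(x) = c_A e^(−x/λ_A) + c_B e^(−(d−x)/λ_B).  Amplitudes are the
atomic numbers; decay lengths derive from first ionization energies via
the asymptotic law ρ ~ e^(−2√(2I) r) (a.u.), both frozen in-repo.  Its CP
has a closed form, x* = [ln(c_A λ_B / c_B λ_A) + d/λ_B] / (1/λ_A + 1/λ_B).
Profiles sample [0.2 d, 0.8 d] (the exponential model has no nuclear
cusps) with a default of 501 points, at which the refinement error is
~1e-5 Å, comfortably inside the 1e-4 Å agreement the tests demand.
This 1-D treatment represents only the along-path minimum; curvatures,
ellipticities and true 3-D searches are out of scope.

## EDA bookkeeping

Terms are stored in kJ/mol and validated against
E_int = E_elec + E_Pauli + E_ind + E_disp and E_pol = E_ind + E_disp at a
default tolerance of 0.15 kJ/mol: tables printed to one decimal can
disagree with their printed totals by up to ~0.15 through rounding alone
(the packaged aqua-ion row sums to 114.1 against a printed 114.0), and
validation must not flag pure rounding.  Relative terms are componentwise
Ac − La differences; by that convention a negative value favours the Ac
complex.  The packaged 17-row relative table is checksummed and
identity-checked on load.

## Exchange thermodynamics

Δlog K(Ac–La) = −ΔG²⁹⁸·1000 / (R T ln 10) with T = 298.15 K and CODATA
R = 8.31446 J mol⁻¹ K⁻¹; with these constants every row of the packaged
16-ligand table reproduces its reference Δlog K and log K(Ac) columns at
their printed precision.  The logarithm is base 10 (required for
consistency of every printed pair).  Display rounding is two decimals,
half away from zero; full precision is kept internally.  Predicted
log K(Ac) is absent — never zero — when no experimental log K(La) exists.
Whether the input free energies contain standard-state corrections is a
property of the upstream calculation and does not affect this module's
contract.

## Speciation and pM

A model lists species M_m L_l H_h with cumulative log β relative to free
M, fully deprotonated L, and H⁺; free M and L are implicit components and
h may be negative for hydroxo species.  The formulation is pH-buffered:
[H⁺] is fixed at 10^(−pH) and the proton balance is not solved — exactly
what a pM at fixed pH requires.  Activity corrections are not applied;
constants are used at their reported ionic strengths.  Metal hydrolysis
enters only if hydroxo species are supplied explicitly.

The two mass balances are solved by damped Newton iteration on
(log₁₀[M], log₁₀[L]) with *logarithmic* residuals log₁₀(T/C), which keep
steps well scaled when cumulative constants span tens of orders of
magnitude.  When a single complex dominates both balances the Jacobian is
nearly singular and the residual surface develops a flat valley along
d(log M, log L) = (−1, +1); each iteration therefore tries the exact
Newton step (which traverses the valley) and then a rank-truncated
pseudoinverse step (pure descent in the well-determined direction), each
rescaled to at most 20 log units and halved up to 60 times until the
residual norm decreases.  Convergence demands relative balance residuals
below 1e-12; the start point is three decades below each total.  The
solver is deterministic.

The independent cross-check is a brute-force oracle sharing no code with
the solver: a sign-change grid scan plus bisection on log₁₀[M], with the
ligand balance solved by an inner bisection at every trial point, driven
to relative residuals ≤ 1e-6.  pM uses the standard comparison
conditions: total metal 1 µM, total ligand 10 µM, pH 7.4.

## Synthetic data: what it emulates and what it does not

*Paired geometries.*  Donors are placed on quasi-uniform Fibonacci-sphere
directions at class-dependent mean distances (carboxylate O 2.50,
pyridine N 2.65, amine N 2.75, water O 2.60 Å — typical nine-coordinate
La³⁺ values), with per-structure Gaussian distance noise of 0.02 Å
(2.5× = 0.05 Å for amine N, encoding the flat amine potential surfaces as
a variance statement) and a true comparison-metal offset of 0.059 Å.  The
default study condition is 17 pairs with a nonadentate 3+3+3 donor set.
Each donor carries the minimal substituent fragment its class needs
(O–C(–O) for carboxylate, a full six-ring for pyridine, three C for
amine, two H for water); orientations are re-drawn (≤ 100 times) whenever
a spurious inter-donor contact would change any donor's perceived class —
classifier fidelity, not hard-sphere realism, is the acceptance
criterion.  The generator does **not** emulate ligand backbones,
conformational strain, correlated donor displacements, or systematic
DFT-vs-crystal biases; recovery tests therefore demonstrate the
statistical machinery, not the accuracy of any quantum-chemistry method.

*EDA tables.*  Component magnitudes are drawn from ranges typical of
trivalent metal–polyaminocarboxylate interactions and the totals are set
exactly by the identities; optional one-decimal rounding emulates printed
tables.

*Equilibrium cases.*  Random models combine up to four cumulative
ligand-protonation species (stepwise log K from 2–11, descending) with an
ML complex (log β 2–30) and optional protonated-complex steps; each case
ships with its oracle pM, regenerating from the next seed substream if
the oracle cannot bracket.  All generators are deterministic given
(spec, seed); truth is emitted as a sidecar table, never only in
filenames.

## Problem sizes and determinism

The radius-recovery study uses 20 replicates of 17 pairs (2040 non-amine
Δd values per study); the solver validation uses 100 random models; the
CP sweep uses 40 element-pair/bond-length draws.  At these sizes the full
test suite and the acceptance script each complete in well under a
minute on one CPU, while the Monte-Carlo standard error of the recovered
center (~0.0006 Å) sits far below the 0.003 Å acceptance band.  All
randomness flows from explicit integer seeds through per-purpose
substreams.

## Known limitations

* Donor classes are graph heuristics; ferrocene-like or highly conjugated
  donors may classify as `other`.
* CIF/crystallographic input is not parsed; experimental reference
  distances enter as plain tables.
* The 1-D CP treatment cannot distinguish a path minimum from a true
  (3,−1) saddle if the supplied profile does not follow a bond path.
* The speciation module solves fixed-pH systems with m, l ≥ 0 species;
  polynuclear species (m or l > 1) are accepted but warned as untested
  against reference speciation software output.
* Stability-constant predictions inherit the ionic-medium inconsistencies
  of their experimental inputs; no activity model is applied.
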