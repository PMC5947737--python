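# Methods

## Model overview

`c4budget` treats steady-state, strictly light-limited C₄ photosynthesis
as a stoichiometric supply–demand problem in two compartments, mesophyll
(M) and bundle sheath (BS).  Three layers are chained:

1. an optical layer that splits absorbed photons between the
   compartments,
2. a whole-leaf electron-budget layer that converts per-CO₂ NADPH and
   ATP demand into linear (LET) and cyclic (CET) electron fluxes, and
3. a cell-type layer that distributes both fluxes between BS and M under
   photon-balance and photosystem-allocation constraints.

A fourth layer inverts the demand tables: given the modelled production
fractions, it solves for the metabolic degrees of freedom (γ, η, η₁, η₂)
that make demand match supply in both cell types.

Everything is closed-form; there is no randomness, no fitting, and the
only numerical iteration is an optional self-consistency loop and the
scalar root solve of the extinction-coefficient helper.

## Optical layer

One interveinal unit comprises the interveinal mesophyll column M1
(width fraction `m`, default 0.55) and the vein column (width `1 − m`)
stacked as adaxial mesophyll M2, bundle sheath (depth fraction `n_BS`,
default 0.6), abaxial mesophyll M3.  M2 and M3 each take half the non-BS
depth, which makes them interchangeable: swapping their nominal heights
changes nothing.

Chlorophyll (`CHL`, µmol m⁻²; `f_bsCHL` of it in BS) is divided among
the M sections by area.  Light enters adaxially in a single pass with no
scattering; each section absorbs `1 − exp(−k·C)` of what reaches it,
where `C` is the section's chlorophyll per unit *leaf* area and the
column widths enter only as the incident-light shares `m` and `1 − m`.
An alternative dialect that renormalises the exponent by column width
(`C/m`) was evaluated and rejected: it fails to reproduce the published
BS:M absorptance ratios of the four species presets (giving ≈0.33 and
≈0.71 where 0.40 and 0.92 are reported), whereas the adopted form
reproduces all four at two decimals.

The extinction coefficient `k` (default 0.005 m² (µmol Chl)⁻¹) can be
refit to a measured whole-leaf absorptance with `fit_k`, a bracketed
Brent solve.  The default bracket tops out at k = 0.02 — four times the
broadband estimate and already near-total absorption at typical
chlorophyll contents — so targets no leaf can exhibit (e.g. 0.9999)
raise an error instead of returning an absurd coefficient.

Degenerate inputs (`k = 0` or `CHL = 0`) return zero absorptances with a
`degenerate` flag and a NaN absorptance ratio rather than an error.

## Demand stoichiometry

Per CO₂ carboxylated, each decarboxylation type has fixed NADPH and ATP
demands in each cell type, parameterised by:

| symbol | meaning | default |
|---|---|---|
| ϕ (`phi_leak`) | leakiness: BS-decarboxylated CO₂ that escapes, inflating the C₄ cycle by (1+ϕ) | 0.16 |
| φ (`phi_extra`) | chloroplastic ATP per C₄ cycle for PEP regeneration | 2 |
| γ (`gamma`) | fraction of 3-PGA reduction located in BS | 0.5 |
| η, η₁, η₂ | route fractions in mixed decarboxylation types | — |
| n (`n_mito`) | mitochondrial ATP per NADH; sets the malate fraction a = 1/(1+n) of the standard PEP-CK subtype | — |
| ν_o/c, ν_n/c, ν_r/c | oxygenation, nitrate-reduction and day-respiration : carboxylation ratios | 0 |

The published demand table hard-codes the PEP-regeneration cost as 2
ATP; the implementation writes it as φ·(1+ϕ) so the φ parameter is
honoured, with identical numbers at the default φ = 2.

Alternative sinks enter through four cost terms: x₁/x₃ (NADPH/ATP landing
in M) and x₂/x₄ (landing in BS), built from the ν ratios with the
photorespiratory reduction share split by γ, nitrate reduction placed in
M, and starch synthesis (0.167·(1 − 0.5ν_o/c − ν_r/c) ATP) plus the
non-reductive photorespiratory costs placed in BS.  These cell
assignments are fixed.  Sinks carry an explicit on/off switch because
the basic model means *all* x terms zero, including the starch term —
not merely zero ν ratios.  The illustrative sink setting used throughout
the examples is ν = (1/20, 1/35, 1/40).

BS:total requirement ratios are always derived from the cell entries.
(The published ratio column for the 'pure' PEP-CK type drops a term of
its own cell entry; deriving from the entries reproduces the stated
3:4 BS ATP share for the simplest scenario.)  Ratios outside [0, 1] are
reported as-is with a feasibility flag — they are the diagnostic signal
the matching layer relies on — never clamped.

## Whole-leaf electron budget

Quantum yield is assumed co-limited by NADPH and ATP: LET is sized
exactly by the NADPH demand (J_LET = 2·N_req) and CET covers the ATP
deficit,

    J_CET = max(0, A_req − J_LET·H_LET/h) · h / H_CET ,

with H_LET = 3, H_CET = 2 (full Q-cycle) and h = 4 protons per ATP, so
LET alone delivers ATP:NADPH = 1.5.  The photon cost per carboxylation
is J_LET·(1/Φ_2LL + 1/Φ_1LL) + J_CET·(1/Φ_1LL) with Φ_2LL = 0.8 and
Φ_1LL derived from the ratio Φ_2LL/Φ_1LL = 0.85 (never stored
independently).  Φ_CO2 is its reciprocal **per Rubisco carboxylation**:
no net-CO₂ correction for photorespiration or day respiration is
applied.  This convention is what makes the sink-enabled yields
(0.065, 0.082–0.083, 0.078) come out as published; applying a net-CO₂
correction instead gives ≈0.062 for the first of these and was
rejected.  The ATP share supplied by LET (≈0.56 at the basic demand) is
always a derived output, preserving the exact closure
J_LET·H_LET/h + J_CET·H_CET/h = A_req whenever the deficit is
non-negative; demand combinations below the LET-only point floor CET at
zero and set an `atp_surplus` flag.

Because this layer sees only the demand totals, f_CET and Φ_CO2 are
exactly invariant to every optical and photosystem-distribution input —
a property the test suite asserts.

## Cell-type partitioning

Let x and y be the BS LET and CET electron fluxes, s = x + y, and
r = k_BS:k_M the BS:M light absorbed per photosystem.  Three constraints
hold simultaneously:

1. BS photon balance: x·(1/Φ_2LL + 1/Φ_1LL) + y·(1/Φ_1LL) = A_BS, where
   A_BS is the BS share of absorbed photons per CO₂ (the M balance then
   holds identically);
2. PSII allocation: α = (x/r) / (x/r + J_LET − x);
3. PSI allocation: f_bsPSI = (s/r) / (s/r + J_tot − s).

Substituting s(x) from (1) and equating the two expressions for r gives
a quadratic in x.  On every realistic input exactly one root is
admissible (x ∈ [0, J_LET], r > 0); if both ever qualified the solver
would raise an ambiguity error rather than guess, and a dedicated test
checks the closed-form root against an independent bisection solve to
1e-9 over the presets and 100 seeded random parameter draws.

Degenerate distributions bypass the quadratic: α = 0 forces x = 0 (with
r pinned by the PSI constraint alone, and the BS PSI:PSII ratio reported
as a flagged infinity — the NADP-ME situation of nearly PSII-free BS
chloroplasts), α = 1 forces x = J_LET, and f_bsPSI ∈ {0, 1} pin s
symmetrically.

Feasibility of a solution means u, v ∈ [0, 1] (the fractions of M- and
BS-absorbed light driving LET), y ∈ [0, J_CET] and r > 0, with closed
bounds so boundary values count.  The α-scan evaluates the solver on a
grid (default step 0.005, matching the published tables) and reports the
contiguous feasible interval, plus the two analytic boundaries: v → 1
(equivalently y → 0) and u → 1 (y → J_CET), each mapped back to α
through the PSI constraint.

## Demand–supply matching

Each matching equation sets a BS:total requirement ratio equal to the
corresponding modelled production fraction.  Written as residuals
(BS requirement − fraction × total requirement), every equation is
affine in the unknowns with no cross terms, so the solvers sample the
residual at unit corners and solve exactly — closed form, no iteration.
The brute-force residual-grid search appears only as a test oracle.

The γ policy for double mixes follows which ratio is η-free: the
aspartate–malate mix takes γ from the ATP balance and η from NADPH; the
NAD-ME + PEP-CK mix takes γ from NADPH and η from ATP; the
NADP-ME + PEP-CK mix needs the simultaneous 2×2 solve.  The triple
pathway closes its third degree of freedom with the imposed BS:M
NADP-MDH abundance ratio, η₂ = ρ·η₁ (default ρ = 0.39); ρ = 0 recovers
the double PEP-CK mix.

Out-of-range solutions are results, not errors: η > 1 for the PEP-CK
secondary route in NADP-ME species and γ_ATP < 0 for the 'pure' PEP-CK
type are precisely the model's mechanism-exclusion arguments.

By default the production fractions are computed once from the pure
primary-subtype budget (single pass).  The opt-in
`self_consistent_match` loop re-derives the budget from the solved mix,
re-solves the cell-type system and iterates to a fixed point; across the
presets it converges in a handful of passes and moves the production
fractions by less than 0.01, which is why the single pass is the
default.

## Parameter presets

`table1_default` carries the indicative parameter set (m = 0.55,
n_BS = 0.6, CHL = 475, f_bsCHL = 0.33, f_bsPSI = 0.35, k = 0.005,
Φ_2LL = 0.8, Φ_2LL/Φ_1LL = 0.85, H_LET = 3, H_CET = 2, h = 4).  That
set specifies no α (the PSII BS fraction is the scanned variable in the
reference analysis), so the preset ships α = 0.1 as an illustrative
value inside the basic-model feasible range; override it for any real
leaf.  `case_I`–`case_IV` overlay the measured inputs of two NADP-ME
species (*Sorghum bicolor*, *Cenchrus ciliaris*) and two NAD-ME species
(*Panicum miliaceum*, *Panicum coloratum*).  Presets are JSON data files
inside the package; users can supply their own via flat JSON/YAML
configs with the same symbol-named keys.

## Numerical choices and tolerances

* Photon-balance and production closures hold to < 1e-9 and are asserted
  at that tolerance.
* The matching residual solves are exact linear algebra; solutions are
  verified to satisfy their defining balances to 1e-9.
* Quadratic root selection clips x into [0, J_LET] only within 1e-12 of
  the boundary (floating-point guard), never substantively.
* Report CSVs use fixed column order and fixed float formatting, so
  identical configurations are byte-identical.

## What the tests do and do not show

The test suite reproduces the published output tables for the four
species presets (two-decimal agreement, at ±0.01 for the quantities
whose second decimal is sensitive to the third decimal of the modelled
BS:M absorptance ratio), verifies the conservation closures and
invariances, and cross-checks the closed-form solver against independent
bisection and grid oracles.  What this demonstrates is internal
consistency of the analytical model and faithful reconstruction of its
published behaviour — not predictive validity for real leaves: the model
assumes steady-state limiting light, single-pass unscattered optics, a
single r scalar for both photosystems, no enzyme limitation, no
fluctuating-light dynamics, and fixed cellular locations for the
alternative sinks.

## Known limitations

* The NAD-ME + PEP-CK η reported for the NAD-ME species and the exact
  triple-pathway η₁ published for the NADP-ME species are not recovered
  by the documented matching procedure (the procedure gives ≈0.52 for
  *P. miliaceum* where 0.78 is printed); the solvers implement the
  documented procedure and flag the discrepancy rather than tune to the
  printed values, which are themselves reported as uncertain.
* Optics are spectrally flat and unidirectional; no sieve or detour
  effects.
* The mitochondrial chain is a single scalar n; no NH₂-shuttle
  bookkeeping for the 'pure' PEP-CK type.
* Day respiration enters only through the starch sink term, not as a
  net-CO₂ offset in the quantum yield (see the basis choice above).
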