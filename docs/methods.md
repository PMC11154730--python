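# Methods

This note records the models implemented in `physchem`, the assumptions
and conventions behind them, the calibration of the packaged
raspberry-ketone fixture, and the package's known limitations. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The species ledger

The ledger is the package's only upstream input: per (species, phase), a
YAML block of electronic-structure summary quantities. Units follow the
conventions of the quantities' home communities — `electronic_energy`,
`zpve` and `thermal_enthalpy_correction` in Hartree (they are combined
and converted exactly once, in `assemble_enthalpy`, with
1 Eh = 2625.4996 kJ·mol⁻¹), Gibbs energies in kJ·mol⁻¹, orbital and
vertical ionic-state energies in eV, wavenumbers in cm⁻¹, rotational
constants in GHz. A record with a negative wavenumber is flagged with a
validation warning rather than rejected, so failed optimizations remain
representable; structural problems (unknown phase, non-positive mass,
HOMO above LUMO) are hard errors. Unknown fields round-trip untouched as
opaque metadata. The schema is versioned through a `schema_version`
header.

Temperature defaults to 298.15 K everywhere and is overridable per call.

## Isodesmic formation enthalpies

A scheme is accepted only if elementally balanced; bond conservation is
checked separately against RDKit bond inventories (bond class = unordered
element pair × bond order, aromatic bonds as their own class, hydrogens
explicit). Reaction enthalpies are stoichiometric sums of assembled
species enthalpies. `formation_enthalpy` solves Hess's law for the single
species lacking a reference value; its uncertainty is the root-sum-square
of the ν-weighted reference uncertainties only — no model error for the
computed reaction enthalpy is added, since that error is precisely what
the isodesmic construction is designed to cancel. Pooling is an
unweighted mean with a Student-t 95% half-width; for the packaged
six-scheme set this half-width is ±3.6 kJ·mol⁻¹, and the test suite
asserts it as such. A much smaller interval sometimes quoted for pooled
isodesmic estimates (±0.17 kJ·mol⁻¹ scale) is not reproducible as a
t-based CI of six values with ~3 kJ·mol⁻¹ scatter; the package reports
the t-based interval and treats the smaller figure as a documented
discrepancy.

The bundled reference table
(`data/reference_formation_synthetic.tsv`) is a synthetic stand-in, not a
copy of any published evaluation: its values were calibrated so that the
fixture's six schemes are mutually consistent (each scheme's ΔrH°, ΔfH°
and u reproduce the calibration targets exactly), while staying close to
experimental gas-phase values for the anchor species (methane, methanol,
phenol, toluene, butan-2-one). The calibration residual is absorbed by
the remaining auxiliaries, which consequently deviate from experimental
evaluations by up to ~14 kJ·mol⁻¹ (benzyl alcohol is the worst case).
The file says so in its header.

## RRHO thermodynamics

Conventional rigid-rotor harmonic-oscillator: Sackur–Tetrode translation
at 1 bar (standard state documented and overridable), classical rigid
rotor with symmetry number (default 1 — rotational entropy depends on
it, so it is a parameter, but no attempt is made to infer it from the
structure), and per-mode quantum harmonic oscillators evaluated in the
e^{-x} form so arbitrarily stiff modes stay finite. The thermal enthalpy
correction includes the PV term (H = U + RT); ZPVE is reported
separately, matching the ledger's split. Cp − Cv = R holds exactly by
construction. No quasi-RRHO / free-rotor damping of soft modes is
applied, and frequencies enter unscaled by default; a global scaling
factor is exposed because composite protocols often scale hybrid-DFT
harmonic frequencies.

## Ionization, partitioning, solubility

- log P: sign convention is ΔG_transfer = G(octanol) − G(aqueous), so a
  favorable transfer into octanol gives positive log P.
- pKa: the cluster-continuum route deliberately avoids the proton's
  solvation energy by neutralizing against hydroxide with n explicit
  waters (n = 2 validated for phenols) retained on both acid and anion.
  The additive constant is the pKa of water on the convention that treats
  liquid water at its molar concentration: 14 + log₁₀(55.33) ≈ 15.74.
  Both ingredients of that constant (K_w = 10⁻¹⁴ and [H₂O] = 55.33 M) are
  inputs of the derivation, so the 55.33 factor must surface in the
  constant; the alternative convention (activity of water = 1, constant
  14) is selectable via the `pka_water` argument.
- log D assumes a monoprotic acid whose anion does not partition into
  octanol (no ion-pair term), hence log D ≤ log P with slope −1 per pH
  unit far above the pKa.
- Phase-change enthalpies use the linear-in-square-roots surface-
  descriptor form ΔH = a·√SA + b·√(ν·σ²_tot) + c. The bundled default
  coefficients are calibrated on the packaged raspberry-ketone
  descriptors (they reproduce ΔvapH = 70.03 and ΔsubH = 96.95 kJ·mol⁻¹
  for that molecule) and are configuration, not physics: projects with a
  fitted coefficient set for their chemistry should supply it.
- GSE constant: the empirical constant C is 0.8 by default. The
  canonical melting-point GSE uses 0.5, but the fusion-enthalpy form
  implemented here absorbs the mole-fraction → molar conversion into C,
  and 0.8 reproduces the reference solubilities (0.0153 M / 0.0202 M)
  from their stated inputs. C is a parameter.
- Working temperature: the reference solubilities back out exactly at
  T = 298 K while the package default is 298.15 K; the difference is
  ~0.3–0.5% in S, inside every stated tolerance. Tests that want the
  exact figures pin T = 298 K explicitly.
- log P feeding the solubility chain is the pipeline's computed value
  (1.83 for the fixture).

## Electrode potentials

The solution-phase cycle sums the gas-phase reaction Gibbs energy, the
signed solvation legs, and one RT·ln(24.46) per unit of signed
stoichiometry on each leg flagged as changing standard state (1 bar gas →
1 M solution); flags are per-species so both the "every species" and
"only species changing state" readings are expressible. Conversion to a
potential uses F = 96.485 kJ·mol⁻¹·V⁻¹ and the absolute SHE potential
4.44 V (configurable; 4.28 V is also in circulation). Two sign
conventions coexist for proton-coupled phenolic couples: the package
always computes the reduction-convention value, exposes
`couple_direction="oxidation"` to render the oxidation-signed number,
and reports the formal potential as |ΔG′|/(nF) − E(SHE) — the magnitude
convention, positive for a strongly exergonic couple either way the
half-reaction is written. The pH correction ΔG′ = ΔG*_aq − N·ln10·RT·pH
gives the textbook 59.16·N mV per pH unit at 298.15 K.
`couple_gibbs` implements the general two-couple ΔG = −nF·ΔE only;
pairing it with a specific partner couple requires that partner's
potential as input.

## Conceptual DFT

Hardness conventions differ between communities: η = I − A (full gap)
and η = (I − A)/2. Published index tables frequently mix them — a
full-gap η alongside an ω computed from the half-gap on the orbital
route, but the half-difference η itself inside ω on the ΔSCF route. The
package refuses to pick a winner: `CDFTIndices` carries both labelled
hardnesses, and ω is computed per route the way each route's tables are
actually constructed (Koopmans: ω = μ²/gap; vertical: ω = μ²/(2·η_half)).
The `eta` property returns the convention conventional for the route.
DOS curves use unit-area Gaussians (default σ = 0.2 eV, grid 0.01 eV —
a typical visual broadening; σ is a parameter), so the TDOS integrates
to the orbital count and fragment PDOS curves sum to the TDOS pointwise.
Fragment weights are ledger inputs from upstream population analysis; no
population analysis is performed here.

## The synthetic generators

Every pipeline map is affine in the ledger energies, so each inverse
problem is solved in closed form — no optimizer, except a 1-D Brent
bracket for the vibrational calibration (Cv is monotone in a global
frequency scale).

`make_rk_fixture` encodes the raspberry-ketone calibration targets: the
six scheme reaction enthalpies, pKa 9.95, log P 1.83, ΔvapH/ΔsubH
70.03/96.95, ΔG*_aq = −510.48 kJ·mol⁻¹, the frontier-orbital and
vertical ionic-state energies per environment (embedded verbatim at
their stated precision), and a 72-mode harmonic spectrum scaled so the
RRHO Cv is 187.44 J·K⁻¹·mol⁻¹ at 298.15 K. One printed inconsistency is
worth flagging: the aqueous vertical chemical potential implied by the
embedded IP/EA is −(6.191 + 0.884)/2 = −3.5375 eV, which rounds to
−3.54, not the −3.55 sometimes quoted alongside those inputs — likely
rounding from unrounded upstream values; the package reports the
computed number. Tolerance policy for fixture-derived values is one unit
in the last printed digit unless a module states otherwise.

What the fixture does *not* emulate: the spectrum, rotational constants
and gauge enthalpies are plausible but synthetic, so quantities outside
the calibration targets (e.g. S°, which comes out ≈429 J·K⁻¹·mol⁻¹ for
the fixture spectrum, or the absolute ZPVE) are internally consistent
but not reference values; passing tests demonstrate the pipeline
algebra, not the accuracy of any electronic-structure method.

`make_random_ledger` samples ground-truth properties inside documented
plausibility bounds (or accepts pinned targets, rejecting out-of-bounds
ones), back-computes a ledger, and returns both. Species total
enthalpies for the formation chain are built as ΔfH plus per-element
chemical potentials, which cancel in any balanced reaction — so the
recovery is exact by construction. The vap/sub inversion solves a 2×2
linear system in (√SA, √(ν·σ²_tot)); because that system is
near-singular under the default coefficients, independently sampled
vap/fus targets are inverted only when explicitly pinned, and otherwise
descriptors are sampled and the targets defined forward. Gaussian noise
(kJ·mol⁻¹) applies to Gibbs energies and electronic energies after
construction; a 0.1 kJ·mol⁻¹ perturbation on each cluster energy
propagates to σ ≈ 0.035 pK units (RSS over the four species divided by
ln10·RT).

## Problem sizes and numerical choices

The whole pipeline is closed-form desk arithmetic: the test suite (≈130
tests including the property-based ones, derandomized) and the
acceptance script each run in seconds. Ledgers are a few kilobytes.
Brent calibration uses xtol = 1e-12 on the frequency scale. Degenerate
inputs are defined, not special-cased: empty spectra are atoms
(Cv = 3R/2), T_m ≤ T clamps the GSE fusion term to zero (a melt), a
single formation estimate pools to itself with an undefined (NaN) CI,
and identical estimates give a zero-width CI.

## Limitations

- No conformational sampling, anharmonicity, hindered rotors, or
  condensed-phase heat capacities.
- No automatic search for isodesmic schemes; schemes are authored inputs.
- pKa is monoprotic-acid only; log D has no ion-pairing term.
- Surface descriptors and fragment weights must come from upstream
  tools; the package neither computes molecular surfaces nor population
  analyses, and it never runs an electronic-structure engine.
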