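# physchem

Physicochemical properties of small bioactive molecules from
quantum-chemistry summary data — a closed-form, fully tested inference
pipeline with raspberry ketone (4-(4-hydroxyphenyl)butan-2-one) as its
worked example.

Early drug-discovery and flavour/nutraceutical work needs ΔfH°, pKa,
log P / log D, aqueous solubility, electrode potentials and reactivity
indices for compounds with little experimental data. Once the expensive
electronic-structure work is done, every one of those properties follows
from a handful of summary quantities by closed-form thermodynamics. This
package implements that downstream chain for computational chemists who
want it reproducible and testable rather than buried in spreadsheets. It
does **not** run quantum-chemistry engines: its input is a *species
ledger* — a YAML file holding, per species and phase, the electronic
energy `E`, zero-point energy `ZPVE` and thermal correction `H_corr`
(Hartree), Gibbs energies (kJ·mol⁻¹), harmonic wavenumbers (cm⁻¹),
frontier-orbital and vertical ionic-state energies (eV), and
molecular-surface descriptors.

## What it computes

- **Species enthalpy** — `H = (E + ZPVE + H_corr) × 2625.4996 kJ·mol⁻¹·Eh⁻¹`.
- **Isodesmic formation enthalpy** — bond-conserving schemes are parsed
  and validated (elemental balance, RDKit bond-class inventories);
  ΔrH° = Σν·H(products) − Σν·H(reactants); Hess's law against a reference
  ΔfH° table solves for the target with root-sum-square uncertainty
  propagation; several schemes pool into a mean with a Student-t 95% CI.
- **RRHO thermochemistry** — Sackur–Tetrode translation, classical rigid
  rotor with symmetry number, per-mode harmonic oscillators: ZPVE,
  H_corr, S°, Cv and Cp = Cv + R.
- **Ionization and partitioning** — log P = −ΔG_transfer/(ln10·RT);
  cluster-continuum pKa = ΔG_neut/(ln10·RT) + pKa(H₂O) with
  pKa(H₂O) = 14 + log₁₀(55.33) ≈ 15.74 (no proton solvation energy
  needed); log D = log P − log₁₀(1 + 10^(pH−pKa)).
- **Solubility** — ΔvapH/ΔsubH from surface descriptors via
  ΔH = a·√SA + b·√(ν·σ²_tot) + c; ΔfusH = ΔsubH − ΔvapH; the general
  solubility equation log S = C − ΔfusH·(T_m−T)/(ln10·R·T·T_m) − log P
  and its Walden-rule variant log S = 0.5 − 0.01·(T_m/°C − 25) − log P.
- **Electrode potentials** — solution thermochemical cycle with
  RT·ln(24.46) standard-state corrections; E = −ΔG*_aq/(nF) − 4.44 V vs
  SHE; formal potential via ΔG′ = ΔG*_aq − N·ln10·RT·pH.
- **Conceptual DFT** — μ = −(I+A)/2, hardness in both the full-gap and
  half-difference conventions, electrophilicity ω = μ²/2η, and
  Gaussian-broadened TDOS/PDOS curves from orbital energies and fragment
  weights.
- **Synthetic ledgers** — every formula above is affine in the energies,
  so `physchem.synthetic` inverts each one exactly: it generates the
  calibrated raspberry-ketone reference ledger and randomized ledgers
  with known ground truth for round-trip testing.

## Worked example

```sh
python examples/solubility_chain.py
```

```
ΔvapH = 70.03  ΔsubH = 96.95  →  ΔfusH = 26.92 kJ/mol
GSE (pipeline ΔfusH):   S = 0.0154 M (2.52 mg/mL)
GSE (calorimetric 22.75): S = 0.0203 M
Walden (melting point only): S = 0.0119 M
```

The fusion enthalpy comes out of the vaporization/sublimation difference;
feeding it to the general solubility equation together with the melting
point (357.58 K) and the computed log P = 1.83 predicts a solubility of a
few hundredths molar — "slightly soluble", and consistent whether the
fusion term comes from the pipeline, from calorimetry, or from Walden's
rule. The other scripts in `examples/` cover the formation-enthalpy
pooling (−299.3 ± 3.60 kJ·mol⁻¹ over six schemes), RRHO heat capacities
(Cv = 187.44, Cp = 195.75 J·K⁻¹·mol⁻¹), pKa/log D (9.95; log D falls
from 1.83 to 1.53 at pH = pKa), redox potentials (ΔG*_aq = −510.48
kJ·mol⁻¹ → E′ = 1.29 V vs SHE at pH 7.4) and the CDFT indices
(η = 7.84 eV full-gap, ω = 1.66 eV).

A thin CLI mirrors the examples: `physchem formation`, `physchem thermo`,
`physchem pka`, `physchem logd --ph 7.4`, `physchem solubility
[--walden]`, `physchem redox`, `physchem cdft`, `physchem fixture`.

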