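"""Isodesmic reaction schemes and formation-enthalpy estimation.

An isodesmic reaction conserves the number and type of chemical bonds on
both sides, so systematic errors in computed species enthalpies largely
cancel in the reaction enthalpy.  Given the reaction enthalpy of such a
scheme and experimental formation enthalpies for every auxiliary species,
Hess's law yields the formation enthalpy of the one remaining (target)
species; several schemes are then pooled into a mean with a Student-t 95%
confidence interval.

Bond typing uses RDKit on the ledger's SMILES connectivity: a bond class is
the unordered element pair together with the bond order, aromatic bonds
flagged as a class of their own.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from scipy import stats

BondClass = tuple[str, str, float, bool]  # (elem1 ≤ elem2, bond order, aromatic)


class SchemeError(ValueError):
    """Unbalanced or unresolvable reaction scheme."""


# --- elemental formulas ------------------------------------------------------

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def parse_formula(formula: str) -> Counter[str]:
    """Parse a molecular formula (parentheses supported) into atom counts."""
    stack: list[Counter[str]] = [Counter()]
    i = 0
    while i < len(formula):
        ch = formula[i]
        if ch == "(":
            stack.append(Counter())
            i += 1
        elif ch == ")":
            i += 1
            m = re.match(r"\d+", formula[i:])
            mult = int(m.group()) if m else 1
            i += len(m.group()) if m else 0
            group = stack.pop()
            if not stack:
                raise SchemeError(f"unbalanced parentheses in formula {formula!r}")
            for el, n in group.items():
                stack[-1][el] += n * mult
        else:
            m = re.match(r"([A-Z][a-z]?)(\d*)", formula[i:])
            if not m:
                raise SchemeError(f"cannot parse formula {formula!r} at {formula[i:]!r}")
            el, digits = m.groups()
            stack[-1][el] += int(digits) if digits else 1
            i += len(m.group())
    if len(stack) != 1:
        raise SchemeError(f"unbalanced parentheses in formula {formula!r}")
    return stack[0]


# --- reaction schemes --------------------------------------------------------


@dataclass(frozen=True)
class ReactionScheme:
    """Stoichiometric scheme: species id → positive integer coefficient."""

    reactants: dict[str, int]
    products: dict[str, int]
    label: str = ""

    def species(self) -> list[str]:
        return list(self.reactants) + [s for s in self.products if s not in self.reactants]

    def signed_coefficients(self) -> dict[str, int]:
        """Products positive, reactants negative (net for species on both sides)."""
        out: dict[str, int] = {}
        for s, nu in self.products.items():
            out[s] = out.get(s, 0) + nu
        for s, nu in self.reactants.items():
            out[s] = out.get(s, 0) - nu
        return out

    def reversed(self) -> "ReactionScheme":
        return ReactionScheme(dict(self.products), dict(self.reactants), self.label)


def check_balance(
    scheme: ReactionScheme, formulas: Mapping[str, str]
) -> None:
    """Verify elemental balance; raise listing per-element deficits."""
    totals: Counter[str] = Counter()
    for side, sign in ((scheme.reactants, -1), (scheme.products, +1)):
        for species, nu in side.items():
            if species not in formulas:
                raise SchemeError(f"no formula known for species {species!r}")
            for el, n in parse_formula(formulas[species]).items():
                totals[el] += sign * nu * n
    deficits = {el: n for el, n in totals.items() if n != 0}
    if deficits:
        detail = ", ".join(
            f"{el}: {'+' if n > 0 else ''}{n} on product side" for el, n in sorted(deficits.items())
        )
        raise SchemeError(f"scheme {scheme.label or '?'} is not elementally balanced ({detail})")


def parse_reaction(
    text: str, formulas: Mapping[str, str] | None = None, label: str = ""
) -> ReactionScheme:
    """Parse ``"A + 2 B = C + D"`` (also ``⇌``/``->``) into a balanced scheme.

    Species tokens are looked up in ``formulas`` (id → molecular formula);
    a token absent from the table is taken to be a formula itself.
    Elemental balance is verified on construction.
    """
    sides = re.split(r"⇌|<=>|->|=", text)
    if len(sides) != 2:
        raise SchemeError(f"reaction {text!r} must have exactly one separator")

    def parse_side(side: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise SchemeError(f"empty term in reaction {text!r}")
            m = re.match(r"^(\d+)\s*(.+)$", term)
            if m:
                nu, species = int(m.group(1)), m.group(2).strip()
            else:
                nu, species = 1, term
            out[species] = out.get(species, 0) + nu
        return out

    scheme = ReactionScheme(parse_side(sides[0]), parse_side(sides[1]), label=label)
    table = dict(formulas or {})
    for s in scheme.species():
        table.setdefault(s, s)  # fall back to the token as a raw formula
    check_balance(scheme, table)
    return scheme


# --- bond inventories --------------------------------------------------------


def bond_inventory(smiles: str) -> Counter[BondClass]:
    """Count bond classes (element pair, order, aromatic flag), hydrogens included."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SchemeError(f"unparseable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    counts: Counter[BondClass] = Counter()
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()
        pair = tuple(sorted((a, b)))
        aromatic = bond.GetIsAromatic()
        order = 1.5 if aromatic else bond.GetBondTypeAsDouble()
        counts[(pair[0], pair[1], order, aromatic)] += 1
    return counts


def check_isodesmic(
    scheme: ReactionScheme, inventories: Mapping[str, Counter[BondClass]]
) -> tuple[bool, dict[BondClass, int]]:
    """Bond-conservation verdict plus the per-class (products − reactants) table."""
    diff: Counter[BondClass] = Counter()
    for species, nu in scheme.signed_coefficients().items():
        if species not in inventories:
            raise SchemeError(f"no bond inventory for species {species!r}")
        for cls, n in inventories[species].items():
            diff[cls] += nu * n
    table = dict(diff)
    return all(n == 0 for n in table.values()), table


# --- enthalpies --------------------------------------------------------------


def reaction_enthalpy(
    scheme: ReactionScheme, enthalpies: Mapping[str, float]
) -> float:
    """ΔrH = Σν·H(products) − Σν·H(reactants), kJ·mol⁻¹."""
    total = 0.0
    for species, nu in scheme.signed_coefficients().items():
        if species not in enthalpies:
            raise SchemeError(f"no enthalpy for species {species!r}")
        total += nu * enthalpies[species]
    return total


@dataclass(frozen=True)
class FormationEstimate:
    """One scheme's Hess-law estimate of the target's formation enthalpy."""

    reaction_label: str
    delta_r_h: float  # kJ·mol⁻¹
    delta_f_h: float  # kJ·mol⁻¹
    uncertainty: float  # kJ·mol⁻¹, RSS-propagated from reference uncertainties

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


def formation_enthalpy(
    scheme: ReactionScheme,
    delta_r_h: float,
    references: Mapping[str, tuple[float, float]],
) -> FormationEstimate:
    """Solve Hess's law for the single species lacking a reference value.

    ΔrH = Σν_p·ΔfH(p) − Σν_r·ΔfH(r); the target's ΔfH is the unique
    unknown.  Uncertainty is the root-sum-square of the ν-weighted reference
    uncertainties (the reaction-enthalpy model error is not included).
    """
    signed = scheme.signed_coefficients()
    unknown = [s for s in signed if s not in references]
    if len(unknown) != 1:
        raise SchemeError(
            f"scheme {scheme.label or '?'}: exactly one species may lack a "
            f"reference value, found {len(unknown)}: {unknown}"
        )
    target = unknown[0]
    known_sum = sum(
        nu * references[s][0] for s, nu in signed.items() if s != target
    )
    delta_f_h = (delta_r_h - known_sum) / signed[target]
    u = math.sqrt(
        sum((nu * references[s][1]) ** 2 for s, nu in signed.items() if s != target)
    ) / abs(signed[target])
    return FormationEstimate(scheme.label, delta_r_h, delta_f_h, u)


def aggregate_formation(
    estimates: Sequence[FormationEstimate],
) -> tuple[float, float, pd.DataFrame]:
    """Unweighted mean, Student-t 95% half-width, and the per-scheme table.

    The half-width is NaN for a single estimate (no degrees of freedom) and
    0 for identical estimates.
    """
    if not estimates:
        raise SchemeError("no formation estimates to aggregate")
    table = pd.DataFrame(
        {
            "reaction": [e.reaction_label for e in estimates],
            "delta_r_h": [e.delta_r_h for e in estimates],
            "delta_f_h": [e.delta_f_h for e in estimates],
            "u": [e.uncertainty for e in estimates],
        }
    )
    values = table["delta_f_h"].to_numpy()
    mean = float(values.mean())
    n = len(values)
    if n < 2:
        return mean, float("nan"), table
    sem = values.std(ddof=1) / math.sqrt(n)
    ci95 = float(stats.t.ppf(0.975, n - 1) * sem)
    return mean, ci95, table


# --- bundled reference table -------------------------------------------------


def load_reference_table(path: str | Path | None = None) -> dict[str, tuple[float, float]]:
    """Load a (species → (ΔfH°, u)) reference table from a TSV file.

    With no path, the packaged synthetic reference table is used (see the
    file header for its provenance and calibration notes).
    """
    if path is None:
        ref = resources.files("physchem.data") / "reference_formation_synthetic.tsv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t", comment="#")
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
    return {
        row.species_id: (float(row.delta_f_h), float(row.u))
        for row in frame.itertuples()
    }


def load_reference_frame(path: str | Path | None = None) -> pd.DataFrame:
    """Full reference table (formula/SMILES/provenance columns included)."""
    if path is None:
        ref = resources.files("physchem.data") / "reference_formation_synthetic.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")
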