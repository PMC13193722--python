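"""Elemental composition arithmetic and the 2HG modification registry.

Monoisotopic masses come from a fixed internal table (CODATA/NIST values) so
that every mass in the package is reproducible without network access. The
central chemical objects are :class:`ElementalComposition` (an immutable
element→count mapping with element-wise arithmetic) and
:class:`ModificationSpec`, which defines a post-translational modification as
a net elemental adduct together with its diagnostic neutral-loss channels and
an optional stable-isotope variant.

The shipped registry describes *O*-2-hydroxyglutarylation: esterification of
a Ser/Thr/Tyr hydroxyl by 2-hydroxyglutarate. The net adduct is C5H6O4
(+130.0266 Da; the free acid C5H8O5 minus water lost on ester formation).
During MS/MS the ester bond can cleave two ways, giving two diagnostic
neutral losses:

* channel A — loss of C5H6O4 (130.0266 Da), restoring the unmodified residue;
* channel B — loss of C5H8O5 (148.0372 Da), leaving a dehydro residue.

The d4 isotope variant (four deuteriums on the glutarate backbone) supports
metabolic-flux validation: a genuine in-vivo modification fed with the
deuterated metabolite appears as a +4.0251 Da heavy/light spectral pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ElementalComposition",
    "ModificationSpec",
    "NeutralLoss",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER",
    "RESIDUE_COMPOSITIONS",
    "composition_mass",
    "peptide_neutral_mass",
    "mz",
    "neutral_mass_from_mz",
    "MOD_2HG",
    "CARBAMIDOMETHYL",
    "builtin_modifications",
]

# Monoisotopic atomic masses, u (CODATA/NIST). Heavy isotopes are distinct
# symbols: D = deuterium (2H), 13C, 15N, 18O.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "C": 12.0,
    "13C": 13.00335483507,
    "N": 14.0030740048,
    "15N": 15.0001088982,
    "O": 15.9949146196,
    "18O": 17.9991610,
    "S": 31.9720710015,
    "P": 30.9737616320,
    "Se": 79.9165213,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: Mass of a proton (H+), u.
PROTON_MASS = 1.00727646688

_FORMULA_TOKEN = re.compile(r"(\d+[A-Z][a-z]?|[A-Z][a-z]?)(\d*)")


class ElementalComposition(Mapping[str, int]):
    """Immutable element→count mapping with element-wise arithmetic.

    Construct from a mapping or a Hill-style formula string such as
    ``"C5H6O4"``; heavy isotopes use a mass-number prefix (``"13C2"``) or the
    ``D`` shorthand for deuterium.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | str | None = None, **kwargs: int):
        if isinstance(counts, str):
            counts = _parse_formula(counts)
        merged: dict[str, int] = dict(counts or {})
        for sym, n in kwargs.items():
            merged[sym] = merged.get(sym, 0) + int(n)
        for sym, n in list(merged.items()):
            if sym not in MONOISOTOPIC_MASS:
                raise KeyError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise ValueError(f"negative count for element {sym}: {n}")
            if n == 0:
                del merged[sym]
        self._counts = merged

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> int:
        return self._counts.get(key, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, key) -> bool:
        return key in self._counts

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self._counts)
        for sym, n in other.items():
            out[sym] = out.get(sym, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self._counts)
        for sym, n in other.items():
            out[sym] = out.get(sym, 0) - n
            if out[sym] < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {sym}"
                )
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalComposition({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula()!r})"

    # -- chemistry ---------------------------------------------------------
    @property
    def mass(self) -> float:
        """Monoisotopic mass in u."""
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self._counts.items())

    def formula(self) -> str:
        """Hill-ordered formula string (C, H, then alphabetical)."""
        order = sorted(
            self._counts,
            key=lambda s: (s != "C", s != "H", s),
        )
        return "".join(
            f"{s}{self._counts[s]}" if self._counts[s] != 1 else s for s in order
        )


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return counts


def composition_mass(comp: ElementalComposition | Mapping[str, int] | str) -> float:
    """Monoisotopic mass (u) of an elemental composition.

    Accepts an :class:`ElementalComposition`, a plain mapping, or a formula
    string. Raises ``KeyError`` naming any unknown element symbol.
    """
    if not isinstance(comp, ElementalComposition):
        comp = ElementalComposition(comp)
    return comp.mass


#: H2O — released on peptide-bond formation, added back for the intact peptide.
WATER = ElementalComposition("H2O")

# Residue (not free amino acid) compositions for the 20 canonical residues.
RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = {
    "G": ElementalComposition("C2H3NO"),
    "A": ElementalComposition("C3H5NO"),
    "S": ElementalComposition("C3H5NO2"),
    "P": ElementalComposition("C5H7NO"),
    "V": ElementalComposition("C5H9NO"),
    "T": ElementalComposition("C4H7NO2"),
    "C": ElementalComposition("C3H5NOS"),
    "L": ElementalComposition("C6H11NO"),
    "I": ElementalComposition("C6H11NO"),
    "N": ElementalComposition("C4H6N2O2"),
    "D": ElementalComposition("C4H5NO3"),
    "Q": ElementalComposition("C5H8N2O2"),
    "K": ElementalComposition("C6H12N2O"),
    "E": ElementalComposition("C5H7NO3"),
    "M": ElementalComposition("C5H9NOS"),
    "H": ElementalComposition("C6H7N3O"),
    "F": ElementalComposition("C9H9NO"),
    "R": ElementalComposition("C6H12N4O"),
    "Y": ElementalComposition("C9H9NO2"),
    "W": ElementalComposition("C11H10N2O"),
}

RESIDUE_MASSES: dict[str, float] = {
    aa: comp.mass for aa, comp in RESIDUE_COMPOSITIONS.items()
}


@dataclass(frozen=True)
class NeutralLoss:
    """One diagnostic neutral-loss channel of a modification."""

    label: str
    composition: ElementalComposition

    @property
    def mass(self) -> float:
        return self.composition.mass


@dataclass(frozen=True)
class ModificationSpec:
    """A post-translational modification as a net elemental adduct.

    Parameters
    ----------
    name
        Registry name, e.g. ``"2HG"``.
    target_residues
        One-letter codes of residues the modification can occupy.
    delta_composition
        Net elemental change of the modified residue.
    neutral_losses
        Diagnostic neutral-loss channels observed in MS/MS, if any.
    isotope_variant
        Optional composition of the stable-isotope-labelled form of the
        adduct (e.g. d4: four H replaced by four D).
    """

    name: str
    target_residues: frozenset[str]
    delta_composition: ElementalComposition
    neutral_losses: tuple[NeutralLoss, ...] = ()
    isotope_variant: ElementalComposition | None = None

    @property
    def delta_mass(self) -> float:
        """Monoisotopic mass shift of the modification, u."""
        return self.delta_composition.mass

    @property
    def isotope_shift(self) -> float:
        """Heavy-minus-light mass difference, u (0 if no isotope variant)."""
        if self.isotope_variant is None:
            return 0.0
        return self.isotope_variant.mass - self.delta_composition.mass

    def heavy(self) -> "ModificationSpec":
        """The stable-isotope-labelled form of this modification."""
        if self.isotope_variant is None:
            raise ValueError(f"modification {self.name!r} has no isotope variant")
        return ModificationSpec(
            name=f"{self.name}:heavy",
            target_residues=self.target_residues,
            delta_composition=self.isotope_variant,
            neutral_losses=tuple(
                NeutralLoss(nl.label, nl.composition - self.delta_composition
                            + self.isotope_variant)
                for nl in self.neutral_losses
            ),
            isotope_variant=None,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "targets": "".join(sorted(self.target_residues)),
            "formula": self.delta_composition.formula(),
            "neutral_losses": [
                {"label": nl.label, "formula": nl.composition.formula()}
                for nl in self.neutral_losses
            ],
        }
        if self.isotope_variant is not None:
            d["isotope_variant"] = self.isotope_variant.formula()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModificationSpec":
        return cls(
            name=d["name"],
            target_residues=frozenset(d["targets"]),
            delta_composition=ElementalComposition(d["formula"]),
            neutral_losses=tuple(
                NeutralLoss(nl["label"], ElementalComposition(nl["formula"]))
                for nl in d.get("neutral_losses", ())
            ),
            isotope_variant=(
                ElementalComposition(d["isotope_variant"])
                if d.get("isotope_variant")
                else None
            ),
        )


#: The 2HG ester adduct on Ser/Thr/Tyr hydroxyls. Channel A loses the net
#: adduct C5H6O4 (130.0266 Da, restores the unmodified backbone); channel B
#: loses the full acid C5H8O5 (148.0372 Da, leaves a dehydro residue).
#: The d4 variant carries four deuteriums on the glutarate carbon skeleton.
MOD_2HG = ModificationSpec(
    name="2HG",
    target_residues=frozenset("STY"),
    delta_composition=ElementalComposition("C5H6O4"),
    neutral_losses=(
        NeutralLoss("A", ElementalComposition("C5H6O4")),
        NeutralLoss("B", ElementalComposition("C5H8O5")),
    ),
    isotope_variant=ElementalComposition("C5H2D4O4"),
)

#: Carbamidomethylation of cysteine from chloroacetamide alkylation; applied
#: as a fixed modification (default on) wherever peptide masses are computed.
CARBAMIDOMETHYL = ModificationSpec(
    name="Carbamidomethyl",
    target_residues=frozenset("C"),
    delta_composition=ElementalComposition("C2H3NO"),
)


def builtin_modifications() -> dict[str, ModificationSpec]:
    """The shipped modification registry, keyed by name."""
    return {m.name: m for m in (MOD_2HG, CARBAMIDOMETHYL)}


def peptide_neutral_mass(
    sequence: str,
    mods: Iterable[tuple[int, ModificationSpec]] = (),
    *,
    carbamidomethyl_cys: bool = True,
) -> float:
    """Neutral monoisotopic mass (u) of a peptide with site-indexed mods.

    ``mods`` is an iterable of ``(site_index, ModificationSpec)`` with 0-based
    indices into ``sequence``. Cysteines are carbamidomethylated as a fixed
    modification unless ``carbamidomethyl_cys`` is False.

    Raises
    ------
    ValueError
        On unknown residues, out-of-range or duplicate mod sites, or a mod
        placed on a residue outside its ``target_residues``.
    """
    mass = WATER.mass
    for aa in sequence:
        try:
            mass += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in sequence") from None
    if carbamidomethyl_cys:
        mass += sequence.count("C") * CARBAMIDOMETHYL.delta_mass
    seen: set[int] = set()
    for site, spec in mods:
        if not 0 <= site < len(sequence):
            raise ValueError(f"mod site {site} outside peptide of length {len(sequence)}")
        if site in seen:
            raise ValueError(f"duplicate modification at site {site}")
        seen.add(site)
        if sequence[site] not in spec.target_residues:
            raise ValueError(
                f"modification {spec.name!r} not allowed on residue "
                f"{sequence[site]!r} at site {site}"
            )
        mass += spec.delta_mass
    return mass


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of an ion of the given neutral mass and positive charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def neutral_mass_from_mz(mz_value: float, charge: int) -> float:
    """Invert :func:`mz`: neutral mass from an observed m/z and charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz_value * charge - charge * PROTON_MASS
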