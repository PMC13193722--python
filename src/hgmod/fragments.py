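"""Theoretical b/y fragment ions for modified peptides.

Generates singly and doubly protonated b and y ladders, neutral-loss
variants for modification-bearing ions (channel A: −130.0266, restores the
unmodified backbone; channel B: −148.0372, leaves a dehydro residue), and
d4-heavy ladders for isotope-pair validation. Only b/y series are produced:
the annotated ester-modification spectra this package targets show b/y ions
plus diagnostic losses and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .chem import (
    CARBAMIDOMETHYL,
    MOD_2HG,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER,
    ModificationSpec,
    mz as _mz,
    peptide_neutral_mass,
)
from .digest import Peptide

__all__ = [
    "FragmentIon",
    "theoretical_fragments",
    "precursor_descriptor",
    "precursor_loss_mz",
    "default_fragment_charges",
]

LOSS_NONE = "none"


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment ion.

    ``loss_label`` is ``"none"`` or a neutral-loss channel label; losses are
    only emitted for ions whose residue span contains a modified site
    (``contains_mod``). ``heavy`` marks the d4-isotopologue ladder; it changes
    the m/z only of mod-containing ions.
    """

    series: str  # "b" or "y"
    index: int  # 1..n-1
    charge: int
    mz: float
    contains_mod: bool
    loss_label: str = LOSS_NONE
    heavy: bool = False

    @property
    def key(self) -> tuple:
        """Identity of the ion independent of isotope labelling and mass."""
        return (self.series, self.index, self.charge, self.loss_label)

    def __str__(self) -> str:
        s = f"{self.series}{self.index}"
        if self.charge > 1:
            s += f"^{self.charge}+"
        if self.loss_label != LOSS_NONE:
            s += f"-{self.loss_label}"
        return s


def default_fragment_charges(precursor_charge: int) -> tuple[int, ...]:
    """Fragment charges to generate: {1, 2} for multiply charged precursors."""
    return (1, 2) if precursor_charge >= 2 else (1,)


def _mod_spec(peptide: Peptide, site: int, heavy: bool) -> ModificationSpec:
    for s, spec in peptide.mods:
        if s == site:
            return spec.heavy() if heavy and spec.isotope_variant else spec
    raise KeyError(site)


def theoretical_fragments(
    peptide: Peptide,
    charges: Iterable[int] | None = None,
    include_losses: bool = True,
    heavy: bool = False,
    *,
    carbamidomethyl_cys: bool = True,
) -> list[FragmentIon]:
    """All theoretical b/y ions (plus loss variants) of a peptide.

    For every cut position i in 1..n−1 and each charge, a b_i and a y_{n−i}
    ion is emitted. Ions whose span covers a modified site additionally get
    one variant per neutral-loss channel of the modification when
    ``include_losses`` is true. ``heavy`` swaps each modification for its
    stable-isotope variant, shifting only mod-containing ions.
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("peptide must have length >= 2")
    charges = tuple(charges) if charges is not None else (1,)
    if not charges:
        raise ValueError("charge set must be non-empty")

    mod_sites = set(peptide.mod_sites)
    # cumulative residue masses with fixed + variable mods applied per site
    site_mass = []
    for i, aa in enumerate(seq):
        m = RESIDUE_MASSES[aa]
        if carbamidomethyl_cys and aa == "C":
            m += CARBAMIDOMETHYL.delta_mass
        if i in mod_sites:
            spec = _mod_spec(peptide, i, heavy)
            m += spec.delta_mass
        site_mass.append(m)

    # neutral-loss channels per site (labels shared across sites for 2HG)
    losses_at = {
        i: [
            (nl.label, nl.mass)
            for nl in _mod_spec(peptide, i, heavy).neutral_losses
        ]
        for i in mod_sites
    }

    ions: list[FragmentIon] = []

    def emit(series: str, index: int, neutral: float, span: range):
        contains = any(i in mod_sites for i in span)
        for z in charges:
            ions.append(
                FragmentIon(series, index, z, _mz(neutral, z), contains,
                            LOSS_NONE, heavy)
            )
            if include_losses and contains:
                for i in span:
                    if i not in mod_sites:
                        continue
                    for label, lmass in losses_at[i]:
                        reduced = neutral - lmass
                        if reduced <= 0:
                            continue
                        ions.append(
                            FragmentIon(series, index, z, _mz(reduced, z),
                                        True, label, heavy)
                        )

    prefix = 0.0
    for i in range(1, n):
        prefix += site_mass[i - 1]
        emit("b", i, prefix, range(0, i))
    suffix = WATER.mass
    for i in range(1, n):
        suffix += site_mass[n - i]
        emit("y", i, suffix, range(n - i, n))
    return ions


def precursor_descriptor(
    peptide: Peptide,
    charge: int,
    heavy: bool = False,
    *,
    carbamidomethyl_cys: bool = True,
) -> tuple[float, int]:
    """(m/z, charge) of the intact peptide precursor ion."""
    mods = peptide.mods
    if heavy:
        mods = tuple(
            (s, spec.heavy() if spec.isotope_variant else spec) for s, spec in mods
        )
    neutral = peptide_neutral_mass(
        peptide.sequence, mods, carbamidomethyl_cys=carbamidomethyl_cys
    )
    return _mz(neutral, charge), charge


def precursor_loss_mz(
    peptide: Peptide,
    charge: int,
    loss_mass: float,
    heavy: bool = False,
) -> float:
    """m/z of the precursor after losing a neutral of ``loss_mass`` u.

    Precursor-level neutral losses are treated as pseudo-fragments so the
    diagnostics scoring handles precursor and fragment losses uniformly.
    """
    pre_mz, z = precursor_descriptor(peptide, charge, heavy)
    neutral = pre_mz * z - z * PROTON_MASS
    return _mz(neutral - loss_mass, z)
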