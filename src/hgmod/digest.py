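"""In silico proteolysis: trypsin, GluC, and sequential trypsin→GluC.

Cleavage follows simple positional rules: an enzyme cuts C-terminal to the
residues in ``cleave_after`` unless the next residue is in
``suppress_before`` (the Keil rule for trypsin: no cleavage before proline).
GluC specificity depends on buffer — Glu only in bicarbonate, Glu and Asp in
phosphate; the sequential trypsin→GluC protocol adds phosphate buffer before
GluC, so the phosphate rule is the default second stage.

Also provided is the re-digest loss analysis used to explain why modified
tryptic peptides can vanish after a second protease: the fragment carrying
the modification may become too short to detect or lose all basic residues
(K/R/H), collapsing its positive charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .chem import ModificationSpec

__all__ = [
    "ProteaseRule",
    "Peptide",
    "RedigestReport",
    "TRYPSIN",
    "TRYPSIN_NO_KEIL",
    "GLUC_BICARBONATE",
    "GLUC_PHOSPHATE",
    "cleavage_sites",
    "cleave",
    "sequential_digest",
    "predict_redigest_loss",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Positional cleavage specificity of a protease."""

    name: str
    cleave_after: frozenset[str]
    suppress_before: frozenset[str] = frozenset()


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
TRYPSIN_NO_KEIL = ProteaseRule("trypsin/no-keil", frozenset("KR"))
GLUC_BICARBONATE = ProteaseRule("gluc-bicarbonate", frozenset("E"))
GLUC_PHOSPHATE = ProteaseRule("gluc-phosphate", frozenset("ED"))


@dataclass(frozen=True)
class Peptide:
    """A digested peptide with provenance on its parent protein.

    Coordinates are 0-based, half-open on the parent protein; modification
    ``site`` indices are 0-based within the peptide.
    """

    sequence: str
    protein_id: str = ""
    start: int = 0
    end: int | None = None
    missed_cleavages: int = 0
    mods: tuple[tuple[int, ModificationSpec], ...] = ()

    def __post_init__(self):
        if self.end is None:
            object.__setattr__(self, "end", self.start + len(self.sequence))
        if self.end - self.start != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")
        for site, spec in self.mods:
            if not 0 <= site < len(self.sequence):
                raise ValueError(f"mod site {site} outside peptide")
            if self.sequence[site] not in spec.target_residues:
                raise ValueError(
                    f"{spec.name} not allowed on {self.sequence[site]!r} at {site}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_mods(self, mods) -> "Peptide":
        return replace(self, mods=tuple(mods))

    @property
    def mod_sites(self) -> tuple[int, ...]:
        return tuple(site for site, _ in self.mods)

    def site_label(self, site: int) -> str:
        """1-based protein-coordinate site label, e.g. ``S719``."""
        return f"{self.sequence[site]}{self.start + site + 1}"


def cleavage_sites(sequence: str, rule: ProteaseRule) -> list[int]:
    """Cut positions: boundary index i+1 for each residue i the rule cuts after.

    A cut at position p splits the sequence into ``[:p]`` and ``[p:]``; the
    C-terminal boundary ``len(sequence)`` is never included.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in rule.cleave_after and sequence[i + 1] not in rule.suppress_before:
            sites.append(i + 1)
    return sites


def cleave(
    sequence: str,
    rule: ProteaseRule,
    max_missed: int = 0,
    protein_id: str = "",
) -> list[Peptide]:
    """Digest a protein, emitting peptides with up to ``max_missed`` missed cuts.

    Fully cleaved peptides tile the protein; additionally every run of at most
    ``max_missed + 1`` adjacent fragments is emitted. Output order is by start
    coordinate, then length.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not sequence:
        return []
    bounds = [0] + cleavage_sites(sequence, rule) + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            peptides.append(
                Peptide(
                    sequence=sequence[start:end],
                    protein_id=protein_id,
                    start=start,
                    end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, len(p)))
    return peptides


def sequential_digest(
    sequence: str,
    rules: Sequence[ProteaseRule],
    max_missed: Sequence[int] | int = 0,
    protein_id: str = "",
) -> list[Peptide]:
    """Digest with an ordered series of proteases (e.g. trypsin then GluC).

    Each stage re-cleaves every product of the previous stage; coordinates
    are composed back to the protein frame. Missed cleavages are counted
    against the union of all rules' sites.
    """
    if not rules:
        raise ValueError("at least one protease rule required")
    if isinstance(max_missed, int):
        max_missed = [max_missed] * len(rules)
    if len(max_missed) != len(rules):
        raise ValueError("one max_missed per rule required")

    pieces = [(0, sequence)]  # (protein-frame start, subsequence)
    for rule, mm in zip(rules, max_missed):
        nxt = []
        for off, sub in pieces:
            for pep in cleave(sub, rule, mm):
                nxt.append((off + pep.start, pep.sequence))
        pieces = nxt

    all_sites: set[int] = set()
    for rule in rules:
        all_sites.update(cleavage_sites(sequence, rule))
    peptides = [
        Peptide(
            sequence=sub,
            protein_id=protein_id,
            start=off,
            end=off + len(sub),
            missed_cleavages=sum(1 for s in all_sites if off < s < off + len(sub)),
        )
        for off, sub in pieces
    ]
    peptides.sort(key=lambda p: (p.start, len(p)))
    # re-digestion of overlapping missed-cleavage products can emit duplicates
    seen, unique = set(), []
    for p in peptides:
        key = (p.start, p.end)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


@dataclass(frozen=True)
class RedigestReport:
    """Fate of a modified peptide under a second protease."""

    fragments: tuple[Peptide, ...]
    mod_fragment: Peptide
    lost_short: bool
    lost_basic: bool


def predict_redigest_loss(
    peptide: Peptide,
    rule: ProteaseRule = GLUC_PHOSPHATE,
    min_length: int = 7,
) -> RedigestReport:
    """Re-cleave a modified peptide and ask whether the modified fragment
    would escape detection.

    ``lost_short`` — the modification-bearing fragment is shorter than
    ``min_length`` residues; ``lost_basic`` — it contains no K/R/H, so it
    carries no basic side chain for protonation. Either condition explains
    the absence of the site from a sequential-digest dataset.
    """
    if not peptide.mods:
        raise ValueError("peptide carries no modification")
    fragments = cleave(peptide.sequence, rule, 0, protein_id=peptide.protein_id)
    placed = []
    for frag in fragments:
        frag_mods = tuple(
            (site - frag.start, spec)
            for site, spec in peptide.mods
            if frag.start <= site < frag.end
        )
        placed.append(frag.with_mods(frag_mods) if frag_mods else frag)
    mod_frags = [f for f in placed if f.mods]
    # analyse the fragment carrying the first modification
    mod_fragment = mod_frags[0]
    return RedigestReport(
        fragments=tuple(placed),
        mod_fragment=mod_fragment,
        lost_short=len(mod_fragment) < min_length,
        lost_basic=not any(aa in "KRH" for aa in mod_fragment.sequence),
    )
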