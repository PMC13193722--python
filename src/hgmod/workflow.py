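"""Stage orchestration: candidate generation, batch search, and reports.

These functions glue the pipeline stages together for the CLI and for
end-to-end runs: enumerate modified candidate peptides from a digest, search
a spectrum collection against them (match → localize → neutral-loss
diagnostics), and summarize recovery against a ground-truth ledger when one
is available (synthetic runs only).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .chem import MOD_2HG, ModificationSpec, peptide_neutral_mass
from .digest import Peptide
from .quant import AbundanceMatrix, chirality_call, tic_normalize
from .spectra import (
    PSM,
    Spectrum,
    detect_neutral_loss,
    localize_site,
    match_spectrum,
    nl_frequency_summary,
)

__all__ = [
    "build_candidates",
    "search_spectra",
    "quantify_chirality",
    "recovery_report",
    "nl_summary_frame",
]


def build_candidates(
    peptides: Sequence[Peptide],
    mod: ModificationSpec = MOD_2HG,
    include_unmodified: bool = True,
) -> list[Peptide]:
    """Expand a digest into search candidates with one variable modification.

    Each peptide contributes its unmodified form plus one singly modified
    variant per target residue (the usual variable-modification expansion at
    one site per peptide).
    """
    out: list[Peptide] = []
    for pep in peptides:
        if include_unmodified:
            out.append(pep)
        for i, aa in enumerate(pep.sequence):
            if aa in mod.target_residues:
                out.append(pep.with_mods([(i, mod)]))
    return out


def search_spectra(
    spectra: Sequence[Spectrum],
    candidates: Sequence[Peptide],
    tol_ppm: float = 10.0,
    precursor_tol_ppm: float = 20.0,
    heavy: bool = False,
    localize: bool = True,
    detect_losses: bool = True,
) -> list[PSM]:
    """Match every spectrum against precursor-mass-filtered candidates.

    Candidates are indexed by neutral mass once, so each spectrum only scores
    the mass-compatible subset. Matched modified PSMs are site-localized and
    annotated with neutral-loss flags. Spectra with no candidate in the
    precursor window are dropped (the flagged-empty case).
    """
    def neutral(p: Peptide) -> float:
        mods = p.mods
        if heavy:
            mods = tuple((s, m.heavy() if m.isotope_variant else m) for s, m in mods)
        return peptide_neutral_mass(p.sequence, mods)

    indexed = sorted(((neutral(p), p) for p in candidates), key=lambda t: t[0])
    masses = [m for m, _ in indexed]

    psms: list[PSM] = []
    for spectrum in spectra:
        target = spectrum.precursor_neutral_mass
        tol = target * precursor_tol_ppm * 1e-6
        lo = bisect.bisect_left(masses, target - tol)
        hi = bisect.bisect_right(masses, target + tol)
        window = [p for _, p in indexed[lo:hi]]
        best, _ = match_spectrum(
            spectrum, window, tol_ppm=tol_ppm,
            precursor_tol_ppm=precursor_tol_ppm, heavy=heavy,
        )
        if best is None:
            continue
        if best.peptide.mods:
            if localize and len(best.peptide.mods) == 1:
                localize_site(best, tol_ppm=tol_ppm)
            if detect_losses:
                detect_neutral_loss(best, tol_ppm=tol_ppm)
        psms.append(best)
    return psms


def quantify_chirality(
    matrix: AbundanceMatrix,
    normalize: bool = True,
    **call_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TIC-normalize then run the dose-response chirality assignment."""
    if normalize:
        matrix = tic_normalize(matrix)
    return chirality_call(matrix, **call_kwargs)


def recovery_report(calls: pd.DataFrame, ledger: pd.DataFrame) -> dict[str, float]:
    """Compare chirality calls against a synthetic ground-truth ledger.

    Reports, per planted enantiomer, the fraction recovered with the correct
    call and the cross-assignment rate (planted D called L or vice versa).
    Only meaningful for synthetic data; real runs have no ledger.
    """
    merged = ledger.set_index("peptide_id").join(calls, how="inner")
    out: dict[str, float] = {"n_planted": float(len(merged))}
    for enant in ("D", "L"):
        sub = merged[merged["enantiomer"] == enant]
        if len(sub) == 0:
            continue
        other = "L" if enant == "D" else "D"
        out[f"{enant}_recovery"] = float((sub["call"] == enant).mean())
        out[f"{enant}_cross_assignment"] = float((sub["call"] == other).mean())
    shared = merged[merged["enantiomer"] == "shared"]
    if len(shared):
        out["shared_recovery"] = float((shared["call"] == "shared").mean())
    return out


def nl_summary_frame(psms: Sequence[PSM]) -> pd.DataFrame:
    """Neutral-loss bin counts as a tidy DataFrame (channel × bin)."""
    counts = nl_frequency_summary([p for p in psms if p.nl_flags])
    rows = [
        {"channel": channel, "bin": b, "count": n}
        for channel, bins in sorted(counts.items())
        for b, n in bins.items()
    ]
    return pd.DataFrame(rows, columns=["channel", "bin", "count"])
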