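"""Seeded synthetic data emulating a chiral metabolite-feeding PTM study.

Generates, deterministically per seed: random proteomes (FASTA-ready),
2HG-modified peptides with a ground-truth ledger, MS/MS spectra with b/y
ladders, diagnostic neutral-loss peaks and spurious noise (plus d4-heavy
duplicates), and 3-replicate dose-gradient abundance matrices whose planted
peptides respond to exactly one enantiomer series.

Default study conditions mirror the emulated design: dose gradient
0/5/10/20 (arbitrary units mirroring mM), 3 biological replicates,
lognormal replicate noise with CV 0.15, Ser>Thr>Tyr site usage (0.6:0.3:0.1),
planted top-dose fold changes uniform on [2, 4], a linear-in-log-dose
response shape, and a positive retention-time offset for modified peptides.

The ground-truth ledger is only consumed by test harnesses and recovery
reports — analysis stages never read it.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import MOD_2HG, ModificationSpec, peptide_neutral_mass, mz as _mz
from .digest import GLUC_PHOSPHATE, TRYPSIN, Peptide, sequential_digest
from .fragments import precursor_loss_mz, theoretical_fragments
from .quant import AbundanceMatrix
from .spectra import Spectrum

__all__ = [
    "SimulationConfig",
    "generate_proteome",
    "digest_proteome",
    "plant_modifications",
    "simulate_abundances",
    "simulate_spectra",
    "dose_response_factor",
    "predict_rt",
]

# Kyte–Doolittle hydropathy, used as a crude reversed-phase retention surrogate.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Background residue frequencies: roughly proteome-like but guaranteeing
# cleavage sites (K/R, E/D) and modifiable hydroxyls (S/T/Y).
_BACKGROUND = {
    "A": 0.07, "C": 0.015, "D": 0.05, "E": 0.06, "F": 0.035, "G": 0.065,
    "H": 0.022, "I": 0.05, "K": 0.06, "L": 0.09, "M": 0.02, "N": 0.04,
    "P": 0.045, "Q": 0.039, "R": 0.05, "S": 0.08, "T": 0.055, "V": 0.06,
    "W": 0.011, "Y": 0.038,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 0
    n_proteins: int = 20
    protein_length: tuple[int, int] = (150, 400)
    site_residue_weights: tuple[float, float, float] = (0.6, 0.3, 0.1)  # S,T,Y
    fraction_modified: float = 0.25
    enantiomer_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)  # D,L,shared
    dose_levels: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    n_replicates: int = 3
    fc_range: tuple[float, float] = (2.0, 4.0)
    abundance_cv: float = 0.15
    occupancy: float = 0.10
    baseline_log_mean: float = math.log(1e6)
    baseline_log_sd: float = 1.0
    spurious_peak_fraction: float = 0.20
    intensity_jitter_cv: float = 0.20
    nl_probability: tuple[float, float] = (0.9, 0.7)  # channels A, B
    nl_abundance_range: tuple[float, float] = (0.005, 0.20)  # loguniform
    rt_gradient: tuple[float, float] = (2.0, 58.0)  # minutes
    rt_mod_shift: float = 1.5  # minutes, added for 2HG-modified peptides
    rt_noise_sd: float = 0.1
    precursor_charge: int = 2
    peptide_length_range: tuple[int, int] = (7, 30)

    def __post_init__(self):
        for p in (
            self.fraction_modified,
            *self.enantiomer_probs,
            self.spurious_peak_fraction,
            *self.nl_probability,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if any(b <= a for a, b in zip(self.dose_levels, self.dose_levels[1:])):
            raise ValueError("dose levels must be strictly increasing")
        if self.protein_length[0] < 1:
            raise ValueError("protein length must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """A named independent substream, deterministic in the seed."""
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )


def generate_proteome(config: SimulationConfig) -> list[tuple[str, str]]:
    """Random protein records ``(id, sequence)``, deterministic per seed.

    Sequences are drawn from proteome-like residue frequencies; each protein
    is checked to contain K/R, E/D and S/T/Y so digestion and modification
    are always exercised, and redrawn otherwise.
    """
    rng = config.rng("proteome")
    aas = np.array(list(_BACKGROUND))
    probs = np.array(list(_BACKGROUND.values()))
    probs = probs / probs.sum()
    records = []
    for i in range(config.n_proteins):
        lo, hi = config.protein_length
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(aas, size=length, p=probs))
            if (
                any(aa in seq for aa in "KR")
                and any(aa in seq for aa in "ED")
                and any(aa in seq for aa in "STY")
            ):
                break
        records.append((f"SYN{i + 1:04d}", seq))
    return records


def digest_proteome(
    records: Sequence[tuple[str, str]],
    config: SimulationConfig,
) -> list[Peptide]:
    """Sequential trypsin→GluC digest of the synthetic proteome, keeping
    fully cleaved peptides inside the configured length range."""
    lo, hi = config.peptide_length_range
    peptides = []
    for pid, seq in records:
        for pep in sequential_digest(seq, [TRYPSIN, GLUC_PHOSPHATE], 0, protein_id=pid):
            if lo <= len(pep) <= hi:
                peptides.append(pep)
    return peptides


def plant_modifications(
    peptides: Sequence[Peptide],
    config: SimulationConfig,
    mod: ModificationSpec = MOD_2HG,
) -> tuple[list[Peptide], pd.DataFrame]:
    """Plant one modification per selected peptide and emit the ground truth.

    A ``fraction_modified`` subset of eligible peptides (those containing a
    target residue) is modified at a site sampled by the configured S:T:Y
    weights; each gets an enantiomer label (D/L/shared) and a true top-dose
    fold change drawn uniformly from ``fc_range``. The ledger is a DataFrame
    with columns peptide_id, protein_id, sequence, site (0-based, within
    peptide), residue, site_label, enantiomer, true_fc.
    """
    rng = config.rng("plant")
    weights = dict(zip("STY", config.site_residue_weights))
    eligible = [p for p in peptides if any(aa in weights for aa in p.sequence)]
    n_mod = int(round(config.fraction_modified * len(eligible)))

    # Sample residue class by weight globally, then a peptide offering that
    # class, so the marginal S:T:Y usage matches the configured weights even
    # though residue availability differs between classes.
    by_class: dict[str, list[int]] = {aa: [] for aa in weights}
    for idx, pep in enumerate(eligible):
        for aa in weights:
            if aa in pep.sequence:
                by_class[aa].append(idx)
    for lst in by_class.values():
        rng.shuffle(lst)
    taken: set[int] = set()
    chosen: list[tuple[Peptide, str]] = []
    classes = list(weights)
    while len(chosen) < n_mod:
        avail = [c for c in classes if any(i not in taken for i in by_class[c])]
        if not avail:
            break
        w = np.array([weights[c] for c in avail], dtype=float)
        cls = avail[int(rng.choice(len(avail), p=w / w.sum()))]
        while by_class[cls] and by_class[cls][-1] in taken:
            by_class[cls].pop()
        idx = by_class[cls].pop()
        taken.add(idx)
        chosen.append((eligible[idx], cls))

    modified: list[Peptide] = []
    rows = []
    enant_labels = ("D", "L", "shared")
    for pep, cls in chosen:
        sites = [i for i, aa in enumerate(pep.sequence) if aa == cls]
        site = int(sites[int(rng.integers(len(sites)))])
        enantiomer = enant_labels[rng.choice(3, p=np.array(config.enantiomer_probs))]
        true_fc = float(rng.uniform(*config.fc_range))
        mp = pep.with_mods([(site, mod)])
        modified.append(mp)
        rows.append(
            {
                "peptide_id": f"{pep.sequence}/{mp.site_label(site)}",
                "protein_id": pep.protein_id,
                "sequence": pep.sequence,
                "site": site,
                "residue": pep.sequence[site],
                "site_label": mp.site_label(site),
                "enantiomer": enantiomer,
                "true_fc": true_fc,
            }
        )
    ledger = pd.DataFrame(
        rows,
        columns=[
            "peptide_id", "protein_id", "sequence", "site", "residue",
            "site_label", "enantiomer", "true_fc",
        ],
    )
    return modified, ledger


def dose_response_factor(dose: float, top_dose: float, true_fc: float) -> float:
    """Abundance multiplier at a dose: linear in log(1+dose) from 1 (dose 0)
    to ``true_fc`` at the top dose."""
    if dose <= 0:
        return 1.0
    frac = math.log1p(dose) / math.log1p(top_dose)
    return float(true_fc**frac)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    # mean-one multiplicative noise
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_abundances(
    ledger: pd.DataFrame,
    config: SimulationConfig,
    background: Sequence[Peptide] | None = None,
) -> AbundanceMatrix:
    """Dose-gradient abundance matrix with planted enantiomer responses.

    Samples: vehicle (dose 0) plus every nonzero dose of the D2HG and L2HG
    series, ``n_replicates`` each. Each ledger peptide contributes a modified
    row (responding in its enantiomer series, both series when "shared") and
    an unmodified counterpart row (factor 1 everywhere) for occupancy and
    retention-time pairing. ``background`` peptides (e.g. the rest of the
    digest) contribute non-responding rows, reproducing the real situation in
    which the bulk proteome dominates each sample's total ion current and
    keeps TIC normalization nearly neutral. Baselines are lognormal;
    replicate noise is lognormal with the configured CV.
    """
    rng = config.rng("abundance")
    doses = [d for d in config.dose_levels if d > 0]
    top = max(config.dose_levels)
    cols, meta = [], []
    for r in range(1, config.n_replicates + 1):
        cols.append(f"vehicle_r{r}")
        meta.append(("vehicle_0", "vehicle", 0.0, r))
    for series in ("D2HG", "L2HG"):
        for d in doses:
            for r in range(1, config.n_replicates + 1):
                cols.append(f"{series}_{d:g}_r{r}")
                meta.append((f"{series}_{d:g}", series, d, r))
    samples = pd.DataFrame(
        meta, columns=["condition", "series", "dose", "replicate"], index=cols
    )

    index, values = [], []
    for _, row in ledger.iterrows():
        base_unmod = float(
            np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd))
        )
        occ = config.occupancy
        base_mod = base_unmod * occ / (1.0 - occ)
        responding = (
            ("D2HG", "L2HG") if row["enantiomer"] == "shared" else
            ("D2HG",) if row["enantiomer"] == "D" else ("L2HG",)
        )
        mod_vals, unmod_vals = [], []
        for cond, series, dose, _ in meta:
            factor = (
                dose_response_factor(dose, top, row["true_fc"])
                if series in responding
                else 1.0
            )
            mod_vals.append(base_mod * factor)
            unmod_vals.append(base_unmod)
        noise_m = _lognormal_noise(rng, config.abundance_cv, len(cols))
        noise_u = _lognormal_noise(rng, config.abundance_cv, len(cols))
        index.append(row["peptide_id"])
        values.append(np.asarray(mod_vals) * noise_m)
        index.append(f"{row['sequence']}/unmod")
        values.append(np.asarray(unmod_vals) * noise_u)

    planted_seqs = set(ledger["sequence"])
    for pep in background or ():
        if pep.sequence in planted_seqs:
            continue
        base = float(
            np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd))
        )
        noise = _lognormal_noise(rng, config.abundance_cv, len(cols))
        index.append(f"{pep.sequence}/bg")
        values.append(base * noise)

    data = pd.DataFrame(values, index=index, columns=cols)
    return AbundanceMatrix(data, samples)


def predict_rt(
    peptide: Peptide, config: SimulationConfig, rng: np.random.Generator | None = None
) -> float:
    """Synthetic retention time: hydropathy-scaled position on the gradient
    plus a fixed positive shift for 2HG-modified peptides."""
    kd = sum(_KD[aa] for aa in peptide.sequence) / len(peptide.sequence)
    frac = (kd + 4.5) / 9.0  # map KD average [-4.5, 4.5] onto [0, 1]
    lo, hi = config.rt_gradient
    rt = lo + frac * (hi - lo)
    if peptide.mods:
        rt += config.rt_mod_shift
    if rng is not None and config.rt_noise_sd > 0:
        rt += float(rng.normal(0.0, config.rt_noise_sd))
    return rt


def simulate_spectra(
    peptides: Sequence[Peptide],
    config: SimulationConfig,
    heavy: bool = False,
    include_unmodified_counterparts: bool = False,
) -> list[Spectrum]:
    """MS/MS spectra for (modified) peptides, deterministic per seed.

    Each spectrum holds the full singly/doubly charged b/y ladder at unit
    base intensity with lognormal jitter, diagnostic neutral-loss peaks per
    channel (precursor-level and fragment-level) emitted with the configured
    probability at a log-uniform relative abundance, and uniform spurious
    peaks at ``spurious_peak_fraction`` of the real peak count. ``heavy``
    applies the d4 isotopologue throughout.
    """
    rng = config.rng("spectra-heavy" if heavy else "spectra")
    spectra: list[Spectrum] = []
    todo: list[Peptide] = []
    for pep in peptides:
        todo.append(pep)
        if include_unmodified_counterparts and pep.mods:
            todo.append(pep.with_mods([]))

    for i, pep in enumerate(todo):
        z = config.precursor_charge
        neutral_mods = pep.mods
        if heavy:
            neutral_mods = tuple(
                (s, m.heavy() if m.isotope_variant else m) for s, m in neutral_mods
            )
        neutral = peptide_neutral_mass(pep.sequence, neutral_mods)
        pre_mz = _mz(neutral, z)
        base_int = 100.0

        mzs, ints = [], []
        ladder = theoretical_fragments(
            pep, charges=(1, 2) if z >= 2 else (1,), include_losses=False, heavy=heavy
        )
        jitter = _lognormal_noise(rng, config.intensity_jitter_cv, len(ladder))
        for ion, j in zip(ladder, jitter):
            mzs.append(ion.mz)
            ints.append(base_int * j)

        if pep.mods:
            spec = pep.mods[0][1]
            losses = (spec.heavy() if heavy and spec.isotope_variant else spec).neutral_losses
            loss_ions = theoretical_fragments(
                pep, charges=(1, 2) if z >= 2 else (1,),
                include_losses=True, heavy=heavy,
            )
            for nl, p_emit in zip(losses, config.nl_probability):
                if rng.uniform() >= p_emit:
                    continue
                lo, hi = config.nl_abundance_range
                rel = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
                # precursor-level loss
                mzs.append(precursor_loss_mz(pep, z, nl.mass, heavy=heavy))
                ints.append(base_int * rel)
                # fragment-level loss variants
                for ion in loss_ions:
                    if ion.loss_label == nl.label:
                        mzs.append(ion.mz)
                        ints.append(
                            base_int
                            * rel
                            * float(_lognormal_noise(rng, config.intensity_jitter_cv, ()))
                        )

        n_spurious = int(round(config.spurious_peak_fraction * len(mzs)))
        if n_spurious:
            span_lo, span_hi = 100.0, max(pre_mz * z, 500.0)
            for _ in range(n_spurious):
                mzs.append(float(rng.uniform(span_lo, span_hi)))
                ints.append(float(rng.uniform(0.01, 0.3)) * base_int)

        rt = predict_rt(pep, config, rng if not heavy else None)
        if heavy:
            # co-elution with the light form up to small jitter
            rt = predict_rt(pep, config) + float(rng.normal(0.0, config.rt_noise_sd))
        label = "heavy" if heavy else "light"
        mod_tag = (
            "+".join(pep.site_label(s) for s, _ in pep.mods) if pep.mods else "unmod"
        )
        spectra.append(
            Spectrum.from_peaks(
                id=f"syn|{i:05d}|{pep.sequence}|{mod_tag}|{label}",
                precursor_mz=pre_mz,
                precursor_charge=z,
                rt=rt,
                peaks=list(zip(mzs, ints)),
            )
        )
    return spectra
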