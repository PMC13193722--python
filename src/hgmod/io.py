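"""Readers and writers binding the pipeline to standard text formats.

FASTA goes through Biopython, MGF through pyteomics; abundance matrices,
peptide tables, PSM tables and the ground-truth ledger are tab-separated
files readable by pandas. Every table written here starts with a comment
header naming the producing tool version and, when available, a config hash,
so runs remain traceable. All formats round-trip: ``read(write(x)) == x``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from . import __version__
from .chem import builtin_modifications
from .digest import Peptide
from .quant import AbundanceMatrix
from .spectra import PSM, Spectrum

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "write_table",
    "read_table",
    "write_peptide_table",
    "read_peptide_table",
    "write_psm_table",
    "write_abundance_matrix",
    "read_abundance_matrix",
    "config_hash",
]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg_hash: str | None) -> str:
    tag = f" config={cfg_hash}" if cfg_hash else ""
    return f"# hgmod v{__version__}{tag}\n"


# -- FASTA -------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Protein records as ``(id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# -- MGF ---------------------------------------------------------------------

def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.id,
                "pepmass": (s.precursor_mz, None),
                "charge": s.precursor_charge,
                "rtinseconds": round(s.rt * 60.0, 4),
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[Spectrum]:
    spectra = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            else:
                charge = 1
            spectra.append(
                Spectrum(
                    id=str(params.get("title", "")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    rt=float(params.get("rtinseconds", 0.0)) / 60.0,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra


def read_mzml(path) -> list[Spectrum]:
    """Read-only mzML support for MS2 spectra via pyteomics."""
    from pyteomics import mzml as _mzml

    spectra = []
    with _mzml.read(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            precursor = entry["precursorList"]["precursor"][0]
            ion = precursor["selectedIonList"]["selectedIon"][0]
            rt = entry["scanList"]["scan"][0].get("scan start time", 0.0)
            spectra.append(
                Spectrum(
                    id=entry.get("id", ""),
                    precursor_mz=float(ion["selected ion m/z"]),
                    precursor_charge=int(ion.get("charge state", 1)),
                    rt=float(rt),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra


# -- tab-separated tables ----------------------------------------------------

def write_table(df: pd.DataFrame, path, cfg_hash: str | None = None, index=False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(cfg_hash))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_peptide_table(peptides: Sequence[Peptide], path, cfg_hash=None) -> None:
    """Peptides with 1-based coordinates and site labels, e.g. ``S719``."""
    rows = [
        {
            "protein_id": p.protein_id,
            "start_1based": p.start + 1,
            "end_1based": p.end,
            "sequence": p.sequence,
            "missed_cleavages": p.missed_cleavages,
            "mod_sites": ";".join(
                f"{p.site_label(site)}:{spec.name}" for site, spec in p.mods
            ),
        }
        for p in peptides
    ]
    write_table(pd.DataFrame(rows), path, cfg_hash)


def read_peptide_table(path) -> list[Peptide]:
    df = read_table(path)
    registry = builtin_modifications()
    peptides = []
    for _, r in df.iterrows():
        mods = []
        if isinstance(r.get("mod_sites"), str) and r["mod_sites"]:
            for token in r["mod_sites"].split(";"):
                label, name = token.split(":")
                site_1based_protein = int(label[1:])
                site = site_1based_protein - int(r["start_1based"])
                mods.append((site, registry[name]))
        peptides.append(
            Peptide(
                sequence=r["sequence"],
                protein_id=str(r["protein_id"]),
                start=int(r["start_1based"]) - 1,
                end=int(r["end_1based"]),
                missed_cleavages=int(r["missed_cleavages"]),
                mods=tuple(mods),
            )
        )
    return peptides


def write_psm_table(psms: Sequence[PSM], path, cfg_hash=None) -> None:
    rows = []
    for p in psms:
        row = {
            "spectrum_id": p.spectrum_id,
            "sequence": p.peptide.sequence,
            "mod_sites": ";".join(
                p.peptide.site_label(s) for s, _ in p.peptide.mods
            ),
            "match_score": round(p.match_score, 6),
            "matched_ion_count": p.matched_ion_count,
            "heavy": p.heavy,
        }
        if p.localization is not None:
            best, runner, delta = p.localization
            row["best_site"] = p.peptide.site_label(best)
            row["runner_up_site"] = (
                p.peptide.site_label(runner) if runner is not None else ""
            )
            row["localization_delta"] = delta
        for channel, fl in p.nl_flags.items():
            row[f"nl_{channel}_precursor"] = fl.precursor_observed
            row[f"nl_{channel}_fragment"] = fl.fragment_observed
            row[f"nl_{channel}_rel_abundance"] = round(fl.relative_abundance, 6)
        rows.append(row)
    write_table(pd.DataFrame(rows), path, cfg_hash)


def write_abundance_matrix(matrix: AbundanceMatrix, path_prefix, cfg_hash=None) -> None:
    """Write ``<prefix>.tsv`` (areas) and ``<prefix>.samples.tsv`` (design)."""
    prefix = str(path_prefix)
    write_table(
        matrix.data.rename_axis("peptide_id"), f"{prefix}.tsv", cfg_hash, index=True
    )
    write_table(
        matrix.samples.rename_axis("sample"),
        f"{prefix}.samples.tsv",
        cfg_hash,
        index=True,
    )


def read_abundance_matrix(path_prefix) -> AbundanceMatrix:
    prefix = str(path_prefix)
    data = read_table(f"{prefix}.tsv", index_col="peptide_id")
    samples = read_table(f"{prefix}.samples.tsv", index_col="sample")
    data.index.name = None
    samples.index.name = None
    return AbundanceMatrix(data, samples)
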