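import numpy as np
import pytest

from hgmod.chem import MOD_2HG
from hgmod.digest import Peptide
from hgmod.fragments import theoretical_fragments
from hgmod.simulate import SimulationConfig
from hgmod.spectra import Spectrum


@pytest.fixture
def small_config():
    """Small but fully featured synthetic study configuration."""
    return SimulationConfig(seed=7, n_proteins=10, fraction_modified=0.3)


@pytest.fixture
def gsk_modified():
    """3-mer peptide with one 2HG serine, the smallest interesting case."""
    return Peptide("GSK", mods=((1, MOD_2HG),))


def noiseless_spectrum(peptide: Peptide, charge: int = 2, include_losses=True,
                       heavy: bool = False, rt: float = 10.0) -> Spectrum:
    """A spectrum holding exactly the theoretical ladder of a peptide."""
    from hgmod.chem import peptide_neutral_mass, mz

    mods = peptide.mods
    if heavy:
        mods = tuple((s, m.heavy() if m.isotope_variant else m) for s, m in mods)
    neutral = peptide_neutral_mass(peptide.sequence, mods)
    charges = (1, 2) if charge >= 2 else (1,)
    ions = theoretical_fragments(peptide, charges, include_losses, heavy)
    return Spectrum.from_peaks(
        id=f"noiseless|{peptide.sequence}",
        precursor_mz=mz(neutral, charge),
        precursor_charge=charge,
        rt=rt,
        peaks=[(ion.mz, 100.0) for ion in ions],
    )
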