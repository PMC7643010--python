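import numpy as np
import pytest

from apmsflow.psm_io import PSMRecord, ProteinRecord, map_peptides
from apmsflow.synthetic import SimulationDesign, generate_apms, generate_proteome


def make_psm(
    peptide: str,
    intensity: float,
    band: str = "300kDa",
    condition: str = "bait",
    replicate: int = 1,
    spectrum_id: str = "",
    **kwargs,
) -> PSMRecord:
    """PSM factory with sane defaults for quantification tests."""
    return PSMRecord(
        spectrum_id=spectrum_id or f"{band}_{condition}_r{replicate}_{peptide}_{intensity}",
        peptide=peptide,
        modifications=kwargs.pop("modifications", ()),
        charge=kwargs.pop("charge", 2),
        intensity=intensity,
        sample_id=f"{band}_{condition}_r{replicate}",
        band=band,
        condition=condition,
        replicate=replicate,
        q_value=kwargs.pop("q_value", 0.001),
        e_value=kwargs.pop("e_value", 1e-9),
    )


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(seed=7, n_background=25, n_partners=6)


@pytest.fixture(scope="session")
def small_fixture(small_design):
    """One generated experiment shared across tests: proteome, truth, PSMs, map."""
    proteome, truth = generate_proteome(small_design)
    tables = generate_apms(small_design, proteome, truth)
    psms = [rec for recs in tables.values() for rec in recs]
    pmap = map_peptides(psms, proteome)
    return {"design": small_design, "proteome": proteome, "truth": truth, "psms": psms, "pmap": pmap}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
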