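import pandas as pd
import pytest

from lbproteome import SimulationConfig, generate_experiment
from lbproteome.io import EVIDENCE_COLUMNS, ProteinCatalog


def make_evidence(rows):
    """rows: iterable of (protein_id, sample, replicate, peptide, confidence, spectra)."""
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


@pytest.fixture
def catalog():
    return ProteinCatalog(
        {
            "p1": "MKVRST",
            "p2": "MKVRSTACDEFGHIKLMNPQ",  # length 20
            "p3": "A" * 100,
            "p4": "MKVR" * 75,  # length 300
        }
    )


@pytest.fixture(scope="session")
def bundle():
    """One synthetic fractionation experiment at the default study conditions."""
    return generate_experiment(SimulationConfig(seed=11))
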