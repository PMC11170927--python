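import numpy as np
import pandas as pd
import pytest

from warmsoil import mend, synth, traits


@pytest.fixture(scope="session")
def design():
    return synth.StudyDesign(seed=42)


@pytest.fixture(scope="session")
def forcing_pair(design):
    return synth.gen_forcing(design)


@pytest.fixture(scope="session")
def control_forcing(forcing_pair):
    return forcing_pair[1]


@pytest.fixture(scope="session")
def default_params():
    return mend.MendParams()


@pytest.fixture(scope="session")
def community(design):
    return synth.gen_community(design, n_asvs=120)


@pytest.fixture(scope="session")
def probe_sim(design):
    return synth.gen_probe_signals(design, n_probes=120)


@pytest.fixture(scope="session")
def toy_lookup():
    """Small hand-built rrn hierarchy.

    Family_A
      Genus_A1 (entry: 6)   children: Sp_a (2), Sp_b (4)
      Genus_A2 (entry: 1)
      Genus_A3 (entry: 5)   -> family children entries {6, 1, 5}, mean 4
    Family_B
      Genus_B1 (entry: 3)   children: Sp_c (7)
    """
    rows = [
        ("Genus_A1", "genus", 6.0, "Family_A"),
        ("Genus_A2", "genus", 1.0, "Family_A"),
        ("Genus_A3", "genus", 5.0, "Family_A"),
        ("Genus_B1", "genus", 3.0, "Family_B"),
        ("Sp_a", "species", 2.0, "Genus_A1"),
        ("Sp_b", "species", 4.0, "Genus_A1"),
        ("Sp_c", "species", 7.0, "Genus_B1"),
    ]
    df = pd.DataFrame(rows, columns=["taxon", "rank", "copy_number", "parent"])
    return traits.RrnLookup.from_frame(df)


@pytest.fixture(scope="session")
def constant_forcing():
    dates = pd.date_range("2000-01-01", periods=365, freq="D")
    return pd.DataFrame({"temperature": 15.0, "moisture": 25.0, "gpp": 3.0},
                        index=dates)


def rng_for(name: str, seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(abs(hash((name, seed))) % (2 ** 31))
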