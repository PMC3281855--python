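import numpy as np
import pandas as pd
import pytest

from barcodekit.seqio import Dataset, Marker, SpecimenRecord
from barcodekit.synthetic_data import SimulationConfig, simulate


def make_record(sid, seq, species="Sp1", genus="Gen1", family="Fam1",
                order="Ord1", class_="Cls1", marker=Marker.COI):
    return SpecimenRecord(
        specimen_id=sid, sequence=seq, marker=marker, species=species,
        genus=genus, family=family, order=order, class_=class_,
    )


@pytest.fixture
def toy_dataset():
    """2 genera x 2 species x 2 specimens, 12-bp aligned sequences."""
    rows = [
        ("a1", "ATGGCCATTGTA", "SpA", "GenX"),
        ("a2", "ATGGCCATTGTA", "SpA", "GenX"),
        ("b1", "ATGGCCTTTGTA", "SpB", "GenX"),
        ("b2", "ATGGCGTTTGTA", "SpB", "GenX"),
        ("c1", "TTGACCATCCTA", "SpC", "GenY"),
        ("c2", "TTGACCATCCTA", "SpC", "GenY"),
    ]
    return Dataset([make_record(s, q, species=sp, genus=g) for s, q, sp, g in rows])


@pytest.fixture(scope="session")
def sim_default():
    """Default study-shaped simulation: 2 fam x 2 gen x 2 sp x 3 specimens."""
    return simulate(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def sim_clustered():
    """Low intraspecific (0.2%), well-separated species (>=5%) simulation."""
    return simulate(SimulationConfig(
        seed=7,
        divergence_within_species=0.002,
        divergence_within_genus=0.06,
        divergence_within_family=0.12,
        divergence_within_order=0.18,
    ))


@pytest.fixture
def taxonomy_frame():
    def build(rows):
        df = pd.DataFrame(
            rows, columns=["specimen_id", "species", "genus", "family",
                           "order", "class_"]
        )
        return df.set_index("specimen_id")
    return build


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
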