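from __future__ import annotations

import numpy as np
import pytest

from gutlink.profiles import (
    PREDATORS,
    generate_reference_suite,
    survey_detections,
    survey_rules,
    survey_taxonomy,
)
from gutlink.pipeline import run_survey_library
from gutlink.refdb import MatchPolicy, ReferenceDatabase
from gutlink.taxonomy import Taxonomy, TaxonRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20_160_913)


@pytest.fixture(scope="session")
def taxonomy():
    return survey_taxonomy()


@pytest.fixture(scope="session")
def fixture_detections():
    return survey_detections()


@pytest.fixture(scope="session")
def rules():
    return survey_rules()


@pytest.fixture
def toy_taxonomy():
    """A minimal taxonomy: one family, two genera, three species."""
    return Taxonomy(
        [
            TaxonRecord("root", "root", None),
            TaxonRecord("FamilyF", "family", "root"),
            TaxonRecord("GenusG1", "genus", "FamilyF"),
            TaxonRecord("GenusG2", "genus", "FamilyF"),
            TaxonRecord("speciesA", "species", "GenusG1", "focal_predator"),
            TaxonRecord("speciesB", "species", "GenusG1", "herbivore"),
            TaxonRecord("speciesC", "species", "GenusG2", "herbivore"),
        ]
    )


@pytest.fixture
def toy_db(rng):
    """Two 2-kb references, 10 % divergent, with a mask on the first."""
    from gutlink.refdb import MaskedRegion
    from gutlink.synthetic import mutate_sequence, random_sequence

    seq_a = random_sequence(2_000, rng)
    seq_b = mutate_sequence(seq_a, 0.10, rng)
    return ReferenceDatabase(
        "toy",
        "insect_mitogenome",
        [("refA", seq_a, "speciesA"), ("refB", seq_b, "speciesB")],
        MatchPolicy(min_identity=98, min_overlap=225),
        [MaskedRegion("refA", 1_500, 1_800, "control_region")],
    )


# ---------------------------------------------------------------------------
# shared heavyweight fixtures for the acceptance suite


@pytest.fixture(scope="session")
def suite():
    return generate_reference_suite(1)


ROUNDTRIP_READS = 1_000_000


@pytest.fixture(scope="session")
def roundtrip_results(suite):
    """Full synthetic round-trip: all four predator libraries plus control.

    Libraries are simulated at one million reads each with the foreign-taxon
    frequencies of the emulated survey, then run through the complete
    pipeline against the shared reference suite.
    """
    results = {}
    for name in (*PREDATORS, "control"):
        results[name] = run_survey_library(
            name, suite, n_reads=ROUNDTRIP_READS, seed=1
        )
    return results
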