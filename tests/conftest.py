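import numpy as np
import pytest

from craniomap import ColonySpec, GenotypeStudy, VariantRecord, simulate_colony


@pytest.fixture
def tiny_study() -> GenotypeStudy:
    """3 samples × 4 hand-coded SNPs, incl. one missing call."""
    variants = [
        VariantRecord("2", 6_388_292, "A", "G"),
        VariantRecord("2", 6_430_107, "A", "G"),
        VariantRecord("2", 6_641_309, "C", "T"),
        VariantRecord("2", 6_641_349, "G", "A"),
    ]
    dosages = np.array(
        [
            [0, 1, 2, 1],
            [1, 2, 0, -1],
            [2, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeStudy(
        variants=variants,
        samples=["r1", "r2", "r3"],
        dosages=dosages,
        diagnoses={"r1": "EOS", "r2": "DOS", "r3": "ICN"},
        pedigree={"r1": (None, None), "r2": (None, None), "r3": ("r1", "r2")},
    )


@pytest.fixture(scope="session")
def small_colony():
    """A modest seeded colony shared by the slower integration tests."""
    spec = ColonySpec(n_animals=70, n_variants=400, n_chromosomes=4)
    return simulate_colony(spec, rng=7) + (spec,)
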