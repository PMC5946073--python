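import numpy as np
import pytest

from episyn.core_data import GenotypeStudy
from episyn.synthetic_data import (
    PenetranceEffect,
    SimConfig,
    simulate_study,
    xor_penetrance,
)


@pytest.fixture
def tiny_study() -> GenotypeStudy:
    """Six subjects, three SNPs, one missing call, survival on the cases."""
    return GenotypeStudy(
        subject_ids=[f"s{i}" for i in range(6)],
        phenotype=np.array(
            ["case", "case", "case", "control", "control", "control"], dtype=object
        ),
        sex=np.array(
            ["female", "male", "female", "male", "female", "unknown"], dtype=object
        ),
        genotypes=np.array(
            [
                [0, 1, 2],
                [1, 1, 0],
                [2, -1, 1],
                [0, 0, 0],
                [1, 2, 1],
                [2, 1, 2],
            ],
            dtype=np.int8,
        ),
        snp_ids=["rs1", "rs2", "rs3"],
        survival_months=np.array([12.0, 30.0, 7.0, np.nan, np.nan, np.nan]),
        event=np.array([1.0, 0.0, 1.0, np.nan, np.nan, np.nan]),
    )


@pytest.fixture
def random_study():
    """Moderate null study (no planted effects), fully observed, seeded."""
    cfg = SimConfig(
        n_cases=150,
        n_controls=150,
        panel=(("IIS", 6), ("pro_antioxidant", 5), ("DNA_repair", 5)),
        missing_rate=0.0,
        seed=11,
    )
    study, ann, _ = simulate_study(cfg)
    return study, ann


@pytest.fixture
def planted_study():
    """Study with a pure-epistasis pair planted at loci 0 and 1."""
    cfg = SimConfig(
        n_cases=500,
        n_controls=500,
        panel=(("IIS", 10), ("pro_antioxidant", 5), ("DNA_repair", 5)),
        effects=(
            PenetranceEffect(loci=(0, 1), table=xor_penetrance(), mafs=(0.5, 0.5)),
        ),
        missing_rate=0.0,
        seed=23,
    )
    return simulate_study(cfg)
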