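import numpy as np
import pandas as pd
import pytest

from solegen.lesions import CohortRecords, CLAW_POSITIONS, TIMEPOINTS
from solegen.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across test modules."""
    cfg = SimulationConfig(
        n_founders=150, n_snps=80, genotyped_fraction=0.5,
        daughters_per_sire_range=(3, 7), seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_pedigree_frame():
    """Six animals: 5 = full-sib mating offspring, 6 = sire-daughter offspring."""
    return pd.DataFrame(
        {
            "animal": [1, 2, 3, 4, 5, 6],
            "sire": [0, 0, 1, 1, 3, 1],
            "dam": [0, 0, 2, 2, 4, 3],
        }
    )


def make_records(grade_map, assessments=None):
    """Build CohortRecords from {(animal, timepoint, limb, side, claw): grade}.

    Animals listed get a full 8-claw grid at all 4 timepoints defaulting to
    grade 0 unless overridden; an override of None drops the row entirely
    and np.nan keeps the row with a missing grade.
    """
    animals = sorted({k[0] for k in grade_map})
    rows = []
    for animal in animals:
        for tp in TIMEPOINTS:
            for pos in CLAW_POSITIONS:
                key = (animal, tp) + pos
                grade = grade_map.get(key, 0)
                if grade is None:
                    continue
                rows.append((animal, tp, *pos, float(grade)))
    claws = pd.DataFrame(
        rows, columns=["animal", "timepoint", "limb", "side", "claw", "grade"]
    )
    if assessments is None:
        assessments = pd.DataFrame(
            [
                (animal, tp, {"T1": -50, "T2": 5, "T3": 85, "T4": 200}[tp], 0, 0, 1, 0)
                for animal in animals
                for tp in TIMEPOINTS
            ],
            columns=[
                "animal", "timepoint", "days_from_calving",
                "mobility", "herd", "parity", "hys",
            ],
        )
    return CohortRecords(claws, assessments)
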