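"""Shared fixtures: small synthetic cohorts and toy tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from starchlink.synthetic import CohortDesign, PlantedEffect, generate_cohort
from starchlink.tables import FeatureTable, make_sample_meta

# Canonical planted-module recovery configuration: two cross-layer modules
# (4 and 3 features) coupled at the correlation plateau of the count-noise
# model, on a 50-subject cohort.
RECOVERY_MAGNITUDE = 4.0
RECOVERY_EFFECTS = [
    PlantedEffect("otu", "OTU_0001", "hrs_shift", RECOVERY_MAGNITUDE, module_id=1),
    PlantedEffect("protein", "PROT_0001", "hrs_shift", RECOVERY_MAGNITUDE, module_id=1),
    PlantedEffect("metabolite", "MET_0001", "hrs_shift", RECOVERY_MAGNITUDE, module_id=1),
    PlantedEffect("metabolite", "MET_0002", "hrs_shift", RECOVERY_MAGNITUDE, module_id=1),
    PlantedEffect("otu", "OTU_0002", "lrs_shift", RECOVERY_MAGNITUDE, module_id=2),
    PlantedEffect("otu", "OTU_0003", "lrs_shift", RECOVERY_MAGNITUDE, module_id=2),
    PlantedEffect("protein", "PROT_0002", "lrs_shift", RECOVERY_MAGNITUDE, module_id=2),
]


def recovery_cohort(seed: int = 0):
    design = CohortDesign(
        n_subjects=50, n_otus=60, n_proteins=50, n_metabolites=70, seed=seed
    )
    return generate_cohort(design, RECOVERY_EFFECTS)


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort with no planted effects (null structure)."""
    design = CohortDesign(
        n_subjects=12, n_otus=30, n_proteins=25, n_metabolites=35, seed=7
    )
    return generate_cohort(design, [])


@pytest.fixture()
def toy_meta():
    return make_sample_meta(
        [
            {"sample_id": f"S{i:02d}-{diet}", "subject_id": f"S{i:02d}",
             "arm": "LC", "diet": diet, "day": day}
            for i in range(1, 5)
            for diet, day in (("baseline", 14), ("LRS", 28), ("HRS", 56))
        ]
    )


def make_table(matrix, layer="otu", sample_ids=None, feature_ids=None):
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j}" for j in range(p)]
    data = pd.DataFrame(matrix, index=sample_ids, columns=feature_ids)
    data.index.name = "sample_id"
    return FeatureTable(layer, data)
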