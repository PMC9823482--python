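"""Shared fixtures: one small synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from todcourse.cycling_detection import build_model_library, detect_cycling
from todcourse.normalization import quantile_normalize
from todcourse.synthetic_data import (
    ConditionSpec,
    GOTermSpec,
    PlantedKmer,
    SimConfig,
    simulate_go_map,
    simulate_promoters,
    simulate_timecourses,
)

#: Evening-Element-like planted word, its target phase bin, and carriage
EE = PlantedKmer("AAATATCT", phase_bin=9, fraction=0.8)
#: exclusive planted GO term at the relative-dawn bin
DAWN_TERM = GOTermSpec("GO:0009999", phase_bin=20, odds=float("inf"))


@pytest.fixture(scope="session")
def study_config() -> SimConfig:
    return SimConfig(
        n_genes=1000,
        seed=101,
        conditions=(
            ConditionSpec("c1", 0.0, day_of_season=15),
            ConditionSpec("c2", 2.0, day_of_season=43),
            ConditionSpec("c3", 6.0, day_of_season=85),
        ),
        planted_kmers=(EE,),
        go_terms=(DAWN_TERM, GOTermSpec("GO:0008888", phase_bin=9, odds=12.0)),
    )


@pytest.fixture(scope="session")
def study(study_config):
    """(timecourses, truth) for the shared small study."""
    return simulate_timecourses(study_config)


@pytest.fixture(scope="session")
def promoters(study):
    _, truth = study
    return simulate_promoters(truth, length=500, seed=202)


@pytest.fixture(scope="session")
def gomap(study):
    _, truth = study
    return simulate_go_map(truth, n_terms=30, seed=303)


@pytest.fixture(scope="session")
def library(study):
    tcs, _ = study
    return build_model_library(tcs[0].zt)


@pytest.fixture(scope="session")
def callsets(study, library):
    tcs, _ = study
    return [detect_cycling(quantile_normalize(tc), library) for tc in tcs]


@pytest.fixture(scope="session")
def element_result(callsets, promoters):
    from todcourse.element_discovery import run_element

    return run_element(callsets, promoters, alpha=0.05)


def circular_diff(a, b):
    """Shortest circular distance in hours between two phase arrays."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 24.0)
    return np.minimum(d, 24.0 - d)
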