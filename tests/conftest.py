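"""Shared fixtures: fast device configurations, cohorts and reference tables.

The expensive session fixtures (reference tables of pre-simulated prior
draws) are shared across the recovery and end-to-end tests; everything is
seeded so the suite is reproducible run-to-run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import plateletabc as pa
from plateletabc.inference import PriorSpec, build_reference_table, generative_prior

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

# the simulator warns when a prior draw's rate saturates the per-step
# probability; that is expected while tables are built from wide priors
warnings.filterwarnings("ignore", message="per-step probability clamped")


#: shared parameter values for the non-pathology channels of every study
SHARED = dict(
    adhesion_rate=0.5,
    top_rate=0.2,
    albumin_rate=3e-3,
    velocity_ap=1.5e-3,
    velocity_nap=6e-4,
)

HEALTHY = pa.DepositionParams(aggregation_rate=1.0, albumin_attenuation=3e-4, **SHARED)


@pytest.fixture(scope="session")
def fast_config() -> pa.DeviceConfig:
    """Desk-scale configuration used for simulation-heavy studies."""
    return pa.DeviceConfig(scale=0.05, dt=0.05)


@pytest.fixture(scope="session")
def midi_config() -> pa.DeviceConfig:
    """Larger desk-scale window (lower observation noise) for recovery."""
    return pa.DeviceConfig(scale=0.1, dt=0.05)


def three_group_centers() -> dict[str, pa.DepositionParams]:
    """Healthy / dialysis-like / COPD-like centers differing only in the
    aggregation rate and the albumin attenuation factor."""
    return {
        "healthy": HEALTHY,
        "dialysis": pa.DepositionParams(
            aggregation_rate=1.0, albumin_attenuation=1.2e-3, **SHARED
        ),
        "copd": pa.DepositionParams(
            aggregation_rate=6.0, albumin_attenuation=3e-4, **SHARED
        ),
    }


def pathology_cohort_spec(
    config: pa.DeviceConfig, seed: int, n_per_group: int = 8
) -> pa.CohortSpec:
    """3-group cohort whose groups differ only in aggregation/attenuation.

    The two pathology parameters carry 10% within-group dispersion, the
    controlled parameters 5%.
    """
    groups = []
    for label, center in three_group_centers().items():
        c = center.as_array()
        disp = tuple(
            (0.10 if name in ("aggregation_rate", "albumin_attenuation") else 0.05) * c[i]
            for i, name in enumerate(pa.PARAM_NAMES)
        )
        groups.append(pa.GroupSpec(label=label, center=center, dispersion=disp))
    return pa.CohortSpec(groups=tuple(groups), n_per_group=n_per_group, config=config, seed=seed)


@pytest.fixture(scope="session")
def study_prior() -> PriorSpec:
    """Generative prior of the pathology studies: vague on the two
    pathology parameters, dispersion-matched bands on the rest."""
    spec = pathology_cohort_spec(pa.DeviceConfig(), seed=0)
    return generative_prior(
        spec.groups, vague=("aggregation_rate", "albumin_attenuation")
    )


@pytest.fixture(scope="session")
def small_cohort(fast_config) -> pa.CohortDataset:
    """One 3x8 pathology cohort at desk scale (24 quick simulations)."""
    return pa.generate_cohort(pathology_cohort_spec(fast_config, seed=42))


@pytest.fixture(scope="session")
def gradient_prior() -> PriorSpec:
    """Generative prior of the aggregation-gradient recovery study: vague
    on the aggregation rate, +-20% bands on the controlled parameters."""
    group = pa.GroupSpec("center", HEALTHY, tuple([0.0] * 7))
    return generative_prior([group], vague=("aggregation_rate",))


@pytest.fixture(scope="session")
def fast_table(fast_config, gradient_prior):
    """Reference table at scale 0.05 under the gradient prior (~1 min)."""
    return build_reference_table(gradient_prior, fast_config, n=3000, seed=7)


@pytest.fixture(scope="session")
def midi_table(midi_config, study_prior):
    """Reference table at scale 0.1 under the study prior (~4 min);
    shared by the coverage and end-to-end tests."""
    return build_reference_table(study_prior, midi_config, n=4000, seed=7)
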