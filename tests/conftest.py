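"""Shared fixtures: synthetic studies and fitted models reused across
test modules (session-scoped — SAEM fits are the expensive part)."""

from __future__ import annotations

import numpy as np
import pytest

from mecell.input_model import build_input
from mecell.saem import SAEMConfig, fit_saem
from mecell.synthetic import (StudyConfig, apply_qc_filters, default_population,
                              generate_study)


def recovery_config(**overrides) -> StudyConfig:
    """Study conditions for parameter-recovery checks: known correlated
    population, no feature couplings or lineage correlation."""
    kw = dict(n_cells=200, n_founders=60, shock_gain_sd=0.0, inheritance_rho=0.0)
    kw.update(overrides)
    return StudyConfig(**kw)


@pytest.fixture(scope="session")
def recovery_study():
    cfg = recovery_config()
    return cfg, apply_qc_filters(generate_study(cfg, rng=11))


@pytest.fixture(scope="session")
def recovery_fit(recovery_study):
    cfg, study = recovery_study
    pop_fit, trace = fit_saem(study, cfg.build_input(), SAEMConfig(seed=11))
    return cfg, study, pop_fit, trace


@pytest.fixture(scope="session")
def small_study():
    """Small full-featured study (couplings and inheritance on)."""
    cfg = StudyConfig(n_cells=60, n_founders=30)
    return cfg, apply_qc_filters(generate_study(cfg, rng=5))


@pytest.fixture(scope="session")
def default_pop():
    return default_population()
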