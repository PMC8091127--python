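"""Shared fixtures: published parameter values, default design, small datasets."""
import logging

import numpy as np
import pytest

from sofaer.estimation import VarianceParams
from sofaer.model import StructuralParams
from sofaer.synthetic import TruthParams, default_design, default_truth, generate_trial


@pytest.fixture(autouse=True)
def _quiet_range_warnings(caplog):
    """Silence the out-of-range SOFA warnings that continuous simulated
    DVs legitimately trigger; individual tests re-enable via caplog."""
    logging.getLogger("sofaer.data").setLevel(logging.ERROR)
    yield
    logging.getLogger("sofaer.data").setLevel(logging.NOTSET)


@pytest.fixture(scope="session")
def published_params() -> StructuralParams:
    """Published final estimates of the fixed effects."""
    return StructuralParams(f_placebo=0.792, k=0.263, kin=0.0569, eauc50=1320.0)


@pytest.fixture(scope="session")
def published_variance() -> VarianceParams:
    """omega from the CV% reading of the 30.2 IIV on k; sigma as printed."""
    return VarianceParams(omega=0.302 * 0.263, sigma=1.96)


@pytest.fixture(scope="session")
def truth(published_params, published_variance) -> TruthParams:
    return TruthParams(structural=published_params, variance=published_variance)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_dataset(design, truth):
    """One seeded 34-subject synthetic trial."""
    return generate_trial(design, truth, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def five_subject_oracle(published_params, published_variance):
    """Small deterministic dataset for quadrature/likelihood oracles."""
    from sofaer.data import ObservationRecord, SubjectRecord, TrialDataset
    from sofaer.model import predict_sofa

    gen = np.random.default_rng(77)
    subjects = []
    specs = [("placebo", 12.0, 0.0), ("placebo", 15.0, 0.0), ("0.06", 9.0, 295.0),
             ("0.12", 10.0, 830.0), ("0.24", 11.0, 1480.0)]
    for i, (arm, base, auc) in enumerate(specs):
        days = np.arange(1.0, 9.0)
        eta = gen.normal(0, published_variance.omega)
        dvs = (predict_sofa(days, base, auc, published_params, eta_k=eta)
               + gen.normal(0, published_variance.sigma, days.size))
        obs = tuple(ObservationRecord(float(d), float(v)) for d, v in zip(days, dvs))
        subjects.append(SubjectRecord(id=f"F{i}", arm=arm, base=base, auc=auc,
                                      observations=obs))
    return TrialDataset(subjects=tuple(subjects))
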