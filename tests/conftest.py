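import numpy as np
import pytest

from mrpipe.simulate import (
    BiomarkerSpec,
    OutcomeModel,
    SimulationConfig,
    SNPSpec,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def one_snp_config():
    """Single strong instrument: EAF 0.2647 chosen so a 94.78 ng/mL
    per-allele effect explains ~5% of a 265 ng/mL-SD biomarker."""
    return SimulationConfig(
        n_individuals=718,
        snps=[SNPSpec("snp_iv", "A", "G", 0.2647)],
        biomarkers=[BiomarkerSpec("B2", 700.0, 265.0)],
        effects={"snp_iv": {"B2": 94.78}},
    )


@pytest.fixture
def case_control_config():
    return SimulationConfig(
        n_individuals=3000,
        snps=[SNPSpec("snp_iv", "A", "G", 0.3)],
        biomarkers=[BiomarkerSpec("B2", 700.0, 265.0)],
        effects={"snp_iv": {"B2": 94.78}},
        outcome=OutcomeModel(
            log_or={"B2": 0.2 / 265.0},
            prevalence=0.3,
            grade_log_or={"B2": 0.2 / 265.0},
            grade_high_frac=0.3,
        ),
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(
        n_individuals=500,
        snps=[SNPSpec("s1", "A", "G", 0.3), SNPSpec("s2", "C", "T", 0.45)],
        biomarkers=[
            BiomarkerSpec("B1", 200.0, 50.0),
            BiomarkerSpec("B2", 700.0, 265.0),
        ],
        effects={"s1": {"B2": 94.78}},
        outcome=OutcomeModel(log_or={"B2": 0.1 / 265.0}, prevalence=0.4),
    )
    return simulate_cohort(cfg, seed=42)
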