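import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tfmeth.config import PipelineConfig
from tfmeth.simulate import SimulationScenario, make_truth_table, simulate_cohort
from tfmeth.types import CpGRecord


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def runx1_cohort():
    """Default RUNX1 scenario at 5000 CpGs x 186 samples with truth labels."""
    sc = SimulationScenario.runx1(n_cpgs=5000, rng_seed=0)
    truth = make_truth_table(sc.n_cpgs, sc.frac_near_tfbs, sc.rng_seed)
    cohort, cpg_truth, extras = simulate_cohort(sc, truth)
    manifest = [
        CpGRecord(r.cpg_id, r.chrom, int(r.pos), r.gene)
        for r in truth.itertuples(index=False)
    ]
    return sc, cohort, cpg_truth, extras, manifest


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects: zero shifts, zero coupling."""
    sc = SimulationScenario.runx1(
        n_cpgs=4000, rng_seed=1, delta_near=0.0, delta_far=0.0,
        frac_responsive_far=0.0, tl_coupling=0.0, strong_coupling=0.0,
        n_strong_genes=0, frac_tl=0.0,
    )
    truth = make_truth_table(sc.n_cpgs, sc.frac_near_tfbs, sc.rng_seed)
    cohort, cpg_truth, extras = simulate_cohort(sc, truth)
    manifest = [
        CpGRecord(r.cpg_id, r.chrom, int(r.pos), r.gene)
        for r in truth.itertuples(index=False)
    ]
    return sc, cohort, cpg_truth, extras, manifest
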