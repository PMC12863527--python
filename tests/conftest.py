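import numpy as np
import pandas as pd
import pytest

from adipomet import anthropometry, synthetic


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition cohort (322 pairs, 186 metabolites)."""
    sim = synthetic.generate_matched_cohort(synthetic.CohortSimConfig(seed=11))
    sim.cohort = sim.cohort.join(anthropometry.derive_indices(sim.cohort))
    return sim


@pytest.fixture(scope="session")
def small_sim():
    """A small cohort for fast structural tests."""
    cfg = synthetic.CohortSimConfig(
        n_pairs=60, n_metabolites=24, n_blocks=4, seed=5,
        n_planted=6,
    )
    sim = synthetic.generate_matched_cohort(cfg)
    sim.cohort = sim.cohort.join(anthropometry.derive_indices(sim.cohort))
    return sim


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_harmonized(beta_exp, se_exp, beta_out, se_out, n_exp=1e5, n_out=1e5):
    """Hand-built harmonized set for estimator tests."""
    from adipomet.mr import HarmonizedSet

    k = len(beta_exp)
    t = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(k)],
            "chr": 1, "pos": np.arange(k) * 10**6,
            "effect_allele": "A", "other_allele": "G",
            "beta_exp": np.asarray(beta_exp, float),
            "se_exp": np.asarray(se_exp, float),
            "eaf_exp": 0.3, "n_exp": float(n_exp),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.asarray(se_out, float),
            "eaf_out": 0.3, "n_out": float(n_out),
        }
    )
    return HarmonizedSet(t)
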