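"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import facegwas as fg
from facegwas.simulate import SimSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """600-sample cohort with one 2%-variance causal variant."""
    spec = SimSpec(
        n_samples=600,
        n_variants=120,
        causal={"var00060": ("Prn-AlL", 0.02)},
        seed=42,
    )
    panel, lms, covars, truth = simulate_cohort(spec)
    return {"spec": spec, "panel": panel, "lms": lms, "covars": covars, "truth": truth}


@pytest.fixture(scope="session")
def small_adjusted(small_cohort):
    """Aligned, masked, sex/age-adjusted phenotypes of the small cohort."""
    aligned = fg.gpa_align(small_cohort["lms"])
    pheno = fg.mask_outliers(fg.pairwise_distances(aligned), 3.0)
    adj = fg.adjust_covariates(pheno, small_cohort["covars"].set_index("sample"))
    return adj


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
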