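import numpy as np
import pandas as pd
import pytest

import admixstats as A


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-individual cohort on 6,000 sites, shared across read-only tests."""
    spec = A.DemographicSpec(n_individuals=60, seed=7)
    panel = A.simulate_panel(6000, spec)
    return A.simulate_cohort(spec, panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_genotype_matrix(dosages, chroms=None, sex=None, populations=None):
    """Small GenotypeMatrix from a plain dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, s = dosages.shape
    individuals = pd.DataFrame(
        {
            "population": populations if populations is not None else ["P"] * n,
            "sex": sex if sex is not None else ["female"] * n,
        },
        index=pd.Index([f"i{j}" for j in range(n)], name="individual"),
    )
    sites = pd.DataFrame(
        {
            "site_id": np.arange(s),
            "chrom": chroms if chroms is not None else ["1"] * s,
            "pos_bp": np.arange(1, s + 1) * 1000,
        }
    )
    return A.GenotypeMatrix(dosages, individuals, sites)


def toy_annotations(n, coding=None, known=None, confident=None, conservation=None,
                    cadd=None):
    rngl = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "site_id": np.arange(n),
            "chrom": "1",
            "conservation": conservation if conservation is not None else rngl.normal(size=n),
            "cadd": cadd if cadd is not None else rngl.uniform(0, 40, n),
            "coding": coding if coding is not None else np.zeros(n, bool),
            "ancestral_confident": confident if confident is not None else np.ones(n, bool),
            "known": known if known is not None else np.ones(n, bool),
        }
    )
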