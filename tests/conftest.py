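import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ctdna_monitor as cm

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort() -> cm.SyntheticCohort:
    """A modest default-parameter cohort shared across read-only tests."""
    return cm.generate_cohort(cm.CohortConfig(n_per_arm=60, seed=11))


@pytest.fixture(scope="session")
def small_analysis(small_cohort) -> pd.DataFrame:
    model = cm.CtdnaAssociationModel.from_cohort(small_cohort)
    return model.data


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_calls(rng: np.random.Generator, n: int, patient_id: str = "P1",
                 timepoint: str = "C1", assay: str = "panel",
                 n_loci: int = 12) -> pd.DataFrame:
    """Small random call sets over a limited locus pool (forces key overlaps)."""
    bases = np.array(list("ACGT"))
    loci = rng.integers(1, n_loci + 1, size=n)
    ref_i = loci % 4
    alt_i = (ref_i + 1 + loci % 3) % 4
    total = rng.integers(50, 5000, size=n)
    altr = np.minimum(rng.integers(0, 300, size=n), total)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "timepoint": timepoint,
            "assay": assay,
            "chrom": rng.integers(1, 4, size=n).astype(str),
            "pos": loci * 100,
            "ref": bases[ref_i],
            "alt": bases[alt_i],
            "alt_reads": altr,
            "total_reads": total,
            "vaf": altr / total,
            "in_dbsnp": rng.random(n) < 0.3,
            "in_cosmic": rng.random(n) < 0.3,
            "nonsynonymous": rng.random(n) < 0.6,
            "truth_label": None,
        }
    )
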