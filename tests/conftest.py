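import numpy as np
import pandas as pd
import pytest

from dapes.io_formats import CohortTable, LDReference, SummaryStats
from dapes.synthetic_data import LDBlockSpec, simulate_genotypes


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    """400 individuals, 6 LD blocks of 5 variants (rho 0.5)."""
    spec = LDBlockSpec(30, [5] * 6, within_block_rho=0.5)
    return simulate_genotypes(spec, 400, seed=11)


@pytest.fixture(scope="session")
def small_ld(small_cohort) -> LDReference:
    return LDReference(small_cohort)


def make_sumstats(betas, ses=None, pos=None, chrom="1",
                  effect="A", other="G", pvals=None, n=10000):
    """Hand-built SummaryStats for unit tests."""
    from scipy import stats as sps

    betas = np.asarray(betas, float)
    ses = np.full(len(betas), 0.1) if ses is None else np.asarray(ses, float)
    pos = np.arange(1, len(betas) + 1) * 1000 if pos is None else pos
    z = betas / ses
    p = 2 * sps.norm.sf(np.abs(z)) if pvals is None else np.asarray(pvals)
    return SummaryStats(pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(len(betas))],
        "chrom": chrom, "pos": pos,
        "effect_allele": effect, "other_allele": other,
        "beta": betas, "se": ses,
        "pvalue": np.clip(p, np.nextafter(0, 1), 1.0),
        "n": n,
    }))
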