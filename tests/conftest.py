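import numpy as np
import pytest

from dmrsmicro.scheme import make_scheme_table


@pytest.fixture(scope="session")
def schemes():
    return make_scheme_table()


@pytest.fixture(scope="session")
def scheme100(schemes):
    return schemes[100.0]


@pytest.fixture(scope="session")
def small_dictionary():
    """Small but non-trivial morphometric dictionary shared across tests."""
    from dmrsmicro.morphometric import build_dictionary

    # interpolation mode: exercises the PCHIP TM=100/750 prediction path
    return build_dictionary(64, n_walkers=1500, seed=11, simulate_all=False)


@pytest.fixture(scope="session")
def null_lmm_pvalues():
    """Region/Age p-values from 200 null cohort replicates (no effects).

    Shared by the calibration (uniformity) and type-I-error checks.
    """
    import pandas as pd

    from dmrsmicro.stats import fit_lmm

    p_region, p_age = [], []
    for rep in range(200):
        rng = np.random.default_rng(10_000 + rep)
        rows = []
        for region in ("cerebellum", "thalamus"):
            for p in range(9):
                pup = f"{region[:2]}{p}"
                u = rng.normal(0.0, 0.05)
                for age in (5, 10, 15, 20, 30):
                    rows.append({
                        "pup_id": pup, "region": region, "age": age,
                        "value": 0.4 + u + rng.normal(0.0, 0.05),
                    })
        res = fit_lmm(pd.DataFrame(rows))
        p_region.append(res.p_values["region"])
        p_age.append(res.p_values["age"])
    return np.asarray(p_region), np.asarray(p_age)
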