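import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cernanet as cn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    spec = cn.SyntheticSpec(seed=11)
    return cn.generate_cohort(spec)


@pytest.fixture(scope="session")
def inferred(default_cohort):
    mset, mrna_cat, lnc_cat, truth = default_cohort
    result = cn.infer_network(mset, mrna_cat, lnc_cat)
    return result, truth


def make_matched_set(
    mirna: np.ndarray,
    lncrna: np.ndarray,
    mrna: np.ndarray,
    os_months=None,
    event=None,
) -> cn.MatchedExpressionSet:
    """Assemble a matched set from raw arrays with generated ids."""
    n = mirna.shape[1]
    samples = [f"s{i:03d}" for i in range(n)]

    def _mat(values, prefix, cls):
        ids = [f"{prefix}{i}" for i in range(values.shape[0])]
        return cn.ExpressionMatrix(
            pd.DataFrame(values, index=ids, columns=samples), cls
        )

    clin = cn.ClinicalTable(
        pd.DataFrame(
            {
                "os_months": os_months if os_months is not None else np.ones(n),
                "event": event if event is not None else np.ones(n, dtype=int),
            },
            index=pd.Index(samples, name="sample"),
        )
    )
    return cn.MatchedExpressionSet(
        _mat(mirna, "mir", "miRNA"), _mat(lncrna, "lnc", "lncRNA"),
        _mat(mrna, "gene", "mRNA"), clin,
    )


@pytest.fixture
def tiny_mset():
    """Deterministic 2 miRNA x 3 lncRNA x 3 mRNA, 12 samples."""
    rng = np.random.default_rng(5)
    return make_matched_set(
        rng.normal(size=(2, 12)), rng.normal(size=(3, 12)), rng.normal(size=(3, 12))
    )
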