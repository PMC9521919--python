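import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dilicat import CaseRecord, build_phenotype

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_cases(values, drug="drugX", feature=None):
    """Cohort whose features all equal `values` (or only one feature varies)."""
    cases = []
    for i, v in enumerate(values):
        feats = {"latency": v, "r_value": v, "ast_alt_ratio": v}
        if feature is not None:
            # pin the other two features at a harmless constant
            feats = {f: (v if f == feature else 1.0) for f in feats}
        cases.append(CaseRecord(case_id=f"c{i}", drug=drug,
                                latency_days=feats["latency"],
                                r_value=feats["r_value"],
                                ast_alt_ratio=feats["ast_alt_ratio"]))
    return cases


@pytest.fixture
def cohort_1_to_100():
    return make_cases(np.arange(1, 101, dtype=float))


@pytest.fixture
def phenotype_1_to_100(cohort_1_to_100):
    return build_phenotype(cohort_1_to_100)
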