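import numpy as np
import pytest

from predictval.engine import coefficient_set_from_dict, default_coefficients
from predictval.cohort import PatientRecord

#: toy exponential baselines: H0_breast(t) = LB*t, H0_other(t) = LO*t,
#: so bS = exp(-LB*t*e^(PI+TE)) and oS = exp(-LO*t*e^MI) in closed form
LAMBDA_BREAST = 0.02
LAMBDA_OTHER = 0.01


def exponential_baseline(rate, support=(1e-9, 50.0)):
    # L0(t) = ln(rate) + ln(t)
    return {"kind": "parametric", "intercept": float(np.log(rate)),
            "terms": [{"coef": 1.0, "power": 0}], "support": list(support)}


@pytest.fixture(scope="session")
def toy_coeffs():
    """Single-term PI (0.5 * ln(nodes+1)) over exponential baselines."""
    return coefficient_set_from_dict({
        "version": "toy",
        "pi_terms": {
            "positive": [{"covariate": "nodes", "coefficient": 0.5,
                          "transform": {"shift": 1, "power": 0}}],
            "negative": [{"covariate": "nodes", "coefficient": 0.5,
                          "transform": {"shift": 1, "power": 0}}],
        },
        "baseline_breast": {
            "positive": exponential_baseline(LAMBDA_BREAST),
            "negative": exponential_baseline(LAMBDA_BREAST),
        },
        "baseline_other": exponential_baseline(LAMBDA_OTHER),
        "treatments": {"hormone": -0.4, "chemo": -0.2, "trastuzumab": -0.3},
    })


@pytest.fixture(scope="session")
def v21_coeffs():
    return default_coefficients()


def make_record(**overrides):
    base = dict(
        id="p1", age_years=60.0, menopause="post", detection="symptoms",
        size_mm=20.0, grade=2, nodes=0, er="positive", her2="negative",
        ki67="unknown", hormone=False, chemo=False, trastuzumab=False,
        radiotherapy=False, followup_days=3650.0, dead=False, cause=None,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record():
    return make_record()


COHORT_CSV = """id,age_years,menopause,detection,size_mm,grade,nodes,er,her2,ki67,hormone,chemo,trastuzumab,radiotherapy,followup_days,dead,cause
p1,61.5,post,screening,18,2,0,positive,negative,unknown,true,false,false,true,4200,false,
p2,48.0,pre,symptoms,32,3,4,negative,positive,unknown,false,true,true,true,1500,true,breast
p3,70.2,post,symptoms,25,1,1,positive,negative,positive,true,true,false,false,3900,true,other
"""


@pytest.fixture
def cohort3():
    import io

    from predictval.cohort import read_cohort

    return read_cohort(io.StringIO(COHORT_CSV))
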