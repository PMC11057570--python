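import pandas as pd
import pytest

from rmrs import SubjectRecord


@pytest.fixture
def at_threshold_korean_male() -> SubjectRecord:
    """Male Korean subject with every factor exactly at its cutpoint."""
    return SubjectRecord(
        glucose=100, sbp=130, dbp=85, triglycerides=150, hdl=40, waist=90,
        sex="male", region="korean", id="at-threshold",
    )


@pytest.fixture
def cohort_csv(tmp_path):
    """Small mixed-validity cohort CSV on disk."""
    frame = pd.DataFrame(
        [
            # valid male korean, 3 risk factors (GL, TG, WC)
            dict(id="a", glucose=105, sbp=120, dbp=75, triglycerides=180,
                 hdl=45, waist=95, sex="male", region="korean"),
            # valid female american, low risk
            dict(id="b", glucose=85, sbp=110, dbp=70, triglycerides=90,
                 hdl=65, waist=75, sex="female", region="american"),
            # blank HDL -> rejected
            dict(id="c", glucose=95, sbp=118, dbp=76, triglycerides=120,
                 hdl=None, waist=82, sex="male", region="korean"),
            # implausible bp -> rejected
            dict(id="d", glucose=95, sbp=80, dbp=120, triglycerides=120,
                 hdl=50, waist=82, sex="female", region="korean"),
        ]
    )
    path = tmp_path / "cohort.csv"
    frame.to_csv(path, index=False)
    return path
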