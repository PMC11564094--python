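import numpy as np
import pandas as pd
import pytest

from ehrkit.core import EHRFrame


@pytest.fixture
def toy_csv(tmp_path):
    """Small mixed-type patient table on disk."""
    p = tmp_path / "visits.csv"
    p.write_text(
        "patient_id,age,sex,lab_glucose,smoker,admit_date,note\n"
        "a1,34,M,5.4,yes,2021-01-04,fever and cough\n"
        "a2,61,F,,no,2021-02-11,routine check\n"
        "a3,47,F,6.1,no,2021-03-30,follow up visit\n"
    )
    return p


@pytest.fixture
def mixed_frame():
    """In-memory frame with numeric + categorical variables and a missing
    entry in each."""
    X = np.array([
        [1.0, "low", 10.0],
        [2.0, "high", np.nan],
        [np.nan, "low", 30.0],
        [4.0, np.nan, 40.0],
    ], dtype=object)
    var = pd.DataFrame(
        {"kind": ["numeric", "categorical", "numeric"],
         "encoding_state": "raw"},
        index=["a", "grade", "b"])
    obs = pd.DataFrame({"site": ["s1", "s1", "s2", "s2"]},
                       index=[f"p{i}" for i in range(4)])
    f = EHRFrame(X, obs, var)
    f.set_categories("grade", ["high", "low"])
    return f


def frames_equal(a: EHRFrame, b: EHRFrame) -> bool:
    """Exact equality of matrices (NaN-aware), tables and schemas."""
    if a.shape != b.shape:
        return False
    da = pd.DataFrame(a.X, dtype=object)
    db = pd.DataFrame(b.X, dtype=object)
    na, nb = da.isna(), db.isna()
    if not na.equals(nb):
        return False
    if not (da.where(~na, 0) == db.where(~nb, 0)).all().all():
        return False
    if list(a.obs.index) != list(b.obs.index):
        return False
    if list(a.var.index) != list(b.var.index):
        return False
    if list(a.var["kind"]) != list(b.var["kind"]):
        return False
    if list(a.var["encoding_state"]) != list(b.var["encoding_state"]):
        return False
    return True
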