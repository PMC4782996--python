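import numpy as np
import pandas as pd
import pytest

from bmimatch.survey import SurveyDataset


def make_donor_frame(n: int, rng: np.random.Generator, sex="male",
                     age_band="40-44", race="nh_white", income=3,
                     measured_equals_self: bool = False) -> pd.DataFrame:
    """Single-subgroup donor table with lognormal-BMI anthropometry."""
    h = rng.normal(175 if sex == "male" else 162, 7, n)
    wkg = np.exp(np.log(27.7) + rng.normal(0, 0.21, n)) * (h / 100) ** 2
    self_h = h if measured_equals_self else h + 1.0 + rng.normal(0, 1.5, n)
    self_w = wkg if measured_equals_self else wkg - 1.0 + rng.normal(0, 2.3, n)
    return pd.DataFrame({
        "record_id": [f"D{sex[0]}{i}" for i in range(n)],
        "sex": sex, "age_band": age_band, "race_ethnicity": race,
        "income_cat": income,
        "sample_weight": rng.lognormal(0, 0.5, n),
        "self_height_cm": self_h, "self_weight_kg": self_w,
        "measured_height_cm": h, "measured_weight_kg": wkg,
        "pregnant": False,
    })


def make_recipient_frame(n: int, rng: np.random.Generator, sex="male",
                         age_band="40-44", race="nh_white", income=3,
                         state="XX") -> pd.DataFrame:
    h = rng.normal(175 if sex == "male" else 162, 7, n)
    wkg = np.exp(np.log(27.7) + rng.normal(0, 0.21, n)) * (h / 100) ** 2
    return pd.DataFrame({
        "record_id": [f"R{sex[0]}{i}" for i in range(n)],
        "sex": sex, "age_band": age_band, "race_ethnicity": race,
        "income_cat": income,
        "sample_weight": rng.lognormal(0, 0.5, n),
        "self_height_cm": h + 1.0 + rng.normal(0, 1.5, n),
        "self_weight_kg": wkg - 1.0 + rng.normal(0, 2.3, n),
        "state": state, "pregnant": False,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20130904)


@pytest.fixture
def small_pair(rng):
    """A two-sex donor/recipient pair large enough to fit and match."""
    donor = SurveyDataset(records=pd.concat([
        make_donor_frame(300, rng, sex="male"),
        make_donor_frame(300, rng, sex="female"),
    ], ignore_index=True), role="donor")
    recipient = SurveyDataset(records=pd.concat([
        make_recipient_frame(500, rng, sex="male"),
        make_recipient_frame(500, rng, sex="female", state="YY"),
    ], ignore_index=True), role="recipient")
    return donor, recipient
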