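"""Synthetic paired donor/recipient surveys with known ground truth.

The generator emulates the structure of a national examination survey
(donor: measured *and* self-reported anthropometry) and a much larger
telephone survey (recipient: self-report only, plus state), drawn from
one underlying population so that correction methods can be validated
against the recipient's true, never-observed measured values.

Population model
----------------
* Demographics (sex, 5-year age band, race/ethnicity, income band) are
  drawn from configurable marginal proportions.
* True height is normal within sex with small race and age effects.
* True weight is lognormal around a log-linear height-weight relation
  with demographic effects and an additive per-state shift on log
  weight, so states differ in their BMI distributions.
* Self-report bias: adults over-report height (≈ +1 cm on average) and
  under-report weight (women ≈ -1 kg on average), with the
  under-report growing with weight and heteroscedastic reporting noise
  — the misreporting pattern documented in examination surveys.
* Sample weights are lognormal, so both surveys have unequal weights
  and a Kish effective sample size below the record count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .survey import AGE_BANDS, SurveyDataset, age_midpoint
from .weighted import WeightedSample, bmi, weighted_prevalence

__all__ = ["PopulationSpec", "TruthTable", "generate", "true_prevalence"]

_DEF_AGE_PROPS = (0.155, 0.105, 0.105, 0.100, 0.100, 0.105,
                  0.105, 0.095, 0.080, 0.060, 0.045, 0.030, 0.015)

_DEF_STATES: Mapping[str, float] = {
    "CA": 0.25, "TX": 0.18, "NY": 0.13, "FL": 0.13,
    "OH": 0.11, "CO": 0.08, "MS": 0.06, "WV": 0.06,
}
_DEF_STATE_EFFECTS: Mapping[str, float] = {
    "CA": -0.020, "TX": 0.020, "NY": -0.010, "FL": 0.000,
    "OH": 0.020, "CO": -0.040, "MS": 0.050, "WV": 0.050,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth population and misreporting model.

    All proportions are normalized internally; state effects are
    additive shifts on log weight (so ``0.05`` is about +5% weight).
    The bias defaults reproduce the documented misreporting pattern:
    height over-reported by about 1 cm by both sexes, weight
    under-reported on average by about 1 kg by women, with the
    under-report increasing in true weight (heavier respondents
    under-report more) and reporting noise proportional to weight.
    """

    sex_props: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.48, "female": 0.52})
    age_props: Mapping[str, float] = field(
        default_factory=lambda: dict(zip(AGE_BANDS, _DEF_AGE_PROPS)))
    race_props: Mapping[str, float] = field(
        default_factory=lambda: {"nh_white": 0.64, "nh_black": 0.12,
                                 "hispanic": 0.16, "other": 0.08})
    income_props: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.12, 2: 0.15, 3: 0.18, 4: 0.22, 5: 0.33})

    # true height model (cm)
    height_mean_cm: Mapping[str, float] = field(
        default_factory=lambda: {"male": 175.3, "female": 161.8})
    height_sd_cm: Mapping[str, float] = field(
        default_factory=lambda: {"male": 7.1, "female": 6.8})
    height_race_shift_cm: Mapping[str, float] = field(
        default_factory=lambda: {"nh_white": 0.5, "nh_black": 0.3,
                                 "hispanic": -2.5, "other": -1.5})
    height_age_slope_cm: float = -0.04  # per year above age 40

    # true weight model: log W = log(ref_bmi) + 2 log(h/100) + effects + eps
    ref_median_bmi: float = 27.7
    log_weight_sd: float = 0.21
    bmi_age_effect: float = 0.004       # per year, ages 40-60 plateau
    bmi_income_gradient: float = -0.015  # per band above the middle band
    bmi_race_effect: Mapping[str, float] = field(
        default_factory=lambda: {"nh_white": 0.0, "nh_black": 0.04,
                                 "hispanic": 0.02, "other": -0.06})

    # states (recipient survey only records them; the population has them)
    state_props: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_STATES))
    state_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_STATE_EFFECTS))

    # self-report bias model
    height_bias_cm: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.0, "female": 1.0})
    height_noise_sd_cm: float = 2.5
    weight_bias_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": -0.3, "female": -1.0})
    weight_bias_slope: float = 0.15     # extra under-report per kg above sex mean
    weight_noise_sd_kg: float = 6.0
    heteroscedastic_noise: bool = True  # noise SD scales with w / sex mean w
    heaping: bool = False               # round self-report to whole cm/kg

    # sampling design: lognormal base weights, post-stratified (raked) to
    # the known population margins the way production survey weights are
    # calibrated to census control totals
    weight_lognorm_sigma: float = 0.5
    calibrate_weights: bool = True
    pregnant_frac: float = 0.0

    def validate(self) -> None:
        for name in ("sex_props", "age_props", "race_props", "income_props",
                     "state_props"):
            props = getattr(self, name)
            vals = np.array(list(props.values()), dtype=float)
            if vals.size == 0 or np.any(vals < 0) or vals.sum() <= 0:
                raise ValueError(f"{name} must be nonnegative and sum to > 0")
        if self.log_weight_sd < 0 or self.height_noise_sd_cm < 0 \
                or self.weight_noise_sd_kg < 0:
            raise ValueError("noise SDs must be nonnegative")
        missing = set(self.state_props) - set(self.state_effects)
        if missing:
            raise ValueError(f"states without effects: {sorted(missing)}")

    def without_bias(self) -> "PopulationSpec":
        """Copy with self-report identical to truth (no bias, no noise)."""
        return replace(
            self,
            height_bias_cm={s: 0.0 for s in self.height_bias_cm},
            weight_bias_kg={s: 0.0 for s in self.weight_bias_kg},
            weight_bias_slope=0.0,
            height_noise_sd_cm=0.0,
            weight_noise_sd_kg=0.0,
        )

    def without_state_effects(self) -> "PopulationSpec":
        """Copy in which every state shares the national BMI distribution."""
        return replace(self, state_effects={s: 0.0 for s in self.state_effects})

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class TruthTable:
    """Per-record ground truth for the recipient survey."""

    records: pd.DataFrame  # record_id, state, sample_weight, true_* columns

    def sample(self, state: str | None = None) -> WeightedSample:
        df = self.records
        if state is not None:
            df = df[df["state"] == state]
            if len(df) == 0:
                raise ValueError(f"unknown state: {state!r}")
        return WeightedSample(df["true_bmi"].to_numpy(),
                              df["sample_weight"].to_numpy())

    def prevalence(self, cutoff: float, state: str | None = None) -> float:
        return weighted_prevalence(self.sample(state), cutoff).prevalence

    def mean_bmi(self) -> float:
        s = self.sample()
        return float(np.average(s.values, weights=s.weights))


def true_prevalence(truth: TruthTable, cutoff: float,
                    scope: str = "national") -> float:
    """Weighted prevalence of true BMI >= cutoff, nationally or by state."""
    state = None if scope == "national" else scope
    return truth.prevalence(cutoff, state=state)


def _draw_categories(rng, props: Mapping, n: int) -> np.ndarray:
    keys = list(props.keys())
    p = np.array([props[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return np.array(keys, dtype=object)[idx]


def _simulate_population(spec: PopulationSpec, n: int, rng: np.random.Generator):
    sex = _draw_categories(rng, spec.sex_props, n)
    band = _draw_categories(rng, spec.age_props, n)
    race = _draw_categories(rng, spec.race_props, n)
    income = _draw_categories(rng, spec.income_props, n).astype(int)
    state = _draw_categories(rng, spec.state_props, n)

    band_mid = np.array([age_midpoint(b) for b in band])
    # true age uniform within the band (80+ treated as 80-84)
    lo = np.where(band == "80+", 80.0, band_mid - 2.0)
    hi = np.where(band == "80+", 84.0, band_mid + 2.0)
    lo = np.where(band == "18-24", 18.0, lo)
    hi = np.where(band == "18-24", 24.0, hi)
    age = rng.uniform(lo, hi)

    h_mean = np.array([spec.height_mean_cm[s] for s in sex])
    h_sd = np.array([spec.height_sd_cm[s] for s in sex])
    h_race = np.array([spec.height_race_shift_cm[r] for r in race])
    height = h_mean + h_race + spec.height_age_slope_cm * np.maximum(age - 40.0, 0.0) \
        + rng.normal(0.0, 1.0, n) * h_sd
    height = np.clip(height, 132.0, 220.0)

    log_bmi = np.log(spec.ref_median_bmi) \
        + spec.bmi_age_effect * (np.clip(age, 18.0, 60.0) - 40.0) \
        + spec.bmi_income_gradient * (income - 3) \
        + np.array([spec.bmi_race_effect[r] for r in race]) \
        + np.array([spec.state_effects[s] for s in state]) \
        + rng.normal(0.0, spec.log_weight_sd, n)
    weight = np.exp(log_bmi) * (height / 100.0) ** 2
    weight = np.clip(weight, 35.0, 280.0)

    sample_weight = rng.lognormal(mean=0.0, sigma=spec.weight_lognorm_sigma, size=n) * 100.0
    if spec.calibrate_weights:
        sample_weight = _rake_weights(spec, sample_weight, sex, band, race, income)
    return dict(sex=sex, age_band=band, race_ethnicity=race, income_cat=income,
                state=state, true_height_cm=height, true_weight_kg=weight,
                sample_weight=sample_weight)


def _rake_weights(spec: PopulationSpec, w: np.ndarray, sex, band, race, income,
                  n_rounds: int = 3) -> np.ndarray:
    """Post-stratify weights to the population margins.

    Iterative proportional fitting to the sex x age-band joint margin
    and the race and income margins, mirroring how production survey
    weights are calibrated to census control totals.  Cells absent from
    the sample are skipped (their mass is renormalized away).
    """
    w = w.copy()

    def ratio_adjust(labels, targets: Mapping):
        present = pd.Series(w).groupby(pd.Series(labels)).sum()
        total_target = sum(t for k, t in targets.items() if k in present.index)
        factors = {k: (targets[k] / total_target) / (present[k] / w.sum())
                   for k in present.index}
        return w * pd.Series(labels).map(factors).to_numpy()

    sex_p = {k: v / sum(spec.sex_props.values()) for k, v in spec.sex_props.items()}
    age_p = {k: v / sum(spec.age_props.values()) for k, v in spec.age_props.items()}
    joint = [f"{s}|{b}" for s, b in zip(sex, band)]
    joint_t = {f"{s}|{b}": sex_p[s] * age_p[b] for s in sex_p for b in age_p}
    for _ in range(n_rounds):
        w = ratio_adjust(joint, joint_t)
        w = ratio_adjust(race, dict(spec.race_props))
        w = ratio_adjust(income, dict(spec.income_props))
    return w


def _self_report(spec: PopulationSpec, pop: dict, rng: np.random.Generator):
    sex = pop["sex"]
    h = pop["true_height_cm"]
    w = pop["true_weight_kg"]
    n = h.size
    h_bias = np.array([spec.height_bias_cm[s] for s in sex])
    w_bias = np.array([spec.weight_bias_kg[s] for s in sex])

    # sex-specific mean weight anchors the weight-dependent under-report,
    # keeping the *average* bias at the configured per-sex value
    mean_w = pd.Series(w).groupby(pd.Series(sex)).transform("mean").to_numpy()
    w_sd = spec.weight_noise_sd_kg * (w / mean_w if spec.heteroscedastic_noise else 1.0)

    self_h = h + h_bias + rng.normal(0.0, 1.0, n) * spec.height_noise_sd_cm
    self_w = w + w_bias - spec.weight_bias_slope * (w - mean_w) \
        + rng.normal(0.0, 1.0, n) * w_sd
    if spec.heaping:
        self_h = np.round(self_h)
        self_w = np.round(self_w)
    self_h = np.clip(self_h, 123.0, 240.0)
    self_w = np.clip(self_w, 30.5, 294.0)
    return self_h, self_w


def generate(spec: PopulationSpec, n_donor: int, n_recipient: int,
             seed: int | None = None
             ) -> tuple[SurveyDataset, SurveyDataset, TruthTable]:
    """Generate a paired donor/recipient survey and the recipient's truth.

    Donor records carry measured *and* self-reported values (self =
    measured + bias + noise); recipient records carry self-report only
    plus a state code.  Both surveys are independent draws from the same
    population, so with zero state effects they are exchangeable — the
    regime in which matching must preserve the donor's measured-BMI
    marginal.  Deterministic given ``seed``.
    """
    if n_donor < 1 or n_recipient < 1:
        raise ValueError("n_donor and n_recipient must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)

    donor_pop = _simulate_population(spec, n_donor, rng)
    d_self_h, d_self_w = _self_report(spec, donor_pop, rng)
    donor_df = pd.DataFrame({
        "record_id": [f"D{i:07d}" for i in range(n_donor)],
        "sex": donor_pop["sex"], "age_band": donor_pop["age_band"],
        "race_ethnicity": donor_pop["race_ethnicity"],
        "income_cat": donor_pop["income_cat"],
        "sample_weight": donor_pop["sample_weight"],
        "self_height_cm": d_self_h, "self_weight_kg": d_self_w,
        "measured_height_cm": donor_pop["true_height_cm"],
        "measured_weight_kg": donor_pop["true_weight_kg"],
        "pregnant": False,
    })
    donor = SurveyDataset(records=donor_df, role="donor", years="synthetic")

    rec_pop = _simulate_population(spec, n_recipient, rng)
    r_self_h, r_self_w = _self_report(spec, rec_pop, rng)
    rec_ids = [f"R{i:07d}" for i in range(n_recipient)]
    rec_df = pd.DataFrame({
        "record_id": rec_ids,
        "sex": rec_pop["sex"], "age_band": rec_pop["age_band"],
        "race_ethnicity": rec_pop["race_ethnicity"],
        "income_cat": rec_pop["income_cat"],
        "sample_weight": rec_pop["sample_weight"],
        "self_height_cm": r_self_h, "self_weight_kg": r_self_w,
        "state": rec_pop["state"],
        "pregnant": False,
    })
    recipient = SurveyDataset(records=rec_df, role="recipient", years="synthetic")

    truth = TruthTable(records=pd.DataFrame({
        "record_id": rec_ids,
        "state": rec_pop["state"],
        "sample_weight": rec_pop["sample_weight"],
        "true_height_cm": rec_pop["true_height_cm"],
        "true_weight_kg": rec_pop["true_weight_kg"],
        "true_bmi": bmi(rec_pop["true_height_cm"], rec_pop["true_weight_kg"]),
    }))
    return donor, recipient, truth
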