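"""Percentile-rank statistical matching between two weighted surveys.

The correction imputes a *measured* BMI for every recipient respondent
(who reported height and weight themselves) by matching them to donor
respondents (for whom both self-reported and measured values exist) on
survey-weighted percentile ranks of the self-reported anthropometry,
within demographic subgroups defined by sex, 5-year age band,
race/ethnicity and household income.  Because ranks are computed within
each survey's own subgroup, the match is equipercentile: a recipient at
the 80th percentile of self-reported BMI in their subgroup is matched
to a donor near the 80th percentile of the donor subgroup, and receives
that donor's measured height-weight pair.  This preserves the donor's
measured-BMI marginal distribution while retaining the recipient's
geographic (state-level) variation.  Matching is on the self-reported
BMI rank by default; a joint (height-rank, weight-rank) variant is
available (see :class:`MatchConfig.match_on`).

Three mechanisms keep every recipient matchable:

* **dynamic subgroup loosening** — if a donor subgroup is smaller than a
  minimum sample size, its definition is coarsened step by step
  (collapse income, then race/ethnicity, then widen the age band one
  band on each side at a time); sex is never collapsed;
* **bandwidth expansion** — match eligibility starts at an exact rank
  tie (bandwidth zero) and the tolerance around the recipient's
  (height-rank, weight-rank) pair grows in fixed steps until at least
  one donor falls inside the box; the match is then drawn from eligible
  donors with probability proportional to their sample weight;
* **stochastic averaging** — matching is repeated (default 100
  iterations); a small multiplicative jitter (up to 1%) smooths the
  imputed values, and each record's corrected BMI is the mean of its
  per-iteration imputed BMIs.

Randomness is derived per record from the master seed and a stable hash
of the record id, so results do not depend on row order.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .survey import AGE_BANDS, RACE_CATEGORIES, DegenerateDatasetError, SurveyDataset
from .weighted import (WeightedSample, bmi, effective_n, weighted_draw,
                       weighted_prevalence)

__all__ = [
    "MatchConfig",
    "SubgroupKey",
    "DonorPool",
    "DonorIndex",
    "LooseningExhausted",
    "StatisticalMatchingModel",
    "MatchingResults",
    "index_donor_subgroups",
    "loosen",
    "apply_special_state_rule",
    "find_match",
    "impute_measured",
    "run_iteration",
    "correct_survey",
]

_RANK_TOL = 1e-12

RACE_ANY = "any"
RACE_ANY_NONBLACK = "any_nonblack"
INCOME_ANY = "any"


@dataclass(frozen=True)
class MatchConfig:
    """All the knobs of the matching algorithm.

    ``min_subgroup_size`` may be a single integer or a mapping from
    ``(sex, age_band)`` (or from ``sex``) to integers, supporting the
    age- and sex-specific thresholds selected by grid search.
    ``bandwidth_step`` is in rank units (0.005 = half a percentile
    point).  ``jitter_frac`` bounds the multiplicative smoothing noise
    applied to matched measured values (the default allows up to 1%).

    ``match_on`` selects the matching variable: ``"bmi"`` (default)
    matches on the percentile rank of self-reported BMI, a scalar
    equipercentile match that preserves the donor's measured-BMI
    marginal essentially exactly; ``"height_weight"`` matches jointly
    on the (height-rank, weight-rank) pair with a Chebyshev box.  The
    joint variant ties imputed values to both reported dimensions but,
    because a finite donor pool cannot cover the rank square, its
    nearest-donor geometry systematically contracts the imputed BMI
    distribution's tails toward the dense diagonal; the scalar default
    avoids that while still imputing each donor's (height, weight)
    *pair*, so the imputed height-weight covariance is the donor's.
    """

    min_subgroup_size: int | Mapping = 50
    bandwidth_step: float = 0.005
    jitter_frac: float = 0.01
    n_iterations: int = 100
    seed: int | None = None
    loosening_order: tuple[str, ...] = ("income", "race", "age")
    hawaii_rule: bool = True
    hawaii_state: str = "HI"
    keep_iterations: bool = False
    match_on: str = "bmi"

    def __post_init__(self) -> None:
        if self.match_on not in ("bmi", "height_weight"):
            raise ValueError("match_on must be 'bmi' or 'height_weight'")
        if not (0.0 <= self.jitter_frac <= 0.05):
            raise ValueError("jitter_frac must lie in [0, 0.05]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.bandwidth_step <= 0:
            raise ValueError("bandwidth_step must be positive")
        thresholds = ([self.min_subgroup_size]
                      if isinstance(self.min_subgroup_size, int)
                      else list(self.min_subgroup_size.values()))
        if any(int(t) < 1 for t in thresholds):
            raise ValueError("min_subgroup_size must be >= 1")
        if set(self.loosening_order) != {"income", "race", "age"}:
            raise ValueError("loosening_order must permute income/race/age")

    def threshold_for(self, sex: str, age_band: str) -> int:
        m = self.min_subgroup_size
        if isinstance(m, int):
            return m
        for key in ((sex, age_band), sex):
            if key in m:
                return int(m[key])
        raise KeyError(f"no subgroup-size threshold for {(sex, age_band)!r}")


@dataclass(frozen=True)
class SubgroupKey:
    """A demographic stratum at a given loosening level.

    The age dimension is a closed band-index range ``[age_lo, age_hi]``
    into :data:`~bmimatch.survey.AGE_BANDS`; race may be a category,
    ``"any"``, or ``"any_nonblack"`` (every pool except NH-Black, used
    by the Hawaii rule); income may be a band or ``"any"``.  Sex is
    never loosened.
    """

    sex: str
    age_lo: int
    age_hi: int
    race: str
    income: int | str
    loosen_level: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.age_lo <= self.age_hi < len(AGE_BANDS)):
            raise ValueError("age band range out of bounds")
        if self.race not in RACE_CATEGORIES + (RACE_ANY, RACE_ANY_NONBLACK):
            raise ValueError(f"bad race dimension: {self.race!r}")

    @classmethod
    def level0(cls, sex: str, age_band: str, race: str, income: int) -> "SubgroupKey":
        idx = AGE_BANDS.index(age_band)
        return cls(sex=sex, age_lo=idx, age_hi=idx, race=race, income=income)

    @property
    def region(self) -> tuple:
        """Cache key: the demographic region, ignoring the loosening level."""
        return (self.sex, self.age_lo, self.age_hi, self.race, self.income)

    @property
    def age_label(self) -> str:
        if self.age_lo == self.age_hi:
            return AGE_BANDS[self.age_lo]
        return f"{AGE_BANDS[self.age_lo]}..{AGE_BANDS[self.age_hi]}"

    @property
    def fully_loosened(self) -> bool:
        return (self.income == INCOME_ANY
                and self.race in (RACE_ANY, RACE_ANY_NONBLACK)
                and self.age_lo == 0 and self.age_hi == len(AGE_BANDS) - 1)

    def __str__(self) -> str:  # audit label
        return f"{self.sex}|{self.age_label}|{self.race}|{self.income}|L{self.loosen_level}"


class LooseningExhausted(RuntimeError):
    """A subgroup stayed below the size threshold at full loosening."""


def loosen(key: SubgroupKey, order: tuple[str, ...] = ("income", "race", "age")) -> SubgroupKey:
    """One coarsening move: the next key in the declared loosening order.

    Dimension moves earlier in ``order`` collapse first; the age move
    widens the band range by one adjacent band on each side and repeats
    until the full adult range is covered.  Sex never changes.  A key
    whose race is ``"any_nonblack"`` keeps that restriction (it encodes
    a deliberate pool exclusion, not a tight stratum).
    """
    if key.fully_loosened:
        raise LooseningExhausted(f"{key} cannot be loosened further")
    level = key.loosen_level + 1
    for move in order:
        if move == "income" and key.income != INCOME_ANY:
            return replace(key, income=INCOME_ANY, loosen_level=level)
        if move == "race" and key.race not in (RACE_ANY, RACE_ANY_NONBLACK):
            return replace(key, race=RACE_ANY, loosen_level=level)
        if move == "age" and (key.age_lo > 0 or key.age_hi < len(AGE_BANDS) - 1):
            return replace(key,
                           age_lo=max(0, key.age_lo - 1),
                           age_hi=min(len(AGE_BANDS) - 1, key.age_hi + 1),
                           loosen_level=level)
    raise LooseningExhausted(f"{key} cannot be loosened further")  # pragma: no cover


def apply_special_state_rule(key: SubgroupKey, state: str | None,
                             cfg: MatchConfig) -> SubgroupKey:
    """State-specific pooling rule for Hawaii.

    Recipients in the configured state whose race/ethnicity is a
    non-Black minority (Hispanic or Other) are matched across all races
    except NH-Black, so that the pool does not conflate distinct groups
    folded into "Other" while excluding the one population the rule is
    meant to protect against biasing.
    """
    if not cfg.hawaii_rule or state != cfg.hawaii_state:
        return key
    if key.race in ("hispanic", "other"):
        return replace(key, race=RACE_ANY_NONBLACK)
    return key


# --------------------------------------------------------------------------
# donor index


def _midranks(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted midrank of each element within its own sample."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    left = np.searchsorted(v, v, side="left")
    right = np.searchsorted(v, v, side="right")
    below = np.where(left > 0, cw[left - 1], 0.0)
    at = cw[right - 1] - below
    ranks_sorted = (below + 0.5 * at) / total
    out = np.empty_like(ranks_sorted)
    out[order] = ranks_sorted
    return out


@dataclass
class DonorPool:
    """A donor subgroup with precomputed self-report percentile ranks."""

    key: SubgroupKey
    indices: np.ndarray      # positions into the donor table
    weights: np.ndarray
    rank_h: np.ndarray       # weighted midranks of self height within pool
    rank_w: np.ndarray
    measured_h: np.ndarray
    measured_w: np.ndarray

    def __len__(self) -> int:
        return int(self.indices.size)


class DonorIndex:
    """Subgroup index over a donor survey.

    Pools are materialized lazily per demographic region and cached;
    ``resolve`` walks the loosening ladder from a level-0 key until the
    subgroup-size threshold is met.
    """

    def __init__(self, donor: SurveyDataset, cfg: MatchConfig):
        if donor.role != "donor":
            raise ValueError("DonorIndex requires a donor dataset")
        df = donor.records
        if len(df) == 0:
            raise DegenerateDatasetError("donor survey is empty")
        if df[["measured_height_cm", "measured_weight_kg"]].isna().any().any():
            raise ValueError("donor records must all carry measured values "
                             "(run apply_exclusions first)")
        self.cfg = cfg
        self._sex = df["sex"].to_numpy()
        self._band = df["age_band"].map(AGE_BANDS.index).to_numpy()
        self._race = df["race_ethnicity"].to_numpy()
        self._income = df["income_cat"].to_numpy(dtype=int)
        self._weight = df["sample_weight"].to_numpy(dtype=float)
        self._self_h = df["self_height_cm"].to_numpy(dtype=float)
        self._self_w = df["self_weight_kg"].to_numpy(dtype=float)
        self._self_bmi = bmi(self._self_h, self._self_w)
        self._meas_h = df["measured_height_cm"].to_numpy(dtype=float)
        self._meas_w = df["measured_weight_kg"].to_numpy(dtype=float)
        self.record_ids = df["record_id"].to_numpy()
        self._pools: dict[tuple, DonorPool] = {}

    def region_mask(self, key: SubgroupKey) -> np.ndarray:
        m = (self._sex == key.sex) & (self._band >= key.age_lo) & (self._band <= key.age_hi)
        if key.race == RACE_ANY_NONBLACK:
            m &= self._race != "nh_black"
        elif key.race != RACE_ANY:
            m &= self._race == key.race
        if key.income != INCOME_ANY:
            m &= self._income == key.income
        return m

    def pool(self, key: SubgroupKey) -> DonorPool:
        region = key.region
        cached = self._pools.get(region)
        if cached is not None:
            if cached.key.loosen_level != key.loosen_level:
                cached = replace(cached, key=key)
            return cached
        idx = np.flatnonzero(self.region_mask(key))
        w = self._weight[idx]
        if self.cfg.match_on == "bmi":
            rank_b = _midranks(self._self_bmi[idx], w) if idx.size else np.empty(0)
            rank_h = rank_w = rank_b
        else:
            rank_h = _midranks(self._self_h[idx], w) if idx.size else np.empty(0)
            rank_w = _midranks(self._self_w[idx], w) if idx.size else np.empty(0)
        pool = DonorPool(
            key=key, indices=idx, weights=w,
            rank_h=rank_h, rank_w=rank_w,
            measured_h=self._meas_h[idx], measured_w=self._meas_w[idx],
        )
        self._pools[region] = pool
        return pool

    def resolve(self, key: SubgroupKey) -> DonorPool:
        """Loosen ``key`` until the donor pool meets its size threshold.

        If loosening is exhausted the largest (sex-level) pool is used
        as-is with a warning; an empty sex-level pool is degenerate.
        """
        threshold = self.cfg.threshold_for(key.sex, AGE_BANDS[key.age_lo])
        current = key
        while True:
            pool = self.pool(current)
            if len(pool) >= threshold:
                return pool
            try:
                current = loosen(current, self.cfg.loosening_order)
            except LooseningExhausted:
                if len(pool) == 0:
                    raise DegenerateDatasetError(
                        f"no donors at all for subgroup {current}")
                warnings.warn(
                    f"subgroup {current} has only {len(pool)} donors "
                    f"(threshold {threshold}); using it as-is", stacklevel=2)
                return pool

    def level0_keys(self) -> list[tuple[SubgroupKey, int, bool]]:
        """Observed level-0 donor subgroups as (key, size, below-threshold)."""
        df = pd.DataFrame({"sex": self._sex, "band": self._band,
                           "race": self._race, "income": self._income})
        out = []
        for (sex, band, race, income), size in df.groupby(
                ["sex", "band", "race", "income"], sort=True).size().items():
            key = SubgroupKey(sex=sex, age_lo=int(band), age_hi=int(band),
                              race=race, income=int(income))
            thr = self.cfg.threshold_for(sex, AGE_BANDS[int(band)])
            out.append((key, int(size), size < thr))
        return out


def index_donor_subgroups(donor: SurveyDataset, cfg: MatchConfig) -> DonorIndex:
    """Build the lazy subgroup index over the donor survey."""
    return DonorIndex(donor, cfg)


# --------------------------------------------------------------------------
# record-level operations (the unit the exhaustive oracles test)


def _bandwidth_on_schedule(min_distance: float, step: float) -> float:
    """Smallest bandwidth on the 0, step, 2*step, ... schedule admitting
    a donor at Chebyshev rank distance ``min_distance``."""
    if min_distance <= _RANK_TOL:
        return 0.0
    return math.ceil((min_distance - _RANK_TOL) / step) * step


def find_match(rank_h: float, rank_w: float, pool: DonorPool,
               cfg: MatchConfig, rng: np.random.Generator) -> tuple[int, float]:
    """Match one recipient rank pair against a donor pool.

    Eligibility is a Chebyshev box: a donor qualifies when both its
    height rank and weight rank lie within ±bandwidth of the
    recipient's.  The bandwidth starts at zero and expands by
    ``cfg.bandwidth_step`` until at least one donor qualifies; the
    match is drawn weight-proportionally from the eligible set.

    Returns ``(position in donor table, final bandwidth)``.
    """
    if len(pool) == 0:
        raise DegenerateDatasetError("cannot match against an empty pool")
    cheb = np.maximum(np.abs(pool.rank_h - rank_h), np.abs(pool.rank_w - rank_w))
    bw = _bandwidth_on_schedule(float(cheb.min()), cfg.bandwidth_step)
    eligible = np.flatnonzero(cheb <= bw + _RANK_TOL)
    pick = weighted_draw(rng, pool.weights[eligible])
    return int(pool.indices[eligible[pick]]), bw


def impute_measured(measured_h: float, measured_w: float, cfg: MatchConfig,
                    rng: np.random.Generator) -> tuple[float, float]:
    """Jitter a matched donor's measured values.

    Independent multiplicative Uniform(-jitter_frac, +jitter_frac)
    perturbations on height and weight smooth the imputed distribution.
    """
    u = (2.0 * rng.random(2) - 1.0) * cfg.jitter_frac
    return float(measured_h * (1.0 + u[0])), float(measured_w * (1.0 + u[1]))


def _record_entropy(record_id: str) -> int:
    """Stable 64-bit stream key for a record id (row-order independent)."""
    digest = hashlib.blake2b(str(record_id).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little")


# --------------------------------------------------------------------------
# vectorized fitting machinery


@dataclass
class _Prepared:
    """Eligibility sets and audit fields, fixed across iterations."""

    n: int
    eligible_start: np.ndarray   # CSR offsets into eligible_idx / cumw
    eligible_idx: np.ndarray     # positions into the donor table
    eligible_cumw: np.ndarray    # per-record cumulative donor weights
    final_bandwidth: np.ndarray
    final_loosen_level: np.ndarray
    entropy: np.ndarray          # per-record stream keys
    donor_meas_h: np.ndarray
    donor_meas_w: np.ndarray
    donor_record_ids: np.ndarray


def _recipient_rank_frames(rec_df: pd.DataFrame, match_on: str = "bmi"):
    """Factory for cached per-region weighted rank lookups over the
    recipient survey."""
    sex = rec_df["sex"].to_numpy()
    band = rec_df["age_band"].map(AGE_BANDS.index).to_numpy()
    race = rec_df["race_ethnicity"].to_numpy()
    income = rec_df["income_cat"].to_numpy(dtype=int)
    w = rec_df["sample_weight"].to_numpy(dtype=float)
    if match_on == "bmi":
        self_bmi = bmi(rec_df["self_height_cm"].to_numpy(dtype=float),
                       rec_df["self_weight_kg"].to_numpy(dtype=float))
        self_h = self_w = self_bmi
    else:
        self_h = rec_df["self_height_cm"].to_numpy(dtype=float)
        self_w = rec_df["self_weight_kg"].to_numpy(dtype=float)
    cache: dict[tuple, tuple] = {}

    def region_mask(key: SubgroupKey) -> np.ndarray:
        m = (sex == key.sex) & (band >= key.age_lo) & (band <= key.age_hi)
        if key.race == RACE_ANY_NONBLACK:
            m &= race != "nh_black"
        elif key.race != RACE_ANY:
            m &= race == key.race
        if key.income != INCOME_ANY:
            m &= income == key.income
        return m

    def frame(key: SubgroupKey):
        region = key.region
        if region not in cache:
            m = region_mask(key)
            arrays = []
            for col in (self_h, self_w):
                v = col[m]
                order = np.argsort(v, kind="stable")
                sv = v[order]
                cw = np.cumsum(w[m][order])
                arrays.append((sv, cw))
            cache[region] = tuple(arrays)
        return cache[region]

    def ranks(key: SubgroupKey, members: np.ndarray):
        (svh, cwh), (svw, cww) = frame(key)
        out = []
        for sv, cw, col in ((svh, cwh, self_h), (svw, cww, self_w)):
            x = col[members]
            left = np.searchsorted(sv, x, side="left")
            right = np.searchsorted(sv, x, side="right")
            below = np.where(left > 0, cw[np.maximum(left - 1, 0)], 0.0)
            through = np.where(right > 0, cw[np.maximum(right - 1, 0)], 0.0)
            out.append((below + 0.5 * (through - below)) / cw[-1])
        return out


    return ranks


def _prepare(recipient: SurveyDataset, index: DonorIndex,
             cfg: MatchConfig) -> _Prepared:
    df = recipient.records
    n = len(df)
    if n == 0:
        raise DegenerateDatasetError("recipient survey is empty")

    states = (df["state"] if "state" in df.columns
              else pd.Series([None] * n)).to_numpy(dtype=object)
    race_eff = df["race_ethnicity"].to_numpy(dtype=object).copy()
    if cfg.hawaii_rule:
        in_state = states == cfg.hawaii_state
        minority = np.isin(race_eff, ("hispanic", "other"))
        race_eff[in_state & minority] = RACE_ANY_NONBLACK

    group_frame = pd.DataFrame({
        "sex": df["sex"].to_numpy(),
        "band": df["age_band"].map(AGE_BANDS.index).to_numpy(),
        "race": race_eff,
        "income": df["income_cat"].to_numpy(dtype=int),
    })
    rank_of = _recipient_rank_frames(df, cfg.match_on)

    counts = np.zeros(n, dtype=np.int64)
    elig_idx_parts: list[np.ndarray] = []
    elig_cumw_parts: list[np.ndarray] = []
    order_parts: list[np.ndarray] = []
    final_bw = np.empty(n)
    final_level = np.empty(n, dtype=np.int32)

    for (gsex, gband, grace, gincome), members in group_frame.groupby(
            ["sex", "band", "race", "income"], sort=True).groups.items():
        members = np.asarray(members)
        if grace == RACE_ANY_NONBLACK:
            key0 = SubgroupKey(sex=gsex, age_lo=int(gband), age_hi=int(gband),
                               race=RACE_ANY_NONBLACK, income=int(gincome))
        else:
            key0 = SubgroupKey.level0(gsex, AGE_BANDS[int(gband)], grace, int(gincome))
        pool = index.resolve(key0)
        rank_h, rank_w = rank_of(pool.key, members)

        cheb = np.maximum(np.abs(pool.rank_h[None, :] - rank_h[:, None]),
                          np.abs(pool.rank_w[None, :] - rank_w[:, None]))
        b_min = cheb.min(axis=1)
        steps = np.ceil(np.maximum(b_min - _RANK_TOL, 0.0) / cfg.bandwidth_step)
        bw = np.where(b_min <= _RANK_TOL, 0.0, steps * cfg.bandwidth_step)
        eligible = cheb <= bw[:, None] + _RANK_TOL

        final_bw[members] = bw
        final_level[members] = pool.key.loosen_level
        counts[members] = eligible.sum(axis=1)
        for i in range(members.size):
            cols = np.flatnonzero(eligible[i])
            elig_idx_parts.append(pool.indices[cols])
            elig_cumw_parts.append(np.cumsum(pool.weights[cols]))
            order_parts.append(members[i:i + 1])

    order = np.concatenate(order_parts)
    start = np.zeros(n + 1, dtype=np.int64)
    start[1:] = np.cumsum(counts)
    eligible_idx = np.empty(start[-1], dtype=np.int64)
    eligible_cumw = np.empty(start[-1])
    for rec, idx_arr, cumw_arr in zip(order, elig_idx_parts, elig_cumw_parts):
        s, e = start[rec], start[rec] + idx_arr.size
        eligible_idx[s:e] = idx_arr
        eligible_cumw[s:e] = cumw_arr

    entropy = np.fromiter((_record_entropy(r) for r in df["record_id"]),
                          dtype=np.uint64, count=n)
    return _Prepared(
        n=n, eligible_start=start, eligible_idx=eligible_idx,
        eligible_cumw=eligible_cumw, final_bandwidth=final_bw,
        final_loosen_level=final_level, entropy=entropy,
        donor_meas_h=index._meas_h, donor_meas_w=index._meas_w,
        donor_record_ids=index.record_ids,
    )


def _impute_all(prep: _Prepared, cfg: MatchConfig, master_seed: int,
                keep_donors: bool = False):
    """Draw matches and jittered BMIs for every record and iteration.

    Each record's random stream is seeded by (master seed, record-id
    hash); the stream is laid out as ``n_iterations`` match draws
    followed by the height and weight jitter draws, so iteration ``k``
    of any record is reproducible in isolation.
    """
    k = cfg.n_iterations
    j = cfg.jitter_frac
    n = prep.n
    bmis = np.empty((n, k))
    donor_pos = np.empty((n, k), dtype=np.int64) if keep_donors else None
    start = prep.eligible_start
    for i in range(n):
        s, e = start[i], start[i + 1]
        cumw = prep.eligible_cumw[s:e]
        gen = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([master_seed, int(prep.entropy[i])])))
        u = gen.random(3 * k)
        pick = np.searchsorted(cumw, u[:k] * cumw[-1], side="right")
        didx = prep.eligible_idx[s:e][pick]
        h = prep.donor_meas_h[didx] * (1.0 + (2.0 * u[k:2 * k] - 1.0) * j)
        w = prep.donor_meas_w[didx] * (1.0 + (2.0 * u[2 * k:] - 1.0) * j)
        bmis[i] = w / (h / 100.0) ** 2
        if keep_donors:
            donor_pos[i] = didx
    return bmis, donor_pos


def run_iteration(recipient: SurveyDataset, index: DonorIndex,
                  cfg: MatchConfig, seed: int, iteration: int = 0) -> np.ndarray:
    """One imputation pass: a single imputed BMI per recipient record.

    Equals column ``iteration`` of the full ``n_iterations`` run with
    the same master seed.
    """
    if not (0 <= iteration < cfg.n_iterations):
        raise ValueError("iteration out of range")
    prep = _prepare(recipient, index, cfg)
    bmis, _ = _impute_all(prep, cfg, int(seed))
    return bmis[:, iteration]


# --------------------------------------------------------------------------
# model / results


class StatisticalMatchingModel:
    """Percentile-rank statistical matching correction model.

    Parameters
    ----------
    recipient : SurveyDataset
        Survey to be corrected (self-reported anthropometry + state).
    donor : SurveyDataset
        Survey providing the self-reported-to-measured relationship.
    config : MatchConfig, optional
        Algorithm knobs; defaults follow the documented procedure
        (100 iterations, up to 1% jitter, minimum pool of 50 donors).

    ``fit`` imputes a corrected BMI for every recipient record and
    returns a :class:`MatchingResults`.
    """

    def __init__(self, recipient: SurveyDataset, donor: SurveyDataset,
                 config: MatchConfig | None = None):
        if recipient.role != "recipient" or donor.role != "donor":
            raise ValueError("expected (recipient, donor) dataset roles")
        self.recipient = recipient
        self.donor = donor
        self.config = config or MatchConfig()
        self.donor_index = DonorIndex(donor, self.config)

    @classmethod
    def from_frames(cls, recipient_df: pd.DataFrame, donor_df: pd.DataFrame,
                    config: MatchConfig | None = None) -> "StatisticalMatchingModel":
        return cls(SurveyDataset(records=recipient_df, role="recipient"),
                   SurveyDataset(records=donor_df, role="donor"), config)

    def fit(self, seed: int | None = None) -> "MatchingResults":
        cfg = self.config
        master = seed if seed is not None else (cfg.seed if cfg.seed is not None else 0)
        prep = _prepare(self.recipient, self.donor_index, cfg)
        bmis, donor_pos = _impute_all(prep, cfg, int(master),
                                      keep_donors=cfg.keep_iterations)

        df = self.recipient.records
        corrected = pd.DataFrame({
            "record_id": df["record_id"].to_numpy(),
            "state": df["state"].to_numpy() if "state" in df.columns else None,
            "sex": df["sex"].to_numpy(),
            "age_band": df["age_band"].to_numpy(),
            "race_ethnicity": df["race_ethnicity"].to_numpy(),
            "income_cat": df["income_cat"].to_numpy(),
            "sample_weight": df["sample_weight"].to_numpy(),
            "self_bmi": self.recipient.self_bmi(),
            "corrected_bmi": bmis.mean(axis=1),
            "final_loosen_level": prep.final_loosen_level,
            "final_bandwidth": prep.final_bandwidth,
        })
        per_iteration = bmis if cfg.keep_iterations else None
        matched_ids = (prep.donor_record_ids[donor_pos]
                       if cfg.keep_iterations else None)
        return MatchingResults(
            model=self, corrected=corrected, seed=int(master),
            per_iteration=per_iteration, matched_donor_ids=matched_ids,
            donor_reference=WeightedSample(self.donor.measured_bmi(),
                                           self.donor.records["sample_weight"].to_numpy()),
        )


@dataclass
class MatchingResults:
    """Corrected microdata and diagnostics from a matching fit."""

    model: StatisticalMatchingModel
    corrected: pd.DataFrame
    seed: int
    donor_reference: WeightedSample
    per_iteration: np.ndarray | None = None
    matched_donor_ids: np.ndarray | None = None

    @property
    def corrected_bmi(self) -> np.ndarray:
        return self.corrected["corrected_bmi"].to_numpy()

    @property
    def sample(self) -> WeightedSample:
        return WeightedSample(self.corrected_bmi,
                              self.corrected["sample_weight"].to_numpy())

    def prevalence(self, cutoff: float, corrected: bool = True):
        col = "corrected_bmi" if corrected else "self_bmi"
        s = WeightedSample(self.corrected[col].to_numpy(),
                           self.corrected["sample_weight"].to_numpy())
        return weighted_prevalence(s, cutoff)

    def mean_bmi(self, corrected: bool = True) -> float:
        col = "corrected_bmi" if corrected else "self_bmi"
        return float(np.average(self.corrected[col],
                                weights=self.corrected["sample_weight"]))

    def ks_vs_donor(self):
        from .validation import weighted_ks

        return weighted_ks(self.sample, self.donor_reference,
                           label="corrected vs donor measured")

    def state_table(self, cutoffs=(30.0, 35.0)) -> pd.DataFrame:
        from .validation import state_table

        return state_table(self.corrected, cutoffs=cutoffs)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Statistical matching correction",
            "=" * 47,
            f"recipient records: {len(self.corrected):>10d}",
            f"donor records:     {len(self.model.donor.records):>10d}",
            f"iterations:        {cfg.n_iterations:>10d}",
            f"jitter:            {cfg.jitter_frac:>10.3f}",
            f"seed:              {self.seed:>10d}",
            "-" * 47,
            f"mean BMI (self-reported): {self.mean_bmi(corrected=False):7.2f}",
            f"mean BMI (corrected):     {self.mean_bmi(corrected=True):7.2f}",
        ]
        for cutoff, name in ((30.0, "obesity"), (35.0, "severe obesity")):
            unc = self.prevalence(cutoff, corrected=False)
            cor = self.prevalence(cutoff, corrected=True)
            lines.append(
                f"{name} (BMI>={cutoff:.0f}): uncorrected "
                f"{100 * unc.prevalence:5.2f}%  corrected {100 * cor.prevalence:5.2f}% "
                f"({100 * cor.ci_low:.2f}-{100 * cor.ci_high:.2f})")
        ks = self.ks_vs_donor()
        lines += ["-" * 47,
                  f"KS vs donor measured BMI: D={ks.statistic:.4f}  p={ks.p_value:.3f}",
                  f"max loosening level: {int(self.corrected['final_loosen_level'].max())}",
                  f"median bandwidth:    {float(self.corrected['final_bandwidth'].median()):.4f}"]
        return "\n".join(lines)

    def plot_cdf(self, ax=None):
        """Weighted BMI ECDFs: self-reported, corrected, donor measured."""
        import matplotlib.pyplot as plt

        from .weighted import weighted_ecdf

        if ax is None:
            _, ax = plt.subplots()
        panels = [
            ("self-reported", WeightedSample(self.corrected["self_bmi"].to_numpy(),
                                             self.corrected["sample_weight"].to_numpy())),
            ("corrected", self.sample),
            ("donor measured", self.donor_reference),
        ]
        for label, s in panels:
            x, f = weighted_ecdf(s)
            ax.step(x, f, where="post", label=label)
        ax.set_xlabel("BMI (kg/m$^2$)")
        ax.set_ylabel("weighted CDF")
        ax.legend()
        return ax

    def to_frame(self) -> pd.DataFrame:
        return self.corrected.copy()

    def save(self, path) -> None:
        from .survey import _write_table
        from pathlib import Path

        _write_table(self.corrected, Path(path))


def correct_survey(recipient: SurveyDataset, donor: SurveyDataset,
                   cfg: MatchConfig | None = None,
                   seed: int | None = None) -> MatchingResults:
    """Functional entry point: fit the matching model in one call."""
    return StatisticalMatchingModel(recipient, donor, cfg).fit(seed=seed)
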