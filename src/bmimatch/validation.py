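"""Evaluation machinery for corrected surveys.

Design-aware prevalence comparisons (Pearson chi-square on Kish
effective counts), two-sample Kolmogorov-Smirnov tests on weighted
empirical CDFs, the grid search that tunes subgroup-size thresholds,
and the report/state-table builders.  Under equal weights every test
here reduces exactly to its unweighted textbook form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matching import MatchConfig, StatisticalMatchingModel
from .survey import SurveyDataset
from .weighted import (PrevalenceEstimate, WeightedSample, effective_n,
                       weighted_prevalence)

__all__ = [
    "TestResult",
    "chi2_prevalence",
    "weighted_ks",
    "GridSearchResult",
    "grid_search_thresholds",
    "evaluation_report",
    "state_table",
    "misclassified_count",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value and size information."""

    statistic: float
    p_value: float
    df: float | None = None
    n_eff: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")
        if self.statistic < 0:
            raise ValueError("statistic must be nonnegative")


def chi2_prevalence(a: PrevalenceEstimate, b: PrevalenceEstimate,
                    label: str = "") -> TestResult:
    """Pearson chi-square comparison of two prevalences (df = 1).

    The 2x2 table uses effective counts ``p * n_eff`` so that unequal
    sampling weights deflate the evidence appropriately; with equal
    weights this is the ordinary two-proportion chi-square test.
    """
    table = np.array([
        [a.prevalence * a.n_eff, (1 - a.prevalence) * a.n_eff],
        [b.prevalence * b.n_eff, (1 - b.prevalence) * b.n_eff],
    ])
    if np.any(table.sum(axis=1) <= 0) or np.any(table.sum(axis=0) <= 0):
        raise ValueError("degenerate 2x2 table: zero effective counts")
    n = table.sum()
    det = table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0]
    denom = table.sum(axis=1).prod() * table.sum(axis=0).prod()
    statistic = float(n * det**2 / denom)
    return TestResult(statistic=statistic,
                      p_value=float(stats.chi2.sf(statistic, df=1)),
                      df=1.0, n_eff=(a.n_eff, b.n_eff), label=label)


def weighted_ks(a: WeightedSample, b: WeightedSample, label: str = "") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test on weighted empirical CDFs.

    ``D`` is the supremum distance between the two weighted ECDFs; the
    p-value uses the asymptotic Kolmogorov distribution evaluated at
    ``sqrt(n_e) * D`` with the effective-size harmonic combination
    ``n_e = n_eff_a * n_eff_b / (n_eff_a + n_eff_b)``.
    """
    grid = np.union1d(a.values, b.values)

    def cdf(s: WeightedSample) -> np.ndarray:
        order = np.argsort(s.values, kind="stable")
        v, w = s.values[order], s.weights[order]
        cw = np.cumsum(w)
        idx = np.searchsorted(v, grid, side="right")
        return np.where(idx > 0, cw[np.maximum(idx - 1, 0)], 0.0) / cw[-1]

    d = float(np.max(np.abs(cdf(a) - cdf(b))))
    ne_a, ne_b = a.n_eff, b.n_eff
    en = ne_a * ne_b / (ne_a + ne_b)
    p = float(stats.kstwobign.sf(np.sqrt(en) * d))
    return TestResult(statistic=d, p_value=min(1.0, p),
                      n_eff=(ne_a, ne_b), label=label)


# --------------------------------------------------------------------------
# threshold grid search


@dataclass
class GridSearchResult:
    """Per-candidate, per-cell KS distances and the selected thresholds.

    ``objective`` maps each candidate threshold to the maximum KS
    distance over sex/age cells; ``selected_global`` minimizes that
    objective (ties toward the smaller threshold).  ``selected`` gives
    the per-cell argmin thresholds, usable directly as the sex/age-
    specific ``min_subgroup_size`` map of a :class:`MatchConfig`.
    """

    d_table: pd.DataFrame            # columns: candidate, sex, age_band, d
    objective: dict[int, float]
    selected_global: int
    selected: dict[tuple, int] = field(default_factory=dict)


def _cell_ks(corrected: pd.DataFrame, donor: SurveyDataset,
             cells: Sequence[str] = ("sex", "age_band"),
             min_cell: int = 10) -> pd.DataFrame:
    """Weighted KS distance per demographic cell, corrected vs donor."""
    d_bmi = donor.measured_bmi()
    ddf = donor.records
    rows = []
    for cell, ridx in corrected.groupby(list(cells)).groups.items():
        dmask = np.ones(len(ddf), dtype=bool)
        for col, val in zip(cells, cell):
            dmask &= (ddf[col] == val).to_numpy()
        if dmask.sum() < min_cell or len(ridx) < min_cell:
            continue
        a = WeightedSample(corrected.loc[ridx, "corrected_bmi"].to_numpy(),
                           corrected.loc[ridx, "sample_weight"].to_numpy())
        b = WeightedSample(d_bmi[dmask],
                           ddf["sample_weight"].to_numpy()[dmask])
        res = weighted_ks(a, b)
        rows.append(dict(zip(cells, cell)) | {"d": res.statistic,
                                              "p_value": res.p_value})
    return pd.DataFrame(rows)


def grid_search_thresholds(donor: SurveyDataset, recipient: SurveyDataset,
                           candidates: Sequence[int],
                           cfg: MatchConfig | None = None,
                           eval_iterations: int = 5,
                           seed: int = 0) -> GridSearchResult:
    """Tune the minimum-subgroup-size threshold by distribution distance.

    Each candidate threshold is evaluated by running the matching
    correction at a reduced iteration count and measuring the weighted
    KS distance between corrected recipient BMI and donor measured BMI
    within each sex/age cell.  The global selection minimizes the
    maximum distance over cells; per-cell selections minimize each
    cell's own distance.  Ties break toward the smaller threshold.
    """
    if len(candidates) == 0:
        raise ValueError("candidate grid is empty")
    cfg = cfg or MatchConfig()
    frames = []
    for cand in sorted(int(c) for c in candidates):
        run_cfg = MatchConfig(
            min_subgroup_size=cand, bandwidth_step=cfg.bandwidth_step,
            jitter_frac=cfg.jitter_frac, n_iterations=eval_iterations,
            loosening_order=cfg.loosening_order, hawaii_rule=cfg.hawaii_rule,
            hawaii_state=cfg.hawaii_state)
        res = StatisticalMatchingModel(recipient, donor, run_cfg).fit(seed=seed)
        cell_d = _cell_ks(res.corrected, donor)
        cell_d.insert(0, "candidate", cand)
        frames.append(cell_d)
    d_table = pd.concat(frames, ignore_index=True)

    objective = {int(c): float(g["d"].max())
                 for c, g in d_table.groupby("candidate")}
    best = min(objective, key=lambda c: (objective[c], c))
    selected: dict[tuple, int] = {}
    for cell, g in d_table.groupby(["sex", "age_band"]):
        g = g.sort_values("candidate")
        row = g.loc[g["d"].idxmin()]
        selected[cell] = int(row["candidate"])
    # cells too small to measure a distance fall back to the global choice
    from .survey import AGE_BANDS, SEXES

    for sex in SEXES:
        for band in AGE_BANDS:
            selected.setdefault((sex, band), best)
    return GridSearchResult(d_table=d_table, objective=objective,
                            selected_global=best, selected=selected)


# --------------------------------------------------------------------------
# reporting


def _prevalence_of(df: pd.DataFrame, col: str, cutoff: float) -> PrevalenceEstimate:
    return weighted_prevalence(
        WeightedSample(df[col].to_numpy(), df["sample_weight"].to_numpy()), cutoff)


def evaluation_report(corrected_by_method: Mapping[str, pd.DataFrame],
                      reference: SurveyDataset,
                      cutoffs: Sequence[float] = (30.0, 35.0),
                      strata: Sequence[Sequence[str]] = ((), ("sex",)),
                      ks_cells: Sequence[str] = ("sex", "age_band")
                      ) -> dict[str, pd.DataFrame]:
    """Side-by-side comparison of corrected sets against the donor survey.

    Returns ``{"prevalence": ..., "ks": ...}``.  The prevalence table
    has one row per method x stratum x cutoff with the weighted
    prevalence, its CI, and the chi-square comparison against the donor
    reference; the KS table has the per-cell distribution distances.
    """
    if not corrected_by_method:
        raise ValueError("need at least one corrected dataset")
    d_bmi = reference.measured_bmi()
    ddf = reference.records

    prev_rows = []
    for level in strata:
        level = tuple(level)
        groups = ([((), slice(None), np.ones(len(ddf), dtype=bool))] if not level
                  else None)
        for cutoff in cutoffs:
            if groups is None:
                cells = set()
                for df in corrected_by_method.values():
                    cells |= set(df.groupby(list(level)).groups)
                iter_groups = []
                for cell in sorted(cells):
                    cell_t = cell if isinstance(cell, tuple) else (cell,)
                    dmask = np.ones(len(ddf), dtype=bool)
                    for col, val in zip(level, cell_t):
                        dmask &= (ddf[col] == val).to_numpy()
                    iter_groups.append((cell_t, cell_t, dmask))
            else:
                iter_groups = groups
            for cell_label, cell_sel, dmask in iter_groups:
                if dmask.sum() == 0:
                    continue
                ref_est = weighted_prevalence(
                    WeightedSample(d_bmi[dmask],
                                   ddf["sample_weight"].to_numpy()[dmask]), cutoff)
                stratum_name = "overall" if not level else \
                    "/".join(str(v) for v in cell_label)
                prev_rows.append({
                    "method": "reference", "stratum": stratum_name,
                    "cutoff": cutoff, "prevalence": ref_est.prevalence,
                    "ci_low": ref_est.ci_low, "ci_high": ref_est.ci_high,
                    "chi2": 0.0, "p_value": 1.0, "n_eff": ref_est.n_eff})
                for method, df in corrected_by_method.items():
                    sub = df
                    if level:
                        m = np.ones(len(df), dtype=bool)
                        for col, val in zip(level, cell_label):
                            m &= (df[col] == val).to_numpy()
                        sub = df[m]
                        if len(sub) == 0:
                            continue
                    est = _prevalence_of(sub, "corrected_bmi", cutoff)
                    test = chi2_prevalence(est, ref_est,
                                           label=f"{method} vs reference")
                    prev_rows.append({
                        "method": method, "stratum": stratum_name,
                        "cutoff": cutoff, "prevalence": est.prevalence,
                        "ci_low": est.ci_low, "ci_high": est.ci_high,
                        "chi2": test.statistic, "p_value": test.p_value,
                        "n_eff": est.n_eff})

    ks_frames = []
    for method, df in corrected_by_method.items():
        cell_d = _cell_ks(df, reference, cells=ks_cells)
        cell_d.insert(0, "method", method)
        ks_frames.append(cell_d)
    return {"prevalence": pd.DataFrame(prev_rows),
            "ks": pd.concat(ks_frames, ignore_index=True)}


def state_table(corrected: pd.DataFrame,
                cutoffs: Sequence[float] = (30.0, 35.0)) -> pd.DataFrame:
    """Survey-weighted prevalence with CI per state and cutoff.

    One row per state; per-cutoff prevalence/CI columns, plus the
    record count and effective sample size — a map-ready export.
    """
    if "state" not in corrected.columns or corrected["state"].isna().all():
        raise ValueError("corrected data carries no state codes")
    rows = []
    for state, sub in corrected.groupby("state"):
        if len(sub) == 0:  # pragma: no cover - groupby never yields empties
            warnings.warn(f"state {state} has no records; omitted")
            continue
        row = {"state": state, "n": len(sub),
               "n_eff": effective_n(sub["sample_weight"].to_numpy())}
        for cutoff in cutoffs:
            est = _prevalence_of(sub, "corrected_bmi", cutoff)
            tag = f"{cutoff:g}"
            row[f"prev_{tag}"] = est.prevalence
            row[f"ci_low_{tag}"] = est.ci_low
            row[f"ci_high_{tag}"] = est.ci_high
        rows.append(row)
    return pd.DataFrame(rows).sort_values("state").reset_index(drop=True)


def misclassified_count(prev_a: float, prev_b: float, population: float) -> float:
    """People misclassified by the prevalence gap: ``|p_a - p_b| * N``."""
    if population <= 0:
        raise ValueError("population must be positive")
    return abs(prev_a - prev_b) * population
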