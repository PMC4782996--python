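"""Survey microdata model, file I/O, harmonization and exclusion filtering.

A :class:`SurveyDataset` wraps one respondent-per-row table in one of two
roles: the *donor* survey carries both self-reported and measured height
and weight (an examination survey such as NHANES), while the *recipient*
survey carries self-reported values only, plus a state code (a telephone
survey such as BRFSS).  Race/ethnicity and household income are recoded
through a user-supplied :class:`Crosswalk` so that both surveys share
harmonized category definitions; age arrives as 5-year bands and is
assigned the band midpoint.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BANDS",
    "RACE_CATEGORIES",
    "SEXES",
    "Crosswalk",
    "PersonRecord",
    "SurveyDataset",
    "SchemaError",
    "CrosswalkError",
    "DegenerateDatasetError",
    "age_midpoint",
    "age_band_of",
    "load_survey",
    "apply_exclusions",
    "write_survey",
]

SEXES = ("male", "female")
RACE_CATEGORIES = ("nh_white", "nh_black", "hispanic", "other")

#: Harmonized 5-year age bands; the lowest band pools ages 18-24 and the
#: top band is top-coded at 80.
AGE_BANDS = (
    "18-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

#: Default harmonized income bands (ordinal, low to high).
INCOME_BANDS = (1, 2, 3, 4, 5)

# Plausibility bounds: wide enough to only reject data-entry
# impossibilities, overridable at load time.
HEIGHT_BOUNDS_CM = (122.0, 241.0)
WEIGHT_BOUNDS_KG = (30.0, 295.0)

REQUIRED_COLUMNS = (
    "record_id", "sex", "age_band", "race_ethnicity", "income_cat",
    "sample_weight", "self_height_cm", "self_weight_kg",
)
DONOR_COLUMNS = ("measured_height_cm", "measured_weight_kg")


class SchemaError(ValueError):
    """A required column is missing from the input schema."""


class CrosswalkError(ValueError):
    """A source race or income code has no harmonized mapping."""


class DegenerateDatasetError(ValueError):
    """Filtering left no usable records."""


def _normalize_band(band: str) -> str:
    return str(band).strip().replace("–", "-").replace("—", "-")


def age_midpoint(band: str) -> float:
    """Arithmetic midpoint of a 5-year age band; "80+" maps to 80.0."""
    b = _normalize_band(band)
    if b not in AGE_BANDS:
        raise ValueError(f"unrecognized age band: {band!r}")
    if b.endswith("+"):
        return float(b[:-1])
    lo, hi = b.split("-")
    return (float(lo) + float(hi)) / 2.0


def age_band_of(age_years: float) -> str:
    """Harmonized band containing an age in years (top-coded at 80)."""
    a = float(age_years)
    if a < 18:
        raise ValueError("adult surveys cover ages 18 and older")
    if a >= 80:
        return "80+"
    if a < 25:
        return "18-24"
    lo = int(a // 5) * 5
    return f"{lo}-{lo + 4}"


@dataclass(frozen=True)
class Crosswalk:
    """Recoding maps from source survey codes to harmonized categories.

    The maps must be total over the codes that appear in the data:
    an unmapped code is a load error, never silently passed through.
    Harmonized values map to themselves so that already-harmonized
    files load under any crosswalk.
    """

    race_map: Mapping[object, str] = field(default_factory=dict)
    income_map: Mapping[object, int] = field(default_factory=dict)

    def harmonize_race(self, codes: pd.Series) -> pd.Series:
        return self._apply(codes, dict(self.race_map), set(RACE_CATEGORIES), "race")

    def harmonize_income(self, codes: pd.Series) -> pd.Series:
        out = self._apply(codes, dict(self.income_map), set(INCOME_BANDS), "income")
        return out.astype(int)

    @staticmethod
    def _apply(codes: pd.Series, mapping: dict, harmonized: set, what: str) -> pd.Series:
        def convert(c):
            if c in harmonized:
                return c
            if c in mapping:
                return mapping[c]
            if isinstance(c, str):
                stripped = c.strip()
                if stripped in mapping:
                    return mapping[stripped]
                # CSV round-trips turn numeric codes into strings
                try:
                    as_int = int(stripped)
                except ValueError:
                    pass
                else:
                    if as_int in harmonized:
                        return as_int
                    if as_int in mapping:
                        return mapping[as_int]
            raise CrosswalkError(f"unmapped {what} code: {c!r}")

        return codes.map(convert)

    @classmethod
    def default(cls) -> "Crosswalk":
        """Documented default crosswalk.

        Folds detailed race codes into the four harmonized categories
        (all non-Black, non-White, non-Hispanic groups into ``other``)
        and maps common income band labels onto five ordinal bands.
        These defaults are placeholders for survey-specific recodes and
        should be overridden with a survey's own codebook.
        """
        race = {
            "white": "nh_white", "nh-white": "nh_white",
            "black": "nh_black", "nh-black": "nh_black",
            "mexican_american": "hispanic", "other_hispanic": "hispanic",
            "asian": "other", "american_indian_alaska_native": "other",
            "native_hawaiian_pacific_islander": "other",
            "multiracial": "other", "two_or_more": "other",
        }
        income = {
            "<15k": 1, "15-25k": 2, "25-35k": 3, "35-50k": 4, ">=50k": 5,
            "lt15": 1, "15to25": 2, "25to35": 3, "35to50": 4, "ge50": 5,
        }
        return cls(race_map=race, income_map=income)

    @classmethod
    def from_yaml(cls, path) -> "Crosswalk":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(race_map=raw.get("race_map", {}), income_map=raw.get("income_map", {}))


@dataclass(frozen=True)
class PersonRecord:
    """One survey respondent (convenience view of a dataset row)."""

    record_id: str
    sex: str
    age_band: str
    age_years: float
    race_ethnicity: str
    income_cat: int
    sample_weight: float
    self_height_cm: float
    self_weight_kg: float
    measured_height_cm: float | None = None
    measured_weight_kg: float | None = None
    state: str | None = None
    pregnant: bool = False


@dataclass
class SurveyDataset:
    """A weighted respondent table with a donor or recipient role.

    ``records`` is a :class:`pandas.DataFrame` with the harmonized
    column schema; donor datasets carry measured anthropometry columns,
    recipient datasets carry a ``state`` column instead.
    """

    records: pd.DataFrame
    role: str
    years: str = ""
    weight_normalization: float = 1.0
    load_report: dict = field(default_factory=dict)
    exclusion_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("donor", "recipient"):
            raise ValueError("role must be 'donor' or 'recipient'")
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if self.role == "donor":
            missing = [c for c in DONOR_COLUMNS if c not in df.columns]
            if missing:
                raise SchemaError(f"donor dataset missing measured columns: {missing}")
        if len(df) and df["record_id"].duplicated().any():
            raise ValueError("record_ids must be unique")
        if len(df) and not (df["sample_weight"] > 0).all():
            raise ValueError("sample weights must be strictly positive")
        if "age_years" not in df.columns:
            df = df.copy()
            df["age_years"] = df["age_band"].map(age_midpoint)
            self.records = df
        if "pregnant" not in self.records.columns:
            self.records = self.records.assign(pregnant=False)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_weight(self) -> float:
        return float(self.records["sample_weight"].sum())

    def self_bmi(self) -> np.ndarray:
        from .weighted import bmi

        return bmi(self.records["self_height_cm"].to_numpy(),
                   self.records["self_weight_kg"].to_numpy())

    def measured_bmi(self) -> np.ndarray:
        if self.role != "donor":
            raise ValueError("measured BMI is only available for donor datasets")
        from .weighted import bmi

        return bmi(self.records["measured_height_cm"].to_numpy(),
                   self.records["measured_weight_kg"].to_numpy())

    def iter_records(self):
        for row in self.records.itertuples(index=False):
            yield PersonRecord(
                record_id=str(row.record_id), sex=row.sex, age_band=row.age_band,
                age_years=row.age_years, race_ethnicity=row.race_ethnicity,
                income_cat=int(row.income_cat), sample_weight=row.sample_weight,
                self_height_cm=row.self_height_cm, self_weight_kg=row.self_weight_kg,
                measured_height_cm=getattr(row, "measured_height_cm", None),
                measured_weight_kg=getattr(row, "measured_weight_kg", None),
                state=getattr(row, "state", None),
                pregnant=bool(getattr(row, "pregnant", False)),
            )


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".parquet", ".pq"):
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    if path.suffix.lower() in (".parquet", ".pq"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def load_survey(path, schema: Mapping[str, str] | None, role: str,
                crosswalk: Crosswalk | None = None,
                height_bounds: tuple[float, float] = HEIGHT_BOUNDS_CM,
                weight_bounds: tuple[float, float] = WEIGHT_BOUNDS_KG,
                years: str = "", weight_normalization: float = 1.0) -> SurveyDataset:
    """Load, harmonize and bound-check a survey file.

    Parameters
    ----------
    path:
        CSV or parquet file, one row per respondent.
    schema:
        Mapping from harmonized column names to the file's column names
        (``None`` or missing entries mean the file already uses the
        harmonized name).
    role:
        ``"donor"`` (requires measured columns) or ``"recipient"``.
    crosswalk:
        Race/income recoding maps; defaults to :meth:`Crosswalk.default`.
    weight_normalization:
        Factor dividing each sample weight, used when pooling survey
        cycles (e.g. 3 when pooling three 2-year cycles).

    Rows outside the height/weight plausibility bounds are rejected and
    counted per reason in ``load_report``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    crosswalk = crosswalk or Crosswalk.default()
    raw = _read_table(path)

    schema = dict(schema or {})
    rename = {src: harm for harm, src in schema.items() if src is not None and src in raw.columns}
    for harm, src in schema.items():
        if src is not None and src not in raw.columns:
            raise SchemaError(f"schema names column {src!r} for {harm!r}, not found in file")
    df = raw.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns for role {role!r}: {missing}")
    if role == "donor":
        missing = [c for c in DONOR_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"donor file missing measured columns: {missing}")
    if role == "recipient":
        stray = [c for c in DONOR_COLUMNS if c in df.columns]
        if stray:
            warnings.warn(
                f"recipient file carries measured columns {stray}; ignoring them",
                stacklevel=2,
            )
            df = df.drop(columns=stray)

    keep = list(REQUIRED_COLUMNS) + (list(DONOR_COLUMNS) if role == "donor" else [])
    for opt in ("state", "pregnant", "age_years", "stratum", "psu"):
        if opt in df.columns:
            keep.append(opt)
    df = df[keep].copy()

    df["age_band"] = df["age_band"].map(_normalize_band)
    bad_band = ~df["age_band"].isin(AGE_BANDS) & df["age_band"].notna()
    if bad_band.any():
        raise ValueError(f"unrecognized age bands: {sorted(df.loc[bad_band, 'age_band'].unique())}")
    df["race_ethnicity"] = crosswalk.harmonize_race(df["race_ethnicity"])
    df["income_cat"] = crosswalk.harmonize_income(df["income_cat"])
    df["record_id"] = df["record_id"].astype(str)
    if "pregnant" in df.columns:
        df["pregnant"] = df["pregnant"].fillna(False).astype(bool)

    report: dict[str, int] = {"input_rows": len(df)}
    anthro = ["self_height_cm", "self_weight_kg"]
    if role == "donor":
        anthro += list(DONOR_COLUMNS)
    out_of_bounds = pd.Series(False, index=df.index)
    for col in anthro:
        x = df[col]
        lo, hi = height_bounds if "height" in col else weight_bounds
        out_of_bounds |= x.notna() & ((x < lo) | (x > hi))
    report["rejected_out_of_bounds"] = int(out_of_bounds.sum())
    df = df[~out_of_bounds]

    df = df.copy()
    df["sample_weight"] = df["sample_weight"] / float(weight_normalization)
    report["kept_rows"] = len(df)

    ds = SurveyDataset(records=df.reset_index(drop=True), role=role, years=years,
                       weight_normalization=float(weight_normalization))
    ds.load_report = report
    return ds


def apply_exclusions(ds: SurveyDataset) -> SurveyDataset:
    """Drop pregnant respondents and records with missing analysis fields.

    Donor records must carry both measured height and weight; the
    per-reason exclusion counts are stored in ``exclusion_report``.
    Idempotent: applying it twice changes nothing.
    """
    df = ds.records
    report: dict[str, int] = {"input_rows": len(df)}

    pregnant = df["pregnant"].fillna(False).astype(bool)
    needed = ["sex", "age_band", "race_ethnicity", "income_cat", "sample_weight",
              "self_height_cm", "self_weight_kg"]
    if ds.role == "donor":
        needed += list(DONOR_COLUMNS)
    missing = df[needed].isna().any(axis=1)
    bad_cat = ~df["sex"].isin(SEXES) | ~df["race_ethnicity"].isin(RACE_CATEGORIES)

    report["pregnant"] = int((pregnant & ~missing & ~bad_cat).sum())
    report["missing"] = int(missing.sum())
    report["invalid_category"] = int((bad_cat & ~missing).sum())
    kept = df[~pregnant & ~missing & ~bad_cat].reset_index(drop=True)
    report["kept_rows"] = len(kept)
    if len(kept) == 0:
        raise DegenerateDatasetError("no records remain after exclusions")

    out = SurveyDataset(records=kept, role=ds.role, years=ds.years,
                        weight_normalization=ds.weight_normalization)
    out.load_report = dict(ds.load_report)
    out.exclusion_report = report
    return out


def write_survey(ds: SurveyDataset, path, report_path=None) -> None:
    """Write the harmonized table (CSV/parquet) and optional JSON report."""
    _write_table(ds.records, Path(path))
    if report_path is not None:
        payload = {
            "role": ds.role,
            "years": ds.years,
            "weight_normalization": ds.weight_normalization,
            "load_report": ds.load_report,
            "exclusion_report": ds.exclusion_report,
        }
        Path(report_path).write_text(json.dumps(payload, indent=2))


def read_survey(path, role: str, **kwargs) -> SurveyDataset:
    """Reload a previously harmonized table (round-trip of write_survey)."""
    return load_survey(path, schema=None, role=role, **kwargs)
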