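"""End-to-end orchestration: simulate/load, correct, evaluate, report.

``run_pipeline`` drives the full correction workflow from a
:class:`RunConfig` and writes every artifact plus a JSON manifest with
checksums, so a run is reproducible and auditable from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .comparators import AggregateAlignmentCorrection, IndividualRegressionCorrection
from .matching import MatchConfig, StatisticalMatchingModel
from .simulate import PopulationSpec, generate
from .survey import Crosswalk, apply_exclusions, load_survey, write_survey
from .validation import evaluation_report, state_table

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("bmimatch")

METHODS = ("matching", "indiv-reg", "agg-reg")


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    With ``donor_path``/``recipient_path`` unset, a synthetic survey
    pair is generated from ``population`` (sizes ``n_donor`` /
    ``n_recipient``); otherwise the files are loaded through the given
    schemas and crosswalk.  ``methods`` selects which corrections run.
    """

    out_dir: str = "bmimatch_out"
    seed: int = 0
    methods: Sequence[str] = METHODS
    cutoffs: Sequence[float] = (30.0, 35.0)
    match_config: MatchConfig = field(default_factory=MatchConfig)

    donor_path: str | None = None
    recipient_path: str | None = None
    donor_schema: Mapping[str, str] | None = None
    recipient_schema: Mapping[str, str] | None = None
    crosswalk_path: str | None = None

    population: PopulationSpec = field(default_factory=PopulationSpec)
    n_donor: int = 5_000
    n_recipient: int = 50_000

    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        cutoffs = list(self.cutoffs)
        if sorted(set(cutoffs)) != cutoffs:
            raise ValueError("cutoffs must be strictly increasing")
        for path in (self.donor_path, self.recipient_path, self.crosswalk_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "match_config" in raw:
            raw["match_config"] = MatchConfig(**raw["match_config"])
        if "population" in raw:
            raw["population"] = PopulationSpec(**raw["population"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _obtain_surveys(cfg: RunConfig, out: Path):
    if cfg.donor_path and cfg.recipient_path:
        crosswalk = (Crosswalk.from_yaml(cfg.crosswalk_path)
                     if cfg.crosswalk_path else Crosswalk.default())
        donor = apply_exclusions(load_survey(
            cfg.donor_path, cfg.donor_schema, "donor", crosswalk))
        recipient = apply_exclusions(load_survey(
            cfg.recipient_path, cfg.recipient_schema, "recipient", crosswalk))
        log.info("loaded donor (%d) and recipient (%d) records",
                 len(donor), len(recipient))
        return donor, recipient, None
    log.info("simulating donor (n=%d) and recipient (n=%d), seed=%d",
             cfg.n_donor, cfg.n_recipient, cfg.seed)
    donor, recipient, truth = generate(cfg.population, cfg.n_donor,
                                       cfg.n_recipient, seed=cfg.seed)
    truth.records.to_csv(out / "truth.csv", index=False)
    return donor, recipient, truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Run simulate/load -> correct -> validate -> report; return the manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    donor, recipient, truth = _obtain_surveys(cfg, out)
    write_survey(donor, out / "donor.csv", out / "donor_report.json")
    write_survey(recipient, out / "recipient.csv", out / "recipient_report.json")
    for name in ("donor.csv", "donor_report.json", "recipient.csv",
                 "recipient_report.json"):
        artifacts[name] = _sha256(out / name)
    if truth is not None:
        artifacts["truth.csv"] = _sha256(out / "truth.csv")

    corrected = {}
    if "matching" in cfg.methods:
        log.info("running statistical matching (%d iterations)",
                 cfg.match_config.n_iterations)
        res = StatisticalMatchingModel(recipient, donor,
                                       cfg.match_config).fit(seed=cfg.seed)
        corrected["matching"] = res.corrected
        (out / "summary_matching.txt").write_text(res.summary() + "\n")
        artifacts["summary_matching.txt"] = _sha256(out / "summary_matching.txt")
    if "indiv-reg" in cfg.methods:
        log.info("running individual-level regression correction")
        corrected["indiv-reg"] = IndividualRegressionCorrection(
            recipient, donor).fit().corrected
    if "agg-reg" in cfg.methods:
        log.info("running aggregate-level alignment correction")
        corrected["agg-reg"] = AggregateAlignmentCorrection(
            recipient, donor).fit().corrected

    for method, df in corrected.items():
        name = f"corrected_{method}.csv"
        df.to_csv(out / name, index=False)
        artifacts[name] = _sha256(out / name)

    report = evaluation_report(corrected, donor, cutoffs=cfg.cutoffs)
    report["prevalence"].to_csv(out / "report_prevalence.csv", index=False)
    report["ks"].to_csv(out / "report_ks.csv", index=False)
    artifacts["report_prevalence.csv"] = _sha256(out / "report_prevalence.csv")
    artifacts["report_ks.csv"] = _sha256(out / "report_ks.csv")

    if "matching" in corrected and corrected["matching"]["state"].notna().any():
        st = state_table(corrected["matching"], cutoffs=cfg.cutoffs)
        st.to_csv(out / "state_table.csv", index=False)
        artifacts["state_table.csv"] = _sha256(out / "state_table.csv")

    manifest = {
        "seed": cfg.seed,
        "methods": list(cfg.methods),
        "cutoffs": list(cfg.cutoffs),
        "n_donor": len(donor),
        "n_recipient": len(recipient),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote %d artifacts to %s", len(artifacts), out)
    return manifest
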