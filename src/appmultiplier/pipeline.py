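"""Provincial pipeline: count -> estimate -> diagnose -> select -> multiply.

One configuration drives a full provincial run and produces a report bundle
(JSON report, a CSV row mirroring the provincial summary-table columns, and
a run manifest with the parameters and seed).  Unreliable stages propagate
their flags into the report instead of aborting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
import yaml

from . import __version__ as _pkg_version
from ._utils import to_json
from .counting import ActivityLog, capture_recapture_count, dedup_count, provider_count
from .diagnostics import diagnose, select_estimator, sensitivity_check
from .errors import EstimationError
from .io import read_rds_survey, write_json
from .multiplier import (
    MultiplierEstimate,
    multiplier_estimate,
    ss_multiplier_fixed_point,
    summary_table,
)
from .rds import giles_ss_proportion, rds_i_proportion

__all__ = ["PipelineConfig", "ProvincialReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one provincial pipeline run."""

    province: str
    survey_path: str
    out_dir: str
    # numerator source: exactly one of the three
    activity_log_path: str | None = None
    provider_count_value: int | None = None
    capture_paths: tuple[str, str] | None = None
    # estimation settings
    trait: str = "app_30d"
    population_size_prior: int | None = None  # None -> SS/multiplier fixed point
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    tol: float = 0.02
    window_frac: float = 0.25
    sensitivity_bounds: tuple[float, float] = (0.2, 0.8)
    min_appearances: int = 2
    min_spacing_days: int = 3
    ss_sim_reps: int = 200

    def __post_init__(self) -> None:
        sources = [
            self.activity_log_path is not None,
            self.provider_count_value is not None,
            self.capture_paths is not None,
        ]
        if sum(sources) != 1:
            raise ValueError("exactly one count source must be configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "capture_paths" in d and d["capture_paths"] is not None:
            d["capture_paths"] = tuple(d["capture_paths"])
        if "sensitivity_bounds" in d and d["sensitivity_bounds"] is not None:
            d["sensitivity_bounds"] = tuple(d["sensitivity_bounds"])
        return cls(**d)


@dataclass
class ProvincialReport:
    province: str
    estimate: MultiplierEstimate
    selected_estimator: str
    selection_rationale: str
    diagnostics: dict
    count: dict
    proportions: dict
    sensitive: bool
    reliable: bool
    rng_seed: int
    notes: str = ""


def _count_from_config(cfg: PipelineConfig):
    if cfg.provider_count_value is not None:
        return provider_count(cfg.provider_count_value)
    if cfg.activity_log_path is not None:
        log = ActivityLog.from_csv(cfg.activity_log_path)
        return dedup_count(log, cfg.min_appearances, cfg.min_spacing_days)
    c1 = set(Path(cfg.capture_paths[0]).read_text().split())
    c2 = set(Path(cfg.capture_paths[1]).read_text().split())
    return capture_recapture_count(c1, c2, correction="chapman")


def run_pipeline(config: PipelineConfig) -> ProvincialReport:
    """Execute the full provincial pipeline and write the report bundle.

    Reruns with identical config and seed produce byte-identical artifacts
    (the manifest records parameters and package version, not wall-clock
    time).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample, read_report = read_rds_survey(config.survey_path)
    count = _count_from_config(config)

    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est_rds_i = rds_i_proportion(
            sample, config.trait, reps=config.bootstrap_reps, rng_seed=config.rng_seed
        )
        try:
            if config.population_size_prior is not None:
                est_ss = giles_ss_proportion(
                    sample, config.trait, population_size=config.population_size_prior,
                    sim_reps=config.ss_sim_reps, reps=config.bootstrap_reps,
                    rng_seed=config.rng_seed,
                )
            else:
                est_ss, _ = ss_multiplier_fixed_point(
                    sample, config.trait, count, sim_reps=config.ss_sim_reps,
                    rng_seed=config.rng_seed,
                )
        except EstimationError as exc:
            est_ss = None
            notes.append(f"Gile's SS unavailable: {exc}")

    report_diag = diagnose(
        sample, config.trait, estimator="rds_i", p_hat=est_rds_i.p_hat,
        tol=config.tol, window_frac=config.window_frac,
        sensitivity_bounds=config.sensitivity_bounds, province=config.province,
    )
    selection = select_estimator([report_diag])
    chosen = est_rds_i if (selection.estimator == "rds_i" or est_ss is None) else est_ss
    if selection.estimator == "giles_ss" and est_ss is None:
        notes.append("selection rule chose Gile's SS but it was unavailable; fell back to RDS-I")

    sensitive = not sensitivity_check(chosen.p_hat, *config.sensitivity_bounds)
    if sensitive:
        notes.append(
            f"selected proportion {chosen.p_hat:.3f} outside "
            f"{config.sensitivity_bounds}: estimator sensitive"
        )
    try:
        estimate = multiplier_estimate(count, chosen, province=config.province)
    except EstimationError as exc:
        raise EstimationError(f"multiplier undefined for {config.province}: {exc}") from exc

    reliable = estimate.reliable and chosen.reliable and not sensitive
    report = ProvincialReport(
        province=config.province,
        estimate=estimate,
        selected_estimator=chosen.estimator,
        selection_rationale=selection.rationale,
        diagnostics={
            "homophily_value": report_diag.homophily_value,
            "converged": report_diag.converged,
            "bottleneck_gap": report_diag.bottleneck_gap,
            "notes": report_diag.notes,
        },
        count={"count": count.count, "method": count.method, "ci": count.ci},
        proportions={
            "rds_i": {"p_hat": est_rds_i.p_hat, "ci": est_rds_i.ci, "reliable": est_rds_i.reliable},
            "giles_ss": None if est_ss is None else {
                "p_hat": est_ss.p_hat, "ci": est_ss.ci, "reliable": est_ss.reliable,
            },
        },
        sensitive=sensitive,
        reliable=reliable,
        rng_seed=config.rng_seed,
        notes="; ".join(notes),
    )

    write_json(report, out / f"{config.province}_report.json")
    summary_table([estimate]).to_csv(out / f"{config.province}_summary.csv", index=False)
    manifest = {
        "package": "appmultiplier",
        "version": _pkg_version,
        "province": config.province,
        "rng_seed": config.rng_seed,
        "parameters": {
            k: v for k, v in vars(config).items() if not k.endswith("path") and k != "out_dir"
        },
        "survey_rows": read_report.n_rows,
        "survey_kept": read_report.n_kept,
        "ineligible_excluded": read_report.n_ineligible,
    }
    (out / "manifest.json").write_text(to_json(manifest) + "\n")
    return report
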