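"""End-to-end pipeline: simulate -> analyze -> fit -> agree.

``run_pipeline`` drives the whole chain from a RunConfig, writing the
cohort table, fitted model, agreement report and a manifest whose
exclusion accounting always reconciles (generated = analyzed +
excluded).  Outputs are deterministic given the config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io import write_cohort, write_metadata
from .model import FEATURES, fit_model
from .simulate import CohortSpec, make_cohort
from .stats import agreement_report, make_agreement_plots

__all__ = ["RunConfig", "Manifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "ventdp_run"
    n_patients: int = 20
    conditions_per_patient: int = 3
    generation_mode: str = "mechanistic"
    dpl_noise_sd: float = 1.2
    seed: int = 0
    model: str = "refit"  # or "published"
    make_plots: bool = False
    max_fail_frac: float = 0.5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Manifest:
    """Per-run provenance and exclusion accounting."""

    version: str
    config_hash: str
    seed: int
    n_generated: int = 0
    n_analyzed: int = 0
    n_excluded: int = 0
    exclusions: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.n_generated == self.n_analyzed + self.n_excluded


def run_pipeline(config: RunConfig) -> Manifest:
    """Simulate a cohort, analyze it, fit/predict DP_L, report agreement."""
    import logging

    log = logging.getLogger("ventdp")
    log.setLevel(config.log_level.upper())

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(version=__version__, config_hash=config.config_hash(),
                        seed=config.seed)

    spec = CohortSpec(
        n_patients=config.n_patients,
        conditions_per_patient=config.conditions_per_patient,
        generation_mode=config.generation_mode,  # type: ignore[arg-type]
        dpl_noise_sd=config.dpl_noise_sd,
        seed=config.seed,
    )
    cohort = make_cohort(spec)
    manifest.n_generated = len(cohort)
    ok = cohort["quality_ok"].astype(bool)
    manifest.n_analyzed = int(ok.sum())
    manifest.n_excluded = int((~ok).sum())
    if "exclude_reason" in cohort.columns:
        for _, row in cohort[~ok].iterrows():
            reason = row.get("exclude_reason", "") or "analysis failed"
            manifest.exclusions.append(
                {"patient_id": row["patient_id"], "condition": int(row["condition"]),
                 "reason": reason}
            )
            log.warning("excluded %s/%s: %s", row["patient_id"], row["condition"], reason)
    if manifest.n_analyzed < (1 - config.max_fail_frac) * manifest.n_generated:
        raise RuntimeError(
            f"more than {config.max_fail_frac:.0%} of measurements failed analysis"
        )

    # non-invasive predictions on every analyzed row
    if config.model == "published":
        from .model import DrivingPressureRegressor

        model = DrivingPressureRegressor.published()
    else:
        model = fit_model(cohort)
    analyzed = cohort[ok].copy()
    analyzed["dpl_eit"] = model.predict(analyzed[list(FEATURES)])
    analyzed["el_eit"] = analyzed["dpl_eit"] / (analyzed["tv_ml"] / 1000.0)
    analyzed["pi_eit"] = analyzed["pplat"] * analyzed["el_eit"] / analyzed["ers"]

    cohort_path = outdir / "cohort.csv"
    write_cohort(analyzed, cohort_path)
    model_path = outdir / "model.json"
    model.save(model_path)
    report = agreement_report(analyzed)
    report_path = outdir / "report.json"
    write_metadata(report, report_path)
    manifest.artifacts = {
        "cohort": str(cohort_path), "model": str(model_path), "report": str(report_path)
    }
    if config.make_plots:
        paths = make_agreement_plots(analyzed, outdir / "plots")
        manifest.artifacts["plots"] = [str(p) for p in paths]

    write_metadata(asdict(manifest), outdir / "manifest.json")
    assert manifest.reconciles()
    return manifest
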