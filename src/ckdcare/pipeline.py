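"""End-to-end pipeline: generate -> stage -> alert -> cost-effectiveness.

One plain-text YAML config drives the whole run (environment variables are
never consulted); each stage writes its outputs under the run directory and
a manifest records the tool version, config hash, master seed and the
input/output path of every stage, so a run can be reproduced bit-for-bit
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .alerts import EvalContext, default_ruleset, evaluate_cohort, load_ruleset
from .cohort import GeneratorConfig, cohort_to_csv, generate_cohort
from .errors import ValidationError
from .markov import default_markov_spec, load_markov_spec, run_cea, strategy_from_dict
from .staging import classify, prevalence_summary

__all__ = ["RunManifest", "run_pipeline", "load_pipeline_config"]

log = logging.getLogger("ckdcare.pipeline")


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def load_pipeline_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("config: expected a mapping at top level")
    if "cohort" not in raw:
        raise ValidationError("config: missing required section 'cohort'")
    return raw


def _utcnow() -> str:
    return datetime.now(timezone.utc).isoformat()


def run_pipeline(config_path, out_dir=None) -> RunManifest:
    """Run every stage in order; any stage failure halts with a named error.

    Stages: cohort generation, KDIGO classification + prevalence summary,
    alert evaluation, and the Markov cost-effectiveness comparison.  All
    stage outputs land in ``out_dir`` (default: ``<config stem>_out`` next
    to the config) together with ``manifest.json``.
    """
    config_path = Path(config_path)
    raw_text = config_path.read_text()
    cfg = load_pipeline_config(config_path)

    # Validate everything up front so no stage runs on a bad config.
    gen_cfg = GeneratorConfig(**cfg["cohort"])
    alerts_cfg = cfg.get("alerts", {})
    cea_cfg = cfg.get("cea", {})

    out = Path(out_dir) if out_dir is not None else config_path.with_name(config_path.stem + "_out")
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(raw_text.encode()).hexdigest(),
        seed=gen_cfg.seed,
        started=_utcnow(),
    )

    def stage(name):
        log.info("stage=%s seed=%d config_hash=%s", name, gen_cfg.seed, manifest.config_hash[:12])

    try:
        stage("cohort")
        cohort = generate_cohort(gen_cfg)
        cohort_path = out / "cohort.csv"
        cohort_to_csv(cohort, cohort_path)
        manifest.stages["cohort"] = {"out": str(cohort_path), "n": len(cohort)}
    except ValidationError:
        raise
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'cohort' failed: {e}") from e

    try:
        stage("staging")
        classifications = [classify(p) for p in cohort]
        summary = prevalence_summary(classifications).as_dict()
        import pandas as pd

        cls_path = out / "classifications.csv"
        pd.DataFrame(
            [
                {
                    "id": c.id,
                    "is_ckd": c.is_ckd,
                    "g_stage": c.g_stage,
                    "a_category": c.a_category,
                    "is_ckdu": c.is_ckdu,
                    "latest_egfr": None if c.latest_egfr is None else round(c.latest_egfr, 2),
                    "egfr_slope": None if c.egfr_slope is None else round(c.egfr_slope, 2),
                    "provisional": c.provisional,
                    "undetermined": c.undetermined,
                }
                for c in classifications
            ]
        ).to_csv(cls_path, index=False)
        prev_path = out / "prevalence.json"
        prev_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        manifest.stages["staging"] = {"out": str(cls_path), "summary": str(prev_path)}
    except Exception as e:
        raise RuntimeError(f"stage 'staging' failed: {e}") from e

    try:
        stage("alerts")
        ruleset = (
            load_ruleset(alerts_cfg["rules"]) if alerts_cfg.get("rules") else default_ruleset()
        )
        ctx = EvalContext(lookback_days=int(alerts_cfg.get("lookback_days", 365)))
        events = evaluate_cohort(cohort, ruleset=ruleset, context=ctx)
        alerts_path = out / "alerts.csv"
        events.to_csv(alerts_path, index=False)
        manifest.stages["alerts"] = {"out": str(alerts_path), "n_events": len(events)}
    except Exception as e:
        raise RuntimeError(f"stage 'alerts' failed: {e}") from e

    try:
        stage("cea")
        if cea_cfg.get("params"):
            spec, strategy = load_markov_spec(cea_cfg["params"])
        else:
            spec, strategy = default_markov_spec()
        if cea_cfg.get("strategy"):
            strategy = strategy_from_dict({**strategy.__dict__, **cea_cfg["strategy"]})
        result = run_cea(spec, strategy)
        cea_path = out / "cea.json"
        cea_path.write_text(json.dumps(result.as_dict(), indent=1, sort_keys=True))
        from .markov import null_strategy, run_cohort

        traces = {}
        for strat in (strategy, null_strategy()):
            trace_path = out / f"trace_{strat.name.replace(' ', '_')}.csv"
            run_cohort(spec, strat).as_frame().to_csv(trace_path, index=False)
            traces[strat.name] = str(trace_path)
        manifest.stages["cea"] = {"out": str(cea_path), "traces": traces}
    except ValidationError:
        raise
    except Exception as e:
        raise RuntimeError(f"stage 'cea' failed: {e}") from e

    manifest.finished = _utcnow()
    manifest.write(out / "manifest.json")
    return manifest
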