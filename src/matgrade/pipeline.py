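"""End-to-end orchestration: validate -> classify -> indicators -> tables ->
associations, with a run manifest for reproducibility.

Every stage is deterministic given its inputs, so re-running with the same
cohort, criteria config and plan reproduces byte-identical artifacts; the
manifest records input hashes, the tool version and per-stage output paths.
Artifacts are CSV/JSON only; structured stage logs go to standard error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import PrevalenceRatioRegression, add_derived_bands
from .classifier import classify_cohort
from .criteria import default_criteria, load_criteria
from .indicators import indicator_panel
from .schema import read_cohort, write_cohort
from .tables import build_table

logger = logging.getLogger(__name__)

DEFAULT_PLAN = {
    "table_variables": ["prev_any", "neonatal_near_miss", "delivery_mode"],
    "outcomes": ["MNM"],
    "covariates": ["age_group", "prev_any", "delivery_mode"],
    "cluster": "cluster_id",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return None if math.isnan(v) else v
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def run_pipeline(
    cohort_path,
    outdir,
    criteria_path=None,
    plan: dict | None = None,
    strict: bool = False,
) -> dict:
    """Run the full analysis and return the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = {**DEFAULT_PLAN, **(plan or {})}
    manifest: dict = {
        "tool": "matgrade",
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "inputs": {"cohort": str(cohort_path), "cohort_sha256": _sha256(cohort_path)},
        "plan": plan,
        "stages": {},
    }
    if criteria_path:
        manifest["inputs"]["criteria"] = str(criteria_path)
        manifest["inputs"]["criteria_sha256"] = _sha256(criteria_path)

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        st = stage("validate")
        cohort = read_cohort(cohort_path, strict=strict)
        st["n_records"] = len(cohort)
        st["n_invalid"] = len(cohort.attrs.get("invalid_records", {}))
    except Exception as exc:
        raise PipelineError(f"validate: {exc}") from exc

    try:
        st = stage("classify")
        criteria = load_criteria(criteria_path) if criteria_path else default_criteria()
        classified = classify_cohort(cohort, criteria=criteria)
        classified = add_derived_bands(classified)
        out_csv = outdir / "classified.csv"
        to_write = classified.copy()
        sev = to_write.pop("severity")
        nnm = to_write.pop("neonatal_near_miss")
        to_write = to_write.drop(columns=["age_group", "prenatal_band"])
        write_cohort(to_write, out_csv)
        extras = pd.DataFrame({"severity": sev, "neonatal_near_miss": nnm.map({True: "1", False: "0"})})
        base = pd.read_csv(out_csv, dtype=str, keep_default_na=False)
        pd.concat([base, extras.reset_index(drop=True)], axis=1).to_csv(out_csv, index=False)
        st["output"] = str(out_csv)
        st["class_counts"] = {k: int(v) for k, v in sev.value_counts().items()}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"classify: {exc}") from exc

    try:
        st = stage("indicators")
        panel = indicator_panel(classified)
        out_json = outdir / "panel.json"
        _write_json(panel.rounded() | {"unrounded": panel.__dict__}, out_json)
        st["output"] = str(out_json)
    except Exception as exc:
        raise PipelineError(f"indicators: {exc}") from exc

    try:
        st = stage("tables")
        tables = [
            build_table(classified, var, cluster_col=plan["cluster"]).to_dict()
            for var in plan["table_variables"]
        ]
        out_json = outdir / "tables.json"
        _write_json(tables, out_json)
        st["output"] = str(out_json)
    except Exception as exc:
        raise PipelineError(f"tables: {exc}") from exc

    try:
        st = stage("associate")
        results = []
        for outcome in plan["outcomes"]:
            est = PrevalenceRatioRegression(
                outcome=outcome,
                covariates=tuple(plan["covariates"]),
                cluster_col=plan["cluster"],
            ).fit(classified)
            results.append(
                {
                    "outcome": outcome,
                    "family": est.family_used_,
                    "n_obs": est.n_obs_,
                    "n_clusters": est.n_clusters_,
                    "estimates": [r.to_dict() for r in est.results_],
                }
            )
        out_json = outdir / "pr.json"
        _write_json(results, out_json)
        st["output"] = str(out_json)
    except Exception as exc:
        raise PipelineError(f"associate: {exc}") from exc

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    manifest["artifact_sha256"] = {
        name: _sha256(info["output"]) for name, info in manifest["stages"].items() if "output" in info
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def load_plan(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
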