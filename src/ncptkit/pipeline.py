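"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages: simulate (optional) -> preprocess -> normalize -> grand index ->
norms -> validate.  Each stage writes its outputs under the run directory
and appends an entry (name, outputs, record counts) to the manifest, which
also records the master seed and a hash of the configuration so a run can
be reproduced byte-for-byte.

The master seed fans out to per-stage seeds through
``numpy.random.SeedSequence([master_seed, stage_index])``, so any stage can
be re-run in isolation with the same stream.

A pipeline fed released-schema scores without session logs skips the
time-based filters and records a warning in the manifest: the released
schema carries no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as nio
from .binning import ReferenceComposition
from .norming import (completeness_flags, compute_grand_index,
                      compute_norm_tables, normalize_scores)
from .preprocessing import run_filters
from .simulate import CohortConfig, make_reference, simulate_cohort
from .validation import correlation_matrix, positive_manifold_check, residualize

__all__ = ["RunManifest", "run_pipeline", "load_config"]

STAGES = ("simulate", "preprocess", "normalize", "grand_index", "norms", "validate")


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    tool_version: str
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, outputs: list[str], n_in: int, n_out: int) -> None:
        self.stages.append({"name": name, "outputs": outputs,
                            "records_in": int(n_in), "records_out": int(n_out)})

    def to_dict(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash,
                "tool_version": self.tool_version, "stages": self.stages,
                "warnings": self.warnings}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(master), idx]).generate_state(1)[0] % (2**31))


def _reference_from_config(config: dict, scores: pd.DataFrame) -> ReferenceComposition:
    ref_cfg = config.get("reference", {"kind": "census"})
    kind = ref_cfg.get("kind", "census")
    return make_reference(kind, cohort=scores,
                          explicit=ref_cfg.get("proportions"),
                          strict=ref_cfg.get("strict", True))


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Run the configured stages end to end; returns the manifest.

    ``config`` keys: ``seed``; either ``simulate`` (a cohort spec) or
    ``input`` (paths to a scores CSV and optionally a sessions JSONL);
    optional ``reference``, ``normalize`` and ``norms`` sections.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(seed=seed, config_hash=_config_hash(config),
                           tool_version=__version__)

    logs = None
    gameplay_counts = None

    if "simulate" in config:
        sim_cfg = CohortConfig(**config["simulate"])
        cohort = simulate_cohort(sim_cfg, _stage_seed(seed, "simulate"))
        scores = cohort.scores
        logs = cohort.logs
        gameplay_counts = cohort.gameplay_counts
        bid = sim_cfg.battery_id
        scores_path = out / f"battery{bid}_df.csv"
        nio.write_score_frame(scores, scores_path)
        nio.write_session_logs(logs, out / "sessions.jsonl")
        cohort.truth.to_csv(out / "truth.csv", index=False)
        manifest.add_stage("simulate",
                           [str(scores_path), str(out / "sessions.jsonl"),
                            str(out / "truth.csv")], 0, len(scores))
    elif "input" in config:
        scores = nio.load_score_frame(config["input"]["scores"])
        if config["input"].get("sessions"):
            logs = nio.read_session_logs(config["input"]["sessions"])
            gameplay_counts = {log.user_id: log.pre_test_gameplays for log in logs}
        manifest.add_stage("load", [], 0, len(scores))
    else:
        raise ValueError("config needs either a 'simulate' or an 'input' section")

    # -- preprocess ---------------------------------------------------------
    n_in = len(scores)
    if logs is not None:
        kept, report = run_filters(logs)
        kept_runs = {log.test_run_id for log in kept}
        scores = scores[scores["test_run_id"].astype(str).isin(kept_runs)].copy()
        (out / "exclusion_report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n")
        outputs = [str(out / "exclusion_report.json")]
    else:
        manifest.warnings.append(
            "no session logs: time-based exclusion filters skipped "
            "(released score schema carries no timestamps)")
        outputs = []
    manifest.add_stage("preprocess", outputs, n_in, len(scores))
    if scores.empty:
        raise RuntimeError("stage preprocess: no records survived filtering")

    # -- normalize ----------------------------------------------------------
    reference = _reference_from_config(config, scores)
    norm_cfg = config.get("normalize", {})
    completeness = completeness_flags(scores)
    normalized, _ = normalize_scores(
        scores, reference, completeness, gameplay_counts,
        target_mean=norm_cfg.get("target_mean", 100.0),
        target_sd=norm_cfg.get("target_sd", 15.0),
        tie_policy=norm_cfg.get("tie_policy", "midrank"))
    norm_path = out / "normalized.csv"
    normalized.to_csv(norm_path, index=False)
    manifest.add_stage("normalize", [str(norm_path)], len(scores), len(normalized))

    # -- grand index --------------------------------------------------------
    gi = compute_grand_index(normalized, reference, completeness, gameplay_counts,
                             target_mean=norm_cfg.get("target_mean", 100.0),
                             target_sd=norm_cfg.get("target_sd", 15.0),
                             tie_policy=norm_cfg.get("tie_policy", "midrank"))
    scores_gi = scores.copy()
    scores_gi["grand_index"] = scores_gi["test_run_id"].map(gi)
    clean_paths = []
    for bid, grp in scores_gi.groupby("battery_id", sort=False):
        p = out / f"battery{int(bid)}_df_clean.csv"
        nio.write_score_frame(grp, p)
        clean_paths.append(str(p))
    manifest.add_stage("grand_index", clean_paths, len(scores),
                       int(gi.notna().sum()))

    # -- norms --------------------------------------------------------------
    norms_cfg = config.get("norms", {})
    tables = compute_norm_tables(
        scores_gi, gi=gi, gender_set=tuple(norms_cfg.get("gender_set", ("m", "f"))),
        min_bin_n=int(norms_cfg.get("min_bin_n", 20)),
        completeness=completeness, gameplay_counts=gameplay_counts)
    norm_outputs = []
    for bid, rows in tables.items():
        p = out / f"battery{bid}_norms.csv"
        nio.write_norms_table(rows, p)
        norm_outputs.append(str(p))
    manifest.add_stage("norms", norm_outputs, len(scores_gi),
                       sum(len(r) for r in tables.values()))

    # -- validate -----------------------------------------------------------
    tables_resid = residualize(scores_gi, completeness)
    report = correlation_matrix(tables_resid)
    ok, summary = positive_manifold_check(report)
    val = {
        "positive_manifold": ok,
        "min_offdiag": report.min_offdiag,
        "max_offdiag": report.max_offdiag,
        "violations": summary["violations"],
        "matrices": {str(b): m.round(6).to_dict() for b, m in report.matrices.items()},
    }
    val_path = out / "validation_report.json"
    val_path.write_text(json.dumps(val, indent=2, default=str) + "\n")
    manifest.add_stage("validate", [str(val_path)], len(scores_gi),
                       sum(t.n_participants for t in tables_resid.values()))

    manifest.write(out / "manifest.json")
    return manifest
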