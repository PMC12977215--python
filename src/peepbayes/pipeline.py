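"""End-to-end orchestration: simulate/load -> fit every outcome x prior -> report.

A run produces, per analysis cell, a CSV of posterior draws, a JSON
decision summary, and at the bundle level a reproducibility manifest with
content hashes, the master seed and derived per-cell seeds.  Reruns with
the same configuration and master seed reproduce the bundle exactly at the
summary level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .decisions import DecisionSummary, DecisionThresholds, summarize_outcome
from .inference import (
    HierarchicalModelSpec,
    fit_duration_model,
    fit_mortality_model,
    fit_vfd_model,
)
from .priors import ElicitedSurvey, build_protocol_priors
from .synthetic import SimulationConfig, simulate_trial
from .trial_data import TrialDataset, read_trial_table

log = logging.getLogger("peepbayes")

OUTCOMES = ("vfd", "mortality_28d", "duration")
PRIOR_LABELS = ("neutral", "optimistic", "pessimistic", "survey")

_FITTERS = {
    "vfd": fit_vfd_model,
    "mortality_28d": fit_mortality_model,
    "duration": fit_duration_model,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    data_path: Optional[Path] = None
    simulation: Optional[SimulationConfig] = None
    outcomes: tuple[str, ...] = OUTCOMES
    prior_labels: tuple[str, ...] = PRIOR_LABELS
    thresholds: DecisionThresholds = field(default_factory=DecisionThresholds)
    survey: ElicitedSurvey = field(default_factory=ElicitedSurvey)
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    master_seed: int = 0
    output_dir: Path = Path("peepbayes_run")

    def validate(self) -> None:
        if not self.outcomes or not self.prior_labels:
            raise PipelineError("config", "at least one outcome and one prior must be selected")
        bad = [o for o in self.outcomes if o not in OUTCOMES]
        bad += [p for p in self.prior_labels if p not in PRIOR_LABELS]
        if bad:
            raise PipelineError("config", f"unknown outcome/prior selection: {bad}")
        if self.data_path is None and self.simulation is None:
            raise PipelineError("config", "either data_path or simulation must be given")


def _cell_seed(master: int, outcome: str, label: str) -> int:
    """Deterministic per-cell seed derived from the master seed."""
    key = (OUTCOMES.index(outcome), PRIOR_LABELS.index(label))
    ss = np.random.SeedSequence(entropy=master, spawn_key=key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _summary_dict(s: DecisionSummary) -> dict:
    d = dataclasses.asdict(s)
    d.pop("diagnostics", None)
    return d


def run_full_analysis(config: RunConfig) -> dict:
    """Fit every selected outcome x prior cell and persist draws + summaries."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    try:
        if config.data_path is not None:
            data = read_trial_table(config.data_path)
            data_desc = str(config.data_path)
        else:
            sim = dataclasses.replace(config.simulation)
            data = simulate_trial(sim)
            data_desc = f"synthetic(seed={sim.seed})"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load_data", str(exc)) from exc
    log.info("stage=load_data n=%d source=%s elapsed=%.1fs", len(data), data_desc, time.time() - t0)

    registry, het_prior = build_protocol_priors(config.survey)

    cells: dict[tuple[str, str], DecisionSummary] = {}
    manifest_files: dict[str, str] = {}
    for outcome in config.outcomes:
        for label in config.prior_labels:
            seed = _cell_seed(config.master_seed, outcome, label)
            spec = HierarchicalModelSpec(
                outcome=outcome,
                treatment_prior=registry[(outcome, label)],
                heterogeneity_prior=het_prior,
                n_chains=config.n_chains,
                n_warmup=config.n_warmup,
                n_draws=config.n_draws,
                seed=seed,
            )
            t1 = time.time()
            try:
                draws = _FITTERS[outcome](data, spec)
                summary = summarize_outcome(draws, config.thresholds, prior_label=label)
            except Exception as exc:
                raise PipelineError(f"fit:{outcome}:{label}", str(exc)) from exc
            cells[(outcome, label)] = summary

            stem = f"{outcome}__{label}"
            draws_path = out_dir / f"{stem}_draws.csv"
            pd.DataFrame({"theta": draws.theta, "tau": draws.tau}).to_csv(
                draws_path, index=False
            )
            summ_path = out_dir / f"{stem}_summary.json"
            summ_path.write_text(
                json.dumps(
                    {**_summary_dict(summary), "diagnostics": draws.diagnostics, "seed": seed},
                    indent=2,
                    sort_keys=True,
                )
            )
            manifest_files[draws_path.name] = _sha256(draws_path)
            manifest_files[summ_path.name] = _sha256(summ_path)
            log.info(
                "stage=fit outcome=%s prior=%s seed=%d elapsed=%.1fs class=%s",
                outcome, label, seed, time.time() - t1, summary.classification,
            )

    bundle = {
        "summaries": cells,
        "data_source": data_desc,
        "master_seed": config.master_seed,
        "outcomes": list(config.outcomes),
        "prior_labels": list(config.prior_labels),
        "output_dir": out_dir,
    }
    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "data_source": data_desc,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "outcomes": list(config.outcomes),
                    "priors": list(config.prior_labels),
                    "n_chains": config.n_chains,
                    "n_warmup": config.n_warmup,
                    "n_draws": config.n_draws,
                    "master_seed": config.master_seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "files": manifest_files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle


def verify_manifest(out_dir: str | Path) -> bool:
    """Recompute content hashes against a run's manifest."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return all(
        _sha256(out_dir / name) == digest for name, digest in manifest["files"].items()
    )


def render_report(bundle: dict) -> dict[str, Path]:
    """Write the summary table (CSV + JSON) and per-outcome prior-sensitivity tables."""
    cells: dict[tuple[str, str], DecisionSummary] = bundle.get("summaries", {})
    if not cells:
        raise PipelineError("report", "empty result bundle: no prior/outcome cells")
    expected = [(o, p) for o in bundle["outcomes"] for p in bundle["prior_labels"]]
    missing = [c for c in expected if c not in cells]
    if missing:
        raise PipelineError("report", f"incomplete bundle, missing cells: {missing}")

    out_dir = Path(bundle["output_dir"])
    rows = []
    for (outcome, label), s in cells.items():
        rows.append(
            {
                "outcome": outcome,
                "prior": label,
                "effect_scale": s.effect_scale,
                "posterior_median": s.posterior_median,
                "cri_lo": s.cri_95[0],
                "cri_hi": s.cri_95[1],
                "median_natural": s.posterior_median_natural,
                "p_benefit": s.p_benefit,
                "p_rope": s.p_rope,
                "p_severe_harm": s.p_severe_harm,
                "classification": s.classification,
            }
        )
    table = pd.DataFrame(rows).sort_values(["outcome", "prior"]).reset_index(drop=True)
    paths = {}
    csv_path = out_dir / "summary_table.csv"
    table.to_csv(csv_path, index=False)
    paths["summary_csv"] = csv_path
    json_path = out_dir / "summary_table.json"
    json_path.write_text(table.to_json(orient="records", indent=2))
    paths["summary_json"] = json_path
    for outcome in bundle["outcomes"]:
        sens = table[table["outcome"] == outcome][["prior", "p_benefit", "classification"]]
        p = out_dir / f"sensitivity_{outcome}.csv"
        sens.to_csv(p, index=False)
        paths[f"sensitivity_{outcome}"] = p
    return paths
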