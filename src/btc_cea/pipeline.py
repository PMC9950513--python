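"""End-to-end orchestration: reconstruct -> fit -> select -> base case ->
sensitivity, with on-disk artifacts and a reproducibility manifest.

Stages are independent where possible; each writes plain-text artifacts
(CSV/JSON) into the output directory.  The manifest records the config
hash, seed and artifact list so a rerun with identical inputs is
verifiably idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import ScenarioConfig
from .economics import compute_cea, evaluate_arm
from .km import DigitizedCurve, RiskTable, guyot_reconstruct
from .markov import make_arm_trace
from .sensitivity import owsa, price_threshold, psa
from .survival import fit_all, select_best, write_fit_records

STAGES = ("base", "owsa", "threshold", "psa")


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


def reconstruct_stage(curve_csv, risk_csv, out_csv, total_events=None,
                      label: str = "") -> "pd.DataFrame":
    """Digitized curve + risk table -> pseudo-IPD CSV, plus family fits."""
    curve = DigitizedCurve.from_csv(curve_csv, label)
    risk = RiskTable.from_csv(risk_csv) if risk_csv else None
    ipd = guyot_reconstruct(curve, risk, total_events)
    ipd.to_csv(out_csv)
    return ipd


def fit_stage(ipd, out_json) -> dict:
    """Fit all six families to an IPD sample and select by AIC/BIC."""
    fits = fit_all(ipd.times, ipd.events)
    write_fit_records(out_json, fits)
    best = select_best(fits)
    return {"best_family": best.spec.family.value,
            "params": best.spec.named_params,
            "aic": best.aic, "bic": best.bic}


def run_pipeline(
    config: ScenarioConfig | str | Path,
    perspective: str = "us",
    stages=("base",),
    outdir: str | Path = "results",
    seed: int = 42,
    psa_samples: int = 10_000,
) -> dict:
    """Run the requested stages for one payer perspective.

    Returns the manifest dict (also written to ``manifest_<perspective>.json``).
    """
    if not isinstance(config, ScenarioConfig):
        config = ScenarioConfig.load(config)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    settings = config.settings.to_settings()
    specs = config.survival_specs()
    traces = {arm: make_arm_trace(s["os"], s["pfs"], settings)
              for arm, s in specs.items()}
    inputs = config.build_inputs(perspective)

    result = None
    if "base" in stages:
        arms = {arm: evaluate_arm(arm, tr, inputs) for arm, tr in traces.items()}
        result = compute_cea(arms, inputs.wtp, perspective)
        table = outdir / f"base_case_{perspective}.csv"
        result.to_table().to_csv(table, index=False)
        summary = outdir / f"base_case_{perspective}.json"
        summary.write_text(json.dumps(result.to_json_dict(), indent=2))
        for arm, tr in traces.items():
            p = outdir / f"trace_{arm}.csv"
            tr.to_csv(p)
            artifacts[f"trace_{arm}"] = str(p)
        artifacts["base_case_csv"] = str(table)
        artifacts["base_case_json"] = str(summary)

    if "owsa" in stages:
        tor = owsa(config, perspective)
        p = outdir / f"tornado_{perspective}.csv"
        tor.to_csv(p, index=False)
        artifacts["tornado"] = str(p)

    if "threshold" in stages:
        red = price_threshold(inputs.wtp, config, perspective)
        p = outdir / f"price_threshold_{perspective}.json"
        p.write_text(json.dumps({"wtp": inputs.wtp, "price_reduction": red}, indent=2))
        artifacts["threshold"] = str(p)

    if "psa" in stages:
        res = psa(config, perspective, n_samples=psa_samples, seed=seed)
        ceac = res.ceac()
        p1 = outdir / f"ceac_{perspective}.csv"
        ceac.to_csv(p1, index=False)
        p2 = outdir / f"psa_scatter_{perspective}.csv"
        res.scatter().to_csv(p2, index=False)
        artifacts["ceac"] = str(p1)
        artifacts["psa_scatter"] = str(p2)
        artifacts["psa_prob_cost_effective"] = res.prob_cost_effective()

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "perspective": perspective,
        "stages": list(stages),
        "seed": seed,
        "artifacts": artifacts,
    }
    (outdir / f"manifest_{perspective}.json").write_text(json.dumps(manifest, indent=2))
    return manifest
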