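"""End-to-end session pipeline with a reproducibility manifest.

Runs impute -> standardize -> order selection -> blocked-CV lambda -> sparse
LASSO-VAR -> analytic cTE -> binarization -> graph indexes -> sliding-window
HPE -> behavioural alignment for one session, writing every artifact plus a
manifest sufficient to re-execute the run identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .cte import binarize, cte_matrix
from .graph import graph_indexes
from .hpe import best_worst_contrast, sliding_window_hpe
from .io import read_behavioural_csv, read_hf_csv, write_adjacency_csv, write_hf_csv
from .neurometrics import impute_missing, standardize
from .performance import performance_series
from .synthetic import GroundTruthScenario, generate_session
from .var import default_lambda_grid, fit_var_lasso, select_lambda, select_order


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = __version__

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_all(
    config: PipelineConfig,
    outdir,
    hf_csv=None,
    behavioural_csv=None,
) -> dict:
    """Execute the whole pipeline for one session.

    Without ``hf_csv`` a synthetic session is generated from the config's
    scenario block (behavioural records included); with it, the given HF
    series (and optional behavioural table) are ingested instead.  Stage
    failures abort with the stage name.  Returns the in-memory artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.model_dump(mode="json"), seed=config.seed)
    artifacts: dict = {}
    t_start = time.perf_counter()

    def _stage(name):
        manifest.timings_s[name] = round(time.perf_counter() - t_start, 3)

    # ---- input ----------------------------------------------------------
    stage = "input"
    try:
        if hf_csv is None:
            scenario = GroundTruthScenario(
                density=config.synth.density,
                coupling=config.synth.coupling,
                order=config.synth.order,
                missing_rate=config.synth.missing_rate,
                behavioural_coupling=config.synth.behavioural_coupling,
                phase_density_multipliers=config.synth.phase_density_multipliers,
                seed=config.seed,
            )
            session = generate_session(scenario)
            hf, behavioural = session.hf, session.behavioural
            artifacts["truth"] = session.truth
            write_hf_csv(hf, outdir / "hf_raw.csv")
            behavioural.to_csv(outdir / "behavioural.csv", index=False)
        else:
            hf = read_hf_csv(hf_csv)
            manifest.inputs["hf_csv"] = _digest(hf_csv)
            behavioural = None
            if behavioural_csv is not None:
                behavioural = read_behavioural_csv(behavioural_csv)
                manifest.inputs["behavioural_csv"] = _digest(behavioural_csv)
        _stage(stage)

        stage = "impute"
        hf = impute_missing(hf, k=config.neurometrics.impute_k)
        stage = "standardize"
        hf = standardize(hf)
        write_hf_csv(hf, outdir / "hf_standardized.csv")
        _stage(stage)

        stage = "order_selection"
        if config.var.order is not None:
            p = config.var.order
            artifacts["order_selection"] = None
        else:
            sel = select_order(hf, p_max=config.var.p_max)
            p = sel.p
            artifacts["order_selection"] = sel
        _stage(stage)

        stage = "lambda_selection"
        grid = default_lambda_grid(
            config.var.grid_min, config.var.grid_max, config.var.grid_size
        )
        if config.var.lambda_value is not None:
            lam = np.full(hf.n_series, config.var.lambda_value)
        else:
            lam_sel = select_lambda(hf, p, grid=grid, k=config.var.n_folds,
                                    seed=config.seed)
            lam = lam_sel.lambda_per_row
            artifacts["lambda_selection"] = lam_sel
        _stage(stage)

        stage = "lasso_fit"
        model, report = fit_var_lasso(hf, p, lam)
        model.to_json(outdir / "model.json")
        artifacts["model"], artifacts["report"] = model, report
        _stage(stage)

        stage = "cte"
        result = cte_matrix(model, units=config.cte.units)
        result.to_json(outdir / "cte.json")
        result.to_frame().to_csv(outdir / "cte.csv", index=False)
        artifacts["cte"] = result
        _stage(stage)

        stage = "binarize"
        adj = binarize(result, rule=config.cte.binarize_rule)
        write_adjacency_csv(adj, outdir / "adjacency.csv")
        artifacts["adjacency"] = adj
        _stage(stage)

        stage = "graph_indexes"
        gi = graph_indexes(adj, damping=config.graph.damping,
                           entropy_mode=config.graph.entropy_mode)
        artifacts["graph_indexes"] = gi
        _stage(stage)

        stage = "hpe"
        hpe = sliding_window_hpe(
            hf,
            window=config.hpe.window,
            step=config.hpe.step,
            p=p,
            lambda_per_row=lam,
            lambda_policy=config.hpe.lambda_policy,
            binarize_rule=config.cte.binarize_rule,
            damping=config.graph.damping,
            entropy_mode=config.graph.entropy_mode,
            seed=config.seed,
        )
        hpe.to_frame().to_csv(outdir / "hpe_frames.csv", index=False)
        n_minutes = hf.n_samples // 60
        per_minute = hpe.per_minute(n_minutes)
        pd.DataFrame({"minute": np.arange(n_minutes), "hpe": per_minute}).to_csv(
            outdir / "hpe_per_minute.csv", index=False
        )
        artifacts["hpe"] = hpe
        artifacts["hpe_per_minute"] = per_minute
        if hpe.provenance["n_failed_frames"]:
            manifest.warnings.append(
                f"{hpe.provenance['n_failed_frames']} HPE frame(s) failed and "
                "were skipped"
            )
        _stage(stage)

        if behavioural is not None:
            stage = "performance"
            perf = performance_series(behavioural)
            pd.DataFrame(
                {"minute": np.arange(perf.n_minutes), "performance": perf.values,
                 "phase": perf.phases}
            ).to_csv(outdir / "performance.csv", index=False)
            artifacts["performance"] = perf
            stage = "contrast"
            bw = best_worst_contrast([per_minute[: perf.n_minutes]], [perf.values])
            artifacts["best_worst"] = bw
            _stage(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.to_json(outdir / "manifest.json")
    artifacts["manifest"] = manifest
    return artifacts
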