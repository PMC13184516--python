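"""Config-driven orchestration: simulate -> split -> baseline -> evaluate -> plot.

A run is described by a YAML/dict config with a global seed, an output
directory and per-stage parameter blocks. Stages execute in dependency
order; every artifact written is listed in a JSON manifest together with
its producing stage, parameters and seed, and re-running an identical
config reproduces byte-identical CSV outputs.

Recognized stages (any subset): ``simulate``, ``fit_dose_response``,
``split``, ``evaluate``, ``harmonize``, ``plot``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import dose_response, harmonization, metrics, splitting, synthetic, viz
from .datasets import (
    ResponseType,
    TripletDataset,
    read_dose_response,
    read_predictions,
    read_triplets,
    write_triplets,
)

logger = logging.getLogger("drpeval")

STAGE_ORDER = ("simulate", "fit_dose_response", "split", "evaluate",
               "harmonize", "plot")

_KNOWN_TOP_KEYS = {"seed", "out_dir", "log_level", "stages"}


class ConfigError(ValueError):
    """Raised when a run config fails schema validation."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _validate(cfg: dict) -> dict:
    unknown = set(cfg) - _KNOWN_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" not in cfg or not isinstance(cfg["stages"], dict):
        raise ConfigError("config requires a 'stages' mapping")
    bad = set(cfg["stages"]) - set(STAGE_ORDER)
    if bad:
        raise ConfigError(f"unknown stage(s): {sorted(bad)}")
    # referenced input files must exist before anything runs
    for stage, block in cfg["stages"].items():
        if not isinstance(block, dict):
            raise ConfigError(f"stage {stage!r} block must be a mapping")
        for key, val in block.items():
            if key in ("truth", "predictions", "dose_response", "assignment") and val:
                if not Path(val).exists():
                    raise ConfigError(f"stage {stage!r}: input file not found: {val}")
            if key == "inputs" and isinstance(val, list):
                for v in val:
                    if not Path(v).exists():
                        raise ConfigError(f"stage {stage!r}: input file not found: {v}")
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the run manifest.

    The manifest (also written as ``manifest.json`` in the output
    directory, next to a ``config_echo.yaml``) lists every artifact with
    its stage, parameters and the seed in effect.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _validate(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "drpeval_run"))
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"seed": seed, "out_dir": str(out), "stages": []}
    state: dict = {}

    for stage in STAGE_ORDER:
        if stage not in cfg["stages"]:
            continue
        block = dict(cfg["stages"][stage] or {})
        artifacts = _STAGE_RUNNERS[stage](block, seed, out, state)
        manifest["stages"].append(
            {"stage": stage, "params": block, "seed": seed, "artifacts": artifacts}
        )
        logger.info("stage %s: wrote %s", stage, artifacts)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stage runners: each takes (params, seed, out_dir, shared state) and
# returns the list of files written
# ---------------------------------------------------------------------------

def _get_truth(block: dict, state: dict) -> TripletDataset:
    if block.get("truth"):
        return read_triplets(block["truth"],
                             block.get("response_type", "ln_ic50"))
    if "truth" in state:
        return state["truth"]
    raise ConfigError("stage needs a 'truth' input (file or earlier simulate stage)")


def _run_simulate(block: dict, seed: int, out: Path, state: dict) -> list[str]:
    kind = block.get("kind", "screen")
    if kind == "screen":
        fields = {k: v for k, v in block.items() if k != "kind"}
        cfg = synthetic.ScreenConfig(seed=seed, **fields)
        dataset, latents = synthetic.generate_screen(cfg)
        truth_path = out / "truth.csv"
        write_triplets(dataset, truth_path)
        latents_path = out / "latents.csv"
        long = latents.gamma.stack().rename("gamma").reset_index()
        long.columns = ["cell_id", "drug_id", "gamma"]
        long["alpha"] = latents.alpha.loc[long["drug_id"]].to_numpy()
        long["beta"] = latents.beta.loc[long["cell_id"]].to_numpy()
        long.to_csv(latents_path, index=False, float_format="%.17g")
        state["truth"], state["latents"] = dataset, latents
        return [str(truth_path), str(latents_path)]
    if kind == "curves":
        fields = {k: v for k, v in block.items() if k != "kind"}
        cfg = synthetic.CurveSetConfig(seed=seed, **fields)
        experiments, params = synthetic.generate_curves(cfg)
        from .datasets import write_dose_response

        dr_path = out / "dose_response.csv"
        write_dose_response(experiments, dr_path)
        params_path = out / "curve_params.csv"
        params.to_csv(params_path, index=False, float_format="%.17g")
        state["experiments"] = experiments
        return [str(dr_path), str(params_path)]
    raise ConfigError(f"simulate kind must be 'screen' or 'curves', got {kind!r}")


def _run_fit_dose_response(block: dict, seed: int, out: Path, state: dict) -> list[str]:
    if block.get("dose_response"):
        experiments = read_dose_response(
            block["dose_response"], block.get("concentration_unit", "molar")
        )
    elif "experiments" in state:
        experiments = state["experiments"]
    else:
        raise ConfigError("fit_dose_response needs a 'dose_response' input")
    srange = dose_response.StandardRange(
        cmin=float(block.get("cmin", 1e-10)), cmax=float(block.get("cmax", 1e-4))
    )
    table = dose_response.fit_table(experiments, srange=srange)
    path = out / "curve_fits.csv"
    table.to_csv(path, index=False, float_format="%.17g")
    state["curve_fits"] = table
    return [str(path)]


def _run_split(block: dict, seed: int, out: Path, state: dict) -> list[str]:
    truth = _get_truth(block, state)
    spec = splitting.SplitSpec(
        strategy=block.get("strategy", "random"),
        k=int(block.get("k", 5)),
        seed=int(block.get("seed", seed)),
        validation_fraction=float(block.get("validation_fraction", 0.0)),
    )
    assignment = splitting.split(truth, spec)
    report = splitting.verify_assignment(truth, assignment)
    if not report.passed:  # pragma: no cover - defensive
        raise RuntimeError(f"split verification failed:\n{report}")
    path = out / f"assignment_{spec.strategy}.csv"
    assignment.to_frame(expand_train=bool(block.get("expand_train", False))).to_csv(
        path, index=False
    )
    state["assignment"], state["split_spec"] = assignment, spec
    return [str(path)]


def _run_evaluate(block: dict, seed: int, out: Path, state: dict) -> list[str]:
    truth = _get_truth(block, state)
    if block.get("predictions"):
        pred = read_predictions(block["predictions"])
    elif block.get("baseline", "drug_mean") == "drug_mean" and "assignment" in state:
        # score the drug-mean baseline fold by fold on the existing split
        assignment = state["assignment"]
        frames = []
        for f in range(assignment.k):
            train = truth.with_df(
                assignment.train_pairs(f).merge(truth.df, on=["cell_id", "drug_id"])
            )
            predictor = synthetic.drug_mean_predictor(
                train, jitter_sd=float(block.get("jitter_sd", 0.0)), seed=seed + f
            )
            frames.append(predictor(assignment.test_pairs(f)))
        pred = pd.concat(frames, ignore_index=True)
        pred = pred.drop_duplicates(subset=["cell_id", "drug_id"])
    else:
        raise ConfigError("evaluate needs 'predictions' or a prior split stage")
    report = metrics.evaluate(
        truth, pred,
        min_pairs=int(block.get("min_pairs", 3)),
        scc_threshold=float(block.get("scc_threshold", 0.5)),
    )
    paths = []
    p = out / "overall_metrics.csv"
    pd.DataFrame([report.overall]).to_csv(p, index=False, float_format="%.17g")
    paths.append(str(p))
    p = out / "per_drug_metrics.csv"
    report.per_drug.to_csv(p, index=False, float_format="%.17g")
    paths.append(str(p))
    p = out / "per_cell_metrics.csv"
    report.per_cell.to_csv(p, index=False, float_format="%.17g")
    paths.append(str(p))
    state["report"], state["predictions"] = report, pred
    return paths


def _run_harmonize(block: dict, seed: int, out: Path, state: dict) -> list[str]:
    inputs = block.get("inputs") or []
    if len(inputs) < 2:
        raise ConfigError("harmonize needs >= 2 'inputs' files")
    datasets = [
        read_triplets(p, block.get("response_type", "ln_ic50")) for p in inputs
    ]
    matrix = harmonization.cross_dataset_matrix(
        datasets,
        min_overlap=int(block.get("min_overlap", 10)),
        allow_mixed=bool(block.get("allow_mixed", False)),
    )
    paths = []
    p = out / "cross_dataset_scc.csv"
    matrix.scc.to_csv(p, float_format="%.17g")
    paths.append(str(p))
    p = out / "cross_dataset_n.csv"
    matrix.n_overlap.to_csv(p)
    paths.append(str(p))
    state["matrix"] = matrix
    return paths


def _run_plot(block: dict, seed: int, out: Path, state: dict) -> list[str]:
    paths = []
    kinds = block.get("kinds", ["waterfall", "scatter"])
    if "report" in state:
        truth, pred = state["truth"], state["predictions"]
        if "scatter" in kinds:
            p = out / "per_drug_scatter.png"
            viz.plot_per_drug_scatter(truth, pred, path=p)
            paths += [str(p), str(p.with_suffix(".csv"))]
        if "waterfall" in kinds:
            p = out / "waterfall.png"
            viz.plot_waterfall(state["report"].per_drug, path=p)
            paths += [str(p), str(p.with_suffix(".csv"))]
    if "matrix" in state and "heatmap" in kinds:
        p = out / "cross_dataset_heatmap.png"
        viz.plot_cross_dataset_heatmap(state["matrix"], path=p)
        paths += [str(p), str(p.with_suffix(".csv"))]
    if not paths:
        raise ConfigError("plot stage has nothing to draw (no prior evaluate/harmonize)")
    return paths


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "fit_dose_response": _run_fit_dose_response,
    "split": _run_split,
    "evaluate": _run_evaluate,
    "harmonize": _run_harmonize,
    "plot": _run_plot,
}
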