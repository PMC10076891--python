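"""End-to-end orchestration: wash -> split -> train -> predict.

Each stage materializes its artifacts to disk so a run can be resumed,
audited, or reproduced bit-for-bit from the config snapshot plus the master
seed. Any stage failure halts the run with a diagnostic; artifacts written
before the failure are retained.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import wash as washmod
from .data_io import (
    RunConfig, logger, read_descriptor_table, save_model,
    write_descriptor_table,
)
from .errors import QsarNetError
from .metrics import ModelReport, q_squared, r_squared
from .network import (
    TrainedModel, TrainState, derive_seeds, forward, init_network, predict,
    train,
)
from .split import SplitResult, sphere_exclusion_split
from .synthetic import SyntheticSpec, generate
from .table import DescriptorTable
from .wash import NormalizationParams, WashReport


@dataclass
class StageRecord:
    name: str
    status: str                 # "ok" or "failed: <reason>"
    seconds: float
    outputs: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineRun:
    stages: list[StageRecord] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ------------------------------------------------------------------- stages
def wash_table(
    table: DescriptorTable, config: RunConfig
) -> tuple[DescriptorTable, NormalizationParams, WashReport]:
    """Normalize, remove activity outliers, prune redundant descriptors."""
    w = config.wash
    normalized, norm = washmod.normalize(table, w.normalization)
    cleaned, out_report = washmod.detect_outliers(
        normalized, sigma=w.sigma, min_neighbors=w.min_neighbors,
        radius_quantile=w.radius_quantile,
    )
    pruned, prune_report = washmod.prune_correlated(cleaned, w.corr_threshold)
    report = WashReport(
        removed_outliers=out_report.removed_outliers,
        removed_descriptors=prune_report.removed_descriptors,
        normalization=norm,
    )
    return pruned, norm, report


def fit_model(
    washed: DescriptorTable,
    split: SplitResult,
    norm: NormalizationParams | None,
    config: RunConfig,
    seed: int | None = None,
) -> tuple[TrainedModel, TrainState, ModelReport]:
    """Train on an already-washed (normalized) table along a given split."""
    master = config.seed if seed is None else seed
    tr = washed.select_compounds(split.train_ids)
    te = washed.select_compounds(split.test_ids)
    # fit on the standardized activity scale; q2/r2 are invariant to this
    y_loc = float(tr.y.mean())
    y_scale = float(tr.y.std()) or 1.0
    init_seed = derive_seeds(master)[0] % (2**31)
    params = init_network(
        (washed.n, *config.network.hidden_layers, 1),
        use_bias=config.network.use_bias,
        seed=init_seed,
    )
    trained, state = train(
        params, tr.X, (tr.y - y_loc) / y_scale,
        te.X, (te.y - y_loc) / y_scale, config.network, seed=master,
    )
    model = TrainedModel(
        params=trained,
        normalization=norm,
        descriptor_names=washed.descriptor_names,
        activity_name=washed.activity_name,
        config=config.to_dict(),
        activity_location=y_loc,
        activity_scale=y_scale,
    )
    h_train = forward(trained, tr.X) * y_scale + y_loc
    h_test = forward(trained, te.X) * y_scale + y_loc
    report = ModelReport(
        q2_train=q_squared(tr.y, h_train),
        q2_test=q_squared(te.y, h_test),
        r2_test=r_squared(te.y, h_test),
        n_train=tr.m,
        n_test=te.m,
        descriptors=washed.descriptor_names,
        stopping_epoch=state.best_epoch,
        config=config.to_dict(),
    )
    return model, state, report


def train_state_frame(state: TrainState) -> pd.DataFrame:
    """Epoch-wise cost trajectories as a tidy frame for the history CSV."""
    eval_by_epoch = dict(state.cost_eval)
    return pd.DataFrame({
        "epoch": range(1, state.epochs_run + 1),
        "cost_train": state.cost_train,
        "cost_eval": [eval_by_epoch.get(e) for e in
                      range(1, state.epochs_run + 1)],
    })


# -------------------------------------------------------------- the pipeline
def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    input_csv: str | Path | None = None,
    activity_column: str = "activity",
    stages: tuple[str, ...] = ("wash", "split", "train", "predict"),
    synthetic_spec: SyntheticSpec | None = None,
) -> PipelineRun:
    """Run the requested stages in order, materializing every artifact.

    When ``"simulate"`` is the first stage a synthetic table is generated
    (per ``synthetic_spec`` or defaults seeded from the config) and used as
    the input; otherwise ``input_csv`` must exist.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(config=config.to_dict(), seed=config.seed)

    table: DescriptorTable | None = None
    washed = norm = split = model = None

    for stage in stages:
        t0 = time.perf_counter()
        rec = StageRecord(stage, "ok", 0.0)
        try:
            if stage == "simulate":
                spec = synthetic_spec or SyntheticSpec(seed=config.seed)
                table, truth = generate(spec)
                path = outdir / "simulated.csv"
                write_descriptor_table(table, path)
                truth.to_json(outdir / "ground_truth.json")
                activity_column = table.activity_name
                rec.outputs = {"table": str(path),
                               "truth": str(outdir / "ground_truth.json")}
            elif stage == "wash":
                if table is None:
                    table = read_descriptor_table(input_csv, activity_column)
                washed, norm, report = wash_table(table, config)
                path = outdir / "washed.csv"
                write_descriptor_table(washed, path)
                report.to_frame().to_csv(outdir / "wash_report.csv", index=False)
                rec.outputs = {"table": str(path),
                               "report": str(outdir / "wash_report.csv")}
            elif stage == "split":
                if washed is None:
                    raise QsarNetError("split stage requires a washed table")
                split = sphere_exclusion_split(washed, config.split.test_fraction)
                (outdir / "train_ids.txt").write_text(
                    "\n".join(split.train_ids) + "\n")
                (outdir / "test_ids.txt").write_text(
                    "\n".join(split.test_ids) + "\n")
                (outdir / "split.json").write_text(json.dumps({
                    "radius": split.radius,
                    "seed_compound": split.seed_compound,
                    "n_train": len(split.train_ids),
                    "n_test": len(split.test_ids),
                    "test_fraction": split.test_fraction,
                }, indent=1))
                rec.outputs = {"summary": str(outdir / "split.json")}
            elif stage == "train":
                if washed is None or split is None:
                    raise QsarNetError("train stage requires wash and split")
                model, state, report = fit_model(washed, split, norm, config)
                save_model(model, outdir / "model.json")
                train_state_frame(state).to_csv(
                    outdir / "history.csv", index=False)
                report.to_json(outdir / "model_report.json")
                rec.outputs = {
                    "model": str(outdir / "model.json"),
                    "history": str(outdir / "history.csv"),
                    "report": str(outdir / "model_report.json"),
                }
            elif stage == "predict":
                if model is None or table is None:
                    raise QsarNetError("predict stage requires a trained model")
                preds = predict(model, table)
                preds.to_frame().to_csv(outdir / "predictions.csv")
                rec.outputs = {"predictions": str(outdir / "predictions.csv")}
            else:
                raise QsarNetError(f"unknown pipeline stage {stage!r}")
        except Exception as exc:
            rec.status = f"failed: {exc}"
            rec.seconds = time.perf_counter() - t0
            run.stages.append(rec)
            run.to_json(outdir / "pipeline_run.json")
            logger.error("pipeline: stage %s failed: %s", stage, exc)
            raise
        rec.seconds = time.perf_counter() - t0
        run.stages.append(rec)
        logger.info("pipeline: stage %s done in %.2fs", stage, rec.seconds)
    run.to_json(outdir / "pipeline_run.json")
    return run
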