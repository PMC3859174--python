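"""End-to-end orchestration of the QSBR analysis.

A :func:`run_pipeline` call executes the study stages in order -- load or
simulate data, screen outliers, split, select descriptors, fit models,
validate -- from a single configuration mapping (typically parsed from
YAML by the CLI), writing every artifact plus a manifest into the run
directory.  :func:`reproduce_tables` is the one-shot regeneration of the
published per-subset statistics from the packaged dataset and its printed
predictions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dataset_io, models, selection, synthetic, validation

log = logging.getLogger("qsbr")

MODEL_COLUMNS = {"mlr": "pred_mlr", "svm": "pred_svm", "ann": "pred_ann"}


class ConfigError(ValueError):
    """The pipeline configuration failed validation before execution."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def validate_config(config: dict) -> dict:
    """Check a pipeline configuration before any stage runs.

    Returns the config with defaults filled in.  Raises
    :class:`ConfigError` on missing/unknown inputs so a bad run aborts
    cleanly before producing artifacts.
    """
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", ["validate"])
    cfg.setdefault("models", ["published"])
    cfg.setdefault("selection", {})
    source = cfg.setdefault("input", {"kind": "fixture"})
    kind = source.get("kind")
    if kind not in {"fixture", "csv", "synthetic"}:
        raise ConfigError(f"input.kind must be fixture|csv|synthetic, got {kind!r}")
    if kind == "csv":
        path = source.get("path")
        if not path or not Path(path).exists():
            raise ConfigError(f"input.path does not exist: {path!r}")
    known = {"mlr", "svr", "ann", "published", "svm"}
    bad = [m for m in cfg["models"] if m not in known]
    if bad:
        raise ConfigError(f"unknown model famil(ies): {bad}")
    return cfg


def _load_input(cfg: dict) -> pd.DataFrame:
    kind = cfg["input"]["kind"]
    if kind == "fixture":
        return dataset_io.packaged_frame()
    if kind == "csv":
        return dataset_io._records_to_frame(
            dataset_io.load_dataset(cfg["input"]["path"])
        )
    spec = cfg["input"].get("synthetic", {})
    config = synthetic.SyntheticConfig(
        n=int(spec.get("n", 181)), seed=int(cfg["seed"])
    )
    X, y = synthetic.gen_joint(config)
    frame = X.copy()
    frame["observed"] = y
    frame["sequence"] = [f"SYN{i:04d}" for i in range(len(frame))]
    frame["partition"] = "training"
    return frame


def make_report(
    reports: Sequence[validation.ValidationReport],
) -> pd.DataFrame:
    """Tabulate validation reports, one row per (model, partition)."""
    if not reports:
        raise ValueError("need at least one validation report")
    return pd.DataFrame([r.to_dict() for r in reports]).set_index(
        ["model", "partition"]
    )


def reproduce_tables(with_external: bool = True) -> pd.DataFrame:
    """Regenerate the per-subset statistics of the published study.

    Uses the packaged observations and the printed MLR/SVM/ANN
    predictions; returns a table keyed by (model, partition-or-pool) with
    MPD, IPD bin fractions, R^2/RMSE fit quality, and the external
    criteria on the test partition.
    """
    df = dataset_io.packaged_frame()
    reports: list[validation.ValidationReport] = []
    pools = {
        "training": df[df.partition == "training"],
        "test": df[df.partition == "test"],
        "validation": df[df.partition == "validation"],
        "test+validation": df[df.partition.isin(["test", "validation"])],
        "whole": df,
    }
    for model, col in MODEL_COLUMNS.items():
        for pool, sub in pools.items():
            reports.append(
                validation.ValidationReport.compute(
                    model,
                    pool,
                    sub["observed"],
                    sub[col],
                    p=6,
                    with_external=with_external and pool == "test",
                )
            )
    return make_report(reports)


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the configured stages and write artifacts to ``out_dir``.

    Stages (subset via ``config['stages']``): ``screen`` (outlier check),
    ``partition`` (k-means re-split), ``select`` (the three-stage
    descriptor cascade), ``fit`` (model building on the training part),
    ``validate`` (statistics per model and partition).  A manifest with
    the resolved config and seed is always written; any stage failure
    aborts with the stage name, leaving the manifest marking the partial
    run.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _jsonable(cfg), "completed": []}
    seed = int(cfg["seed"])

    def checkpoint() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    checkpoint()
    try:
        stage = "load"
        df = _load_input(cfg)
        df.to_csv(out / "dataset.csv", index=False)
        manifest["completed"].append(stage)

        feature_cols = [
            c
            for c in df.columns
            if c
            not in {"sequence", "partition", "observed", "duplicate"}
            and not c.startswith(("pred_", "ipd_"))
        ]
        if "screen" in cfg["stages"]:
            stage = "screen"
            flagged = dataset_io.screen_outliers(
                df["observed"], cfg.get("outlier_threshold", 3.0)
            )
            (out / "outliers.json").write_text(json.dumps(flagged))
            log.info("outlier screen: %d flagged", len(flagged))
            manifest["completed"].append(stage)

        if "partition" in cfg["stages"]:
            stage = "partition"
            feats = df[feature_cols + ["observed"]] if feature_cols else df[["observed"]]
            part = dataset_io.kmeans_partition(
                feats,
                n_clusters=cfg.get("n_clusters", 10),
                fractions=tuple(cfg.get("fractions", (0.79, 0.16, 0.05))),
                seed=seed,
            )
            df["partition"] = part.labels
            df.to_csv(out / "dataset.csv", index=False)
            manifest["completed"].append(stage)

        selected = feature_cols
        if "select" in cfg["stages"]:
            stage = "select"
            train = df[df.partition == "training"]
            sel_cfg = cfg["selection"]
            result = selection.run_cascade(
                train[feature_cols],
                train["observed"],
                gapls_config=selection.GaplsConfig(
                    seed=seed, **sel_cfg.get("gapls", {})
                ),
                p_enter=sel_cfg.get("p_enter", 0.05),
                p_remove=sel_cfg.get("p_remove", 0.10),
            )
            result.to_json(out / "selection.json")
            selected = result.kept
            log.info("selection kept %d descriptors: %s", len(selected), selected)
            manifest["completed"].append(stage)

        fitted: dict[str, models.FittedModel] = {}
        if "fit" in cfg["stages"]:
            stage = "fit"
            train = df[df.partition == "training"]
            X, y = train[selected], train["observed"]
            for family in cfg["models"]:
                if family == "published":
                    continue
                if family == "mlr":
                    fitted[family] = models.fit_mlr(X, y)
                elif family in ("svr", "svm"):
                    fitted["svr"] = models.fit_svr(
                        X, y, models.SvrConfig(**cfg.get("svr", {}))
                    )
                elif family == "ann":
                    fitted[family] = models.fit_ann(
                        X, y, models.AnnConfig(seed=seed, **cfg.get("ann", {}))
                    )
            for family, model in fitted.items():
                model.to_json(out / f"model_{family}.json")
            manifest["completed"].append(stage)

        if "validate" in cfg["stages"]:
            stage = "validate"
            reports = []
            for family in cfg["models"]:
                for part_name in dataset_io.PARTITIONS:
                    sub = df[df.partition == part_name]
                    if sub.empty:
                        continue
                    if family == "published":
                        pred = models.predict_published(sub[list(selected)])
                    elif family in MODEL_COLUMNS and MODEL_COLUMNS[family] in sub:
                        pred = sub[MODEL_COLUMNS[family]]
                    elif family in fitted or (family == "svm" and "svr" in fitted):
                        pred = fitted.get(family, fitted.get("svr")).predict(sub)
                    else:
                        raise StageError(
                            f"no predictions available for model {family!r}"
                        )
                    reports.append(
                        validation.ValidationReport.compute(
                            family,
                            part_name,
                            sub["observed"],
                            np.asarray(pred, dtype=float),
                            p=len(selected),
                            with_external=part_name == "test",
                        )
                    )
            table = make_report(reports)
            table.to_csv(out / "validation.csv")
            (out / "validation.json").write_text(
                json.dumps(_jsonable(table.reset_index().to_dict("records")), indent=2)
            )
            manifest["completed"].append(stage)
    except (ConfigError, StageError):
        checkpoint()
        raise
    except Exception as exc:
        checkpoint()
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    checkpoint()
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
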