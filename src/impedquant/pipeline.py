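"""End-to-end pipelines: simulate -> split -> train -> evaluate.

``run_quantification`` reproduces the five-way concentration assay: one
chip, three ~1,000-bead experiments per concentration, a stratified 70:30
train/test split, a 30:70 layer split, coarse-kNN layers 1 and 2, and 50
disjoint test mock experiments (10 per class, each holding 10 % of the
class's test peaks).

``run_binary`` reproduces the control-vs-protein (OSCC screening) assay:
two chips pooled (the second including the 25 and 300 pg/mL fill-in
points), non-zero concentrations relabeled "protein" and undersampled to
balance the control group, a linear-discriminant layer 1, coarse-kNN
layer 2, and 10 test mocks.

A master seed deterministically derives per-stage seeds (by hashing the
stage name) so any stage can be rerun in isolation; runs with the same
master seed are byte-identical.  When ``output_dir`` is set, each run
writes its artifacts (peak tables, confusion matrices, report JSON) plus
a manifest sufficient to reproduce them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import PipelineConfig, chip1_design, chip2_design
from .errors import ImpedquantError, StageError
from .evaluate import ConfusionMatrix, accuracy, confusion, composition_scatter
from .resample import (BINARY_LABEL_COLUMN, LABEL_COLUMN_DEFAULT,
                       binarize_and_balance, layer_split, make_test_mocks,
                       pool_experiments, train_test_split)
from .synthgen import simulate_study
from .tables import amplitude_matrix
from .twolayer import (TwoLayerModel, fit_two_layer, predict_sample,
                       _predict_layer1, save_model)
from .io import write_peak_table, write_mocks

__all__ = ["derive_seed", "run_quantification", "run_binary"]

logger = logging.getLogger("impedquant")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ImpedquantError as exc:
            raise StageError(name, str(exc)) from exc
    return wrap


def _evaluate_mocks(model: TwoLayerModel, mocks):
    true_labels = [m.sample_label for m in mocks]
    pred_labels = []
    for m in mocks:
        lab, _ = predict_sample(model, m)
        pred_labels.append(lab)
    cm = confusion(true_labels, pred_labels, model.class_order)
    return cm, accuracy(cm)


def _layer1_bead_eval(model: TwoLayerModel, test: pd.DataFrame, label_col: str):
    pred, scores = _predict_layer1(model.layer1, amplitude_matrix(test))
    cm = confusion(test[label_col].to_numpy(), pred, model.class_order)
    return cm, accuracy(cm), scores


def _cm_dict(cm: ConfusionMatrix) -> dict:
    return {"class_order": [str(c) for c in cm.class_order],
            "counts": cm.counts.tolist()}


def _write_artifacts(report: dict, config: PipelineConfig, model, tables: dict,
                     mocks, scatter_points: pd.DataFrame | None) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        write_peak_table(table, out / f"{name}.csv")
    write_mocks(mocks, out / "test_mocks.csv")
    save_model(model, out / "model.json")
    if scatter_points is not None:
        scatter_points.to_csv(out / "composition_scatter.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
    manifest = {
        "impedquant_version": _pkg_version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": config.master_seed,
        "stage_seeds": {s: derive_seed(config.master_seed, s)
                        for s in ("simulate-chip1", "simulate-chip2", "split")},
        "task": config.task,
        "layer1_kind": config.layer1_kind,
        "generator": dataclasses.asdict(config.generator),
        "detection": dataclasses.asdict(config.detection),
        "split": dataclasses.asdict(config.split),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str),
        encoding="utf-8")


def run_quantification(config: PipelineConfig) -> dict:
    """Run the five-way concentration-quantification pipeline.

    Returns a report with the layer-1 bead confusion matrix, the 50-mock
    sample confusion matrix, both accuracies, per-stage counts and the
    composition-scatter point set; artifacts land in ``config.output_dir``
    when set.
    """
    gen = config.generator
    design = dict(config.design) if config.design is not None else chip1_design()
    spec = dataclasses.replace(config.split,
                               seed=derive_seed(config.master_seed, "split"))
    label_col = LABEL_COLUMN_DEFAULT

    table = _stage("simulate")(simulate_study, gen, design,
                               derive_seed(config.master_seed, "simulate-chip1"),
                               "chip1")
    train, test = _stage("split")(train_test_split, table, spec)
    l1_train, l2_train = _stage("layer-split")(layer_split, train, spec)
    model = _stage("train")(fit_two_layer, l1_train, l2_train, spec,
                            config.layer1_kind, label_col)
    mocks = _stage("test-mocks")(make_test_mocks, test, spec)
    sample_cm, sample_acc = _stage("predict")(_evaluate_mocks, model, mocks)
    bead_cm, bead_acc, _ = _stage("evaluate")(_layer1_bead_eval, model, test,
                                              label_col)
    x_cls, y_cls = model.class_order[0], model.class_order[1]
    points = composition_scatter(mocks, model.layer1, x_cls, y_cls,
                                 ax=_null_axis())

    report = {
        "task": "quantification",
        "n_peaks": int(len(table)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "n_layer1_train": int(len(l1_train)),
        "n_layer2_train": int(len(l2_train)),
        "n_test_mocks": len(mocks),
        "test_mock_sizes": sorted({len(m) for m in mocks}),
        "layer1_bead_confusion": _cm_dict(bead_cm),
        "layer1_bead_accuracy": bead_acc,
        "sample_confusion": _cm_dict(sample_cm),
        "sample_accuracy": sample_acc,
        "composition_scatter_classes": [str(x_cls), str(y_cls)],
        "master_seed": config.master_seed,
    }
    logger.info("quantification: %d peaks -> %d/%d train/test, %d mocks, "
                "bead acc %.3f, sample acc %.3f", len(table), len(train),
                len(test), len(mocks), bead_acc, sample_acc)
    if config.output_dir:
        _write_artifacts(report, config, model,
                         {"peaks": table, "train": train, "test": test},
                         mocks, points)
    return report


def run_binary(config: PipelineConfig) -> dict:
    """Run the binary control-vs-protein pipeline on two pooled chips."""
    gen = config.generator
    if gen.n_chips < 2:
        raise StageError("simulate", "the binary pipeline pools two chips; "
                         "generator.n_chips must be >= 2")
    spec = dataclasses.replace(config.split,
                               seed=derive_seed(config.master_seed, "split"))
    if config.design is not None:
        d1 = d2 = dict(config.design)
    else:
        d1, d2 = chip1_design(), chip2_design()

    t1 = _stage("simulate")(simulate_study, gen, d1,
                            derive_seed(config.master_seed, "simulate-chip1"),
                            "chip1")
    t2 = _stage("simulate")(simulate_study, gen, d2,
                            derive_seed(config.master_seed, "simulate-chip2"),
                            "chip2")
    pooled = _stage("pool")(pool_experiments, [t1, t2])
    balanced = _stage("balance")(binarize_and_balance, pooled, spec)
    label_col = BINARY_LABEL_COLUMN
    train, test = _stage("split")(train_test_split, balanced, spec, label_col)
    l1_train, l2_train = _stage("layer-split")(layer_split, train, spec,
                                               label_col)
    model = _stage("train")(fit_two_layer, l1_train, l2_train, spec,
                            config.layer1_kind, label_col)
    mocks = _stage("test-mocks")(make_test_mocks, test, spec, label_col)
    sample_cm, sample_acc = _stage("predict")(_evaluate_mocks, model, mocks)
    bead_cm, bead_acc, _ = _stage("evaluate")(_layer1_bead_eval, model, test,
                                              label_col)
    points = composition_scatter(mocks, model.layer1, model.class_order[0],
                                 model.class_order[1], ax=_null_axis())

    n_control = int((balanced[label_col] == "control").sum())
    n_protein = int((balanced[label_col] == "protein").sum())
    report = {
        "task": "binary",
        "n_peaks_pooled": int(len(pooled)),
        "n_control": n_control,
        "n_protein": n_protein,
        "balanced": n_control == n_protein,
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "n_test_mocks": len(mocks),
        "test_mock_sizes": sorted({len(m) for m in mocks}),
        "layer1_bead_confusion": _cm_dict(bead_cm),
        "layer1_bead_accuracy": bead_acc,
        "sample_confusion": _cm_dict(sample_cm),
        "sample_accuracy": sample_acc,
        "master_seed": config.master_seed,
    }
    logger.info("binary: %d pooled -> %d+%d balanced, %d mocks, bead acc "
                "%.3f, sample acc %.3f", len(pooled), n_control, n_protein,
                len(mocks), bead_acc, sample_acc)
    if config.output_dir:
        _write_artifacts(report, config, model,
                         {"pooled": pooled, "balanced": balanced,
                          "train": train, "test": test},
                         mocks, points)
    return report


def _null_axis():
    """A headless matplotlib axis so pipelines stay side-effect free."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig = plt.figure()
    ax = fig.add_subplot(111)
    plt.close(fig)
    return ax
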