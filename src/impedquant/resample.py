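"""Pooling, splitting, mock-experiment construction and class balancing.

The assay protocol pools all experiments per class, splits the peaks
70:30 into training and test sets (stratified per class so every class
survives every stage), splits the training peaks 30:70 between the
bead-level (layer-1) and sample-level (layer-2) models, partitions the
layer-2 peaks into 100 equal-sized disjoint *mock experiments* per class
(each worth roughly 3 min of recording), and partitions each class's test
peaks into disjoint test mocks holding 10 % of the class each.

Rounding conventions: the 70:30 and 30:70 splits use round-half-up on the
training count; mock sizes use floor, dropping the remainder peaks.
All operations are deterministic functions of their inputs and the
``SplitSpec`` seed; each operation derives an independent RNG stream so a
stage can be rerun in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SplitSpec
from .errors import InputError
from .tables import amplitude_columns

__all__ = [
    "MockExperiment",
    "LABEL_COLUMN_DEFAULT",
    "BINARY_LABEL_COLUMN",
    "pool_experiments",
    "train_test_split",
    "layer_split",
    "make_training_mocks",
    "make_test_mocks",
    "binarize_and_balance",
]

LABEL_COLUMN_DEFAULT = "concentration_pg_ml"
BINARY_LABEL_COLUMN = "group"

_CONTROL, _PROTEIN = "control", "protein"


@dataclass
class MockExperiment:
    """A disjoint subset of peaks treated as one sample with one label."""

    peaks: pd.DataFrame
    sample_label: object
    mock_id: str

    def __post_init__(self):
        if len(self.peaks) == 0:
            raise InputError(f"mock experiment {self.mock_id} is empty")

    def __len__(self) -> int:
        return len(self.peaks)


def _rng(spec: SplitSpec, op_tag: int) -> np.random.Generator:
    # independent stream per operation so stages can be rerun in isolation
    return np.random.default_rng(np.random.SeedSequence([spec.seed, op_tag]))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _class_groups(table: pd.DataFrame, label_col: str):
    if label_col not in table.columns:
        raise InputError(f"peak table has no label column '{label_col}'")
    return table.groupby(label_col, sort=True)


def pool_experiments(tables: list) -> pd.DataFrame:
    """Concatenate peak tables, preserving provenance columns."""
    if not tables:
        raise InputError("no tables to pool")
    n_ch = len(amplitude_columns(tables[0]))
    for t in tables[1:]:
        if len(amplitude_columns(t)) != n_ch:
            raise InputError("cannot pool tables with different panel lengths")
    return pd.concat(tables, ignore_index=True)


def _stratified_split(table: pd.DataFrame, fraction: float, label_col: str,
                      rng: np.random.Generator, min_rows: int = 10):
    first_idx, second_idx = [], []
    for _, grp in _class_groups(table, label_col):
        n = len(grp)
        if n < min_rows:
            raise InputError(
                f"class {grp[label_col].iloc[0]!r} has only {n} rows "
                f"(minimum {min_rows})")
        n_first = _round_half_up(fraction * n)
        perm = rng.permutation(grp.index.to_numpy())
        first_idx.append(perm[:n_first])
        second_idx.append(perm[n_first:])
    first = table.loc[np.concatenate(first_idx)].sort_index()
    second = table.loc[np.concatenate(second_idx)].sort_index()
    return first, second


def train_test_split(table: pd.DataFrame, spec: SplitSpec,
                     label_col: str = LABEL_COLUMN_DEFAULT):
    """Stratified 70:30 (by default) train/test split of a peak table."""
    rng = _rng(spec, 1)
    return _stratified_split(table, spec.train_fraction, label_col, rng)


def layer_split(train: pd.DataFrame, spec: SplitSpec,
                label_col: str = LABEL_COLUMN_DEFAULT):
    """Stratified 30:70 split of the training peaks into layer-1/layer-2."""
    rng = _rng(spec, 2)
    return _stratified_split(train, spec.layer1_fraction_of_train,
                             label_col, rng)


def make_training_mocks(layer2_train: pd.DataFrame, spec: SplitSpec,
                        label_col: str = LABEL_COLUMN_DEFAULT) -> list:
    """Partition each class into ``n_training_mocks_per_class`` equal mocks.

    Per class the peaks are shuffled and divided into equal-sized disjoint
    groups; the remainder (n mod n_mocks) peaks are dropped.
    """
    rng = _rng(spec, 3)
    mocks = []
    for label, grp in _class_groups(layer2_train, label_col):
        n_mocks = spec.n_training_mocks_per_class
        size = len(grp) // n_mocks
        if size < 1:
            raise InputError(
                f"class {label!r} has {len(grp)} rows; cannot form "
                f"{n_mocks} non-empty mocks")
        perm = rng.permutation(grp.index.to_numpy())
        for m in range(n_mocks):
            idx = perm[m * size:(m + 1) * size]
            mocks.append(MockExperiment(layer2_train.loc[idx], label,
                                        f"train-{label}-{m + 1}"))
    return mocks


def make_test_mocks(test: pd.DataFrame, spec: SplitSpec,
                    label_col: str = LABEL_COLUMN_DEFAULT) -> list:
    """Partition each class's test peaks into disjoint fixed-fraction mocks.

    Each mock holds ``floor(test_mock_fraction * n_class)`` peaks;
    ``n_test_mocks_per_class`` disjoint mocks are drawn per class (10 for
    the five-way quantification task -> 50 mocks; 5 for the binary task
    -> 10 mocks).
    """
    rng = _rng(spec, 4)
    mocks = []
    for label, grp in _class_groups(test, label_col):
        size = math.floor(spec.test_mock_fraction * len(grp))
        if size < 1:
            raise InputError(
                f"class {label!r} has {len(grp)} rows; "
                f"{spec.test_mock_fraction:.0%} of it is not a whole peak")
        needed = size * spec.n_test_mocks_per_class
        if needed > len(grp):
            raise InputError(
                f"class {label!r}: {spec.n_test_mocks_per_class} disjoint "
                f"mocks of {size} peaks need {needed} rows, have {len(grp)}")
        perm = rng.permutation(grp.index.to_numpy())
        for m in range(spec.n_test_mocks_per_class):
            idx = perm[m * size:(m + 1) * size]
            mocks.append(MockExperiment(test.loc[idx], label,
                                        f"test-{label}-{m + 1}"))
    return mocks


def binarize_and_balance(table: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Relabel concentrations as control/protein and balance group sizes.

    The negative control (0 pg/mL) keeps its own group; every non-zero
    concentration becomes ``"protein"``.  The larger group is undersampled
    without replacement to the size of the smaller, giving an exactly
    balanced table with a new ``group`` column (original concentration
    labels are preserved).

    The undersampling is stratified proportionally over (chip, original
    concentration) strata.  Unstratified subsampling lets the retained
    group's chip mix fluctuate; because chips are identifiable from their
    amplitude offsets and the same subsample later feeds both training and
    test splits, that shared fluctuation leaks label information and lifts
    a no-effect dataset above chance.  Proportional allocation removes the
    imbalance at its source.
    """
    if LABEL_COLUMN_DEFAULT not in table.columns:
        raise InputError(f"peak table has no '{LABEL_COLUMN_DEFAULT}' column")
    rng = _rng(spec, 5)
    out = table.copy()
    conc = out[LABEL_COLUMN_DEFAULT].to_numpy(dtype=float)
    out[BINARY_LABEL_COLUMN] = np.where(conc > 0, _PROTEIN, _CONTROL)
    n_control = int((out[BINARY_LABEL_COLUMN] == _CONTROL).sum())
    n_protein = int((out[BINARY_LABEL_COLUMN] == _PROTEIN).sum())
    if n_control == 0 or n_protein == 0:
        raise InputError("both a control group and a protein group are "
                         "required for the binary task")
    target = min(n_control, n_protein)
    parts = []
    for name in (_CONTROL, _PROTEIN):
        grp = out[out[BINARY_LABEL_COLUMN] == name]
        if len(grp) > target:
            grp = _stratified_subsample(grp, target, rng)
        parts.append(grp)
    return pd.concat(parts).sort_index()


def _stratified_subsample(grp: pd.DataFrame, target: int,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Sample ``target`` rows with proportional (largest-remainder)
    allocation over (chip_id, concentration) strata."""
    strata = list(grp.groupby(["chip_id", LABEL_COLUMN_DEFAULT], sort=True))
    exact = np.array([target * len(g) / len(grp) for _, g in strata])
    take = np.floor(exact).astype(int)
    frac_order = np.argsort(-(exact - take), kind="stable")
    for i in frac_order[: target - take.sum()]:
        take[i] += 1
    kept = []
    for (_, g), k in zip(strata, take):
        kept.append(rng.choice(g.index.to_numpy(), size=k, replace=False))
    return grp.loc[np.sort(np.concatenate(kept))]
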