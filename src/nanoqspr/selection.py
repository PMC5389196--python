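"""Kennard-Stone subset selection and train/validation splitting.

The calibration subset (32 congeners, 2% of 1,701 by default) is picked by
the Kennard-Stone maximin rule in the autoscaled space of all 26
descriptors: start from the two most distant points, then repeatedly add
the point whose minimum distance to the already-selected set is largest.
The selection is split 24/8 into training/validation by taking every
fourth congener of the selection order; everything unselected forms the
prediction set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


def autoscale(
    X, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise standardization to mean 0, sd 1 (default ddof = 1).

    Accepts an ndarray or DataFrame; returns (scaled array, means, sds).
    A zero-variance column raises, naming the offending column.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = list(range(arr.shape[1])) if arr.ndim == 2 else []
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("autoscale needs a 2-D array with at least 2 rows")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sds == 0.0)
    if bad.size:
        raise ValueError(f"zero-variance column(s): {[names[j] for j in bad]}")
    return (arr - means) / sds, means, sds


def kennard_stone(X: np.ndarray, k: int) -> list[int]:
    """Kennard-Stone maximin selection of *k* row indices from scaled *X*.

    The first two picks are the pair at maximal Euclidean distance; each
    later pick maximizes the minimum distance to the selected set.  Ties
    break toward the lowest row index, making the output deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= {n}, got {k}")
    # squared pairwise distances via the Gram expansion; symmetric, >= 0
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    i, j = divmod(int(np.argmax(d2)), n)  # first max in row-major order
    selected = [min(i, j), max(i, j)]
    free = np.ones(n, dtype=bool)
    free[selected] = False
    mindist = np.minimum(d2[selected[0]], d2[selected[1]])
    while len(selected) < k:
        cand = np.where(free, mindist, -np.inf)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        free[nxt] = False
        np.minimum(mindist, d2[nxt], out=mindist)
    return selected


@dataclass
class SplitResult:
    """Partition of the congener set into training/validation/prediction.

    ``scaling_means``/``scaling_sds`` are the autoscaling statistics of the
    selection space (all descriptors over the full congener set).
    """

    training_indices: list[int]
    validation_indices: list[int]
    prediction_indices: list[int]
    scaling_means: list[float] = field(default_factory=list)
    scaling_sds: list[float] = field(default_factory=list)

    @property
    def selected_indices(self) -> list[int]:
        return self.training_indices + self.validation_indices

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "training_indices": self.training_indices,
                    "validation_indices": self.validation_indices,
                    "prediction_indices": self.prediction_indices,
                    "scaling_means": self.scaling_means,
                    "scaling_sds": self.scaling_sds,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SplitResult":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)


def split_train_validation(
    selected: Sequence[int],
    n_val: int,
    n_total: int | None = None,
    scaling_means: Sequence[float] = (),
    scaling_sds: Sequence[float] = (),
) -> SplitResult:
    """Split the Kennard-Stone selection into training and validation sets.

    Every ``ceil(len(selected)/n_val)``-th congener of the selection order
    (i.e. selection ranks step, 2*step, ...) goes to validation, the rest to
    training; with the 32/8 default this is ranks 4, 8, ..., 32.  If the
    stride yields fewer than *n_val* picks the tail of the selection order
    tops it up.  ``n_val = 0`` puts everything in training.
    """
    selected = list(selected)
    if len(set(selected)) != len(selected):
        raise ValueError("selected indices contain duplicates")
    if n_val < 0 or n_val >= len(selected):
        if n_val != 0:
            raise ValueError("n_val must satisfy 0 <= n_val < len(selected)")
    if n_val == 0:
        val: list[int] = []
    else:
        step = math.ceil(len(selected) / n_val)
        val = selected[step - 1 :: step][:n_val]
        for idx in reversed(selected):  # top-up from the latest KS ranks
            if len(val) == n_val:
                break
            if idx not in val:
                val.append(idx)
    val_set = set(val)
    train = [i for i in selected if i not in val_set]
    if n_total is None:
        prediction: list[int] = []
    else:
        sel_set = set(selected)
        prediction = [i for i in range(n_total) if i not in sel_set]
    return SplitResult(
        training_indices=train,
        validation_indices=val,
        prediction_indices=prediction,
        scaling_means=list(map(float, scaling_means)),
        scaling_sds=list(map(float, scaling_sds)),
    )
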