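"""Leverage-based applicability domain and Insubria-plot data.

The applicability domain (AD) of a QSPR model is the descriptor-space
region where its predictions count as interpolation.  For each congener
the leverage

    h = x' (X'X)^{-1} x

measures the distance from the training-set centroid in the autoscaled
space of the selected descriptors (X is the autoscaled training block; the
query x is scaled with the training statistics).  A congener is inside the
domain when h <= h* with the conventional critical leverage
h* = 3 (p + 1) / n; with p = 4 descriptors and n = 24 training congeners
this gives 0.625.  The Insubria table pairs every congener's leverage with
its predicted adsorption energy, which is the standard way to judge AD
membership for a prediction set lacking reference values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .pls import PLSModel, predict
from .selection import SplitResult


def critical_leverage(p: int, n: int) -> float:
    """Critical leverage h* = 3 (p + 1) / n.

    p is the number of model descriptors, n the training-set size.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if n <= p:
        raise ValueError(f"training size n={n} must exceed descriptor count p={p}")
    return 3.0 * (p + 1) / n


def leverage(X_train_scaled, X_query_scaled) -> np.ndarray:
    """Leverages h = x'(X'X)^{-1}x of query rows w.r.t. the training block.

    Both arguments must already be in the same autoscaled space (training
    statistics).  Uses a Cholesky solve, never an explicit inverse.
    """
    X = np.asarray(X_train_scaled, dtype=float)
    Q = np.atleast_2d(np.asarray(X_query_scaled, dtype=float))
    xtx = X.T @ X
    try:
        cho = linalg.cho_factor(xtx)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "X'X is singular - the selected descriptors are collinear on the "
            "training set; drop or decorrelate descriptors"
        ) from exc
    return np.einsum("ij,ji->i", Q, linalg.cho_solve(cho, Q.T))


@dataclass
class ADSummary:
    """Counts of congeners outside the applicability domain."""

    h_star: float
    n_out_of_domain: int
    n_total: int

    @property
    def pct_out_of_domain(self) -> float:
        return 100.0 * self.n_out_of_domain / self.n_total

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "h_star": self.h_star,
                    "n_out_of_domain": self.n_out_of_domain,
                    "n_total": self.n_total,
                    "pct_out_of_domain": self.pct_out_of_domain,
                },
                fh,
                indent=1,
            )


def insubria_table(
    model: PLSModel,
    split: SplitResult,
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, ADSummary]:
    """Per-congener leverage, prediction and set label; plus the AD summary.

    The returned frame holds the Insubria-plot data (x = leverage,
    y = predicted E_ads, vertical cut at h*) for every congener in
    *table*, flagged in/out of domain against h* = 3(p+1)/n_train.
    """
    X_all = table[model.selected_descriptors].to_numpy(dtype=float)
    Xs_all = (X_all - model.x_mean) / model.x_sd
    train_rows = table.index[table["index"].isin(split.training_indices)]
    Xs_train = Xs_all[table.index.get_indexer(train_rows)]
    h = leverage(Xs_train, Xs_all)
    h_star = critical_leverage(len(model.selected_descriptors), len(split.training_indices))
    label = np.full(len(table), "prediction", dtype=object)
    label[table["index"].isin(split.training_indices)] = "training"
    label[table["index"].isin(split.validation_indices)] = "validation"
    result = pd.DataFrame(
        {
            "index": table["index"].to_numpy(),
            "name": table["name"].to_numpy(),
            "set_label": label,
            "leverage": h,
            "predicted_E_ads_kcal_mol": predict(model, table),
            "in_domain": h <= h_star,
        }
    )
    summary = ADSummary(
        h_star=h_star,
        n_out_of_domain=int((~result["in_domain"]).sum()),
        n_total=len(result),
    )
    return result, summary
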