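"""Clamping-based interpretation of trained ensembles.

Clamping fixes one photoreceptor input at its median value across the whole
stimulus database, so that input carries no information, and re-evaluates
each trained network on the complete database.  A receptor whose clamping
drops accuracy towards chance (0.5 in this balanced two-class design) was
load-bearing.  For load-bearing receptors, the direction analysis splits
the stimuli whose classification changed by the sign of
(clamped − original) excitation and reports, within each sign group, the
proportion reclassified 'leaf'→'animal' — exposing the opponent sign
structure the network learned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ann_engine import EnsembleResult, MLPModel, accuracy, classify
from .receptor_model import RECEPTOR_COLUMNS, ExcitationDataset


def _as_frame(dataset) -> pd.DataFrame:
    return dataset.frame if isinstance(dataset, ExcitationDataset) else dataset


def clamp_dataset(dataset, receptor_id: str) -> pd.DataFrame:
    """Return a copy of the excitation table with one receptor fixed at its median.

    The median is taken over all rows of the table passed in (both classes,
    both illumination conditions); the caller decides whether fabrics are
    part of that database.
    """
    frame = _as_frame(dataset)
    if receptor_id not in RECEPTOR_COLUMNS:
        raise ValueError(f"unknown receptor {receptor_id!r}; expected one of {tuple(RECEPTOR_COLUMNS)}")
    column = RECEPTOR_COLUMNS[receptor_id]
    clamped = frame.copy()
    clamped[column] = frame[column].median()
    return clamped


def clamping_accuracy(ensemble: EnsembleResult, dataset) -> pd.DataFrame:
    """Accuracy of each model on the full database with each receptor clamped.

    Returns one row per receptor (plus a ``baseline`` row with no clamping)
    with per-model accuracies summarized as mean and sample s.d.
    """
    frame = _as_frame(dataset)
    spec = ensemble.task_spec
    y = spec.labels(frame)

    def summarize(name: str, frame_used: pd.DataFrame) -> dict:
        X = spec.design(frame_used)
        accs = np.array([accuracy(m, X, y) for m in ensemble.models])
        return {"receptor": name, "mean_accuracy": accs.mean(),
                "sd_accuracy": accs.std(ddof=1) if accs.size > 1 else 0.0,
                "accuracies": accs}

    rows = [summarize("baseline", frame)]
    for rid in spec.input_subset:
        rows.append(summarize(rid, clamp_dataset(frame, rid)))
    return pd.DataFrame(rows)


def reclassification_analysis(ensemble: EnsembleResult, dataset,
                              receptor_id: str) -> pd.DataFrame:
    """Direction of the classification changes caused by clamping one receptor.

    For each model: find the stimuli whose classification changed, split
    them by whether clamping increased or decreased that stimulus's
    excitation for the clamped receptor, and within each sign group report
    the proportion of changes that went positive-ward (0→1, i.e.
    'leaf'→'animal' for the animal task).  A model with no changed stimuli
    in a group gets a missing (NaN) proportion, never a zero.
    """
    frame = _as_frame(dataset)
    spec = ensemble.task_spec
    if receptor_id not in spec.input_subset:
        raise ValueError(f"receptor {receptor_id!r} is not an input of this ensemble")
    column = RECEPTOR_COLUMNS[receptor_id]
    clamped_frame = clamp_dataset(frame, receptor_id)
    delta = (clamped_frame[column] - frame[column]).to_numpy()

    X = spec.design(frame)
    X_clamped = spec.design(clamped_frame)
    rows = []
    for idx, model in enumerate(ensemble.models):
        before = classify(model, X)
        after = classify(model, X_clamped)
        changed = before != after
        for direction, mask in (("increased", changed & (delta > 0)),
                                ("decreased", changed & (delta < 0))):
            n = int(mask.sum())
            prop = float(np.mean(after[mask] == 1)) if n else float("nan")
            rows.append({"model": idx, "receptor": receptor_id, "direction": direction,
                         "n_changed": n, "prop_to_positive": prop})
    return pd.DataFrame(rows)


def export_weights(ensemble: EnsembleResult) -> pd.DataFrame:
    """Flat table of all connection weights and biases, one row per model.

    Columns are ``w1_<receptor>_h<j>`` (input→hidden), ``b1_h<j>``,
    ``w2_h<j>`` (hidden→output) and ``b2``: 5·3 + 3 + 3 + 1 = 22 weight
    columns for a five-input ensemble.
    """
    rows = []
    for idx, m in enumerate(ensemble.models):
        row: dict = {"model": idx}
        for i, rid in enumerate(m.input_ids):
            for j in range(m.n_hidden):
                row[f"w1_{RECEPTOR_COLUMNS[rid]}_h{j + 1}"] = m.W1[i, j]
        for j in range(m.n_hidden):
            row[f"b1_h{j + 1}"] = m.b1[j]
        for j in range(m.n_hidden):
            row[f"w2_h{j + 1}"] = m.W2[j]
        row["b2"] = m.b2
        rows.append(row)
    return pd.DataFrame(rows)


def import_weights(table: pd.DataFrame, input_ids: tuple[str, ...],
                   hidden_activation: str = "logistic") -> list[MLPModel]:
    """Rebuild models from an :func:`export_weights` table (round-trip exact)."""
    models = []
    n_hidden = sum(c.startswith("b1_h") for c in table.columns)
    for _, row in table.iterrows():
        W1 = np.array([[row[f"w1_{RECEPTOR_COLUMNS[rid]}_h{j + 1}"] for j in range(n_hidden)]
                       for rid in input_ids])
        b1 = np.array([row[f"b1_h{j + 1}"] for j in range(n_hidden)])
        W2 = np.array([row[f"w2_h{j + 1}"] for j in range(n_hidden)])
        models.append(MLPModel(tuple(input_ids), W1, b1, W2, float(row["b2"]),
                               hidden_activation))
    return models


__all__ = [
    "clamp_dataset",
    "clamping_accuracy",
    "export_weights",
    "import_weights",
    "reclassification_analysis",
]
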