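"""Challenge trained ensembles with control-device fabric excitations.

Fabrics never enter training: their excitations, computed with the same
mean-leaf background, illuminants, receptors and transform as the natural
stimulus database, are presented to the 20 trained animal-networks and the
20 trained shaded-networks, and the proportion of each ensemble voting
'animal' / 'shaded' is tabulated per fabric per illumination condition —
the probability that a fly using such a mechanism would mistake the fabric
for a host or for shade.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ann_engine import EnsembleResult, classify
from .receptor_model import ExcitationDataset


def evaluate_fabrics(animal_ensemble: EnsembleResult, shaded_ensemble: EnsembleResult,
                     fabric_dataset: ExcitationDataset | pd.DataFrame) -> pd.DataFrame:
    """Misclassification proportions, one row per fabric.

    Columns ``p_animal_open``/``p_animal_shade`` are the fraction of the
    animal ensemble classifying the fabric as 'animal' under each
    illuminant, and ``p_shaded_open``/``p_shaded_shade`` likewise for the
    shaded ensemble; each proportion is an exact multiple of 1/n_models.
    """
    frame = fabric_dataset.frame if isinstance(fabric_dataset, ExcitationDataset) else fabric_dataset
    for name, ens in (("animal", animal_ensemble), ("shaded", shaded_ensemble)):
        if len(ens.models) != 20:
            import logging
            logging.getLogger(__name__).warning(
                "%s ensemble has %d models (protocol uses 20); proportions use that denominator",
                name, len(ens.models))

    def votes(ensemble: EnsembleResult, rows: pd.DataFrame) -> np.ndarray:
        X = ensemble.task_spec.design(rows)
        counts = np.zeros(len(rows))
        for m in ensemble.models:
            counts += classify(m, X)
        return counts / len(ensemble.models)

    out = []
    for stimulus_id, group in frame.groupby("stimulus_id", sort=False):
        row = {"fabric_id": stimulus_id,
               "kind": group["class_label"].iloc[0].removeprefix("fabric:")}
        for condition in ("open", "shade"):
            rows = group[group["condition"] == condition]
            if not len(rows):
                continue
            row[f"p_animal_{condition}"] = float(votes(animal_ensemble, rows)[0])
            row[f"p_shaded_{condition}"] = float(votes(shaded_ensemble, rows)[0])
        out.append(row)
    return pd.DataFrame(out)


def format_fabric_table(report: pd.DataFrame) -> str:
    """Human-readable table: open-illumination value with the shade value in brackets."""
    lines = [f"{'fabric':<28} {'animal':<14} {'shaded':<14}"]
    for _, r in report.iterrows():
        animal = f"{r['p_animal_open']:.2f} ({r['p_animal_shade']:.2f})"
        shaded = f"{r['p_shaded_open']:.2f} ({r['p_shaded_shade']:.2f})"
        lines.append(f"{r['fabric_id']:<28} {animal:<14} {shaded:<14}")
    return "\n".join(lines)


__all__ = ["evaluate_fabrics", "format_fabric_table"]
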