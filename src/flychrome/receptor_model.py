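"""Quantum catches and photoreceptor excitations.

The quantum catch of receptor class *i* for a stimulus with reflectance
``R_s`` under stimulus irradiance ``I_s``, adapted to a background with
reflectance ``R_b`` under background irradiance ``I_b``, is

    Q_i = ∫ I_s(λ) R_s(λ) S_i(λ) dλ / ∫ I_b(λ) R_b(λ) S_i(λ) dλ

over 300–700 nm — a von Kries-style normalization by the receptor's response
to the adapting background.  The receptor signal fed to the classifiers is
the excitation E = ln(Q) (alternative linear and hyperbolic transforms are
available as configuration options for sensitivity analysis).

The background is always the mean leaf reflectance under the open/cloudy
illuminant: the modelled fly scans a stand of vegetation from an open
position, whether the stimulus itself sits in the open or in woodland shade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .spectral_core import (
    MASTER_GRID,
    Spectrum,
    SpectrumError,
    SpectrumTable,
    WavelengthGrid,
    integrate_product,
    resample,
)
from .synthetic_data import RECEPTOR_IDS, IlluminantPair, ReceptorTemplates

TRANSFORMS = ("ln", "linear", "hyperbolic")

#: excitation column name per receptor id, as used in CSV output and by the ANNs
RECEPTOR_COLUMNS = {
    "R1-6": "E_R16",
    "R7p": "E_R7p",
    "R7y": "E_R7y",
    "R8p": "E_R8p",
    "R8y": "E_R8y",
}
COLUMN_RECEPTORS = {v: k for k, v in RECEPTOR_COLUMNS.items()}


class DegenerateBackgroundError(SpectrumError):
    """The background integrand is (numerically) zero for some receptor."""


def quantum_catch(R_s: Spectrum, I_s: Spectrum, R_b: Spectrum, I_b: Spectrum,
                  S: Spectrum) -> float:
    """Background-adapted quantum catch Q for one receptor.

    All five spectra must share one grid.  Q is dimensionless and equals 1
    when the stimulus is the adapted background itself.
    """
    denominator = integrate_product([I_b, R_b, S])
    if denominator <= 0.0:
        raise DegenerateBackgroundError(
            f"background catch is zero for receptor {S.id!r}"
        )
    return integrate_product([I_s, R_s, S]) / denominator


def excitation(Q: float | np.ndarray, transform: str = "ln") -> float | np.ndarray:
    """Receptor excitation E from quantum catch Q.

    ``ln``: E = ln(Q) (the main analysis); ``linear``: E = Q;
    ``hyperbolic``: E = Q / (Q + 1) (saturating alternative).
    """
    Q = np.asarray(Q, dtype=float)
    if transform == "ln":
        if np.any(Q <= 0):
            raise SpectrumError("ln transform requires Q > 0")
        out = np.log(Q)
    elif transform == "linear":
        if np.any(Q < 0):
            raise SpectrumError("quantum catch must be non-negative")
        out = Q
    elif transform == "hyperbolic":
        if np.any(Q <= 0):
            raise SpectrumError("hyperbolic transform requires Q > 0")
        out = Q / (Q + 1.0)
    else:
        raise SpectrumError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")
    return float(out) if out.ndim == 0 else out


CONDITIONS = ("open", "shade")


@dataclass
class ExcitationRecord:
    """Five receptor excitations for one stimulus under one illumination condition."""

    stimulus_id: str
    class_label: str
    condition: str
    Q: dict[str, float]
    E: dict[str, float]


@dataclass
class ExcitationDataset:
    """Excitation records plus the background and transform that produced them."""

    records: list[ExcitationRecord]
    background_reflectance: Spectrum
    transform: str
    species: str = "musca_calliphora"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "stimulus_id": r.stimulus_id,
                "class_label": r.class_label,
                "condition": r.condition,
                **{RECEPTOR_COLUMNS[rid]: r.E[rid] for rid in RECEPTOR_IDS},
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")


def build_excitation_dataset(stimuli: SpectrumTable, illuminants: IlluminantPair,
                             receptors: ReceptorTemplates, transform: str = "ln",
                             background: Spectrum | None = None) -> ExcitationDataset:
    """Compute excitations for every stimulus under both illumination conditions.

    One record per stimulus per condition.  The adapting background is the
    mean of the table's ``leaf`` spectra unless an explicit ``background``
    reflectance is supplied (as when evaluating fabrics against the natural
    background); the background irradiance is the open illuminant in both
    conditions.
    """
    if not len(stimuli):
        raise SpectrumError("empty stimulus table")
    if background is None:
        try:
            background = stimuli.mean_spectrum(id="mean_leaf", label="leaf")
        except SpectrumError:
            raise SpectrumError(
                "no leaf spectra to form the adapting background; pass background= explicitly"
            ) from None
    I_b = illuminants.open
    records: list[ExcitationRecord] = []
    for condition, I_s in (("open", illuminants.open), ("shade", illuminants.shade)):
        for spectrum in stimuli:
            Q = {rid: quantum_catch(spectrum, I_s, background, I_b, S)
                 for rid, S in receptors}
            E = {rid: float(excitation(q, transform)) for rid, q in Q.items()}
            records.append(ExcitationRecord(
                spectrum.id, stimuli.labels[spectrum.id], condition, Q, E))
    return ExcitationDataset(records, background, transform, receptors.species)


def resolution_invariance_check(stimuli: SpectrumTable, illuminants: IlluminantPair,
                                receptors: ReceptorTemplates, transform: str = "ln",
                                coarse_step: float = 10.0,
                                fine_grid: WavelengthGrid = MASTER_GRID) -> float:
    """Spearman rank correlation of excitations at fine vs coarse spectral resolution.

    Stimulus reflectances are degraded to ``coarse_step`` resolution and
    linearly interpolated back onto the fine grid; excitations under both
    illumination conditions are computed through the identical pipeline for
    the native and degraded spectra (each with its own mean-leaf
    background), and the rank correlation across all paired stimulus ×
    receptor × condition values is returned.
    """
    coarse_grid = WavelengthGrid(fine_grid.start, fine_grid.stop, coarse_step)
    degraded = stimuli.resampled(coarse_grid).resampled(fine_grid)

    fine = build_excitation_dataset(stimuli, illuminants, receptors, transform)
    coarse = build_excitation_dataset(degraded, illuminants, receptors, transform)
    e_cols = list(RECEPTOR_COLUMNS.values())
    x = fine.frame[e_cols].to_numpy().ravel()
    y = coarse.frame[e_cols].to_numpy().ravel()
    if x.size < 3:
        raise SpectrumError("need at least 3 paired excitation values")
    return float(spearmanr(x, y).statistic)


__all__ = [
    "COLUMN_RECEPTORS",
    "CONDITIONS",
    "DegenerateBackgroundError",
    "ExcitationDataset",
    "ExcitationRecord",
    "RECEPTOR_COLUMNS",
    "TRANSFORMS",
    "build_excitation_dataset",
    "excitation",
    "quantum_catch",
    "resolution_invariance_check",
]
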