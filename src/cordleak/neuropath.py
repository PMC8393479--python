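"""Motor-neuron and pTDP-43 inclusion counting in the anterior horns.

Motor neurons (SMI-32-positive somata) are detected by background-relative
thresholding and a soma-area window, pooled over both anterior horns and
normalized to horn area. pTDP-43 inclusions are thresholded objects whose
equivalent diameter — the diameter of the circle with the object's area —
meets a minimum gate (8 µm by default, which captures neuronal inclusions
while passing over most small glial ones). Inclusion load is inclusions per
motor neuron.

The field's reference procedure for motor-neuron counting is manual; this
module provides an automated detector validated against rendered ground
truth, and also ingests a manual click list (CSV of points) so a manual count
can flow through the same normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging import RegionSet, threshold_relative

__all__ = [
    "NeuronCriteria",
    "InclusionCriteria",
    "count_motor_neurons",
    "count_inclusions",
    "inclusion_load",
    "ingest_manual_counts",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class NeuronCriteria:
    """Soma-area window (µm²) and intensity factor for SMI-32 detection."""

    min_soma_area_um2: float = 100.0
    max_soma_area_um2: float = 3000.0
    intensity_k: float = 3.0

    def __post_init__(self):
        if not (0 < self.min_soma_area_um2 < self.max_soma_area_um2):
            raise ValueError("need 0 < min < max soma area")


@dataclass(frozen=True)
class InclusionCriteria:
    """Equivalent-diameter gate (µm) and intensity factor for pTDP-43."""

    min_equiv_diameter_um: float = 8.0
    intensity_k: float = 3.0

    def __post_init__(self):
        if self.min_equiv_diameter_um < 0:
            raise ValueError("min_equiv_diameter_um must be nonnegative")


def _labeled_objects(raster, region, k, pixel_size_um):
    mask = threshold_relative(raster, region, k)
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return labels, np.array([])
    areas = ndi.sum_labels(np.ones_like(labels), labels,
                           index=np.arange(1, n + 1)) * pixel_size_um ** 2
    return labels, areas


def count_motor_neurons(smi32: np.ndarray, regions: RegionSet,
                        crit: NeuronCriteria = NeuronCriteria()) -> tuple[int, float]:
    """Count SMI-32-positive somata in both anterior horns.

    Returns ``(count, density per mm² of anterior horn)``.
    """
    horns = regions.anterior_horns
    if not np.any(horns):
        raise ValueError("anterior-horn labels are missing")
    _, areas = _labeled_objects(smi32, horns, crit.intensity_k, regions.pixel_size_um)
    count = int(np.count_nonzero((areas >= crit.min_soma_area_um2) &
                                 (areas <= crit.max_soma_area_um2)))
    horn_mm2 = np.count_nonzero(horns) * regions.pixel_size_um ** 2 / 1e6
    return count, count / horn_mm2


def count_inclusions(ptdp: np.ndarray, regions: RegionSet,
                     crit: InclusionCriteria = InclusionCriteria()) -> int:
    """Count pTDP-43 objects in the anterior horns whose equivalent diameter
    meets the gate. Touching inclusions are not split (no watershed)."""
    horns = regions.anterior_horns
    if not np.any(horns):
        raise ValueError("anterior-horn labels are missing")
    _, areas = _labeled_objects(ptdp, horns, crit.intensity_k, regions.pixel_size_um)
    if areas.size == 0:
        return 0
    equiv_diam = 2.0 * np.sqrt(areas / np.pi)
    return int(np.count_nonzero(equiv_diam >= crit.min_equiv_diameter_um))


def inclusion_load(inclusion_count: int, neuron_count: int) -> float:
    """Inclusions per motor neuron; missing (NaN) when no neurons remain."""
    if inclusion_count < 0 or neuron_count < 0:
        raise ValueError("counts must be nonnegative")
    if neuron_count == 0:
        warnings.warn("no motor neurons: inclusion load is undefined", stacklevel=2)
        return float("nan")
    return inclusion_count / neuron_count


def ingest_manual_counts(clicks: pd.DataFrame, regions: RegionSet) -> tuple[int, float]:
    """Manual click list -> (count, density per mm² of anterior horn).

    ``clicks`` has columns ``row, col`` (pixel coordinates, one click per
    soma); clicks outside the anterior horns are ignored with a warning.
    """
    horns = regions.anterior_horns
    if not np.any(horns):
        raise ValueError("anterior-horn labels are missing")
    rr = clicks["row"].round().astype(int).to_numpy()
    cc = clicks["col"].round().astype(int).to_numpy()
    inside = (rr >= 0) & (rr < horns.shape[0]) & (cc >= 0) & (cc < horns.shape[1])
    inside &= horns[np.clip(rr, 0, horns.shape[0] - 1),
                    np.clip(cc, 0, horns.shape[1] - 1)]
    if inside.sum() < len(clicks):
        warnings.warn(f"{len(clicks) - int(inside.sum())} clicks outside the "
                      "anterior horns were ignored", stacklevel=2)
    count = int(inside.sum())
    horn_mm2 = np.count_nonzero(horns) * regions.pixel_size_um ** 2 / 1e6
    return count, count / horn_mm2
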