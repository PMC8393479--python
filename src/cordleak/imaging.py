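"""Rasters, physical units, tissue regions, and binary-morphology primitives.

Everything downstream (vessel detection, leakage scoring, inclusion counting)
is composed from the operations here: robust background-relative thresholding,
local adaptive thresholding, disk-structuring-element morphology, and the
region bookkeeping that separates gray matter, white matter and the anterior
horns while excluding a band at the tissue edge.

Conventions: rasters are 2-D ``float64``/``bool`` numpy arrays indexed
``(row, col)``, 0-based; all physical distances are micrometres and converted
to pixels through :func:`um_to_px`; areas in µm² are ``pixel count ×
pixel_size_um²``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "SectionImage",
    "RegionSet",
    "REGION_LABELS",
    "um_to_px",
    "threshold_relative",
    "adaptive_threshold",
    "fill_holes",
    "dilate",
    "erode",
    "disk_element",
    "exclude_edge",
    "area_um2",
    "read_section",
    "write_section",
]

#: Integer codes used in every region label raster.
REGION_LABELS = {
    "background": 0,
    "white": 1,
    "gray": 2,
    "anterior_horn_left": 3,
    "anterior_horn_right": 4,
}

DEFAULT_PIXEL_SIZE_UM = 0.65  # typical 10x slide-scanner sampling


@dataclass
class SectionImage:
    """A multichannel section raster with its physical pixel size.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D nonnegative intensity array. All channels
        must share one shape.
    pixel_size_um
        Edge length of one pixel in micrometres.
    case, level, section
        Identity of the section within a cohort; ``level`` is one of
        ``cervical | thoracic | lumbar``.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    case: str = ""
    level: str = ""
    section: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not present (have {sorted(self.channels)})")
        return self.channels[name]


@dataclass
class RegionSet:
    """Label raster of tissue compartments plus the edge-exclusion flag.

    Invariants: anterior horns are part of gray matter (their labels are
    distinct but :meth:`gray` includes them); gray and white are disjoint by
    construction of the label raster.
    """

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    edge_margin_um: float = 0.0

    @property
    def tissue(self) -> np.ndarray:
        return self.labels > 0

    @property
    def gray(self) -> np.ndarray:
        return np.isin(self.labels, (REGION_LABELS["gray"],
                                     REGION_LABELS["anterior_horn_left"],
                                     REGION_LABELS["anterior_horn_right"]))

    @property
    def white(self) -> np.ndarray:
        return self.labels == REGION_LABELS["white"]

    @property
    def anterior_horns(self) -> np.ndarray:
        return np.isin(self.labels, (REGION_LABELS["anterior_horn_left"],
                                     REGION_LABELS["anterior_horn_right"]))

    def compartment(self, name: str) -> np.ndarray:
        try:
            return {"tissue": self.tissue, "gray": self.gray, "white": self.white,
                    "anterior_horns": self.anterior_horns}[name]
        except KeyError:
            raise KeyError(f"unknown compartment {name!r}") from None


def um_to_px(distance_um: float, pixel_size_um: float) -> int:
    """Convert a physical distance to an integer pixel radius.

    Rounds half away from zero and never returns less than 1 px, so a
    morphological radius requested in micrometres always has an effect.
    """
    if distance_um <= 0 or pixel_size_um <= 0:
        raise ValueError("distance_um and pixel_size_um must be positive")
    ratio = distance_um / pixel_size_um
    return max(1, int(np.floor(ratio + 0.5)))


def area_um2(mask: np.ndarray, pixel_size_um: float) -> float:
    """Area of a boolean mask in µm²."""
    return float(np.count_nonzero(mask)) * pixel_size_um ** 2


def _background_stats(raster: np.ndarray, region: np.ndarray) -> tuple[float, float]:
    """Median and MAD of the region background (top intensity decile excluded)."""
    vals = raster[region]
    cutoff = np.quantile(vals, 0.9)
    bg = vals[vals <= cutoff]
    if bg.size == 0:  # degenerate: everything in the top decile (constant raster)
        bg = vals
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med, mad


def threshold_relative(raster: np.ndarray, region: np.ndarray, k: float = 3.0,
                       return_background: bool = False):
    """Background-relative threshold: true where intensity exceeds
    ``median + k * MAD`` of the region background.

    The background estimate excludes the top decile of region intensities so
    that bright objects do not inflate their own threshold. Pixels outside
    ``region`` are always false.
    """
    if not np.any(region):
        raise ValueError("region is empty")
    med, mad = _background_stats(raster, region)
    mask = region & (raster > med + k * mad)
    if mad == 0 and not np.any(raster[region] > med):
        warnings.warn("constant raster within region: empty mask", stacklevel=2)
    if return_background:
        return mask, med
    return mask


def adaptive_threshold(raster: np.ndarray, window_um: float, k: float = 3.0,
                       pixel_size_um: float = 1.0,
                       tissue: np.ndarray | None = None,
                       valid: np.ndarray | None = None) -> np.ndarray:
    """Local mean/SD threshold: true where intensity exceeds the mean plus
    ``k`` standard deviations of a square window around the pixel.

    ``valid`` restricts the *statistics* (and the output) to a pixel subset —
    e.g. extravascular tissue, so that bright foreign structures do not
    inflate the local background estimate. Falls back to
    :func:`threshold_relative` (with a warning) when the window does not fit
    inside the image. Pixels outside ``tissue`` are forced false.
    """
    win = um_to_px(window_um, pixel_size_um)
    if win < 5:
        raise ValueError(f"adaptive window {win} px is below the 5 px minimum")
    if win > min(raster.shape):
        warnings.warn("adaptive window exceeds image; using global threshold",
                      stacklevel=2)
        region = valid if valid is not None else (
            tissue if tissue is not None else np.ones(raster.shape, bool))
        return threshold_relative(raster, region, k)
    data = raster.astype(np.float64, copy=False)
    if valid is None:
        mean = ndi.uniform_filter(data, size=win, mode="reflect")
        sq = ndi.uniform_filter(data * data, size=win, mode="reflect")
    else:
        w = valid.astype(np.float64)
        norm = ndi.uniform_filter(w, size=win, mode="reflect")
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = ndi.uniform_filter(data * w, size=win, mode="reflect") / norm
            sq = ndi.uniform_filter(data * data * w, size=win, mode="reflect") / norm
        # windows with (numerically) no valid support carry no statistics
        unsupported = norm <= 1e-12
        mean[unsupported] = 0.0
        sq[unsupported] = 0.0
    var = np.clip(sq - mean * mean, 0.0, None)
    mask = data > mean + k * np.sqrt(var)
    if valid is not None:
        mask &= valid
    if tissue is not None:
        mask &= tissue
    return mask


def disk_element(radius_px: int) -> np.ndarray:
    """Disk structuring element of the given pixel radius."""
    r = int(radius_px)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= r * r


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill fully enclosed false regions of a binary mask."""
    return ndi.binary_fill_holes(mask)


def dilate(mask: np.ndarray, radius_um: float, pixel_size_um: float = 1.0) -> np.ndarray:
    """Binary dilation with a Euclidean disk of ``radius_um``.

    Implemented through the exact Euclidean distance transform, which gives
    the same pixel set as structuring-element dilation with
    :func:`disk_element` but stays O(pixels) for arbitrarily large radii.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    r = um_to_px(radius_um, pixel_size_um)
    return ndi.distance_transform_edt(~mask) <= r


def erode(mask: np.ndarray, radius_um: float, pixel_size_um: float = 1.0) -> np.ndarray:
    """Binary erosion with a Euclidean disk of ``radius_um``.

    Distance-transform implementation (see :func:`dilate`); the frame border
    is treated as background, matching structuring-element erosion.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    r = um_to_px(radius_um, pixel_size_um)
    padded = np.pad(mask, 1, constant_values=False)
    return (ndi.distance_transform_edt(padded) > r)[1:-1, 1:-1]


def exclude_edge(regions: RegionSet, margin_um: float) -> RegionSet:
    """Remove a band of ``margin_um`` from the tissue boundary of every class.

    Not idempotent: applying twice erodes twice. A margin of 0 returns the
    input unchanged (flagged applied).
    """
    if not np.any(regions.tissue):
        raise ValueError("tissue mask is empty")
    if margin_um == 0:
        return replace(regions, edge_margin_um=0.0)
    keep = erode(regions.tissue, margin_um, regions.pixel_size_um)
    if not np.any(keep):
        raise ValueError(f"edge margin {margin_um} µm erodes the tissue to nothing")
    labels = np.where(keep, regions.labels, 0)
    return RegionSet(labels, regions.pixel_size_um,
                     edge_margin_um=regions.edge_margin_um + margin_um)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF (one page per channel) + JSON sidecar
# ---------------------------------------------------------------------------

def write_section(image: SectionImage, path: str | Path) -> Path:
    """Write a section as a multi-page TIFF with a ``.json`` sidecar."""
    path = Path(path)
    names = list(image.channels)
    stack = np.stack([image.channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {"channels": names, "pixel_size_um": image.pixel_size_um,
               "case": image.case, "level": image.level, "section": image.section}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_section(path: str | Path) -> SectionImage:
    """Read a section written by :func:`write_section`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {n: np.asarray(stack[i], dtype=np.float64)
                for i, n in enumerate(meta["channels"])}
    return SectionImage(channels, pixel_size_um=float(meta["pixel_size_um"]),
                        case=meta.get("case", ""), level=meta.get("level", ""),
                        section=int(meta.get("section", 0)))
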