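"""Synthetic spinal-cord sections and CSF cohorts with known ground truth.

Post-mortem image data for hemoglobin-leakage studies are rarely deposited, so
this module renders sections in which every quantity the pipeline measures is
known exactly: lectin-positive vessel cross-sections of varying caliber, an
intravascular hemoglobin pool in every vessel, an exponentially decaying
extravascular hemoglobin halo around the *leaked* subset of vessels, SMI-32
somata confined to the anterior horns, pTDP-43 puncta straddling the 8 µm size
gate, and Poisson-Gaussian shot/read noise over a diffuse autofluorescence
background. Region geometry is a two-lobed ("butterfly") gray matter inside an
elliptical cord with labeled anterior horns — sufficient for compartment
bookkeeping without any claim of anatomical fidelity.

CSF cohorts are drawn from heavy-tailed log-normal hemoglobin distributions
whose per-arm location and scale are derived from the published cohort medians
and upper quartiles (control 39.86 / Q3 310.4 ng/mL; ALS 74.25 / Q3 889.8
ng/mL), with below-LOD values censored at 6.25 ng/mL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import REGION_LABELS, RegionSet, SectionImage, write_section

__all__ = [
    "SectionSpec",
    "GroundTruth",
    "generate_section",
    "generate_cohort",
    "CsfArmParams",
    "generate_csf_cohort",
    "lognormal_from_quartiles",
    "CONTROL_CSF",
    "ALS_CSF",
    "LOD_NG_ML",
]

LOD_NG_ML = 6.25  # ELISA limit of detection for free hemoglobin

LEVELS = ("cervical", "thoracic", "lumbar")


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of one rendered section.

    Length parameters are micrometres. ``leak_fraction`` of the vessels carry
    an extravascular halo of amplitude ``leak_amplitude`` at the vessel rim
    decaying with length constant ``leak_halo_decay_um``.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 1.0
    n_vessels: int = 40
    vessel_radius_range_um: tuple[float, float] = (3.0, 12.0)
    leak_fraction: float = 0.3
    leak_halo_decay_um: float = 20.0
    leak_amplitude: float = 150.0
    n_neurons_per_horn: int = 0
    neuron_diameter_um: float = 20.0
    n_inclusions: int = 0
    inclusion_diameter_um_range: tuple[float, float] = (4.0, 12.0)
    background_level: float = 50.0
    noise_gain: float = 0.0
    read_noise_sd: float = 0.0
    seed: int = 0
    # rendering amplitudes (arbitrary fluorescence units)
    lectin_amplitude: float = 400.0
    hb_intravascular: float = 300.0
    smi32_amplitude: float = 400.0
    ptdp_amplitude: float = 400.0
    vessel_rim_um: float = 3.0

    def validate(self) -> None:
        rmin, rmax = self.vessel_radius_range_um
        if not (0.0 <= self.leak_fraction <= 1.0):
            raise ValueError("leak_fraction must lie in [0, 1]")
        if rmin <= 0 or rmax < rmin:
            raise ValueError("vessel radius range must satisfy 0 < min <= max")
        for name in ("pixel_size_um", "leak_halo_decay_um", "neuron_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        dmin, dmax = self.inclusion_diameter_um_range
        if dmin <= 0 or dmax < dmin:
            raise ValueError("inclusion diameter range must satisfy 0 < min <= max")
        if self.background_level < 0 or self.noise_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("background and noise parameters must be nonnegative")
        frame_um = min(self.width_px, self.height_px) * self.pixel_size_um
        if 2 * rmax >= 0.5 * frame_um:
            raise ValueError(
                f"largest vessel (diameter {2 * rmax} µm) does not fit the frame "
                f"({frame_um} µm); non-physical spec")


@dataclass
class GroundTruth:
    """Exact description of what was rendered, before noise."""

    vessels: pd.DataFrame        # row, col, radius_um, leaked
    neurons: pd.DataFrame        # row, col, horn
    inclusions: pd.DataFrame     # row, col, diameter_um, compartment
    regions: RegionSet
    #: noise-free integrated extravascular halo signal per compartment
    halo_integral: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center, semi_axes) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cy, cx = center
    ay, ax = semi_axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_regions(height_px: int, width_px: int, pixel_size_um: float) -> RegionSet:
    """Butterfly gray matter inside an elliptical cord, horns at the bottom.

    Rows increase toward the anterior (ventral) aspect, so the anterior horns
    sit in the lower half of each gray lobe.
    """
    h, w = height_px, width_px
    labels = np.zeros((h, w), dtype=np.uint8)
    tissue = _ellipse_mask((h, w), (h / 2, w / 2), (0.46 * h, 0.46 * w))
    labels[tissue] = REGION_LABELS["white"]

    gray = np.zeros((h, w), bool)
    for sx in (-1, 1):  # two lateral lobes
        gray |= _ellipse_mask((h, w), (h * 0.52, w / 2 + sx * 0.17 * w),
                              (0.28 * h, 0.10 * w))
    # central commissural bridge
    gray |= _ellipse_mask((h, w), (h * 0.50, w / 2), (0.05 * h, 0.18 * w))
    gray &= tissue
    labels[gray] = REGION_LABELS["gray"]

    for sx, name in ((-1, "anterior_horn_left"), (1, "anterior_horn_right")):
        horn = _ellipse_mask((h, w), (h * 0.64, w / 2 + sx * 0.17 * w),
                             (0.15 * h, 0.095 * w))
        labels[horn & gray] = REGION_LABELS[name]
    return RegionSet(labels, pixel_size_um=pixel_size_um)


def _place_disks(rng, allowed: np.ndarray, radii_px: np.ndarray,
                 min_sep_px: float, max_tries: int = 2000) -> np.ndarray:
    """Rejection-sample non-overlapping disk centers inside ``allowed``.

    Returns an ``(n, 2)`` float array of (row, col) centers; raises if the
    frame cannot accommodate the requested objects.
    """
    rows, cols = np.nonzero(allowed)
    if rows.size == 0:
        raise ValueError("no admissible placement area")
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii_px:
        for _ in range(max_tries):
            i = rng.integers(rows.size)
            cy, cx = float(rows[i]), float(cols[i])
            ok = True
            for (py, px), pr in zip(centers, placed_r):
                if (cy - py) ** 2 + (cx - px) ** 2 < (r + pr + min_sep_px) ** 2:
                    ok = False
                    break
            if ok:
                centers.append((cy, cx))
                placed_r.append(float(r))
                break
        else:
            raise ValueError("could not place all objects without overlap; "
                             "frame too crowded")
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _patch(shape, cy, cx, extent):
    """Slices and centered coordinate grids of a square patch (clipped)."""
    y0 = max(0, int(np.floor(cy - extent)))
    y1 = min(shape[0], int(np.ceil(cy + extent)) + 1)
    x0 = max(0, int(np.floor(cx - extent)))
    x1 = min(shape[1], int(np.ceil(cx + extent)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    return (slice(y0, y1), slice(x0, x1)), d


# ---------------------------------------------------------------------------
# section rendering
# ---------------------------------------------------------------------------

def generate_section(spec: SectionSpec, case: str = "", level: str = "",
                     section: int = 0) -> tuple[SectionImage, GroundTruth]:
    """Render one section and its exact ground truth.

    Deterministic given ``spec.seed``: two calls with the same spec return
    bit-identical rasters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w, p = spec.height_px, spec.width_px, spec.pixel_size_um
    regions = make_regions(h, w, p)
    shape = (h, w)

    lectin = np.zeros(shape)
    hb_halo = np.zeros(shape)      # extravascular halo field only
    hb_intra = np.zeros(shape)
    vessel_interior = np.zeros(shape, bool)

    # --- vessels -----------------------------------------------------------
    n = spec.n_vessels
    if n > 0:
        rmin, rmax = spec.vessel_radius_range_um
        radii_um = rng.uniform(rmin, rmax, size=n)
        radii_px = radii_um / p
        halo_margin = 3.0 * spec.leak_halo_decay_um / p
        from .imaging import erode as _erode
        allowed = _erode(regions.tissue, max(rmax, 1.0) + 2 * p, p)
        centers = _place_disks(rng, allowed, radii_px, min_sep_px=8.0 / p)
        n_leak = int(round(spec.leak_fraction * n))
        leaked = np.zeros(n, bool)
        leaked[rng.choice(n, size=n_leak, replace=False)] = True

        rim_px = spec.vessel_rim_um / p
        for i in range(n):
            cy, cx = centers[i]
            r = radii_px[i]
            sl, d = _patch(shape, cy, cx, r + 1)
            inside = d <= r
            ring = inside & (d >= max(r - rim_px, 0.0))
            lectin[sl][ring] = spec.lectin_amplitude
            hb_intra[sl][inside] = spec.hb_intravascular
            vessel_interior[sl] |= inside
            if leaked[i]:
                slh, dh = _patch(shape, cy, cx, r + 6 * spec.leak_halo_decay_um / p)
                out = dh > r
                hb_halo[slh][out] += spec.leak_amplitude * np.exp(
                    -(dh[out] - r) * p / spec.leak_halo_decay_um)
        vessels = pd.DataFrame({
            "row": centers[:, 0], "col": centers[:, 1],
            "radius_um": radii_um, "leaked": leaked})
    else:
        vessels = pd.DataFrame(columns=["row", "col", "radius_um", "leaked"])

    extravascular = ~vessel_interior
    halo_integral = {
        comp: float(hb_halo[extravascular & regions.compartment(comp)].sum())
        for comp in ("tissue", "gray", "white")}

    # --- nuclei (context only) --------------------------------------------
    nuclei = np.zeros(shape)
    n_nuc = int(0.00015 * h * w)
    if n_nuc:
        ny = rng.integers(0, h, n_nuc)
        nx = rng.integers(0, w, n_nuc)
        keep = regions.tissue[ny, nx]
        for cy, cx in zip(ny[keep], nx[keep]):
            sl, d = _patch(shape, float(cy), float(cx), 4.0 / p)
            nuclei[sl][d <= 3.5 / p] = 200.0

    channels = {"nuclei": nuclei, "lectin": lectin,
                "hemoglobin": hb_intra + hb_halo}

    # --- SMI-32 motor neuron somata in the anterior horns ------------------
    neuron_rows = []
    if spec.n_neurons_per_horn > 0:
        smi32 = np.zeros(shape)
        r_n = spec.neuron_diameter_um / 2 / p
        for horn in ("anterior_horn_left", "anterior_horn_right"):
            horn_mask = regions.labels == REGION_LABELS[horn]
            from .imaging import erode as _erode
            allowed = _erode(horn_mask, spec.neuron_diameter_um / 2 + p, p)
            centers = _place_disks(rng, allowed,
                                   np.full(spec.n_neurons_per_horn, r_n),
                                   min_sep_px=4.0 / p)
            for cy, cx in centers:
                sl, d = _patch(shape, cy, cx, r_n + 1)
                smi32[sl][d <= r_n] = spec.smi32_amplitude
                neuron_rows.append({"row": cy, "col": cx, "horn": horn})
        channels["smi32"] = smi32
    neurons = pd.DataFrame(neuron_rows, columns=["row", "col", "horn"])

    # --- pTDP-43 puncta ----------------------------------------------------
    inclusion_rows = []
    if spec.n_inclusions > 0:
        ptdp = np.zeros(shape)
        dmin, dmax = spec.inclusion_diameter_um_range
        diams = rng.uniform(dmin, dmax, size=spec.n_inclusions)
        from .imaging import erode as _erode
        allowed = _erode(regions.anterior_horns, dmax / 2 + p, p)
        centers = _place_disks(rng, allowed, diams / 2 / p, min_sep_px=6.0 / p)
        label_at = regions.labels
        for (cy, cx), dia in zip(centers, diams):
            r = dia / 2 / p
            sl, d = _patch(shape, cy, cx, r + 1)
            ptdp[sl][d <= r] = spec.ptdp_amplitude
            lab = int(label_at[int(round(cy)), int(round(cx))])
            comp = {v: k for k, v in REGION_LABELS.items()}[lab]
            inclusion_rows.append({"row": cy, "col": cx, "diameter_um": dia,
                                   "compartment": comp})
        channels["ptdp43"] = ptdp
    inclusions = pd.DataFrame(inclusion_rows,
                              columns=["row", "col", "diameter_um", "compartment"])

    # --- background + noise ------------------------------------------------
    bg = np.where(regions.tissue, spec.background_level, 0.0)
    for name in channels:
        img = channels[name] + bg
        if spec.noise_gain > 0:
            img = rng.poisson(np.clip(img, 0, None) * spec.noise_gain) / spec.noise_gain
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=shape)
        channels[name] = np.clip(img, 0.0, None)

    image = SectionImage(channels, pixel_size_um=p, case=case, level=level,
                         section=section)
    gt = GroundTruth(vessels=vessels, neurons=neurons, inclusions=inclusions,
                     regions=regions, halo_integral=halo_integral)
    return image, gt


# ---------------------------------------------------------------------------
# cohorts of sections on disk
# ---------------------------------------------------------------------------

_SPEC_FIELDS = {f for f in SectionSpec.__dataclass_fields__}


def generate_cohort(case_specs: pd.DataFrame, out_dir: str | Path,
                    base_spec: SectionSpec | None = None) -> pd.DataFrame:
    """Render a cohort to ``out_dir`` with layout ``case/level/section``.

    ``case_specs`` needs columns ``case``, ``level``, ``section``; any other
    column named after a :class:`SectionSpec` field overrides that field for
    that row. A ``seed`` column is honored; otherwise seeds are derived from
    the base spec seed plus the row index. Returns the manifest (also written
    as ``manifest.csv``).
    """
    if len(case_specs) == 0:
        raise ValueError("need at least one case")
    keys = case_specs[["case", "level", "section"]].astype(str).agg("/".join, axis=1)
    dup = keys[keys.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate case-level-section keys: {sorted(set(dup))}")
    base = base_spec or SectionSpec()
    out_dir = Path(out_dir)
    rows = []
    for idx, rec in enumerate(case_specs.to_dict("records")):
        overrides = {k: v for k, v in rec.items()
                     if k in _SPEC_FIELDS and pd.notna(v)}
        overrides.setdefault("seed", base.seed + idx)
        spec = replace(base, **overrides)
        image, gt = generate_section(spec, case=str(rec["case"]),
                                     level=str(rec["level"]),
                                     section=int(rec["section"]))
        d = out_dir / str(rec["case"]) / str(rec["level"])
        d.mkdir(parents=True, exist_ok=True)
        stem = d / f"section_{int(rec['section'])}"
        write_section(image, stem.with_suffix(".tif"))
        tifffile.imwrite(stem.parent / f"{stem.name}_labels.tif", gt.regions.labels)
        (stem.parent / f"{stem.name}_truth.json").write_text(json.dumps({
            "vessels": gt.vessels.to_dict("list"),
            "neurons": gt.neurons.to_dict("list"),
            "inclusions": gt.inclusions.to_dict("list"),
            "halo_integral": gt.halo_integral,
        }))
        rows.append({"case": rec["case"], "level": rec["level"],
                     "section": int(rec["section"]), "seed": spec.seed,
                     "path": str(stem.with_suffix(".tif").relative_to(out_dir))})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# CSF cohorts
# ---------------------------------------------------------------------------

_Z75 = 0.6744897501960817  # upper-quartile z of the standard normal


def lognormal_from_quartiles(median: float, upper_quartile: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) with the given median and upper quartile."""
    if median <= 0 or upper_quartile <= median:
        raise ValueError("need 0 < median < upper_quartile")
    mu = float(np.log(median))
    sigma = float(np.log(upper_quartile / median) / _Z75)
    return mu, sigma


@dataclass(frozen=True)
class CsfArmParams:
    """Log-normal location/scale for CSF hemoglobin and total protein."""

    hb_log_mean: float
    hb_log_sd: float
    protein_log_mean: float
    protein_log_sd: float = 0.35

    def __post_init__(self):
        if self.hb_log_sd <= 0 or self.protein_log_sd <= 0:
            raise ValueError("scale parameters must be positive")


def _arm_from_published(median, q3, protein_median) -> CsfArmParams:
    mu, sigma = lognormal_from_quartiles(median, q3)
    return CsfArmParams(mu, sigma, float(np.log(protein_median)))


#: default arms matching the published cohort medians / upper quartiles
CONTROL_CSF = _arm_from_published(39.86, 310.4, 741.0)
ALS_CSF = _arm_from_published(74.25, 889.8, 778.5)


def generate_csf_cohort(n_control: int, n_als: int,
                        control_params: CsfArmParams = CONTROL_CSF,
                        als_params: CsfArmParams = ALS_CSF,
                        seed: int = 0, lod: float = LOD_NG_ML) -> pd.DataFrame:
    """Draw a two-arm CSF cohort; hemoglobin below ``lod`` is censored at it."""
    if n_control < 1 or n_als < 1:
        raise ValueError("need at least one donor per arm")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, par in (("control", n_control, control_params),
                          ("ALS", n_als, als_params)):
        hb = rng.lognormal(par.hb_log_mean, par.hb_log_sd, size=n)
        protein = rng.lognormal(par.protein_log_mean, par.protein_log_sd, size=n)
        censored = hb < lod
        hb = np.where(censored, lod, hb)
        for i in range(n):
            rows.append({"donor": f"{group}_{i:03d}", "group": group,
                         "hb_ng_ml": hb[i], "total_protein": protein[i],
                         "hb_over_protein": hb[i] / protein[i],
                         "censored": bool(censored[i])})
    return pd.DataFrame(rows)
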