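"""Synthetic foraminiferal-cell phantom with Poisson ion-count acquisition.

Raw NanoSIMS count data for this kind of study are rarely deposited, so the
package ships a ground-truth generator: a single convex cell (ellipse
occupying ~60 % of a 10 × 10 µm field) wrapped in a thin organic-lining
ring and embedded in resin, with organelles placed inside the cytosome —
disks for most classes, rods for the possible endobionts (elongated,
~0.1–0.3 µm wide).  Electron dense bodies are 200–500 nm disks; under the
anoxic condition they and the endobionts cluster in a peripheral band
adjacent to the organic lining, mimicking the ultrastructure seen in
anoxia-incubated specimens, while under dysoxia they scatter uniformly.

The acquisition model is the simplest one consistent with counting
statistics: per pixel and per plane the *total* ion count of an isotope
pair is Poisson with a class-specific rate, and the minor-isotope count is
a Binomial split of that total at the true atom fraction.  No dead-time,
QSA or drift effects are modeled.

Class emission rates are not constrained by published values; the defaults
are chosen so that accumulated CN⁻ totals straddle the 1000-count mask
threshold (resin, vacuoles and lipid droplets mostly below it, cell classes
well above), reproducing the strong cell/background contrast of published
ratio images while leaving every class with enough valid pixels to
quantify.  The CN mask thresholds the *pair total*, so straddling it costs
pixels but does not bias the surviving ratios.  The ³²S⁻ mask thresholds
the *major species alone*: pixels whose S emission sits near 60 counts pass
the mask preferentially when the ³⁴S share is small, which biases the
ratio low.  S rates are therefore kept clear of the 60-count threshold at
the standard 50-plane protocol (S-poor classes ≈ 120 accumulated counts);
the gentler 25-plane protocol halves the totals and exercises the S mask.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidArgumentError, PlacementError
from .organelles import OrganelleClass
from .stack_io import IonCountStack, MeasurementSession, ROILabelMap, Species

__all__ = [
    "ClassTruth",
    "PhantomConfig",
    "AcquisitionSpec",
    "PhantomTruth",
    "default_class_truth",
    "build_label_map",
    "simulate_session",
]

_C = OrganelleClass

# Mean atom% (value ± SD) of 15N and 34S per class and condition, as measured
# on dysoxia/anoxia-incubated specimens.  Plastids were too rarely measured
# to be tabulated; they default to the cytosome values.
_ATOM_PCT = {
    # class: ((f15_dys, sd), (f15_anx, sd), (f34_dys, sd), (f34_anx, sd))
    _C.VACUOLE: ((0.52, 0.09), (0.39, 0.04), (6.03, 1.54), (4.15, 0.36)),
    _C.MITOCHONDRION: ((1.24, 0.20), (0.50, 0.03), (6.16, 1.22), (4.54, 0.30)),
    _C.ORGANIC_LINING: ((0.60, 0.06), (0.51, 0.09), (7.12, 2.35), (4.30, 0.17)),
    _C.ELECTRON_DENSE_BODY: ((1.64, 0.42), (0.79, 0.13), (6.92, 3.38), (4.26, 0.23)),
    _C.FOOD_VACUOLE: ((1.25, 0.51), (0.50, 0.13), (5.60, 0.72), (4.61, 0.36)),
    _C.POSSIBLE_ENDOBIONT: ((1.42, 0.52), (0.53, 0.06), (5.70, 0.57), (4.34, 0.20)),
    _C.CYTOSOME: ((1.31, 0.22), (0.52, 0.03), (6.13, 1.14), (4.63, 0.24)),
    _C.PEROXISOME: ((1.17, 0.17), (0.54, 0.05), (5.03, 0.80), (4.58, 0.22)),
    _C.LIPID_DROPLET: ((0.55, 0.07), (0.41, 0.05), (4.79, 1.23), (4.41, 0.22)),
    _C.RESIN: ((0.39, 0.04), (0.37, 0.02), (4.28, 0.29), (3.91, 0.30)),
    _C.PLASTID: ((1.31, 0.22), (0.52, 0.03), (6.13, 1.14), (4.63, 0.24)),
}

# Mean total CN- / S- counts per pixel per plane.  Nitrogen-poor materials
# (embedding resin, watery vacuoles, lipids) emit weakly; S- emission is
# strongest from the sulfur-rich electron dense bodies and organic lining.
_LAMBDA_CN_LOW = 19.0  # x50 planes = 950, mostly under the 1000-count mask
_LAMBDA_CN_CELL = 40.0  # x50 planes = 2000, comfortably above it
_LAMBDA_CN = {
    _C.RESIN: _LAMBDA_CN_LOW,
    _C.VACUOLE: _LAMBDA_CN_LOW,
    _C.LIPID_DROPLET: _LAMBDA_CN_LOW,
}
_LAMBDA_S = {
    _C.ELECTRON_DENSE_BODY: 8.0,
    _C.ORGANIC_LINING: 6.0,
    _C.RESIN: 2.4,
    _C.VACUOLE: 2.4,
    _C.LIPID_DROPLET: 2.4,
}
_LAMBDA_S_CELL = 3.0

#: Default number of organelles of each placed class per field.
DEFAULT_ORGANELLE_COUNTS = {
    _C.VACUOLE: 4,
    _C.FOOD_VACUOLE: 3,
    _C.MITOCHONDRION: 6,
    _C.PEROXISOME: 2,
    _C.PLASTID: 2,
    _C.LIPID_DROPLET: 4,
    _C.POSSIBLE_ENDOBIONT: 4,
    _C.ELECTRON_DENSE_BODY: 8,
}

#: Diameter ranges in nm (disks), with the endobiont rod handled separately.
DEFAULT_SIZE_RANGES_NM = {
    _C.VACUOLE: (800.0, 1500.0),
    _C.FOOD_VACUOLE: (600.0, 1200.0),
    _C.MITOCHONDRION: (400.0, 800.0),
    _C.PEROXISOME: (200.0, 500.0),
    _C.PLASTID: (500.0, 1000.0),
    _C.LIPID_DROPLET: (400.0, 900.0),
    _C.ELECTRON_DENSE_BODY: (200.0, 500.0),
    _C.POSSIBLE_ENDOBIONT: (100.0, 300.0),  # rod width; length drawn separately
}

DEFAULT_ENDOBIONT_LENGTH_NM = (600.0, 1500.0)


@dataclass(frozen=True)
class ClassTruth:
    """Ground truth for one organelle class.

    ``f15``/``f34`` are true minor-isotope atom fractions (in [0, 1));
    ``f15_sd``/``f34_sd`` the between-ROI spread used for optional per-ROI
    heterogeneity; ``lambda_cn``/``lambda_s`` mean total CN⁻ / S⁻ counts
    per pixel per plane.
    """

    organelle: OrganelleClass
    f15: float
    f34: float
    lambda_cn: float
    lambda_s: float
    f15_sd: float = 0.0
    f34_sd: float = 0.0

    def __post_init__(self):
        for name in ("f15", "f34"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidArgumentError(f"{name} must be in [0, 1), got {v}")
        for name in ("lambda_cn", "lambda_s", "f15_sd", "f34_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidArgumentError(f"{name} must be finite and >= 0, got {v}")


def default_class_truth(condition: str) -> list:
    """Per-class ground truth for a condition (``dysoxic`` or ``anoxic``).

    Atom fractions are the tabulated per-condition class means divided by
    100, SDs likewise; emission rates are the documented module defaults.
    """
    if condition not in ("dysoxic", "anoxic"):
        raise InvalidArgumentError(
            f"condition must be 'dysoxic' or 'anoxic', got {condition!r}"
        )
    idx = 0 if condition == "dysoxic" else 1
    truths = []
    for cls in OrganelleClass:
        n_dys, n_anx, s_dys, s_anx = _ATOM_PCT[cls]
        f15_pct, f15_sd_pct = (n_dys, n_anx)[idx]
        f34_pct, f34_sd_pct = (s_dys, s_anx)[idx]
        truths.append(
            ClassTruth(
                organelle=cls,
                f15=f15_pct / 100.0,
                f34=f34_pct / 100.0,
                f15_sd=f15_sd_pct / 100.0,
                f34_sd=f34_sd_pct / 100.0,
                lambda_cn=_LAMBDA_CN.get(cls, _LAMBDA_CN_CELL),
                lambda_s=_LAMBDA_S.get(cls, _LAMBDA_S_CELL),
            )
        )
    return truths


@dataclass
class PhantomConfig:
    """Geometry and ground-truth configuration for one phantom field."""

    rows: int = 256
    cols: int = 256
    pixel_size_nm: float = 10000.0 / 256.0  # 10 um field at 256 px
    condition: str = "dysoxic"
    organelle_counts: dict = field(default_factory=lambda: dict(DEFAULT_ORGANELLE_COUNTS))
    size_ranges_nm: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_RANGES_NM))
    endobiont_length_nm: tuple = DEFAULT_ENDOBIONT_LENGTH_NM
    cell_fraction: float = 0.6
    ring_width_px: int = 1
    band_width_nm: float = 1500.0  # peripheral clustering band (anoxic mode)
    heterogeneity: bool = True  # per-ROI jitter of true fractions
    max_attempts: int = 1000
    chamber: str = ""
    seed: int = 0

    def __post_init__(self):
        if self.rows < 16 or self.cols < 16:
            raise InvalidArgumentError("field must be at least 16x16 px")
        if self.condition not in ("dysoxic", "anoxic"):
            raise InvalidArgumentError(
                f"condition must be 'dysoxic' or 'anoxic', got {self.condition!r}"
            )
        for cls, rng in self.size_ranges_nm.items():
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise InvalidArgumentError(f"bad size range for {cls}: {rng}")
        if self.band_width_nm >= min(self.rows, self.cols) * self.pixel_size_nm:
            raise InvalidArgumentError("peripheral band wider than the field")
        if self.ring_width_px < 1:
            raise InvalidArgumentError("ring width must be >= 1 px")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition protocol: plane count, raster and species pairs.

    The standard protocol amalgamates 50 planes on a 256 × 256 raster; a
    gentler 25-plane / 128 × 128 variant is used for beam-sensitive S
    measurements.  ``species`` selects the pairs to acquire: ``"CN"``
    (¹²C¹⁴N⁻ + ¹²C¹⁵N⁻) and/or ``"S"`` (³²S⁻ + ³⁴S⁻).
    """

    planes: int = 50
    raster: int = 256
    species: tuple = ("CN", "S")

    def __post_init__(self):
        if self.planes < 1:
            raise InvalidArgumentError("planes must be >= 1")
        bad = set(self.species) - {"CN", "S"}
        if bad:
            raise InvalidArgumentError(f"unknown species pairs {sorted(bad)}")


@dataclass
class PhantomTruth:
    """Ground truth bundle: label map, class truths, per-ROI truths, seed."""

    label_map: ROILabelMap
    truths: list
    roi_truth: pd.DataFrame  # label, class, f15_true, f34_true, lambda_cn, lambda_s
    seed: int
    config: PhantomConfig

    def truth_of(self, label: int) -> pd.Series:
        row = self.roi_truth.loc[self.roi_truth["label"] == label]
        if row.empty:
            raise InvalidArgumentError(f"no truth recorded for label {label}")
        return row.iloc[0]


# ---------------------------------------------------------------------------
# Geometry helpers


def _ellipse_mask(rows, cols, shrink_px: float, cell_fraction: float) -> np.ndarray:
    """Pixels inside the cell ellipse shrunk by ``shrink_px`` on both axes."""
    s = np.sqrt(cell_fraction / np.pi)
    a = rows * s - shrink_px
    b = cols * s - shrink_px
    if a <= 0 or b <= 0:
        return np.zeros((rows, cols), dtype=bool)
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def _disk_pixels(rows, cols, cy, cx, radius_px):
    y0, y1 = int(np.floor(cy - radius_px)), int(np.ceil(cy + radius_px))
    x0, x1 = int(np.floor(cx - radius_px)), int(np.ceil(cx + radius_px))
    if y0 < 0 or x0 < 0 or y1 >= rows or x1 >= cols:
        return None
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
    return yy[sel], xx[sel]


def _rod_pixels(rows, cols, cy, cx, length_px, width_px, theta):
    half_diag = np.hypot(length_px, width_px) / 2.0
    y0, y1 = int(np.floor(cy - half_diag)), int(np.ceil(cy + half_diag))
    x0, x1 = int(np.floor(cx - half_diag)), int(np.ceil(cx + half_diag))
    if y0 < 0 or x0 < 0 or y1 >= rows or x1 >= cols:
        return None
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    sel = (np.abs(u) <= length_px / 2.0) & (np.abs(v) <= width_px / 2.0)
    if not sel.any():
        return None
    return yy[sel], xx[sel]


def build_label_map(config: PhantomConfig) -> PhantomTruth:
    """Construct the ground-truth label map for one phantom field.

    Layout: resin outside the cell (label 1), a closed organic-lining ring
    (label 2), cytosome filling the cell interior (label 3), then one label
    per placed organelle (labels 4, 5, ...) in class enumeration order.
    Placement is rejection sampling without overlap, capped at
    ``config.max_attempts`` tries per organelle; deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols, ps = config.rows, config.cols, config.pixel_size_nm

    cell = _ellipse_mask(rows, cols, 0.0, config.cell_fraction)
    interior = _ellipse_mask(rows, cols, config.ring_width_px, config.cell_fraction)
    ring = cell & ~interior
    band_px = config.band_width_nm / ps
    core = _ellipse_mask(rows, cols, config.ring_width_px + band_px, config.cell_fraction)
    band = interior & ~core

    labels = np.ones((rows, cols), dtype=np.int32)  # 1 = resin
    labels[ring] = 2
    labels[interior] = 3  # cytosome (overwritten by organelles)

    records = [
        (1, _C.RESIN),
        (2, _C.ORGANIC_LINING),
        (3, _C.CYTOSOME),
    ]
    occupied = np.zeros((rows, cols), dtype=bool)
    peripheral_classes = {_C.ELECTRON_DENSE_BODY, _C.POSSIBLE_ENDOBIONT}
    next_label = 4

    for cls in OrganelleClass:  # placement order = class enumeration order
        n = config.organelle_counts.get(cls, 0)
        if n <= 0:
            continue
        if cls not in config.size_ranges_nm:
            raise InvalidArgumentError(f"no size range configured for {cls.value}")
        lo_nm, hi_nm = config.size_ranges_nm[cls]
        if config.condition == "anoxic" and cls in peripheral_classes:
            region = band
        else:
            region = interior
        region_idx = np.flatnonzero(region)
        if region_idx.size == 0:
            raise PlacementError(cls.value, 0)
        for _ in range(n):
            placed = False
            for _attempt in range(config.max_attempts):
                flat = rng.choice(region_idx)
                cy = flat // cols + rng.uniform(-0.5, 0.5)
                cx = flat % cols + rng.uniform(-0.5, 0.5)
                if cls is _C.POSSIBLE_ENDOBIONT:
                    width_px = rng.uniform(lo_nm, hi_nm) / ps
                    length_px = rng.uniform(*config.endobiont_length_nm) / ps
                    theta = rng.uniform(0.0, np.pi)
                    pix = _rod_pixels(rows, cols, cy, cx, length_px, width_px, theta)
                else:
                    radius_px = rng.uniform(lo_nm, hi_nm) / (2.0 * ps)
                    pix = _disk_pixels(rows, cols, cy, cx, radius_px)
                if pix is None:
                    continue
                yy, xx = pix
                if not region[yy, xx].all():
                    continue
                if occupied[yy, xx].any():
                    continue
                labels[yy, xx] = next_label
                occupied[yy, xx] = True
                records.append((next_label, cls))
                next_label += 1
                placed = True
                break
            if not placed:
                raise PlacementError(cls.value, config.max_attempts)

    truths = default_class_truth(config.condition)
    by_class = {t.organelle: t for t in truths}

    rows_tbl, truth_rows = [], []
    for label, cls in records:
        t = by_class[cls]
        f15, f34 = t.f15, t.f34
        if config.heterogeneity:
            if t.f15_sd > 0:
                f15 = _truncated_normal(rng, t.f15, t.f15_sd)
            if t.f34_sd > 0:
                f34 = _truncated_normal(rng, t.f34, t.f34_sd)
        rows_tbl.append(
            {
                "label": label,
                "roi_id": label,
                "class": cls.value,
                "condition": config.condition,
                "chamber": config.chamber,
            }
        )
        truth_rows.append(
            {
                "label": label,
                "class": cls.value,
                "f15_true": f15,
                "f34_true": f34,
                "lambda_cn": t.lambda_cn,
                "lambda_s": t.lambda_s,
            }
        )

    label_map = ROILabelMap(labels=labels, table=pd.DataFrame(rows_tbl))
    return PhantomTruth(
        label_map=label_map,
        truths=truths,
        roi_truth=pd.DataFrame(truth_rows),
        seed=config.seed,
        config=dataclasses.replace(config),
    )


def _truncated_normal(rng, mean, sd, lo=1e-9, hi=0.999999):
    """Normal draw truncated to (lo, hi) by redrawing (SDs here are tiny)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(min(max(mean, lo), hi))


# ---------------------------------------------------------------------------
# Acquisition


def simulate_session(
    truth: PhantomTruth, acq: AcquisitionSpec = AcquisitionSpec(), seed: int = 0
) -> MeasurementSession:
    """Simulate one NanoSIMS acquisition of a phantom field.

    For every pixel and plane the total count of a species pair is
    Poisson(λ_class) and the minor-isotope count is Binomial(total, f_true);
    the major species gets the remainder, so counts are conserved exactly.
    Deterministic given ``seed``.

    A raster coarser than the label map (e.g. 128 on a 256-px map) must
    divide it evenly; the maps are then stride-subsampled and the pixel
    size scaled accordingly.
    """
    labels = truth.label_map.labels
    rows, cols = labels.shape
    if rows % acq.raster or cols % acq.raster:
        raise DimensionError(
            f"raster {acq.raster} does not divide label map dims {labels.shape}"
        )
    factor = rows // acq.raster
    if factor > 1:
        labels = labels[::factor, ::factor]
    pixel_size = truth.config.pixel_size_nm * factor

    max_label = int(labels.max())
    lut = {c: np.zeros(max_label + 1) for c in ("f15", "f34", "lambda_cn", "lambda_s")}
    for _, r in truth.roi_truth.iterrows():
        lab = int(r["label"])
        if lab > max_label:
            continue
        lut["f15"][lab] = r["f15_true"]
        lut["f34"][lab] = r["f34_true"]
        lut["lambda_cn"][lab] = r["lambda_cn"]
        lut["lambda_s"][lab] = r["lambda_s"]
    present = set(np.unique(labels)) - {0}
    known = set(truth.roi_truth["label"].astype(int))
    if present - known:
        raise InvalidArgumentError(
            f"labels without ClassTruth: {sorted(present - known)}"
        )

    rng = np.random.default_rng(seed)
    shape = (acq.planes,) + labels.shape
    stacks = {}
    if "CN" in acq.species:
        lam = lut["lambda_cn"][labels]
        f15 = np.broadcast_to(lut["f15"][labels], shape)
        total = rng.poisson(lam, size=shape)
        cn15 = rng.binomial(total, f15)
        stacks[Species.CN15] = IonCountStack(Species.CN15, cn15, pixel_size)
        stacks[Species.CN14] = IonCountStack(Species.CN14, total - cn15, pixel_size)
    if "S" in acq.species:
        lam = lut["lambda_s"][labels]
        f34 = np.broadcast_to(lut["f34"][labels], shape)
        total = rng.poisson(lam, size=shape)
        s34 = rng.binomial(total, f34)
        stacks[Species.S34] = IonCountStack(Species.S34, s34, pixel_size)
        stacks[Species.S32] = IonCountStack(Species.S32, total - s34, pixel_size)
    if not stacks:
        raise InvalidArgumentError("acquisition requests no species pairs")

    return MeasurementSession(
        stacks=stacks,
        pixel_size_nm=pixel_size,
        condition=truth.config.condition,
        specimen_id=f"phantom-seed{truth.seed}",
        seed=seed,
    )
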