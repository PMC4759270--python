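"""Plane amalgamation, count masking, ratio maps and ROI statistics.

The quantification chain mirrors standard NanoSIMS ratio-image processing:

1. *Accumulate* — sum the repeated raster planes of each species.
2. *Mask* — discard noisy pixels: for nitrogen analysis, pixels whose
   accumulated ¹²C¹⁴N⁻+¹²C¹⁵N⁻ total is below 1000 counts; for sulfur,
   pixels whose accumulated ³²S⁻ is below 60.  "Below … removed" is a
   strict ``<``: the boundary value is kept.  Thresholds apply to the
   accumulated counts, not per plane.
3. *Ratio map* — per valid pixel, the minor-isotope atom fraction.
4. *ROI statistics* — per labeled region, either the mean of per-pixel
   fractions (``pixelwise``, the default) or the fraction of region-summed
   counts (``pooled``, count-weighted and less ratio-biased at low counts),
   with a binomial counting standard error from the summed counts.

ROIs with no valid pixels are reported with ``has_estimate=False`` rather
than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DimensionError,
    InsufficientDataError,
    InvalidArgumentError,
    MissingInputError,
)
from .isotope import counting_se
from .organelles import OrganelleClass
from .stack_io import IonCountStack, MeasurementSession, ROILabelMap, Species

__all__ = [
    "PixelMask",
    "RatioMap",
    "ROIStat",
    "accumulate",
    "build_mask",
    "ratio_map",
    "quantify_rois",
    "roi_stats_frame",
    "summarize",
    "qc_count_dependence",
    "DEFAULT_CN_MIN",
    "DEFAULT_S_MIN",
]

logger = logging.getLogger("nanosip.quantify")

DEFAULT_CN_MIN = 1000  # accumulated 12C14N- + 12C15N- counts
DEFAULT_S_MIN = 60  # accumulated 32S- counts

#: Fixed column order of ROI result tables.
ROI_TABLE_COLUMNS = (
    "specimen",
    "condition",
    "class",
    "roi_id",
    "n_valid",
    "f_mean",
    "f_sd",
    "f_se",
    "total_minor",
    "total_major",
    "method",
    "element",
    "has_estimate",
)


@dataclass
class PixelMask:
    """Validity mask with the thresholds that produced it."""

    valid: np.ndarray
    cn_min: float
    s_min: float
    element: str  # "N" or "S"

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class RatioMap:
    """Per-pixel minor-isotope atom fraction; invalid pixels are NaN."""

    fraction: np.ndarray
    mask: PixelMask
    element: str
    n_demoted: int = 0  # masked-in pixels demoted for zero total counts


@dataclass
class ROIStat:
    """Atom-fraction estimate for one quantified region."""

    specimen: str
    condition: str
    organelle: OrganelleClass
    roi_id: int
    n_valid: int
    f_mean: float
    f_sd: float
    f_se: float
    total_minor: int
    total_major: int
    method: str
    element: str
    has_estimate: bool

    @property
    def atom_percent(self) -> float:
        return 100.0 * self.f_mean


def accumulate(stack: IonCountStack) -> np.ndarray:
    """Sum a stack over its planes (plane amalgamation)."""
    return stack.counts.sum(axis=0, dtype=np.int64)


def build_mask(
    cn_total: np.ndarray | None = None,
    s32_total: np.ndarray | None = None,
    cn_min: float = DEFAULT_CN_MIN,
    s_min: float = DEFAULT_S_MIN,
    element: str = "N",
) -> PixelMask:
    """Validity mask for an analysis from accumulated count images.

    Nitrogen analysis keeps pixels with accumulated CN⁻ total ``>= cn_min``;
    sulfur analysis keeps pixels with accumulated ³²S⁻ ``>= s_min`` (each
    analysis thresholds only its own species — the two are separate
    acquisitions).
    """
    if cn_min < 0 or s_min < 0:
        raise InvalidArgumentError("thresholds must be >= 0")
    if element == "N":
        if cn_total is None:
            raise MissingInputError("nitrogen analysis requires the CN total image")
        valid = np.asarray(cn_total) >= cn_min
    elif element == "S":
        if s32_total is None:
            raise MissingInputError("sulfur analysis requires the 32S total image")
        valid = np.asarray(s32_total) >= s_min
    else:
        raise InvalidArgumentError(f"element must be 'N' or 'S', got {element!r}")
    if not valid.any():
        logger.warning("mask has zero valid pixels (element=%s)", element)
    return PixelMask(valid=valid, cn_min=cn_min, s_min=s_min, element=element)


def ratio_map(minor: np.ndarray, major: np.ndarray, mask: PixelMask) -> RatioMap:
    """Per-pixel atom-fraction map over the mask's valid pixels.

    A pixel that passes the mask but has zero total counts of the ratio
    pair (possible for S, where the mask thresholds ³²S⁻ only) is demoted
    to invalid, counted and logged.
    """
    minor = np.asarray(minor, dtype=float)
    major = np.asarray(major, dtype=float)
    if minor.shape != major.shape or minor.shape != mask.valid.shape:
        raise DimensionError(
            f"shape mismatch: minor {minor.shape}, major {major.shape}, "
            f"mask {mask.valid.shape}"
        )
    total = minor + major
    valid = mask.valid & (total > 0)
    n_demoted = int(mask.valid.sum() - valid.sum())
    if n_demoted:
        logger.info("demoted %d zero-total pixels to invalid", n_demoted)
    fraction = np.full(minor.shape, np.nan)
    fraction[valid] = minor[valid] / total[valid]
    out_mask = PixelMask(valid=valid, cn_min=mask.cn_min, s_min=mask.s_min,
                         element=mask.element)
    return RatioMap(fraction=fraction, mask=out_mask, element=mask.element,
                    n_demoted=n_demoted)


_ELEMENT_SPECIES = {
    "N": (Species.CN15, Species.CN14),
    "S": (Species.S34, Species.S32),
}


def quantify_rois(
    session: MeasurementSession,
    labels: ROILabelMap,
    element: str = "N",
    method: str = "pixelwise",
    cn_min: float = DEFAULT_CN_MIN,
    s_min: float = DEFAULT_S_MIN,
) -> list:
    """ROI-wise atom-fraction estimates for one element on one session.

    The label map may be finer than the session raster by an integer
    factor, in which case it is stride-downsampled to match.
    """
    if method not in ("pixelwise", "pooled"):
        raise InvalidArgumentError(f"method must be pixelwise|pooled, got {method!r}")
    if element not in _ELEMENT_SPECIES:
        raise InvalidArgumentError(f"element must be 'N' or 'S', got {element!r}")
    minor_sp, major_sp = _ELEMENT_SPECIES[element]
    for sp in (minor_sp, major_sp):
        if sp not in session.stacks:
            raise MissingInputError(f"session lacks {sp.value} stack for element {element}")

    lab_img = labels.labels
    if lab_img.shape != session.shape:
        fr, fc = lab_img.shape[0] / session.shape[0], lab_img.shape[1] / session.shape[1]
        if fr == fc and fr >= 1 and fr == int(fr):
            labels = labels.downsample(int(fr))
            lab_img = labels.labels
        else:
            raise DimensionError(
                f"label map {lab_img.shape} incompatible with session raster "
                f"{session.shape}"
            )

    minor_tot = accumulate(session.stacks[minor_sp])
    major_tot = accumulate(session.stacks[major_sp])
    if element == "N":
        mask = build_mask(cn_total=minor_tot + major_tot, cn_min=cn_min,
                          s_min=s_min, element="N")
    else:
        mask = build_mask(s32_total=major_tot, cn_min=cn_min, s_min=s_min, element="S")
    rmap = ratio_map(minor_tot, major_tot, mask)

    class_of = labels.class_of()
    cond_of = dict(zip(labels.table["label"].astype(int), labels.table["condition"]))
    out = []
    for lab in sorted(set(np.unique(lab_img)) - {0}):
        sel = (lab_img == lab) & rmap.mask.valid
        n_valid = int(sel.sum())
        n_total = int((lab_img == lab).sum())
        if n_total:
            logger.debug("ROI %d: %.1f%% pixels masked", lab,
                         100.0 * (1 - n_valid / n_total))
        if n_valid == 0:
            out.append(
                ROIStat(
                    specimen=session.specimen_id,
                    condition=str(cond_of.get(int(lab), session.condition)),
                    organelle=class_of[int(lab)],
                    roi_id=int(lab),
                    n_valid=0,
                    f_mean=np.nan,
                    f_sd=np.nan,
                    f_se=np.nan,
                    total_minor=0,
                    total_major=0,
                    method=method,
                    element=element,
                    has_estimate=False,
                )
            )
            continue
        tm = int(minor_tot[sel].sum())
        tM = int(major_tot[sel].sum())
        pix = rmap.fraction[sel]
        if method == "pixelwise":
            f_mean = float(pix.mean())
        else:
            f_mean = tm / (tm + tM)
        f_sd = float(pix.std(ddof=1)) if n_valid > 1 else np.nan
        out.append(
            ROIStat(
                specimen=session.specimen_id,
                condition=str(cond_of.get(int(lab), session.condition)),
                organelle=class_of[int(lab)],
                roi_id=int(lab),
                n_valid=n_valid,
                f_mean=f_mean,
                f_sd=f_sd,
                f_se=float(counting_se(tm, tM)),
                total_minor=tm,
                total_major=tM,
                method=method,
                element=element,
                has_estimate=True,
            )
        )
    return out


def roi_stats_frame(stats) -> pd.DataFrame:
    """ROIStat list → DataFrame with the fixed documented column order."""
    rows = [
        {
            "specimen": s.specimen,
            "condition": s.condition,
            "class": s.organelle.value,
            "roi_id": s.roi_id,
            "n_valid": s.n_valid,
            "f_mean": s.f_mean,
            "f_sd": s.f_sd,
            "f_se": s.f_se,
            "total_minor": s.total_minor,
            "total_major": s.total_major,
            "method": s.method,
            "element": s.element,
            "has_estimate": s.has_estimate,
        }
        for s in stats
    ]
    return pd.DataFrame(rows, columns=list(ROI_TABLE_COLUMNS))


def summarize(stats) -> pd.DataFrame:
    """Per-(element, condition, class) summary of ROI-level atom%.

    Returns columns (element, condition, class, n, mean_atom_pct,
    sd_atom_pct); the SD is the between-ROI sample SD and is empty (NaN)
    for n = 1.  ROIs without estimates are excluded; an empty input yields
    an empty table.
    """
    frame = roi_stats_frame(s for s in stats if s.has_estimate)
    cols = ["element", "condition", "class", "n", "mean_atom_pct", "sd_atom_pct"]
    if frame.empty:
        return pd.DataFrame(columns=cols)
    frame["atom_pct"] = 100.0 * frame["f_mean"]
    grouped = (
        frame.groupby(["element", "condition", "class"], sort=True)["atom_pct"]
        .agg(n="count", mean_atom_pct="mean", sd_atom_pct=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return grouped.loc[:, cols]


def qc_count_dependence(stats) -> tuple:
    """Spearman correlation between ROI total counts and atom fraction.

    A sound acquisition shows no relationship between total count numbers
    and isotopic composition; a strong correlation flags count-dependent
    artifacts.  Requires at least 3 ROIs with estimates.
    """
    est = [s for s in stats if s.has_estimate]
    if len(est) < 3:
        raise InsufficientDataError(
            f"need >= 3 ROIs with estimates, got {len(est)}"
        )
    totals = [s.total_minor + s.total_major for s in est]
    fracs = [s.f_mean for s in est]
    rho, p = sps.spearmanr(totals, fracs)
    return float(rho), float(p)
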