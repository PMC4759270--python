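"""Isotope arithmetic: atom fractions from ion counts and δ-notation.

NanoSIMS quantification works on the *atom fraction* of the rare isotope,

    f = minor / (minor + major),

e.g. ¹²C¹⁵N⁻/(¹²C¹⁴N⁻ + ¹²C¹⁵N⁻) for nitrogen and ³⁴S⁻/(³²S⁻ + ³⁴S⁻) for
sulfur (a two-isotope treatment that ignores the trace ³³S/³⁶S isotopes).
Atom% is simply 100·f.  The classical geochemical δ-notation expresses the
same composition as a per-mil deviation from a standard; two conventions are
in circulation and both are provided:

``fraction_ratio``
    δ = (f / f_std − 1)·1000 — the ratio of atom fractions.  This is the
    default because it reproduces the conventional NanoSIMS cross-check
    (0.3751 atom% ¹⁵N ↔ +24.0 ‰ vs AIR).
``isotope_ratio``
    δ = (R / R_std − 1)·1000 with R = f/(1−f) — the textbook definition on
    isotope-abundance ratios.  For tracer-level fractions the two agree to
    first order in f.

Standards: atmospheric N₂ (AIR) for nitrogen and Vienna Cañon Diablo
Troilite (VCDT) for sulfur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidArgumentError, OutOfRangeError, UndefinedRatioError

__all__ = [
    "IsotopeStandard",
    "AIR_N",
    "VCDT_S",
    "STANDARDS",
    "atom_fraction",
    "counting_se",
    "delta_from_fraction",
    "fraction_from_delta",
]

Convention = Literal["fraction_ratio", "isotope_ratio"]
_CONVENTIONS = ("fraction_ratio", "isotope_ratio")


@dataclass(frozen=True)
class IsotopeStandard:
    """A reference isotopic composition for δ-notation.

    Attributes
    ----------
    name : str
        Standard identifier (``AIR_N`` or ``VCDT_S``).
    element : str
        Element tag, ``"N"`` or ``"S"``.
    f_std : float
        Minor-isotope atom fraction of the standard.
    r_std : float
        Minor/major isotope abundance ratio of the standard; equals
        ``f_std / (1 - f_std)`` to 5 significant digits.
    """

    name: str
    element: str
    f_std: float
    r_std: float

    def __post_init__(self):
        if not 0.0 < self.f_std < 1.0:
            raise InvalidArgumentError(f"f_std must be in (0, 1), got {self.f_std}")


#: Atmospheric nitrogen: ¹⁵N atom fraction 0.3663 atom%, ¹⁵N/¹⁴N = 0.0036765.
AIR_N = IsotopeStandard(name="AIR_N", element="N", f_std=0.0036630, r_std=0.0036765)

#: Vienna Cañon Diablo Troilite under the two-isotope (³²S/³⁴S) model:
#: ³⁴S/³²S = 0.0441626, hence f_std = R/(1+R).
VCDT_S = IsotopeStandard(
    name="VCDT_S", element="S", f_std=0.0441626 / (1.0 + 0.0441626), r_std=0.0441626
)

STANDARDS = {s.name: s for s in (AIR_N, VCDT_S)}


def _as_standard(standard: IsotopeStandard | str) -> IsotopeStandard:
    if isinstance(standard, IsotopeStandard):
        return standard
    try:
        return STANDARDS[standard]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown isotope standard {standard!r}; known: {sorted(STANDARDS)}"
        ) from None


def _check_convention(convention: str) -> None:
    if convention not in _CONVENTIONS:
        raise InvalidArgumentError(
            f"unknown delta convention {convention!r}; known: {_CONVENTIONS}"
        )


def atom_fraction(minor, major):
    """Minor-isotope atom fraction ``minor / (minor + major)``.

    Accepts scalars or arrays of non-negative counts.  The result is
    scale-invariant: multiplying both counts by the same factor leaves it
    unchanged.

    Raises
    ------
    UndefinedRatioError
        If any total ``minor + major`` is zero.
    InvalidArgumentError
        If any count is negative.
    """
    minor = np.asarray(minor, dtype=float)
    major = np.asarray(major, dtype=float)
    if np.any(minor < 0) or np.any(major < 0):
        raise InvalidArgumentError("counts must be non-negative")
    total = minor + major
    if np.any(total == 0):
        raise UndefinedRatioError("atom fraction undefined for zero total counts")
    out = minor / total
    return float(out) if out.ndim == 0 else out


def counting_se(minor, major):
    """Binomial counting standard error of the atom fraction.

    For total ion counts ``n = minor + major`` and fraction ``f``, the
    shot-noise standard error of ``f`` is ``sqrt(f (1 - f) / n)``.  This is
    the irreducible precision floor of a NanoSIMS ratio measurement.
    """
    f = atom_fraction(minor, major)
    total = np.asarray(minor, dtype=float) + np.asarray(major, dtype=float)
    out = np.sqrt(np.asarray(f) * (1.0 - np.asarray(f)) / total)
    return float(out) if out.ndim == 0 else out


def delta_from_fraction(
    f,
    standard: IsotopeStandard | str = AIR_N,
    convention: Convention = "fraction_ratio",
):
    """Convert atom fraction(s) to δ-notation (‰) against a standard."""
    std = _as_standard(standard)
    _check_convention(convention)
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f >= 1):
        raise OutOfRangeError("atom fraction must lie in [0, 1)")
    if convention == "fraction_ratio":
        delta = (f / std.f_std - 1.0) * 1000.0
    else:
        delta = ((f / (1.0 - f)) / std.r_std - 1.0) * 1000.0
    return float(delta) if delta.ndim == 0 else delta


def fraction_from_delta(
    delta,
    standard: IsotopeStandard | str = AIR_N,
    convention: Convention = "fraction_ratio",
):
    """Exact inverse of :func:`delta_from_fraction` under the same convention.

    Raises
    ------
    OutOfRangeError
        If the implied fraction would fall outside [0, 1) — for the
        fraction-ratio convention this happens at δ ≤ −1000 ‰ (or at very
        large δ where f would reach 1).
    """
    std = _as_standard(standard)
    _check_convention(convention)
    delta = np.asarray(delta, dtype=float)
    if convention == "fraction_ratio":
        if np.any(delta <= -1000.0):
            raise OutOfRangeError(
                "delta <= -1000 permil implies a non-positive atom fraction"
            )
        f = (delta / 1000.0 + 1.0) * std.f_std
    else:
        r = (delta / 1000.0 + 1.0) * std.r_std
        if np.any(r < 0):
            raise OutOfRangeError("delta implies a negative isotope ratio")
        f = r / (1.0 + r)
    if np.any(f < 0) or np.any(f >= 1):
        raise OutOfRangeError(
            f"delta {delta} implies an atom fraction outside [0, 1)"
        )
    return float(f) if f.ndim == 0 else f


def atom_percent(f) -> float:
    """Atom% = 100 × atom fraction (display convenience)."""
    return 100.0 * np.asarray(f, dtype=float)


def display_ratio(f):
    """Convert an atom fraction to the minor/major display ratio f/(1−f).

    Ratio images in publications are often shown as ¹²C¹⁵N⁻/¹²C¹⁴N⁻ rather
    than as atom fractions; this is the conversion between the two.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f >= 1):
        raise OutOfRangeError("atom fraction must be < 1")
    out = f / (1.0 - f)
    return float(out) if out.ndim == 0 else out
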