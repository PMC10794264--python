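"""The delta-notation calculus for carbon isotope ratios.

Natural-abundance 13C measurements are reported in delta notation,

    delta13C = (R_sample / R_standard - 1) * 1000   [mUr]

where R = 13C/12C and the standard is Vienna Peedee Belemnite (VPDB,
R_VPDB = 0.0112372).  One mUr (milli-Urey) is exactly one per mil; a
less negative delta13C is more enriched in 13C.  This module converts
among delta13C, the isotope ratio R, and the atom fraction
13C/(13C + 12C) used to express "%13C enrichment" in figures.

All functions are pure and accept either ``DeltaValue`` objects or bare
floats where a delta is expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "IsotopeConstants",
    "VPDB",
    "DeltaValue",
    "AtomFraction",
    "delta_to_ratio",
    "ratio_to_delta",
    "ratio_to_atom_fraction",
    "atom_fraction_to_ratio",
    "delta_to_atom_fraction",
]

#: Scale labels for DeltaValue.
RAW = "raw"
VPDB_SCALE = "vpdb"

_MIN_DELTA = -1000.0  # delta of -1000 mUr <=> R = 0; below is unphysical


@dataclass(frozen=True)
class IsotopeConstants:
    """Registry of physical constants anchoring the delta scale.

    Parameters
    ----------
    r_vpdb
        13C/12C isotope ratio of the VPDB standard (dimensionless).
    """

    r_vpdb: float = 0.0112372

    def __post_init__(self) -> None:
        if not self.r_vpdb > 0:
            raise ValueError(f"r_vpdb must be positive, got {self.r_vpdb}")


#: Default constants used throughout the package.
VPDB = IsotopeConstants()


@dataclass(frozen=True)
class DeltaValue:
    """A delta13C value in mUr on a declared scale.

    Parameters
    ----------
    value
        delta13C in mUr (per mil). Must exceed -1000 (R = 0 limit).
    sd
        Optional 1-SD measurement uncertainty, mUr.
    scale
        ``"raw"`` for un-normalized instrument values, ``"vpdb"`` for
        values normalized to the VPDB reference scale.
    """

    value: float
    sd: Optional[float] = None
    scale: str = VPDB_SCALE

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("delta value must be finite")
        if self.value <= _MIN_DELTA:
            raise ValueError(
                f"delta13C of {self.value} mUr is at or below the physical "
                f"limit of {_MIN_DELTA} mUr (zero 13C)"
            )
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.scale not in (RAW, VPDB_SCALE):
            raise ValueError(f"scale must be 'raw' or 'vpdb', got {self.scale!r}")

    def rounded(self, ndigits: int = 2) -> float:
        """Presentation value, rounded only at the point of display."""
        return round(self.value, ndigits)


@dataclass(frozen=True)
class AtomFraction:
    """Fraction of carbon atoms that are 13C: 13C/(13C + 12C)."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"atom fraction must lie in [0, 1], got {self.value}")

    @property
    def percent(self) -> float:
        """The fraction as %13C, as printed in figure captions."""
        return 100.0 * self.value


def _delta_float(d: "DeltaValue | float") -> float:
    v = d.value if isinstance(d, DeltaValue) else float(d)
    if v <= _MIN_DELTA:
        raise ValueError(f"delta13C must exceed {_MIN_DELTA} mUr, got {v}")
    return v


def delta_to_ratio(d: "DeltaValue | float", c: IsotopeConstants = VPDB) -> float:
    """Convert delta13C (mUr) to the isotope ratio R = 13C/12C.

    R = R_VPDB * (1 + delta/1000); strictly increasing in delta.
    """
    return c.r_vpdb * (1.0 + _delta_float(d) / 1000.0)


def ratio_to_delta(r: float, c: IsotopeConstants = VPDB, scale: str = VPDB_SCALE) -> DeltaValue:
    """Convert an isotope ratio R = 13C/12C back to delta13C.

    Inverse of :func:`delta_to_ratio`; R = 0 maps to the -1000 mUr
    limit, which is rejected as a stored value.
    """
    if r < 0:
        raise ValueError(f"isotope ratio must be non-negative, got {r}")
    value = 1000.0 * (r / c.r_vpdb - 1.0)
    return DeltaValue(value=value, scale=scale)


def ratio_to_atom_fraction(r: float) -> AtomFraction:
    """Convert R = 13C/12C to the atom fraction 13C/(13C + 12C) = R/(1+R)."""
    if r < 0:
        raise ValueError(f"isotope ratio must be non-negative, got {r}")
    return AtomFraction(r / (1.0 + r))


def atom_fraction_to_ratio(f: "AtomFraction | float") -> float:
    """Convert atom fraction F back to R = F/(1 - F)."""
    v = f.value if isinstance(f, AtomFraction) else float(f)
    if not 0.0 <= v < 1.0:
        raise ValueError(f"atom fraction must lie in [0, 1), got {v}")
    return v / (1.0 - v)


def delta_to_atom_fraction(d: "DeltaValue | float", c: IsotopeConstants = VPDB) -> AtomFraction:
    """delta13C (mUr) straight to atom fraction 13C/(13C + 12C)."""
    return ratio_to_atom_fraction(delta_to_ratio(d, c))
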