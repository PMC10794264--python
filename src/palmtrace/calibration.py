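"""Multipoint normalization of raw instrument delta13C to the VPDB scale.

GC-C-IRMS reports delta values relative to a laboratory working gas.
Certified reference materials (CRMs, e.g. USGS70/USGS71/USGS72 methyl
esters) injected within each instrument sequence anchor those values to
the international VPDB scale: an ordinary least-squares line predicting
the certified ("true") delta from the measured delta is fitted per
sequence and applied to unknowns.  An R-squared quality gate (default
0.999) flags poor calibrations as warnings without discarding them.

Regression direction: the certified value is regressed on the measured
value, so the fitted line applies directly to unknown samples with no
inversion.  At the R-squared values typical of these calibrations the
two directions are numerically indistinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from palmtrace.isotope import RAW, VPDB_SCALE, DeltaValue

__all__ = [
    "ReferenceMaterial",
    "CalibrationModel",
    "CalibrationError",
    "ScaleMismatchError",
    "fit_normalization",
    "apply_normalization",
    "read_crm_csv",
    "DEFAULT_R2_GATE",
]

logger = logging.getLogger(__name__)

DEFAULT_R2_GATE = 0.999

#: Placeholder certified delta13C values (mUr, VPDB) for the USGS FAME
#: reference materials.  These are user-supplied configuration inputs:
#: replace them with the certificate values for your CRM lots.
DEFAULT_CRM_CERTIFIED = {
    "USGS70": -30.53,
    "USGS71": -10.50,
    "USGS72": -1.54,
}


class CalibrationError(ValueError):
    """Raised when a normalization fit is impossible or degenerate."""


class ScaleMismatchError(ValueError):
    """Raised when a delta value is on the wrong scale for an operation."""


@dataclass(frozen=True)
class ReferenceMaterial:
    """One CRM injection: certified (VPDB) and measured (raw) delta13C."""

    id: str
    certified_delta: DeltaValue
    measured_delta: DeltaValue
    sequence_position: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reference material id must be non-empty")
        if self.certified_delta.scale != VPDB_SCALE:
            raise ScaleMismatchError("certified delta must be on the vpdb scale")
        if self.measured_delta.scale != RAW:
            raise ScaleMismatchError("measured delta must be on the raw scale")


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map from raw instrument delta to the VPDB scale."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")


def fit_normalization(
    crms: Sequence[ReferenceMaterial],
    r2_gate: float = DEFAULT_R2_GATE,
) -> CalibrationModel:
    """Fit the per-sequence normalization line from CRM injections.

    Ordinary least squares predicting certified delta from measured
    delta.  Fewer than two points, or all measured values equal, is a
    :class:`CalibrationError`.  R-squared below ``r2_gate`` logs a
    warning but does not fail: the gate is a QC outcome, not an
    exclusion rule.
    """
    if len(crms) < 2:
        raise CalibrationError(
            f"need at least 2 reference materials, got {len(crms)}"
        )
    x = np.array([c.measured_delta.value for c in crms], dtype=float)
    y = np.array([c.certified_delta.value for c in crms], dtype=float)
    if np.ptp(x) == 0.0:
        raise CalibrationError("all measured CRM deltas identical; fit is degenerate")

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)

    if r2 < r2_gate:
        logger.warning(
            "calibration R^2 = %.6f below the %.3f gate (n=%d)", r2, r2_gate, len(crms)
        )
    return CalibrationModel(slope=float(slope), intercept=float(intercept),
                            r_squared=r2, n_points=len(crms))


def apply_normalization(model: CalibrationModel, d: DeltaValue) -> DeltaValue:
    """Map a raw-scale delta to the VPDB scale through the fitted line.

    The measurement uncertainty, when present, is carried through
    unchanged (the calibration slope is ~1 at natural abundance).
    """
    if d.scale != RAW:
        raise ScaleMismatchError(
            "apply_normalization expects a raw-scale delta; value is already "
            f"on the {d.scale!r} scale"
        )
    return DeltaValue(
        value=model.slope * d.value + model.intercept,
        sd=d.sd,
        scale=VPDB_SCALE,
    )


def read_crm_csv(path) -> "dict[str, list[ReferenceMaterial]]":
    """Read a CRM table and group injections by instrument sequence.

    Expected columns: ``sequence_id, crm_id, certified_delta_mur,
    measured_delta_mur`` (UTF-8, comma-separated, header row).
    """
    df = pd.read_csv(path)
    required = {"sequence_id", "crm_id", "certified_delta_mur", "measured_delta_mur"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CRM table missing columns: {sorted(missing)}")
    out: dict[str, list[ReferenceMaterial]] = {}
    for seq_id, grp in df.groupby("sequence_id", sort=False):
        out[str(seq_id)] = [
            ReferenceMaterial(
                id=str(row.crm_id),
                certified_delta=DeltaValue(float(row.certified_delta_mur), scale=VPDB_SCALE),
                measured_delta=DeltaValue(float(row.measured_delta_mur), scale=RAW),
                sequence_position=i,
            )
            for i, row in enumerate(grp.itertuples(index=False))
        ]
    return out


def calibrate_sequences(
    crms_by_sequence: "dict[str, list[ReferenceMaterial]]",
    r2_gate: float = DEFAULT_R2_GATE,
) -> "dict[str, CalibrationModel]":
    """Fit one normalization model per instrument sequence."""
    return {
        seq: fit_normalization(crms, r2_gate=r2_gate)
        for seq, crms in crms_by_sequence.items()
    }
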