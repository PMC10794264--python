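"""Internal-standard quantification of fatty acids from peak areas.

A known amount of an exogenous fatty acid (heptadecanoic acid, 17:0)
spiked into each tissue homogenate converts integrated chromatographic
peak areas into absolute amounts:

    amount_i = (area_i / area_IS) * amount_IS

Concentrations are per gram of tissue, and relative percent composition
is computed over endogenous analytes only (the internal standard is
excluded from the denominator).  Response factors default to unity for
all species; a per-species table may override them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from palmtrace.derivatization import FattyAcidSpecies, species as _species

__all__ = [
    "PeakRecord",
    "InternalStandard",
    "CompositionRow",
    "QuantificationError",
    "quantify_sample",
    "quantify_table",
]


class QuantificationError(ValueError):
    """Missing/zero internal standard or duplicated analyte peaks."""


@dataclass(frozen=True)
class PeakRecord:
    """One integrated chromatographic peak."""

    sample_id: str
    species: FattyAcidSpecies
    area: float
    retention_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"peak area must be non-negative, got {self.area}")


@dataclass(frozen=True)
class InternalStandard:
    """The spiked exogenous species and the amount added per sample (ug)."""

    species: FattyAcidSpecies = _species("17:0")
    amount: float = 10.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("internal standard amount must be positive")


@dataclass(frozen=True)
class CompositionRow:
    """Quantified analyte: amount (ug), concentration (ug/g), relative %."""

    sample_id: str
    species: FattyAcidSpecies
    amount: float
    concentration: float
    relative_percent: float


def quantify_sample(
    peaks: Sequence[PeakRecord],
    is_std: InternalStandard,
    tissue_mass: float,
    response_factors: Optional[Mapping[str, float]] = None,
) -> list[CompositionRow]:
    """Quantify one sample's analytes against its internal standard.

    Exactly one internal-standard peak (matched by species shorthand)
    must be present with non-zero area.  Zero-area analytes are kept as
    zeros so composition denominators stay comparable across samples.
    """
    if tissue_mass <= 0:
        raise ValueError("tissue mass must be positive")
    rf = dict(response_factors or {})

    is_peaks = [p for p in peaks if p.species.shorthand == is_std.species.shorthand]
    if len(is_peaks) != 1:
        raise QuantificationError(
            f"expected exactly one internal-standard ({is_std.species.shorthand}) "
            f"peak, found {len(is_peaks)}"
        )
    if is_peaks[0].area == 0:
        raise QuantificationError("internal-standard peak has zero area")
    area_is = is_peaks[0].area

    analytes = [p for p in peaks if p.species.shorthand != is_std.species.shorthand]
    seen: set[str] = set()
    for p in analytes:
        if p.species.shorthand in seen:
            raise QuantificationError(
                f"duplicate peaks for species {p.species.shorthand}"
            )
        seen.add(p.species.shorthand)

    amounts = {
        p.species.shorthand: (p.area / area_is)
        * is_std.amount
        * rf.get(p.species.shorthand, 1.0)
        for p in analytes
    }
    total = sum(amounts.values())
    rows = []
    for p in analytes:
        amt = amounts[p.species.shorthand]
        rows.append(
            CompositionRow(
                sample_id=p.sample_id,
                species=p.species,
                amount=amt,
                concentration=amt / tissue_mass,
                relative_percent=(100.0 * amt / total) if total > 0 else 0.0,
            )
        )
    return rows


def quantify_table(
    peak_table: pd.DataFrame,
    sample_table: pd.DataFrame,
    is_species: str = "17:0",
) -> pd.DataFrame:
    """Quantify every sample in a tidy peak table.

    ``peak_table`` columns: sample_id, species, area[, retention_time];
    ``sample_table`` columns: sample_id, tissue_mass_g, is_amount_ug.
    Returns a tidy composition table (one row per sample x species).
    """
    meta = sample_table.set_index("sample_id")
    out = []
    for sample_id, grp in peak_table.groupby("sample_id", sort=False):
        info = meta.loc[sample_id]
        peaks = [
            PeakRecord(
                sample_id=str(sample_id),
                species=_species(str(r.species)),
                area=float(r.area),
                retention_time=float(r.retention_time)
                if "retention_time" in grp.columns and pd.notna(r.retention_time)
                else None,
            )
            for r in grp.itertuples(index=False)
        ]
        is_std = InternalStandard(
            species=_species(is_species), amount=float(info["is_amount_ug"])
        )
        for row in quantify_sample(peaks, is_std, float(info["tissue_mass_g"])):
            out.append(
                {
                    "sample_id": row.sample_id,
                    "species": row.species.shorthand,
                    "amount_ug": row.amount,
                    "concentration_ug_per_g": row.concentration,
                    "relative_percent": row.relative_percent,
                }
            )
    return pd.DataFrame(out)
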