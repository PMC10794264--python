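"""Dietary end-member delta13C signatures.

A two-end-member apportionment needs the isotope signatures of its
sources.  Dietary sugars (sucrose, cornstarch, maltodextrin — largely
C4-derived, hence 13C-enriched) are pooled into one "dietary sugars"
end-member; each diet's preformed palmitate carries its own measured
delta.  The pooled signature uses the arithmetic mean of component
deltas with their sample SD ("replicate" mode, the default, matching
equal technical replication per component); an energy-weighted mean is
available as an option and differs from the replicate mean by ~0.1 mUr
for typical rodent-diet carbohydrate blends.

:func:`reference_diets` ships the three-diet design used throughout the
package's examples and simulations: low (LP), medium (MP) and high (HP)
palmitate diets that are isocaloric and differ only in the PAM/OLA
split of the fat fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from palmtrace.derivatization import FattyAcidSpecies
from palmtrace.isotope import DeltaValue, VPDB_SCALE

__all__ = [
    "DietComponent",
    "SourceSignature",
    "AbsentEndMember",
    "pool_signature",
    "diet_fat_signature",
    "sugar_signature",
    "reference_diets",
    "read_diet_csv",
]

_MACRO_CLASSES = ("fat", "protein", "carbohydrate")


@dataclass(frozen=True)
class DietComponent:
    """One diet ingredient with its energy share and delta13C."""

    name: str
    macro_class: str
    pct_energy: float
    delta: Optional[DeltaValue] = None  # None: not isotopically characterized
    n_reps: int = 3

    def __post_init__(self) -> None:
        if self.macro_class not in _MACRO_CLASSES:
            raise ValueError(f"macro_class must be one of {_MACRO_CLASSES}")
        if self.pct_energy < 0:
            raise ValueError("pct_energy must be non-negative")


@dataclass(frozen=True)
class SourceSignature:
    """A pooled end-member signature: label, delta13C +- SD, members."""

    label: str
    delta: DeltaValue
    members: tuple = ()


class AbsentEndMember:
    """Marker for a diet that lacks the requested fat end-member.

    The LP diet contains no palmitate, so it has no dietary-PAM
    signature; callers must substitute one explicitly (see
    :func:`palmtrace.mixing.mixing_fraction`).
    """

    def __init__(self, diet_id: str, species: str):
        self.diet_id = diet_id
        self.species = species

    def __repr__(self) -> str:  # pragma: no cover
        return f"AbsentEndMember(diet={self.diet_id!r}, species={self.species!r})"


def pool_signature(
    components: Sequence[DietComponent],
    weighting: Literal["replicate", "energy"] = "replicate",
    label: str = "pooled",
) -> SourceSignature:
    """Pool component deltas into one end-member signature.

    ``replicate`` mode (default, for equal replication across
    components) returns the arithmetic mean of component deltas with
    the n-1 sample SD of those deltas.  ``energy`` mode returns the
    pct_energy-weighted mean with the weighted SD.
    """
    comps = [c for c in components if c.delta is not None]
    if not comps:
        raise ValueError("no isotopically characterized components to pool")
    deltas = np.array([c.delta.value for c in comps], dtype=float)

    if weighting == "replicate":
        reps = np.array([c.n_reps for c in comps], dtype=float)
        if np.any(reps <= 0):
            raise ValueError("n_reps must be positive")
        w = reps / reps.sum()
        mean = float(w @ deltas)
        sd = float(np.std(deltas, ddof=1)) if len(deltas) > 1 else (
            comps[0].delta.sd or 0.0
        )
    elif weighting == "energy":
        w = np.array([c.pct_energy for c in comps], dtype=float)
        if np.any(w < 0):
            raise ValueError("negative energy weights")
        if w.sum() == 0:
            raise ValueError("zero total energy weight")
        w = w / w.sum()
        mean = float(w @ deltas)
        var = float(w @ (deltas - mean) ** 2)
        n_eff = 1.0 / float(w @ w)
        sd = (var * n_eff / (n_eff - 1.0)) ** 0.5 if n_eff > 1 else 0.0
    else:
        raise ValueError(f"unknown weighting mode {weighting!r}")

    return SourceSignature(
        label=label,
        delta=DeltaValue(mean, sd=sd, scale=VPDB_SCALE),
        members=tuple(c.name for c in comps),
    )


def sugar_signature(
    diet: Sequence[DietComponent],
    weighting: Literal["replicate", "energy"] = "replicate",
) -> SourceSignature:
    """The pooled "dietary sugars" end-member of a diet's carbohydrates."""
    carbs = [c for c in diet if c.macro_class == "carbohydrate"]
    return pool_signature(carbs, weighting=weighting, label="dietary sugars")


def diet_fat_signature(
    diet: Sequence[DietComponent],
    target_species: FattyAcidSpecies,
    diet_id: str = "",
) -> "SourceSignature | AbsentEndMember":
    """The measured delta of a diet's fat matching ``target_species``.

    Fat components are matched by name against the species shorthand
    and its common name (e.g. 16:0 <-> "palmitic acid").  A diet with
    no such fat yields an :class:`AbsentEndMember` marker, never a
    number.
    """
    aliases = {
        "16:0": ("palmitic", "16:0", "pam"),
        "18:1n-9": ("oleic", "18:1", "ola"),
        "18:0": ("stearic", "18:0", "sta"),
    }.get(target_species.shorthand, (target_species.shorthand.lower(),))

    matches = [
        c
        for c in diet
        if c.macro_class == "fat"
        and c.delta is not None
        and any(a in c.name.lower() for a in aliases)
    ]
    if not matches:
        return AbsentEndMember(diet_id=diet_id, species=target_species.shorthand)
    if len(matches) > 1:
        raise ValueError(
            f"ambiguous fat end-member for {target_species.shorthand}: "
            f"{[c.name for c in matches]}"
        )
    c = matches[0]
    return SourceSignature(label=f"dietary {c.name}", delta=c.delta, members=(c.name,))


def _d(value: float, sd: float) -> DeltaValue:
    return DeltaValue(value, sd=sd, scale=VPDB_SCALE)


def reference_diets() -> "dict[str, list[DietComponent]]":
    """The three-diet (LP/MP/HP palmitate) composition table.

    Isocaloric diets (16.78% fat, 19.36% protein, 63.89% carbohydrate
    by energy); the fat fraction swaps oleate for palmitate.  Soybean
    oil, L-cystine and the shared carbohydrates round out each diet;
    components without a measured delta carry ``delta=None``.
    """
    carbs = [
        DietComponent("Sucrose", "carbohydrate", 10.64, _d(-11.86, 0.08)),
        DietComponent("Cornstarch", "carbohydrate", 38.06, _d(-11.01, 0.61)),
        DietComponent("Maltodextrin 10", "carbohydrate", 13.34, _d(-10.58, 0.24)),
    ]
    protein = [
        DietComponent("Casein", "protein", 19.04, _d(-23.88, 0.12)),
        DietComponent("L-Cystine", "protein", 0.32, None),
    ]
    soy = DietComponent("Soybean oil", "fat", 1.2, None)
    return {
        "LP": [
            DietComponent("Oleic acid", "fat", 15.58, _d(-28.39, 0.12)),
            soy, *protein, *carbs,
        ],
        "MP": [
            DietComponent("Palmitic acid", "fat", 7.79, _d(-29.44, 0.12)),
            DietComponent("Oleic acid", "fat", 7.79, _d(-28.26, 0.12)),
            soy, *protein, *carbs,
        ],
        "HP": [
            DietComponent("Palmitic acid", "fat", 15.58, _d(-29.70, 0.19)),
            soy, *protein, *carbs,
        ],
    }


def read_diet_csv(path) -> "dict[str, list[DietComponent]]":
    """Read a diet composition table.

    Columns: ``diet_id, component, macro_class, pct_energy, delta_mur,
    sd_mur`` (empty delta_mur means not characterized).
    """
    df = pd.read_csv(path)
    out: dict[str, list[DietComponent]] = {}
    for diet_id, grp in df.groupby("diet_id", sort=False):
        comps = []
        for r in grp.itertuples(index=False):
            delta = None
            if pd.notna(r.delta_mur):
                sd = float(r.sd_mur) if pd.notna(r.sd_mur) else None
                delta = DeltaValue(float(r.delta_mur), sd=sd, scale=VPDB_SCALE)
            comps.append(
                DietComponent(
                    name=str(r.component),
                    macro_class=str(r.macro_class),
                    pct_energy=float(r.pct_energy),
                    delta=delta,
                )
            )
        out[str(diet_id)] = comps
    return out
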