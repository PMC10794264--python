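"""Methyl-carbon mass-balance correction for FAME delta13C values.

Fatty acids are analyzed by GC as methyl esters (FAMEs); the methylation
adds one exogenous carbon whose isotope signature must be removed to
recover the native fatty-acid delta13C.  The correction is a carbon
mass balance over the ester:

    n_FAME * d13C_FAME = d13C_ME + n_FA * d13C_FA

where n_FA is the fatty-acid carbon count, n_FAME = n_FA + 1 the ester
count, and d13C_ME the signature of the single derivatized methyl
carbon (weight 1 in the balance).  d13C_ME is determined empirically by
running a methylated/unmethylated standard pair (conventionally 17:0);
the package default is -41.56 mUr.

The correction is linear in d13C_FAME (slope n_FAME/n_FA > 1), so
first-order uncertainty propagation is exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from palmtrace.isotope import DeltaValue, VPDB_SCALE

__all__ = [
    "FattyAcidSpecies",
    "MethylCorrection",
    "DEFAULT_METHYL_DELTA_MUR",
    "species",
    "methyl_delta",
    "fame_delta",
    "correct_fame_delta",
]

#: Default delta13C of the derivatized methyl carbon, mUr (VPDB scale),
#: as determined from a methylated/unmethylated 17:0 pair.
DEFAULT_METHYL_DELTA_MUR = -41.56

#: Carbon counts for common fatty-acid shorthands; n_fame = n_fa + 1.
_SPECIES_CARBONS = {
    "14:0": 14,
    "16:0": 16,   # palmitic acid, PAM
    "16:1n-7": 16,  # palmitoleic, POA
    "17:0": 17,   # heptadecanoic, the usual internal standard
    "18:0": 18,   # stearic, STA
    "18:1n-9": 18,  # oleic, OLA
    "18:2n-6": 18,  # linoleic, LNA
    "20:4n-6": 20,  # arachidonic, ARA
    "22:6n-3": 22,  # docosahexaenoic, DHA
}


@dataclass(frozen=True)
class FattyAcidSpecies:
    """A fatty-acid analyte: shorthand, native and ester carbon counts."""

    shorthand: str
    n_fa: int
    n_fame: int

    def __post_init__(self) -> None:
        if self.n_fa < 2:
            raise ValueError(f"n_fa must be >= 2, got {self.n_fa}")
        if self.n_fame != self.n_fa + 1:
            raise ValueError(
                f"methyl ester of {self.shorthand} must have n_fa + 1 carbons "
                f"(n_fa={self.n_fa}, n_fame={self.n_fame})"
            )


def species(shorthand: str) -> FattyAcidSpecies:
    """Look up (or parse) a fatty acid by shorthand like ``"16:0"``.

    Known species come from the registry; unknown shorthands are parsed
    as ``<carbons>:<double bonds>[n-x]`` with n_fame = n_fa + 1.
    """
    if shorthand in _SPECIES_CARBONS:
        n_fa = _SPECIES_CARBONS[shorthand]
    else:
        m = re.match(r"^(\d+):\d+(n-\d+)?$", shorthand)
        if not m:
            raise KeyError(f"unrecognized fatty-acid shorthand: {shorthand!r}")
        n_fa = int(m.group(1))
    return FattyAcidSpecies(shorthand=shorthand, n_fa=n_fa, n_fame=n_fa + 1)


@dataclass(frozen=True)
class MethylCorrection:
    """delta13C of the derivatized CH3 carbon (one carbon, VPDB scale)."""

    delta_me: DeltaValue

    def __post_init__(self) -> None:
        if self.delta_me.scale != VPDB_SCALE:
            raise ValueError("methyl-carbon delta must be on the vpdb scale")


#: Package default correction (applied when no standard pair is supplied).
DEFAULT_METHYL_CORRECTION = MethylCorrection(
    DeltaValue(DEFAULT_METHYL_DELTA_MUR, scale=VPDB_SCALE)
)


def _require_vpdb(d: DeltaValue, name: str) -> None:
    if d.scale != VPDB_SCALE:
        raise ValueError(f"{name} must be on the vpdb scale, got {d.scale!r}")


def methyl_delta(
    delta_fame_std: DeltaValue,
    delta_fa_std: DeltaValue,
    sp: FattyAcidSpecies,
) -> MethylCorrection:
    """Determine d13C_ME from a methylated/unmethylated standard pair.

    d13C_ME = n_FAME * d13C_FAME - n_FA * d13C_FA.
    """
    _require_vpdb(delta_fame_std, "delta_fame_std")
    _require_vpdb(delta_fa_std, "delta_fa_std")
    value = sp.n_fame * delta_fame_std.value - sp.n_fa * delta_fa_std.value
    sd: Optional[float] = None
    if delta_fame_std.sd is not None and delta_fa_std.sd is not None:
        sd = ((sp.n_fame * delta_fame_std.sd) ** 2
              + (sp.n_fa * delta_fa_std.sd) ** 2) ** 0.5
    return MethylCorrection(DeltaValue(value, sd=sd, scale=VPDB_SCALE))


def fame_delta(
    delta_fa: DeltaValue,
    sp: FattyAcidSpecies,
    corr: MethylCorrection = DEFAULT_METHYL_CORRECTION,
) -> DeltaValue:
    """Forward balance: the ester delta a given native fatty acid yields.

    d13C_FAME = (d13C_ME + n_FA * d13C_FA) / n_FAME.
    """
    _require_vpdb(delta_fa, "delta_fa")
    value = (corr.delta_me.value + sp.n_fa * delta_fa.value) / sp.n_fame
    sd = None if delta_fa.sd is None else sp.n_fa / sp.n_fame * delta_fa.sd
    return DeltaValue(value, sd=sd, scale=VPDB_SCALE)


def correct_fame_delta(
    delta_fame: DeltaValue,
    sp: FattyAcidSpecies,
    corr: MethylCorrection = DEFAULT_METHYL_CORRECTION,
) -> DeltaValue:
    """Remove the methyl carbon: recover the native fatty-acid delta.

    d13C_FA = (n_FAME * d13C_FAME - d13C_ME) / n_FA, the exact algebraic
    inverse of :func:`fame_delta`.
    """
    _require_vpdb(delta_fame, "delta_fame")
    assert sp.n_fa > 0
    value = (sp.n_fame * delta_fame.value - corr.delta_me.value) / sp.n_fa
    sd = None if delta_fame.sd is None else sp.n_fame / sp.n_fa * delta_fame.sd
    return DeltaValue(value, sd=sd, scale=VPDB_SCALE)
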