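"""Forward simulator of the three-diet developmental isotope study.

Generates, from declared ground truth, every table the analysis
pipeline consumes: diet definitions feed true tissue mixing fractions;
those produce native fatty-acid delta13C values; the derivatization
balance maps them to FAME deltas; an affine instrument distortion plus
Gaussian noise yields raw instrument deltas together with per-sequence
CRM injections; and peak areas are drawn so that internal-standard
quantification recovers the configured compositions.  The bundle keeps
ground truth in a separate sidecar so recovery tests can compare
pipeline output against what was simulated without leakage.

The default configuration emulates a low/medium/high-palmitate (LP <
MP < HP) diet design over four developmental timepoints (P0-P35) with
true sugar-derived fractions ordered f(LP) > f(MP) > f(HP), biological
between-animal scatter of 0.5 mUr, instrument noise of 0.3 mUr, CRM
repeatability of 0.05 mUr, and one instrument sequence (with its own
CRM injections) per tissue-timepoint batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from palmtrace.calibration import DEFAULT_CRM_CERTIFIED
from palmtrace.derivatization import (
    DEFAULT_METHYL_CORRECTION,
    fame_delta,
    species,
)
from palmtrace.isotope import DeltaValue, VPDB_SCALE
from palmtrace.mixing import substitute_fat_endmember
from palmtrace.signatures import (
    AbsentEndMember,
    DietComponent,
    diet_fat_signature,
    reference_diets,
    sugar_signature,
)

__all__ = ["GeneratorConfig", "SyntheticBundle", "generate", "generate_null"]

_TIMEPOINTS = ("P0", "P10", "P21", "P35")
_PAM = species("16:0")


def _default_f_true() -> "dict[tuple[str, str], float]":
    """Default true sugar-derived fractions per (diet, timepoint).

    Ordered f(LP) > f(MP) > f(HP) in every cell; the LP fraction rises
    and the HP fraction falls over development (the low-PAM pups lean
    harder on lipogenesis later; the high-PAM pups earlier).  These are
    generator parameters that set the qualitative dose-response shape,
    not estimates of any real cohort.
    """
    lp = dict(zip(_TIMEPOINTS, (0.84, 0.86, 0.88, 0.90)))
    mp = dict(zip(_TIMEPOINTS, (0.80, 0.80, 0.80, 0.80)))
    hp = dict(zip(_TIMEPOINTS, (0.76, 0.74, 0.72, 0.70)))
    out = {}
    for tp in _TIMEPOINTS:
        out[("LP", tp)] = lp[tp]
        out[("MP", tp)] = mp[tp]
        out[("HP", tp)] = hp[tp]
    return out


def _default_pam_percent() -> "dict[str, float]":
    """Target tissue PAM relative percent (post-weaning) per diet."""
    return {"LP": 20.0, "MP": 21.0, "HP": 22.0}


def _default_milk_carryover() -> "dict[str, tuple[float, float]]":
    """Pre-weaning stomach-content PAM ranges (%) per diet.

    Dams eat the study diets, so milk carries graded PAM: low (21-28%),
    medium (25-35%) and high (31-41%) for LP/MP/HP respectively.
    """
    return {"LP": (21.0, 28.0), "MP": (25.0, 35.0), "HP": (31.0, 41.0)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the forward model needs, with study-scale defaults."""

    seed: int = 20240117
    diets: Mapping[str, Sequence[DietComponent]] = field(default_factory=reference_diets)
    timepoints: tuple = _TIMEPOINTS
    n_per_cell: int = 6
    f_true: Mapping[tuple, float] = field(default_factory=_default_f_true)
    biological_sd: float = 0.5
    measurement_sd: float = 0.3
    drift_slope: float = 1.02
    drift_intercept: float = 0.8
    noise_sd_crm: float = 0.05
    tissue: str = "brain"
    tissue_pam_percent: Mapping[str, float] = field(default_factory=_default_pam_percent)
    milk_carryover: Mapping[str, tuple] = field(default_factory=_default_milk_carryover)
    crm_certified: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CRM_CERTIFIED)
    )
    is_amount_ug: float = 10.0
    tissue_mass_g: float = 0.1
    total_fa_ug: float = 200.0

    def __post_init__(self) -> None:
        for key, f in self.f_true.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"f_true[{key}] must lie in [0, 1], got {f}")
        for name in ("biological_sd", "measurement_sd", "noise_sd_crm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        missing = [
            (d, tp)
            for d in self.diets
            for tp in self.timepoints
            if (d, tp) not in self.f_true
        ]
        if missing:
            raise ValueError(f"f_true missing cells: {missing}")


@dataclass(frozen=True)
class SyntheticBundle:
    """The generated tables plus a ground-truth sidecar."""

    crm_table: pd.DataFrame
    raw_delta_table: pd.DataFrame
    peak_table: pd.DataFrame
    sample_metadata: pd.DataFrame
    ground_truth: dict

    def write(self, out_dir) -> None:
        """Write the pipeline-facing CSVs and the ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.crm_table.to_csv(out / "crm.csv", index=False)
        self.raw_delta_table.to_csv(out / "raw_deltas.csv", index=False)
        self.peak_table.to_csv(out / "peaks.csv", index=False)
        self.sample_metadata.to_csv(out / "samples.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)


#: Endogenous species carried in the simulated composition besides PAM.
_OTHER_SPECIES = ("18:0", "18:1n-9", "22:6n-3", "20:4n-6", "16:1n-7")


def _fat_endmembers(diets) -> "dict[str, float]":
    """Per-diet dietary-PAM end-member deltas; LP gets the substitute."""
    sigs = {d: diet_fat_signature(comps, _PAM, diet_id=d) for d, comps in diets.items()}
    real = [s for s in sigs.values() if not isinstance(s, AbsentEndMember)]
    sub = substitute_fat_endmember(real)
    return {
        d: (sub.delta.value if isinstance(s, AbsentEndMember) else s.delta.value)
        for d, s in sigs.items()
    }


def generate(config: GeneratorConfig = GeneratorConfig()) -> SyntheticBundle:
    """Run the forward model; deterministic for a given config + seed."""
    rng = np.random.default_rng(config.seed)
    any_diet = next(iter(config.diets.values()))
    d_sugar = sugar_signature(any_diet).delta.value
    d_fat = _fat_endmembers(config.diets)

    crm_rows, raw_rows, peak_rows, meta_rows = [], [], [], []
    truth_samples = {}

    for tp in config.timepoints:
        seq_id = f"{config.tissue}-{tp}"
        # CRM injections through the same instrument distortion
        for crm_id, certified in config.crm_certified.items():
            measured = (certified - config.drift_intercept) / config.drift_slope
            measured += rng.normal(0.0, config.noise_sd_crm)
            crm_rows.append(
                {
                    "sequence_id": seq_id,
                    "crm_id": crm_id,
                    "certified_delta_mur": certified,
                    "measured_delta_mur": measured,
                }
            )
        for diet in config.diets:
            f_cell = config.f_true[(diet, tp)]
            for k in range(config.n_per_cell):
                sample_id = f"{config.tissue}-{diet}-{tp}-{k + 1:02d}"
                delta_fa_true = f_cell * d_sugar + (1.0 - f_cell) * d_fat[diet]
                delta_fa = delta_fa_true + rng.normal(0.0, config.biological_sd)
                delta_fame = fame_delta(
                    DeltaValue(delta_fa, scale=VPDB_SCALE), _PAM,
                    DEFAULT_METHYL_CORRECTION,
                ).value
                raw = (delta_fame - config.drift_intercept) / config.drift_slope
                raw += rng.normal(0.0, config.measurement_sd)
                raw_rows.append(
                    {
                        "sample_id": sample_id,
                        "sequence_id": seq_id,
                        "species": "16:0",
                        "raw_delta_mur": raw,
                    }
                )
                # composition: pre-weaning cells track milk carryover
                if tp in ("P0", "P10"):
                    lo, hi = config.milk_carryover[diet]
                    pam_pct = 0.5 * (lo + hi)
                else:
                    pam_pct = config.tissue_pam_percent[diet]
                rest = 100.0 - pam_pct
                shares = np.array([0.30, 0.28, 0.20, 0.15, 0.07]) * rest / 100.0
                pcts = {"16:0": pam_pct, **{
                    sp: 100.0 * sh for sp, sh in zip(_OTHER_SPECIES, shares)
                }}
                area_is = 1000.0
                peak_rows.append(
                    {"sample_id": sample_id, "species": "17:0", "area": area_is}
                )
                for sp, pct in pcts.items():
                    amount = config.total_fa_ug * pct / 100.0
                    area = amount / config.is_amount_ug * area_is
                    peak_rows.append(
                        {"sample_id": sample_id, "species": sp, "area": area}
                    )
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "diet": diet,
                        "timepoint": tp,
                        "sex": "M",
                        "tissue": config.tissue,
                        "sequence_id": seq_id,
                        "tissue_mass_g": config.tissue_mass_g,
                        "is_amount_ug": config.is_amount_ug,
                    }
                )
                truth_samples[sample_id] = {
                    "f_true": f_cell,
                    "delta_fa_true": delta_fa_true,
                    "delta_fa_with_bio_noise": delta_fa,
                    "pam_percent_true": pam_pct,
                }

    ground_truth = {
        "seed": config.seed,
        "sugar_delta": d_sugar,
        "fat_delta_by_diet": d_fat,
        "drift": {"slope": config.drift_slope, "intercept": config.drift_intercept},
        "f_true_by_cell": {f"{d}/{tp}": f for (d, tp), f in config.f_true.items()},
        "samples": truth_samples,
    }
    return SyntheticBundle(
        crm_table=pd.DataFrame(crm_rows),
        raw_delta_table=pd.DataFrame(raw_rows),
        peak_table=pd.DataFrame(peak_rows),
        sample_metadata=pd.DataFrame(meta_rows),
        ground_truth=ground_truth,
    )


def generate_null(config: GeneratorConfig = GeneratorConfig()) -> SyntheticBundle:
    """Generate with all diet and time effects zeroed (type-I harness).

    Every (diet, timepoint) cell shares the same true fraction — the
    mean of the configured profile — so any detected effect is noise.
    """
    f_bar = float(np.mean(list(config.f_true.values())))
    flat = {key: f_bar for key in config.f_true}
    return generate(replace(config, f_true=flat))
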