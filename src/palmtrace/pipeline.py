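"""End-to-end orchestration: calibrate, correct, quantify, mix, test.

The pipeline runs the stages in measurement order — per-sequence VPDB
normalization, methyl-carbon correction, internal-standard
quantification, end-member signature construction, two-end-member
apportionment, and diet x time statistics — either in memory
(:func:`analyze_tables`, used by tests and simulations) or from CSV
files on disk (:func:`run_pipeline`), which also writes each stage's
table plus a manifest of SHA-256 checksums so a rerun with the same
config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from palmtrace.calibration import (
    DEFAULT_R2_GATE,
    ReferenceMaterial,
    apply_normalization,
    calibrate_sequences,
    fit_normalization,
    read_crm_csv,
)
from palmtrace.derivatization import (
    DEFAULT_METHYL_CORRECTION,
    MethylCorrection,
    correct_fame_delta,
    species,
)
from palmtrace.isotope import RAW, DeltaValue, VPDB_SCALE
from palmtrace.mixing import mixing_fraction, substitute_fat_endmember
from palmtrace.quantification import quantify_table
from palmtrace.signatures import (
    AbsentEndMember,
    diet_fat_signature,
    read_diet_csv,
    reference_diets,
    sugar_signature,
)
from palmtrace.stats import ALPHA, one_way_gate, rout_screen, two_way_anova

__all__ = [
    "RunConfig",
    "PipelineError",
    "fit_sequence_models",
    "normalize_and_correct",
    "analyze_tables",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STAGES = ("calibrate", "correct", "quantify", "signatures", "mix", "stats")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending records."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    """Declarative run configuration (defaults match study constants)."""

    crm_csv: str = "crm.csv"
    raw_delta_csv: str = "raw_deltas.csv"
    peak_csv: str = "peaks.csv"
    sample_csv: str = "samples.csv"
    diet_csv: Optional[str] = None  # None: built-in reference diet table
    out_dir: str = "results"
    methyl_delta_mur: float = -41.56
    r2_gate: float = DEFAULT_R2_GATE
    alpha: float = ALPHA
    rout_q: float = 0.01
    weighting: str = "replicate"
    seed: int = 20240117
    target_species: str = "16:0"


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def fit_sequence_models(crm_table: pd.DataFrame, r2_gate: float = DEFAULT_R2_GATE):
    """Fit one VPDB normalization model per instrument sequence."""
    groups: dict[str, list[ReferenceMaterial]] = {}
    for i, r in enumerate(crm_table.itertuples(index=False)):
        groups.setdefault(str(r.sequence_id), []).append(
            ReferenceMaterial(
                id=str(r.crm_id),
                certified_delta=DeltaValue(float(r.certified_delta_mur),
                                           scale=VPDB_SCALE),
                measured_delta=DeltaValue(float(r.measured_delta_mur), scale=RAW),
                sequence_position=i,
            )
        )
    return calibrate_sequences(groups, r2_gate=r2_gate)


def normalize_and_correct(
    models,
    raw_delta_table: pd.DataFrame,
    corr: MethylCorrection = DEFAULT_METHYL_CORRECTION,
) -> pd.DataFrame:
    """Normalize raw deltas to VPDB and remove the methyl carbon."""
    rows = []
    for r in raw_delta_table.itertuples(index=False):
        seq = str(r.sequence_id)
        if seq not in models:
            raise PipelineError("correct", f"no calibration for sequence {seq!r}")
        norm = apply_normalization(
            models[seq], DeltaValue(float(r.raw_delta_mur), scale=RAW)
        )
        fa = correct_fame_delta(norm, species(str(r.species)), corr)
        rows.append(
            {"sample_id": r.sample_id, "species": r.species,
             "delta_vpdb_mur": norm.value, "delta_fa_mur": fa.value}
        )
    return pd.DataFrame(rows)


def analyze_tables(
    crm_table: pd.DataFrame,
    raw_delta_table: pd.DataFrame,
    peak_table: pd.DataFrame,
    sample_metadata: pd.DataFrame,
    diets=None,
    config: RunConfig = RunConfig(),
) -> "dict[str, object]":
    """Run the full analysis in memory; returns a dict of stage tables.

    Keys: ``calibration`` (per-sequence slope/intercept/R2),
    ``corrected`` (per-sample VPDB-normalized, methyl-corrected delta),
    ``composition`` (quantified amounts and relative %), ``signatures``
    (end-member deltas), ``mixing`` (per-sample sugar fraction with CI
    and flags), ``anova`` (diet x time effects on the corrected delta).
    """
    diets = diets if diets is not None else reference_diets()
    corr = MethylCorrection(DeltaValue(config.methyl_delta_mur, scale=VPDB_SCALE))
    target = species(config.target_species)

    # --- calibrate: one normalization per instrument sequence
    models = _stage("calibrate", fit_sequence_models, crm_table, config.r2_gate)
    calibration_df = pd.DataFrame(
        [
            {"sequence_id": s, "slope": m.slope, "intercept": m.intercept,
             "r_squared": m.r_squared, "n_points": m.n_points}
            for s, m in models.items()
        ]
    )

    # --- normalize + methyl-correct
    corrected = _stage("correct", normalize_and_correct, models, raw_delta_table, corr)

    # --- quantify
    composition = _stage(
        "quantify", quantify_table, peak_table, sample_metadata
    )

    # --- end-member signatures
    def _signatures():
        sugar = sugar_signature(next(iter(diets.values())), weighting=config.weighting)
        fat_sigs = {
            d: diet_fat_signature(comps, target, diet_id=d)
            for d, comps in diets.items()
        }
        real = [s for s in fat_sigs.values() if not isinstance(s, AbsentEndMember)]
        if not real:
            raise PipelineError("signatures", "no diet provides a fat end-member")
        sub = substitute_fat_endmember(real)
        return sugar, fat_sigs, sub

    sugar, fat_sigs, substitute = _stage("signatures", _signatures)
    signature_rows = [
        {"label": sugar.label, "delta_mur": sugar.delta.value,
         "sd_mur": sugar.delta.sd, "substituted": False}
    ]
    for d, s in fat_sigs.items():
        if isinstance(s, AbsentEndMember):
            signature_rows.append(
                {"label": f"{d}: {substitute.label}",
                 "delta_mur": substitute.delta.value,
                 "sd_mur": substitute.delta.sd, "substituted": True}
            )
        else:
            signature_rows.append(
                {"label": f"{d}: {s.label}", "delta_mur": s.delta.value,
                 "sd_mur": s.delta.sd, "substituted": False}
            )
    signatures_df = pd.DataFrame(signature_rows)

    # --- mixing apportionment per sample
    def _mix():
        meta = sample_metadata.set_index("sample_id")
        rows = []
        sub = corrected[corrected["species"] == config.target_species]
        for r in sub.itertuples(index=False):
            diet = str(meta.loc[r.sample_id, "diet"])
            fat = fat_sigs[diet]
            substituted = isinstance(fat, AbsentEndMember)
            if substituted:
                fat = substitute
            est = mixing_fraction(
                DeltaValue(float(r.delta_fa_mur), scale=VPDB_SCALE),
                sugar, fat, seed=config.seed, substituted=substituted,
            )
            rows.append(
                {"sample_id": r.sample_id, "diet": diet,
                 "timepoint": str(meta.loc[r.sample_id, "timepoint"]),
                 "fraction_sugar": est.fraction_sugar,
                 "ci_low": est.ci_low, "ci_high": est.ci_high,
                 "clamped": est.clamped,
                 "substituted_endmember": est.substituted_endmember}
            )
        return pd.DataFrame(rows)

    mixing_df = _stage("mix", _mix)

    # --- group statistics on the corrected tissue delta
    def _stats():
        meta = sample_metadata.set_index("sample_id")
        sub = corrected[corrected["species"] == config.target_species].copy()
        sub["diet"] = [str(meta.loc[s, "diet"]) for s in sub["sample_id"]]
        sub["timepoint"] = [str(meta.loc[s, "timepoint"]) for s in sub["sample_id"]]
        # ROUT screen within each diet x time cell before testing
        keep: list[str] = []
        for _, grp in sub.groupby(["diet", "timepoint"], sort=False):
            res = rout_screen(grp["delta_fa_mur"].to_numpy(), q=config.rout_q)
            mask = pd.Series(True, index=grp.index)
            mask.iloc[list(res.outlier_indices)] = False
            keep.extend(grp.index[mask].tolist())
        screened = sub.loc[keep]
        results = two_way_anova(
            screened, "delta_fa_mur", "diet", "timepoint", alpha=config.alpha
        )
        rows = []
        for res in results:
            rows.append(
                {"effect": res.effect, "F": res.f, "p": res.p,
                 "df_effect": res.df[0], "df_resid": res.df[1],
                 "n_posthoc": len(res.posthoc)}
            )
        posthoc_rows = [
            {"effect": res.effect, "pair": pair, "meandiff": diff, "p_adj": padj}
            for res in results
            for pair, diff, padj in res.posthoc
        ]
        return pd.DataFrame(rows), pd.DataFrame(posthoc_rows)

    anova_df, posthoc_df = _stage("stats", _stats)

    return {
        "calibration": calibration_df,
        "corrected": corrected,
        "composition": composition,
        "signatures": signatures_df,
        "mixing": mixing_df,
        "anova": anova_df,
        "posthoc": posthoc_df,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, input_dir=".") -> "dict[str, object]":
    """Run the pipeline from CSV inputs and write all stage outputs.

    On any stage failure, partially written outputs are removed and a
    :class:`PipelineError` names the failing stage.  The manifest
    (``manifest.json``) records the config and a SHA-256 checksum per
    output table.
    """
    in_dir = Path(input_dir)
    for name in (config.crm_csv, config.raw_delta_csv, config.peak_csv,
                 config.sample_csv):
        if not (in_dir / name).exists():
            raise PipelineError("config", f"missing input file {name!r}")

    crm = pd.read_csv(in_dir / config.crm_csv)
    raw = pd.read_csv(in_dir / config.raw_delta_csv)
    peaks = pd.read_csv(in_dir / config.peak_csv)
    samples = pd.read_csv(in_dir / config.sample_csv)
    diets = (
        read_diet_csv(in_dir / config.diet_csv) if config.diet_csv else None
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        results = analyze_tables(crm, raw, peaks, samples, diets=diets,
                                 config=config)
        manifest: dict[str, object] = {
            "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
            "stages": list(STAGES),
            "checksums": {},
        }
        for name, table in results.items():
            path = out_dir / f"{name}.csv"
            table.to_csv(path, index=False)
            written.append(path)
            manifest["checksums"][name] = _sha256(path)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return results
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
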