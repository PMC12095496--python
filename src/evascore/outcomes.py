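"""Inference of cellular editing outcomes from comparative screens.

Amplicon sequencing only sees surviving, amplifiable cells, so raw NGS
frequencies understate what the nuclease actually did. Three identities
relate the measurements:

    death-corrected NGS frequency = (100 − cell death) × NGS frequency / 100
    gRNA activity = cell death + (100 − cell death) × NGS frequency / 100
    LSR correction factor = (100 − maximum activity) / (100 − activity)

Screening each target with and without the NHEJ inhibitor M3814 makes two
otherwise invisible ("cryptic") outcomes measurable. The maximum activity
across all conditions is the closest estimate of true cleavage. When the
condition without M3814 falls short of it, NHEJ was quietly restoring the
wild-type sequence: the deficit is perfect repair. When the condition
with M3814 falls short, MMEJ was producing lesions too large to amplify:
the deficit is large-scale repair, and NGS frequencies from the affected
conditions are rescaled by the correction factor above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

TENDENCY_BAND = 5.0  # percentage points: |Δactivity| ≤ band -> "comparable"

MEASUREMENT_COLUMNS = [
    "target",
    "donor",
    "m3814",
    "replicate",
    "cell_death",
    "indels",
    "substitutions",
]


class MeasurementValidationError(ValueError):
    pass


def _check_range(name, value):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise MeasurementValidationError(f"{name} must lie in [0, 100]")
    return arr


def death_corrected_frequency(cell_death, ngs_frequency):
    """Fraction of the initial population carrying a sequenced outcome (%)."""
    d = _check_range("cell_death", cell_death)
    f = _check_range("ngs_frequency", ngs_frequency)
    out = (100.0 - d) * f / 100.0
    return float(out) if out.ndim == 0 else out


def grna_activity(cell_death, ngs_frequency):
    """In vivo gRNA activity (%): cell death plus death-corrected editing."""
    d = _check_range("cell_death", cell_death)
    f = _check_range("ngs_frequency", ngs_frequency)
    out = d + (100.0 - d) * f / 100.0
    return float(out) if out.ndim == 0 else out


def lsr_correction_factor(max_activity, activity):
    """Factor rescaling NGS frequencies when large-scale repair removes
    alleles from the amplifiable pool; NaN when activity is saturated."""
    a_max = float(max_activity)
    a = float(activity)
    if a_max < a:
        raise ValueError("max_activity must be ≥ activity")
    if a >= 100.0:
        return float("nan")
    return (100.0 - a_max) / (100.0 - a)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Schema/range checks for a tidy screen table; returns a clean copy."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementValidationError(f"measurement table lacks columns: {missing}")
    out = df.copy()
    out["donor"] = out["donor"].astype(bool)
    out["m3814"] = out["m3814"].astype(bool)
    for col in ("cell_death", "indels", "substitutions"):
        _check_range(col, out[col])
    if np.any(out["indels"] + out["substitutions"] > 100.0 + 1e-9):
        raise MeasurementValidationError("indels + substitutions exceed 100%")
    stray = out.loc[~out["donor"] & (out["substitutions"] > 0)]
    if len(stray):
        warnings.warn(
            f"{len(stray)} measurements report substitutions without a donor "
            "(no HDR template present)",
            stacklevel=2,
        )
    return out


@dataclass
class OutcomeSummary:
    """Per-target derived metrics from the comparative screen."""

    target: str
    editing: dict  # (donor, m3814) -> editing % (indels + substitutions)
    activity: dict  # (donor, m3814) -> gRNA activity %
    max_activity: float
    perfect_repair: float
    large_scale_repair: float
    repair_class: str  # perfect_tendency | large_scale_tendency | comparable
    corrected_frequency: dict = field(default_factory=dict)
    available: bool = True
    note: Optional[str] = None

    def to_row(self) -> dict:
        row = {
            "target": self.target,
            "max_activity": self.max_activity,
            "perfect_repair": self.perfect_repair,
            "large_scale_repair": self.large_scale_repair,
            "repair_class": self.repair_class,
            "available": self.available,
        }
        for (donor, m), v in self.activity.items():
            row[f"activity_donor{int(donor)}_m{int(m)}"] = v
        for (donor, m), v in self.editing.items():
            row[f"editing_donor{int(donor)}_m{int(m)}"] = v
        return row


def infer_cryptic_repair(
    condition_means: pd.DataFrame,
    tendency_band: float = TENDENCY_BAND,
) -> OutcomeSummary:
    """Infer perfect / large-scale repair for one target.

    ``condition_means`` holds one row per condition (replicate means) with
    columns ``donor``, ``m3814``, ``cell_death``, ``indels``,
    ``substitutions``. The ±M3814 comparison uses the donor-present pair
    when present, else the donor-absent pair.
    """
    df = condition_means.copy()
    target = str(df["target"].iloc[0]) if "target" in df.columns else "?"
    df["editing"] = df["indels"] + df["substitutions"]
    df["activity"] = grna_activity(df["cell_death"], df["editing"])

    editing = {(r.donor, r.m3814): float(r.editing) for r in df.itertuples()}
    activity = {(r.donor, r.m3814): float(r.activity) for r in df.itertuples()}
    max_activity = float(max(activity.values()))

    # choose the ±M3814 comparison pair
    pair = None
    for donor_flag in (True, False):
        if (donor_flag, False) in activity and (donor_flag, True) in activity:
            pair = donor_flag
            break
    if pair is None:
        return OutcomeSummary(
            target=target,
            editing=editing,
            activity=activity,
            max_activity=max_activity,
            perfect_repair=0.0,
            large_scale_repair=0.0,
            repair_class="comparable",
            available=False,
            note="missing +M3814 or -M3814 condition; cryptic repair not inferred",
        )

    act_minus = activity[(pair, False)]
    act_plus = activity[(pair, True)]
    diff = act_plus - act_minus

    perfect = large = 0.0
    corrected: dict = {}
    if abs(diff) <= tendency_band:
        repair_class = "comparable"
    elif diff > 0:
        repair_class = "perfect_tendency"
        perfect = max_activity - act_minus
    else:
        repair_class = "large_scale_tendency"
        large = max_activity - act_plus
        # +M3814 NGS frequencies understate editing among the initial
        # population once large-scale alleles drop out of the amplicon pool
        for r in df.itertuples():
            if r.m3814:
                factor = lsr_correction_factor(max_activity, float(r.activity))
                corrected[(r.donor, r.m3814)] = {
                    "factor": factor,
                    "indels": death_corrected_frequency(r.cell_death, r.indels) * factor,
                    "substitutions": death_corrected_frequency(
                        r.cell_death, r.substitutions
                    )
                    * factor,
                }
    if perfect < 0 or large < 0:  # cannot occur: max ≥ every activity
        warnings.warn(
            f"negative inferred repair for target {target}; data inconsistent",
            stacklevel=2,
        )
        perfect, large = max(perfect, 0.0), max(large, 0.0)
    return OutcomeSummary(
        target=target,
        editing=editing,
        activity=activity,
        max_activity=max_activity,
        perfect_repair=perfect,
        large_scale_repair=large,
        repair_class=repair_class,
        corrected_frequency=corrected,
    )


def replicate_correlations(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (two-tailed p) between replicate pairs for each metric."""
    df = measurements.copy()
    df["editing"] = df["indels"] + df["substitutions"]
    df["activity"] = grna_activity(df["cell_death"], df["editing"])
    metrics = ["cell_death", "indels", "substitutions", "editing", "activity"]
    reps = sorted(df["replicate"].unique())
    rows = []
    wide = df.pivot_table(
        index=["target", "donor", "m3814"], columns="replicate", values=metrics
    )
    for metric in metrics:
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1 :]:
                x = wide[(metric, r1)].to_numpy(dtype=float)
                y = wide[(metric, r2)].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                    r = p = float("nan")
                else:
                    r, p = stats.pearsonr(x[ok], y[ok])
                rows.append(
                    {"metric": metric, "rep_a": r1, "rep_b": r2, "r": r, "p": p}
                )
    return pd.DataFrame(rows)


def summarize_screen(
    measurements: pd.DataFrame,
    tendency_band: float = TENDENCY_BAND,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-mean outcomes and cryptic-repair inference per target.

    Returns ``(summary, replicate_stats)``: one OutcomeSummary row per
    target, and replicate-pair Pearson correlations per metric (empty with
    a warning when only one replicate exists).
    """
    df = validate_measurements(measurements)
    means = (
        df.groupby(["target", "donor", "m3814"], as_index=False)[
            ["cell_death", "indels", "substitutions"]
        ].mean()
    )
    summaries = [
        infer_cryptic_repair(grp, tendency_band=tendency_band)
        for _, grp in means.groupby("target", sort=True)
    ]
    summary = pd.DataFrame([s.to_row() for s in summaries])
    if df["replicate"].nunique() < 2:
        warnings.warn("single replicate: correlations omitted", stacklevel=2)
        rep_stats = pd.DataFrame(columns=["metric", "rep_a", "rep_b", "r", "p"])
    else:
        rep_stats = replicate_correlations(df)
    return summary, rep_stats


def activity_distribution(summary: pd.DataFrame, column: str = "max_activity") -> dict:
    """Mean/range/quartiles and the fraction of targets above 40%."""
    x = summary[column].to_numpy(dtype=float)
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "fraction_above_40": float(np.mean(x >= 40.0)),
    }
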