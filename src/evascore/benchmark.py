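"""Benchmarking the activity score against measured datasets, and
variant-targetability classification.

The quartile benchmark asks a deliberately one-sided question: among the
guides the score calls inefficient (score < 50), what fraction were indeed
in the worst quartile (Q1) or worst half (Q2) of the measured efficiencies?
A score that merely shuffles guides lands near 0.25 / 0.5 on those
fractions; a useful inefficiency flag should sit far above.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .activity import EFFICIENCY_THRESHOLD

logger = logging.getLogger(__name__)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-tailed p value.

    Returns (nan, nan) for degenerate input (zero variance), which keeps
    "no correlation computable" distinct from "correlation zero".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def quartile_benchmark(
    records: pd.DataFrame,
    measured: str = "measured",
    score: str = "eva_score",
    threshold: float = EFFICIENCY_THRESHOLD,
    dataset: Optional[str] = "dataset",
) -> pd.DataFrame:
    """Fraction of predicted-inefficient guides below Q1 / Q2 of measured
    efficiency, per dataset.

    Quartiles are linear-interpolation quantiles of the full dataset.
    Datasets without any predicted-inefficient guide report NaN fractions
    with ``n_inefficient = 0`` (explicit zero-denominator marker).
    """
    if len(records) < 8:
        raise ValueError("need at least 8 records for a quartile benchmark")
    if dataset is not None and dataset in records.columns:
        groups = records.groupby(dataset, sort=True)
    else:
        groups = [("all", records)]
    rows = []
    for name, grp in groups:
        m = grp[measured].to_numpy(dtype=float)
        q1, q2 = np.percentile(m, [25, 50])
        flagged = grp.loc[grp[score].astype(float) < threshold]
        n_bad = len(flagged)
        if n_bad == 0:
            below_q1 = below_q2 = float("nan")
        else:
            below_q1 = float(np.mean(flagged[measured].to_numpy(dtype=float) < q1))
            below_q2 = float(np.mean(flagged[measured].to_numpy(dtype=float) < q2))
        rows.append(
            {
                "dataset": name,
                "n": len(grp),
                "n_inefficient": n_bad,
                "q1": float(q1),
                "q2": float(q2),
                "fraction_below_q1": below_q1,
                "fraction_below_q2": below_q2,
            }
        )
    return pd.DataFrame(rows)


TARGETABLE = "targetable"
NO_CUT_SITE = "no_PAM_cut_site"
NO_EFFICIENT_GUIDE = "no_efficient_guide"


def targetability_filter(
    variants: pd.DataFrame,
    guides: pd.DataFrame,
    window: int = 10,
    score_threshold: float = EFFICIENCY_THRESHOLD,
    score: str = "eva_score",
) -> pd.DataFrame:
    """Classify variants by the availability of a nearby efficient guide.

    ``variants`` needs columns ``chrom`` and ``pos`` (0-based); ``guides``
    needs ``chrom``, ``cut`` (0-based cut position) and a score column. A
    variant is *targetable* when at least one guide cuts within ``window``
    bases (|cut − pos| ≤ window, inclusive) with score ≥ threshold;
    *no_PAM_cut_site* when no guide cuts within the window at all; and
    *no_efficient_guide* otherwise. Malformed rows are rejected per row
    with a log line, not fatally.
    """
    rows = []
    by_chrom = {c: g for c, g in guides.groupby("chrom")}
    for idx, v in variants.iterrows():
        try:
            chrom, pos = v["chrom"], int(v["pos"])
            if pos < 0:
                raise ValueError("negative coordinate")
        except (KeyError, TypeError, ValueError) as exc:
            logger.warning("rejecting malformed variant row %s: %s", idx, exc)
            rows.append({**dict(v), "classification": "rejected"})
            continue
        near = pd.DataFrame()
        if chrom in by_chrom:
            g = by_chrom[chrom]
            near = g.loc[(g["cut"].astype(int) - pos).abs() <= window]
        if len(near) == 0:
            cls = NO_CUT_SITE
        elif (near[score].astype(float) >= score_threshold).any():
            cls = TARGETABLE
        else:
            cls = NO_EFFICIENT_GUIDE
        rows.append({**dict(v), "classification": cls})
    return pd.DataFrame(rows)
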