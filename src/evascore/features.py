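"""Assembly of the five-feature table used by the activity score.

Feature columns (TSV schema, usable as output and as precomputed input):
id, spacer, pam, delta_g (kcal/mol, ≤ 0), n_ga, g17, c20, mit_score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from . import folding
from .guides import GuideRecord, count_ga, position_flags, validate_spacer
from .offtarget import guide_mit_score

FEATURE_COLUMNS = ["id", "spacer", "pam", "delta_g", "n_ga", "g17", "c20", "mit_score"]


@dataclass
class GuideFeatures:
    """The five sequence features feeding the activity score."""

    delta_g_spacer: float  # unimolecular MFE of the spacer RNA, kcal/mol, ≤ 0
    n_ga: int  # GA dinucleotide count, 0..19
    g17: bool  # G immediately 5' of the cut site
    c20: bool  # C immediately before the PAM
    mit_score: float  # aggregate off-target specificity, 0..100

    def __post_init__(self) -> None:
        if self.delta_g_spacer > 0:
            raise ValueError("delta_g_spacer must be ≤ 0 (positive MFE clamps to 0)")
        if not 0 <= self.n_ga <= 19:
            raise ValueError("n_ga must lie in [0, 19]")
        if not 0.0 <= self.mit_score <= 100.0:
            raise ValueError("mit_score must lie in [0, 100]")


def compute_features(
    spacer: str,
    mit_score: Optional[float] = None,
    delta_g: Optional[float] = None,
) -> GuideFeatures:
    """Features for one spacer; folding and MIT values may be precomputed.

    With no genome at hand the MIT aggregate defaults to 100 (no predicted
    off-targets), the correct value for a guide without enumerable sites.
    """
    s = validate_spacer(spacer)
    g17, c20 = position_flags(s)
    return GuideFeatures(
        delta_g_spacer=folding.spacer_free_energy(s) if delta_g is None else min(delta_g, 0.0),
        n_ga=count_ga(s),
        g17=g17,
        c20=c20,
        mit_score=100.0 if mit_score is None else float(mit_score),
    )


def feature_table(
    guides: Iterable[GuideRecord],
    genome=None,
    precomputed: Optional[pd.DataFrame] = None,
    max_mismatches: int = 4,
) -> pd.DataFrame:
    """Five-feature table for a batch of guides.

    MIT scores are enumerated against ``genome`` when given; ``precomputed``
    (indexed by guide id or bearing an ``id`` column) overrides ``delta_g``
    and/or ``mit_score`` per guide, which allows externally computed values
    (e.g. genome-browser CRISPR-track scores) to be injected.
    """
    pre = None
    if precomputed is not None:
        pre = precomputed.set_index("id") if "id" in precomputed.columns else precomputed
    rows = []
    for g in guides:
        mit = delta_g = None
        if pre is not None and g.id in pre.index:
            row = pre.loc[g.id]
            if "mit_score" in pre.columns and pd.notna(row["mit_score"]):
                mit = float(row["mit_score"])
            if "delta_g" in pre.columns and pd.notna(row["delta_g"]):
                delta_g = float(row["delta_g"])
        if mit is None and genome is not None:
            mit = guide_mit_score(g, genome, max_mismatches=max_mismatches)
        f = compute_features(g.spacer, mit_score=mit, delta_g=delta_g)
        rows.append(
            {
                "id": g.id,
                "spacer": g.spacer,
                "pam": g.pam,
                "delta_g": f.delta_g_spacer,
                "n_ga": f.n_ga,
                "g17": f.g17,
                "c20": f.c20,
                "mit_score": f.mit_score,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
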