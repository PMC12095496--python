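"""Readers and writers: spacer FASTA, feature/screen/donor TSV, BED9 track.

All tables are plain TSV with a header line. Genomic intervals are
0-based half-open throughout, matching BED. The score track writes BED9:
the BED score column maps the 0-100 activity score linearly onto 0-1000,
and itemRgb encodes the efficiency call (green efficient, orange
inefficient).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .activity import EFFICIENCY_THRESHOLD, classify_efficiency
from .guides import GuideRecord
from .hdr import DonorRecord, format_edits, parse_edits

logger = logging.getLogger(__name__)

GREEN = "0,160,60"
ORANGE = "230,120,0"


def read_spacer_fasta(path) -> list[GuideRecord]:
    """Read spacers from FASTA; record ids come from the headers."""
    from Bio import SeqIO

    return [GuideRecord(id=rec.id, spacer=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_donor_table(path) -> list[DonorRecord]:
    """Donor TSV: id, sequence, orientation, edits ("pos:ref>alt;...")."""
    df = read_table(path)
    donors = []
    for row in df.itertuples():
        donors.append(
            DonorRecord(
                id=str(row.id),
                sequence=row.sequence,
                orientation=getattr(row, "orientation", "spacer_strand"),
                edits=parse_edits(getattr(row, "edits", "")),
            )
        )
    return donors


def write_donor_table(donors: Iterable[DonorRecord], path) -> None:
    rows = [
        {
            "id": d.id,
            "sequence": d.sequence,
            "orientation": d.orientation,
            "edits": format_edits(d.edits),
        }
        for d in donors
    ]
    write_table(pd.DataFrame(rows), path)


def write_score_track(
    guides: Iterable[GuideRecord],
    scores,
    path,
    threshold: float = EFFICIENCY_THRESHOLD,
) -> int:
    """Write a BED9 score track; returns the number of rows skipped for
    missing coordinates. Name field is "id|score" (rounded score)."""
    guides = list(guides)
    scores = np.asarray(scores, dtype=float)
    if len(guides) != len(scores):
        raise ValueError("guides and scores differ in length")
    skipped = 0
    lines = []
    for g, s in zip(guides, scores):
        if g.chrom is None or g.start is None:
            skipped += 1
            continue
        bed_score = int(round(np.clip(s, 0, 100) * 10))
        color = GREEN if s >= threshold else ORANGE
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    str(g.start),
                    str(g.end),
                    f"{g.id}|{int(round(s))}",
                    str(bed_score),
                    g.strand or "+",
                    str(g.start),
                    str(g.end),
                    color,
                ]
            )
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    if skipped:
        logger.warning("score track: skipped %d guides without coordinates", skipped)
    return skipped


BED9_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "thick_start",
    "thick_end",
    "item_rgb",
]


def read_score_track(path) -> pd.DataFrame:
    """Re-parse a written BED9 track into a DataFrame (round-trip check)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED9_COLUMNS)
    parts = df["name"].str.rsplit("|", n=1)
    df["id"] = parts.str[0]
    df["eva_score"] = parts.str[1].astype(float)
    df["classification"] = classify_efficiency(df["eva_score"])
    return df
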