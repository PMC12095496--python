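"""HDR efficiency prediction for single-stranded DNA donors.

Predicted HDR (%) is a linear term in the guide's EVA activity score, the
donor's single-stranded folding free energy, and a nucleotide-change
penalty, multiplied by a distance-decay factor and capped by the EVA score
(a repair outcome cannot outrun the cleavage that enables it):

    HDR = min(EVA, decay(d) × (b0 + b_eva·EVA + b_dg·ΔG_donor + b_sub·penalty))

The decay is 1 at the cut and halves every 5 nt by default, matching the
observation that an edit five nucleotides from the cut halves efficiency.
Substitution penalties encode that C→T is the easiest change, changes into
purines are disfavored, and T/G are roughly twice as hard to edit away as
A/C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .activity import _check_rank
from .folding import donor_free_energy
from .guides import normalize_sequence

_BASES = "ACGT"

# relative ease of removing the reference base / writing in the new base;
# product normalised so the easiest change (C→T) carries zero penalty
_REF_EASE = {"A": 1.0, "C": 1.0, "T": 0.5, "G": 0.5}
_ALT_EASE = {"C": 1.0, "T": 1.0, "A": 0.7, "G": 0.7}
PENALTY_SCALE = 20.0  # percentage points at zero relative efficiency

HDR_COEF_NAMES = ["eva_score", "donor_dg", "sub_penalty"]


def default_substitution_table() -> dict[tuple[str, str], float]:
    """Penalty (percentage points) for each of the 12 ordered base changes."""
    table = {}
    for ref in _BASES:
        for alt in _BASES:
            if ref == alt:
                continue
            eff = _REF_EASE[ref] * _ALT_EASE[alt]
            table[(ref, alt)] = (1.0 - eff) * PENALTY_SCALE
    return table


@dataclass(frozen=True)
class Edit:
    """One intended substitution: signed offset from the cut (0 = the base
    immediately 3' of the cut on the spacer strand), ref and alt bases."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        ref, alt = self.ref.upper(), self.alt.upper()
        if ref not in _BASES or alt not in _BASES:
            raise ValueError(f"edit bases must be A/C/G/T, got {self.ref}>{self.alt}")
        if ref == alt:
            raise ValueError(f"edit ref equals alt ({ref}); not a substitution")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)


def parse_edits(text: str) -> list[Edit]:
    """Parse the TSV edit syntax ``pos:ref>alt;pos:ref>alt;...``."""
    edits = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        pos_part, change = token.split(":")
        ref, alt = change.split(">")
        edits.append(Edit(int(pos_part), ref, alt))
    return edits


def format_edits(edits: Sequence[Edit]) -> str:
    return ";".join(f"{e.position}:{e.ref}>{e.alt}" for e in edits)


@dataclass
class DonorRecord:
    """A single-stranded DNA donor with its intended edits.

    ``orientation`` states whether the donor matches the gRNA spacer strand
    or its reverse complement; folding always uses the sequence as written,
    since that is the single-stranded species delivered to the cell.
    """

    id: str
    sequence: str
    orientation: str = "spacer_strand"  # or "reverse_complement"
    arm_lengths: tuple[int, int] = (45, 45)
    edits: list[Edit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if self.orientation not in ("spacer_strand", "reverse_complement"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if sum(self.arm_lengths) > len(self.sequence):
            raise ValueError("homology arms longer than the donor sequence")

    def free_energy(self) -> float:
        return donor_free_energy(self.sequence)

    def max_edit_distance(self) -> int:
        if not self.edits:
            raise ValueError(f"donor {self.id!r} carries no edits")
        return max(abs(e.position) for e in self.edits)


@dataclass
class HdrModel:
    """Parameters of the HDR predictor (linear part + penalty table + decay)."""

    params: dict  # intercept + HDR_COEF_NAMES
    substitution_table: dict = field(default_factory=default_substitution_table)
    decay_half_distance: float = 5.0
    nobs: Optional[int] = None
    train_pearson_r: Optional[float] = None
    bse: Optional[dict] = None

    def substitution_penalty(self, ref: str, alt: str) -> float:
        ref, alt = ref.upper(), alt.upper()
        if ref == alt:
            raise ValueError(f"ref equals alt ({ref}); not a substitution")
        if (ref, alt) not in self.substitution_table:
            raise ValueError(f"no penalty defined for {ref}>{alt}")
        return float(self.substitution_table[(ref, alt)])

    def distance_decay(self, distance) -> np.ndarray:
        """Monotone non-increasing decay factor in (0, 1]; decay(0) = 1,
        decay(half_distance) = 1/2. Signed distances are folded by |.|."""
        d = np.abs(np.asarray(distance, dtype=float))
        out = np.power(2.0, -d / self.decay_half_distance)
        return out if out.ndim else float(out)

    def _linear(self, eva_score, donor_dg, sub_penalty) -> np.ndarray:
        beta = np.array(
            [self.params["intercept"]] + [self.params[n] for n in HDR_COEF_NAMES]
        )
        X = np.column_stack(
            [
                np.ones_like(np.asarray(eva_score, dtype=float)),
                np.asarray(eva_score, dtype=float),
                np.asarray(donor_dg, dtype=float),
                np.asarray(sub_penalty, dtype=float),
            ]
        )
        return X @ beta

    def predict(self, eva_score, donor_dg, edits: Sequence[Edit]) -> float:
        """Predicted HDR % for one donor; uses the farthest edit's decay and
        the worst (largest) substitution penalty among the edits."""
        if not edits:
            raise ValueError("edit list is empty")
        penalty = max(self.substitution_penalty(e.ref, e.alt) for e in edits)
        distance = max(abs(e.position) for e in edits)
        base = float(self._linear([eva_score], [donor_dg], [penalty])[0])
        value = base * float(self.distance_decay(distance))
        return float(np.clip(value, 0.0, min(float(eva_score), 100.0)))

    def summary(self) -> str:
        lines = [
            "HDR efficiency model — linear in (EVA score, donor ΔG, substitution penalty)",
            f"distance decay: 2^(-d/{self.decay_half_distance:g}), d in nt from the cut",
            "",
            f"{'term':<14}{'coef':>12}{'std err':>12}",
        ]
        bse = self.bse or {}
        rows = [("intercept", self.params["intercept"], bse.get("const"))]
        rows += [(n, self.params[n], bse.get(n)) for n in HDR_COEF_NAMES]
        for name, coef, se in rows:
            se_s = f"{se:>12.4f}" if se is not None else f"{'—':>12}"
            lines.append(f"{name:<14}{coef:>12.4f}{se_s}")
        if self.nobs is not None:
            lines.append("")
            lines.append(f"n = {self.nobs}, training Pearson r = {self.train_pearson_r:.3f}")
        return "\n".join(lines)


class HdrEfficiencyModel:
    """statsmodels-style wrapper: data in, ``fit()`` out.

    ``data`` needs columns ``eva_score``, ``donor_dg``, ``sub_penalty`` and
    the response column (default ``hdr``, measured HDR % at the cut, i.e.
    before distance decay, which is a fixed multiplier, not a fitted term).
    """

    def __init__(self, data: pd.DataFrame, response: str = "hdr", **model_kwargs):
        if len(data) < 10:
            raise ValueError("at least 10 records are required to fit")
        self.data = data.reset_index(drop=True)
        self.response = response
        self.model_kwargs = model_kwargs

    def fit(self) -> HdrModel:
        X = sm.add_constant(
            self.data[HDR_COEF_NAMES].astype(float), has_constant="add"
        )
        _check_rank(X)
        y = self.data[self.response].astype(float)
        res = sm.OLS(y, X).fit()
        fitted = np.asarray(res.fittedvalues)
        r = (
            float(np.corrcoef(fitted, y)[0, 1])
            if np.std(fitted) > 0 and np.std(y) > 0
            else float("nan")
        )
        params = {"intercept": float(res.params["const"])}
        params.update({n: float(res.params[n]) for n in HDR_COEF_NAMES})
        return HdrModel(
            params=params,
            nobs=len(y),
            train_pearson_r=r,
            bse={k: float(v) for k, v in res.bse.items()},
            **self.model_kwargs,
        )


def fit_hdr(data: pd.DataFrame, response: str = "hdr", **kwargs) -> HdrModel:
    return HdrEfficiencyModel(data, response=response, **kwargs).fit()


def hdr_share(substitutions, indels) -> float:
    """HDR-dependent intended edits as a fraction of all editing events.

    Returns NaN (undefined) when nothing was edited at all, rather than
    conflating "no editing" with "no HDR".
    """
    s = float(substitutions)
    i = float(indels)
    if s < 0 or i < 0:
        raise ValueError("percentages must be non-negative")
    if s + i == 0:
        return float("nan")
    return s / (s + i)
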