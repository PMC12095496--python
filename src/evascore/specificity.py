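"""MIT (Hsu) off-target specificity scoring.

The per-site score penalizes an off-target site by its mismatch positions:

    score = 100 × Π_p (1 − W[p]) × 1/(((19 − d̄)/19) × 4 + 1) × 1/n²

with W the 20-entry experimental weight vector (PAM-distal = position 1),
d̄ the mean pairwise distance between mismatch positions and n the mismatch
count. A perfect match scores 100. The aggregate (guide-level) score is

    100 × 100 / (100 + Σ site scores)

over all off-target sites (on-target excluded): 100 means no predicted
off-targets, lower means more promiscuous binding.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from itertools import combinations
from typing import Iterable, Sequence


@lru_cache(maxsize=None)
def load_mit_weights(name: str = "mit_weights") -> tuple[float, ...]:
    """Load the 20-entry per-position weight vector from packaged config."""
    text = resources.files("evascore.data").joinpath(f"{name}.json").read_text()
    weights = tuple(float(w) for w in json.loads(text)["weights"])
    if len(weights) != 20:
        raise ValueError(f"weight vector must have 20 entries, got {len(weights)}")
    return weights


def mit_site_score(
    mismatch_positions: Sequence[int], weights: Sequence[float] | None = None
) -> float:
    """Score one off-target site (0-100) from its 1-based mismatch positions."""
    if weights is None:
        weights = load_mit_weights()
    positions = sorted(set(int(p) for p in mismatch_positions))
    if positions and not (1 <= positions[0] and positions[-1] <= 20):
        raise ValueError(f"mismatch positions must lie in 1..20, got {positions}")
    if len(positions) != len(mismatch_positions):
        raise ValueError("mismatch positions must be unique")
    n = len(positions)
    if n == 0:
        return 100.0
    score = 1.0
    for p in positions:
        score *= 1.0 - weights[p - 1]
    if n > 1:
        pairs = list(combinations(positions, 2))
        mean_dist = sum(b - a for a, b in pairs) / len(pairs)
        score *= 1.0 / (((19.0 - mean_dist) / 19.0) * 4.0 + 1.0)
        score *= 1.0 / (n * n)
    return 100.0 * score


def mit_aggregate_score(site_scores: Iterable[float]) -> float:
    """Guide-level specificity (0-100] from off-target site scores."""
    total = 0.0
    for s in site_scores:
        if s < 0:
            raise ValueError("site scores must be non-negative")
        total += float(s)
    return 100.0 * 100.0 / (100.0 + total)
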