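"""Synthetic data generation emulating the comparative screen design.

The generator mirrors the screen layout — 78 targets, 3 biological
replicates, 4 conditions (±DNA donor × ±M3814) — and works in "activity
space": each target carries a true maximum gRNA activity, a cell-death
fraction, exactly one cryptic tendency (perfect repair, large-scale
repair, or neither), and an HDR share with donor. Measured NGS
frequencies are derived by inverting the activity equation for each
condition, so at zero measurement noise the outcome inference recovers
the planted partition exactly:

- without M3814, perfect repair is invisible: measured activity drops by
  the planted perfect-repair amount;
- with M3814, large-scale repair removes alleles from the amplicon pool:
  measured activity drops by the planted large-scale amount.

Gaussian measurement noise (s.d. in percentage points) is added per
replicate and truncated to the valid range. Nonzero cryptic fractions are
drawn above the ±5-point tendency band, since a smaller deviation is by
definition indistinguishable from "comparable". All randomness flows
through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import COEF_NAMES, clip_features
from .hdr import default_substitution_table

# class mix observed in the comparative screen
DEFAULT_CLASS_PROBS = {
    "perfect_tendency": 0.19,
    "large_scale_tendency": 0.49,
    "comparable": 0.32,
}

# planted coefficient vector for feature->activity simulations; respects the
# documented sign conventions and keeps noiseless responses inside [0, 100]
# over the feature ranges drawn below
PLANTED_EVA_PARAMS = {
    "intercept": 55.0,
    "delta_g": 3.0,
    "n_ga": 2.5,
    "mit_score": 0.5,
    "g17": -6.0,
    "c20": -6.0,
}

PLANTED_HDR_PARAMS = {
    "intercept": 5.0,
    "eva_score": 0.7,
    "donor_dg": 0.8,
    "sub_penalty": -0.8,
}


@dataclass
class SyntheticScreenSpec:
    """Layout and generative parameters of a synthetic comparative screen."""

    n_targets: int = 78
    replicates: int = 3
    noise_sd: float = 3.0  # percentage points on each measured quantity
    seed: int = 0
    tendency_band: float = 5.0
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    activity_range: tuple[float, float] = (33.0, 93.0)
    death_fraction_range: tuple[float, float] = (0.10, 0.50)
    cryptic_range: tuple[float, float] = (8.0, 30.0)
    hdr_share_range: tuple[float, float] = (0.20, 0.60)

    def validate(self) -> None:
        if self.n_targets < 1 or self.replicates < 1:
            raise ValueError("n_targets and replicates must be positive")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if self.cryptic_range[0] <= self.tendency_band:
            raise ValueError(
                "cryptic fractions must exceed the tendency band to be inferable"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _truth_table(spec: SyntheticScreenSpec, rng: np.random.Generator) -> pd.DataFrame:
    classes = rng.choice(
        list(spec.class_probs), size=spec.n_targets, p=list(spec.class_probs.values())
    )
    lo_a, hi_a = spec.activity_range
    activity = rng.uniform(lo_a, hi_a, spec.n_targets)
    death = activity * rng.uniform(*spec.death_fraction_range, spec.n_targets)
    death = np.minimum(death, 50.0)
    rows = []
    for i in range(spec.n_targets):
        a, d, cls = activity[i], death[i], classes[i]
        # the invisible fraction must leave measured activity ≥ cell death
        hi = min(spec.cryptic_range[1], a - d - 5.0)
        lo = spec.cryptic_range[0]
        amount = rng.uniform(lo, max(hi, lo + 1e-6)) if cls != "comparable" else 0.0
        rows.append(
            {
                "target": f"T{i + 1:03d}",
                "repair_class": cls,
                "max_activity": a,
                "cell_death": d,
                "perfect_repair": amount if cls == "perfect_tendency" else 0.0,
                "large_scale_repair": amount if cls == "large_scale_tendency" else 0.0,
                "hdr_share_donor": rng.uniform(*spec.hdr_share_range),
            }
        )
    return pd.DataFrame(rows)


def generate_synthetic_screen(
    spec: SyntheticScreenSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a tidy measurement table plus its ground-truth partition.

    Returns ``(measurements, truth)``; measurements follow the screen TSV
    schema (target, donor, m3814, replicate, cell_death, indels,
    substitutions).
    """
    spec = spec or SyntheticScreenSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = _truth_table(spec, rng)
    records = []
    for t in truth.itertuples():
        for donor in (False, True):
            for m3814 in (False, True):
                act = t.max_activity
                if not m3814:
                    act -= t.perfect_repair  # NHEJ restores wild type unseen
                else:
                    act -= t.large_scale_repair  # alleles lost to MMEJ lesions
                editing_ngs = (act - t.cell_death) / (100.0 - t.cell_death) * 100.0
                share = t.hdr_share_donor if donor else 0.0
                if donor and m3814:
                    # NHEJ inhibition diverts repair toward HDR
                    share = min(share * 1.5, 0.9)
                subs = editing_ngs * share
                indels = editing_ngs - subs
                for rep in range(1, spec.replicates + 1):
                    noise = rng.normal(0.0, spec.noise_sd, 3) if spec.noise_sd else (0.0,) * 3
                    cd = float(np.clip(t.cell_death + noise[0], 0.0, 100.0))
                    ind = float(np.clip(indels + noise[1], 0.0, 100.0))
                    # without a donor template the substitution channel
                    # reads zero (unexpected substitutions are discarded as
                    # sequencing error in amplicon analysis)
                    sub = (
                        float(np.clip(subs + noise[2], 0.0, 100.0 - ind))
                        if donor
                        else 0.0
                    )
                    records.append(
                        {
                            "target": t.target,
                            "donor": donor,
                            "m3814": m3814,
                            "replicate": rep,
                            "cell_death": cd,
                            "indels": ind,
                            "substitutions": sub,
                        }
                    )
    return pd.DataFrame(records), truth


# ---------------------------------------------------------------------------
# feature-space simulators for the linear models


def generate_guide_feature_table(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic five-feature table with realistic marginal distributions:
    most spacers fold weakly (ΔG clipped at −3), GA counts are small, and
    specificity is skewed toward unique-ish guides."""
    weak = rng.random(n) < 0.5
    delta_g = np.where(weak, 0.0, rng.uniform(-14.0, -3.0, n))
    return pd.DataFrame(
        {
            "id": [f"g{i + 1:04d}" for i in range(n)],
            "delta_g": delta_g,
            "n_ga": np.minimum(rng.binomial(19, 0.10, n), 6),
            "mit_score": rng.uniform(0.0, 100.0, n),
            "g17": rng.random(n) < 0.3,
            "c20": rng.random(n) < 0.3,
        }
    )


def activity_from_features(
    features: pd.DataFrame,
    params: dict | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    clip_dg: float = -3.0,
    clip_mit: float = 75.0,
) -> np.ndarray:
    """Planted-model response: linear score on clipped features plus noise,
    truncated to [0, 100] (the planted coefficients keep the noiseless
    response strictly inside the range, so truncation only acts on noise)."""
    params = params or PLANTED_EVA_PARAMS
    clipped = clip_features(features, clip_dg, clip_mit)
    y = np.full(len(features), params["intercept"], dtype=float)
    for name in COEF_NAMES:
        y += params[name] * clipped[name].astype(float).to_numpy()
    if noise_sd:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        y = y + rng.normal(0.0, noise_sd, len(y))
    return np.clip(y, 0.0, 100.0)


def generate_hdr_table(
    n: int,
    rng: np.random.Generator,
    params: dict | None = None,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Synthetic HDR training table (eva_score, donor_dg, sub_penalty, hdr)."""
    params = params or PLANTED_HDR_PARAMS
    table = default_substitution_table()
    pairs = sorted(table)
    picks = rng.integers(0, len(pairs), n)
    penalty = np.array([table[pairs[k]] for k in picks])
    df = pd.DataFrame(
        {
            "id": [f"d{i + 1:04d}" for i in range(n)],
            "eva_score": rng.uniform(20.0, 100.0, n),
            "donor_dg": rng.uniform(-10.0, 0.0, n),
            "sub_penalty": penalty,
            "ref": [pairs[k][0] for k in picks],
            "alt": [pairs[k][1] for k in picks],
        }
    )
    y = (
        params["intercept"]
        + params["eva_score"] * df["eva_score"]
        + params["donor_dg"] * df["donor_dg"]
        + params["sub_penalty"] * df["sub_penalty"]
    ).to_numpy()
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, n)
    df["hdr"] = np.clip(y, 0.0, 100.0)
    return df


def generate_spacers(n: int, rng: np.random.Generator) -> list[str]:
    """Random 20-mers for exercising the sequence-feature pipeline."""
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(n)]
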