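"""The EVA activity score: a five-feature linear model of synthetic
Cas9 gRNA activity.

The model is ordinary least squares on clipped features:

    score = b0 + b_dg·ΔG' + b_ga·#GA + b_mit·MIT' + b_g17·[G17] + b_c20·[C20]

with ΔG' = min(ΔG, −3) and MIT' = min(MIT, 75): free energies above −3
kcal/mol and specificity above 75 carry no additional benefit, so they are
clipped to those boundaries before entering the linear term. Predictions
are clamped to the 0-100 activity scale, and a score below 50 flags a
guide as inefficient.

Follows the statsmodels convention: :class:`EvaActivityModel` holds data,
``fit()`` returns :class:`EvaActivityResults` carrying estimates,
uncertainties and diagnostics; a results object can also be constructed
from a coefficient config without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

EFFICIENCY_THRESHOLD = 50.0
CLIP_DG_DEFAULT = -3.0
CLIP_MIT_DEFAULT = 75.0

# design-matrix column order: (clipped ΔG, #GA, clipped MIT, G17, C20)
COEF_NAMES = ["delta_g", "n_ga", "mit_score", "g17", "c20"]


class RankDeficiencyError(ValueError):
    """OLS design matrix is rank deficient; names the collinear columns."""


def clip_features(
    features: pd.DataFrame,
    clip_dg: float = CLIP_DG_DEFAULT,
    clip_mit: float = CLIP_MIT_DEFAULT,
) -> pd.DataFrame:
    """Apply the boundary transforms ΔG' = min(ΔG, clip_dg), MIT' = min(MIT, clip_mit)."""
    out = features.copy()
    out["delta_g"] = np.minimum(out["delta_g"].astype(float), clip_dg)
    out["mit_score"] = np.minimum(out["mit_score"].astype(float), clip_mit)
    out["g17"] = out["g17"].astype(float)
    out["c20"] = out["c20"].astype(float)
    return out


def _design(features: pd.DataFrame, clip_dg: float, clip_mit: float) -> pd.DataFrame:
    missing = [c for c in COEF_NAMES if c not in features.columns]
    if missing:
        raise KeyError(f"feature table is missing required columns: {missing}")
    clipped = clip_features(features, clip_dg, clip_mit)
    X = clipped[COEF_NAMES].astype(float)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name columns involved in exact collinearity
        bad = []
        for name in X.columns:
            reduced = X.drop(columns=[name])
            if np.linalg.matrix_rank(np.asarray(reduced)) == np.linalg.matrix_rank(arr):
                bad.append(name)
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {bad or list(X.columns)}"
        )


class EvaActivityModel:
    """OLS model of in vivo gRNA activity (%) on the five clipped features.

    Parameters
    ----------
    endog : array-like
        Measured activity per guide on the 0-100 scale (replicate means).
    features : DataFrame
        Columns ``delta_g, n_ga, mit_score, g17, c20`` (extra columns
        such as ``id``/``spacer`` are ignored).
    """

    def __init__(
        self,
        endog,
        features: pd.DataFrame,
        clip_dg: float = CLIP_DG_DEFAULT,
        clip_mit: float = CLIP_MIT_DEFAULT,
    ):
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 1:
            raise ValueError("endog must be one-dimensional")
        if len(self.endog) != len(features):
            raise ValueError("endog and features differ in length")
        if len(self.endog) < 10:
            raise ValueError("at least 10 guides are required to fit")
        if np.nanmin(self.endog) < 0 or np.nanmax(self.endog) > 100:
            raise ValueError("activity response must lie in [0, 100]")
        self.features = features.reset_index(drop=True)
        self.clip_dg = float(clip_dg)
        self.clip_mit = float(clip_mit)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str = "activity", **kwargs
    ) -> "EvaActivityModel":
        return cls(data[response], data, **kwargs)

    def fit(self) -> "EvaActivityResults":
        X = _design(self.features, self.clip_dg, self.clip_mit)
        _check_rank(X)
        res = sm.OLS(self.endog, X).fit()
        predicted = np.asarray(res.fittedvalues)
        if np.std(predicted) > 0 and np.std(self.endog) > 0:
            train_r = float(np.corrcoef(predicted, self.endog)[0, 1])
        else:
            train_r = float("nan")
        params = {"intercept": float(res.params["const"])}
        params.update({name: float(res.params[name]) for name in COEF_NAMES})
        return EvaActivityResults(
            params=params,
            clip_dg=self.clip_dg,
            clip_mit=self.clip_mit,
            n_ga_ref=int(self.features["n_ga"].max()),
            provenance="fitted",
            nobs=len(self.endog),
            train_pearson_r=train_r,
            bse={k: float(v) for k, v in res.bse.items()},
            _sm_results=res,
        )


@dataclass
class EvaActivityResults:
    """Fitted (or configured) EVA score parameters plus diagnostics.

    ``n_ga_ref`` is the non-penalizing reference GA count used by the
    penalty decomposition (the training maximum by default).
    """

    params: dict
    clip_dg: float = CLIP_DG_DEFAULT
    clip_mit: float = CLIP_MIT_DEFAULT
    n_ga_ref: int = 4
    provenance: str = "config"
    nobs: Optional[int] = None
    train_pearson_r: Optional[float] = None
    bse: Optional[dict] = None
    _sm_results: object = None

    # -- construction from / export to flat config -------------------------
    @classmethod
    def from_config(cls, config: dict) -> "EvaActivityResults":
        params = {"intercept": float(config["intercept"])}
        for name in COEF_NAMES:
            params[name] = float(config[f"coef_{name}"])
        return cls(
            params=params,
            clip_dg=float(config.get("clip_dg", CLIP_DG_DEFAULT)),
            clip_mit=float(config.get("clip_mit", CLIP_MIT_DEFAULT)),
            n_ga_ref=int(config.get("n_ga_ref", 4)),
            provenance=str(config.get("provenance", "config")),
        )

    @classmethod
    def default(cls) -> "EvaActivityResults":
        """The packaged default coefficient set (synthetic calibration)."""
        text = resources.files("evascore.data").joinpath("eva_default.json").read_text()
        return cls.from_config(json.loads(text))

    def to_config(self) -> dict:
        config = {
            "provenance": self.provenance,
            "intercept": self.params["intercept"],
            "clip_dg": self.clip_dg,
            "clip_mit": self.clip_mit,
            "n_ga_ref": self.n_ga_ref,
        }
        for name in COEF_NAMES:
            config[f"coef_{name}"] = self.params[name]
        return config

    # -- prediction --------------------------------------------------------
    def _linear(self, features: pd.DataFrame) -> np.ndarray:
        X = _design(features, self.clip_dg, self.clip_mit)
        beta = np.array([self.params["intercept"]] + [self.params[n] for n in COEF_NAMES])
        return np.asarray(X) @ beta

    def predict(self, features: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """EVA scores for a feature table; clamped to [0, 100] by default."""
        raw = self._linear(features)
        return np.clip(raw, 0.0, 100.0) if clamp else raw

    def zero_penalty_score(self) -> float:
        """Score of a guide with no penalizing feature: ΔG and MIT at their
        clip boundaries, GA count at the reference, no G17/C20."""
        ref = pd.DataFrame(
            [
                {
                    "delta_g": self.clip_dg,
                    "n_ga": self.n_ga_ref,
                    "mit_score": self.clip_mit,
                    "g17": 0.0,
                    "c20": 0.0,
                }
            ]
        )
        return float(self._linear(ref)[0])

    def penalty_decomposition(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-feature additive penalties; rows sum to
        ``zero_penalty_score() − unclamped prediction`` exactly."""
        clipped = clip_features(features, self.clip_dg, self.clip_mit)
        ref = {
            "delta_g": self.clip_dg,
            "n_ga": float(self.n_ga_ref),
            "mit_score": self.clip_mit,
            "g17": 0.0,
            "c20": 0.0,
        }
        out = {}
        for name in COEF_NAMES:
            out[f"penalty_{name}"] = self.params[name] * (
                ref[name] - clipped[name].astype(float).to_numpy()
            )
        return pd.DataFrame(out, index=features.index)

    def summary(self) -> str:
        lines = [
            "EVA activity score — linear model on clipped features",
            f"provenance: {self.provenance}",
            f"clip boundaries: dG > {self.clip_dg} -> {self.clip_dg}; "
            f"MIT > {self.clip_mit} -> {self.clip_mit}",
            f"zero-penalty score: {self.zero_penalty_score():.2f} "
            f"(n_ga reference = {self.n_ga_ref})",
            "",
            f"{'term':<12}{'coef':>12}{'std err':>12}",
        ]
        bse = self.bse or {}
        rows = [("intercept", self.params["intercept"], bse.get("const"))]
        rows += [(n, self.params[n], bse.get(n)) for n in COEF_NAMES]
        for name, coef, se in rows:
            se_s = f"{se:>12.4f}" if se is not None else f"{'—':>12}"
            lines.append(f"{name:<12}{coef:>12.4f}{se_s}")
        if self.nobs is not None:
            lines.append("")
            lines.append(f"n = {self.nobs}, training Pearson r = {self.train_pearson_r:.3f}")
        return "\n".join(lines)


def classify_efficiency(score) -> np.ndarray:
    """'inefficient' iff score < 50, else 'efficient' (vectorized)."""
    arr = np.asarray(score, dtype=float)
    out = np.where(arr < EFFICIENCY_THRESHOLD, "inefficient", "efficient")
    return out if out.ndim else out[()]


def prune_features(
    candidates: pd.DataFrame,
    response,
    alpha: float = 0.05,
    cross_corr_cutoff: float = 0.5,
) -> list[str]:
    """Feature-selection by significance then cross-correlation pruning.

    Keeps candidate columns whose two-tailed Pearson correlation with the
    response is significant at ``alpha``; then walks the survivors in order
    of decreasing |r| (ties broken by column name) and drops any feature
    correlated at |r| ≥ ``cross_corr_cutoff`` with an already-kept,
    better-correlated one.
    """
    if candidates.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    y = np.asarray(response, dtype=float)
    stats_per_col = {}
    for col in candidates.columns:
        x = candidates[col].astype(float).to_numpy()
        if np.std(x) == 0:
            continue
        r, p = stats.pearsonr(x, y)
        if p <= alpha:
            stats_per_col[col] = abs(r)
    ordered = sorted(stats_per_col, key=lambda c: (-stats_per_col[c], c))
    kept: list[str] = []
    for col in ordered:
        x = candidates[col].astype(float).to_numpy()
        collides = False
        for other in kept:
            r_x = abs(np.corrcoef(x, candidates[other].astype(float))[0, 1])
            if r_x >= cross_corr_cutoff:
                collides = True
                break
        if not collides:
            kept.append(col)
    return kept


def fit_eva(
    features: pd.DataFrame,
    response,
    clip_dg: float = CLIP_DG_DEFAULT,
    clip_mit: float = CLIP_MIT_DEFAULT,
) -> EvaActivityResults:
    """Convenience wrapper: build the model and fit in one call."""
    return EvaActivityModel(response, features, clip_dg=clip_dg, clip_mit=clip_mit).fit()
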