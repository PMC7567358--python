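"""Score computation: condition flags x published integer weights -> M-CDS.

The weights are the condition coefficients of a multivariable Cox model for
1-year mortality, multiplied by 10 and rounded to the nearest integer
(half away from zero).  The total score is the sum of the weights of the
conditions present; the default stratification splits it into six risk
classes (<=1, 2, 3-4, 5-6, 7-9, >=10).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "coefficient_to_weight",
    "WeightTable",
    "default_weights",
    "StratificationScheme",
    "DEFAULT_SCHEME",
    "compute_score",
    "assign_class",
    "score_profiles",
]


def coefficient_to_weight(beta: float) -> int:
    """Integer weight from a Cox log-hazard-ratio: round(10*beta), half away from zero.

    Negative coefficients transform fine but are flagged with a warning,
    since the published table contains none.
    """
    if not math.isfinite(beta):
        raise ValueError(f"coefficient must be finite, got {beta!r}")
    if beta < 0:
        warnings.warn(f"negative coefficient {beta} yields a negative weight", stacklevel=2)
    scaled = 10.0 * beta
    return int(math.floor(abs(scaled) + 0.5)) * (1 if scaled >= 0 else -1)


@dataclass
class WeightTable:
    """Condition -> (coefficient, integer weight), ordered.

    On construction each stored weight is cross-checked against the
    transform of its coefficient; a mismatch is an error (it means the file
    was edited inconsistently).
    """

    entries: pd.DataFrame  # columns: condition, coefficient, weight

    def __post_init__(self):
        df = self.entries
        missing = {"condition", "coefficient", "weight"} - set(df.columns)
        if missing:
            raise ValueError(f"weight table lacks columns {sorted(missing)}")
        df = df.copy()
        df["weight"] = df["weight"].astype(int)
        recomputed = df["coefficient"].map(coefficient_to_weight)
        bad = df["weight"] != recomputed
        if bad.any():
            rows = df.loc[bad, "condition"].tolist()
            raise ValueError(f"stored weight != round(10*coefficient) for {rows}")
        if df["condition"].duplicated().any():
            raise ValueError("duplicate condition in weight table")
        self.entries = df.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return self.entries["condition"].tolist()

    @property
    def weights(self) -> pd.Series:
        return self.entries.set_index("condition")["weight"]

    def max_score(self) -> int:
        return int(self.entries["weight"].clip(lower=0).sum())

    @classmethod
    def from_coefficients(cls, coefficients: pd.Series) -> "WeightTable":
        df = pd.DataFrame({
            "condition": coefficients.index,
            "coefficient": coefficients.values,
            "weight": [coefficient_to_weight(b) for b in coefficients.values],
        })
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "WeightTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def default_weights() -> WeightTable:
    """The published 18-condition weight table."""
    with resources.files("mcds.data").joinpath("weights_default.csv").open() as fh:
        return WeightTable(pd.read_csv(fh))


class StratificationScheme:
    """Ordered, exhaustive, non-overlapping integer score intervals.

    Boundaries are the first score of each class after the first; the
    default ``[2, 3, 5, 7, 10]`` yields the six classes <=1 / 2 / 3-4 /
    5-6 / 7-9 / >=10.  Class indices are 1-based, increasing with risk.
    """

    def __init__(self, lower_bounds: list[int]):
        bounds = [int(b) for b in lower_bounds]
        if bounds != sorted(set(bounds)):
            raise ValueError("class lower bounds must be strictly increasing")
        if bounds and bounds[0] <= 0:
            raise ValueError("the first class implicitly starts at 0")
        self._bounds = np.asarray(bounds, dtype=int)

    @property
    def n_classes(self) -> int:
        return len(self._bounds) + 1

    @property
    def lower_bounds(self) -> list[int]:
        return self._bounds.tolist()

    def intervals(self) -> list[tuple[int, float]]:
        """Half-open-at-infinity [low, high] integer intervals per class."""
        lows = [0, *self._bounds.tolist()]
        highs = [*(b - 1 for b in self._bounds.tolist()), math.inf]
        return list(zip(lows, highs))

    def labels(self) -> list[str]:
        out = []
        for low, high in self.intervals():
            if high is math.inf:
                out.append(f">={low}" if low > 0 else "all")
            elif low == 0:
                out.append(f"<={high}" if high > 0 else "0")
            elif low == high:
                out.append(str(low))
            else:
                out.append(f"{low}-{high}")
        return out

    def assign(self, scores) -> np.ndarray:
        scores = np.asarray(scores)
        if (scores < 0).any():
            raise ValueError("scores must be nonnegative")
        return np.searchsorted(self._bounds, scores, side="right") + 1

    def __eq__(self, other):
        return isinstance(other, StratificationScheme) and self.lower_bounds == other.lower_bounds

    def __repr__(self):
        return f"StratificationScheme({self.labels()})"


DEFAULT_SCHEME = StratificationScheme([2, 3, 5, 7, 10])


def assign_class(score: int, scheme: StratificationScheme = DEFAULT_SCHEME) -> int:
    """1-based risk class of a single integer score."""
    return int(scheme.assign([score])[0])


def compute_score(profile: pd.Series, weights: WeightTable) -> int:
    """Total score of one patient's binary condition profile.

    Conditions in the profile but absent from the weight table contribute 0
    (they were dropped by variable selection); a weighted condition missing
    from the profile is an error.
    """
    missing = [c for c in weights.conditions if c not in profile.index]
    if missing:
        raise KeyError(f"profile lacks weighted conditions: {missing}")
    w = weights.weights
    return int((profile[w.index].astype(int) * w).sum())


def score_profiles(profiles: pd.DataFrame, weights: WeightTable | None = None,
                   scheme: StratificationScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Score every row of a profile frame; returns patient_id, score, risk_class."""
    if weights is None:
        weights = default_weights()
    missing = [c for c in weights.conditions if c not in profiles.columns]
    if missing:
        raise KeyError(f"profiles lack weighted conditions: {missing}")
    w = weights.weights
    scores = profiles[w.index].to_numpy(dtype=int) @ w.to_numpy()
    return pd.DataFrame({
        "patient_id": profiles.index.astype(str),
        "score": scores.astype(int),
        "risk_class": scheme.assign(scores),
    })
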