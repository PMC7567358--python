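"""CHAID classification tree on an ordinal score against a binary outcome.

The classic chi-square automatic interaction detection algorithm (Kass 1980)
restricted to a single ordinal predictor — the integer comorbidity score —
and a binary outcome (death within follow-up).  It is how the published six
risk classes were discovered, and lets the stratification be re-derived on
any cohort:

* **merge step** — treat each observed score value as an ordinal category;
  repeatedly merge the *adjacent* pair whose 2x2 chi-square p-value is
  largest, while that p-value exceeds ``alpha_merge``;
* **split step** — test the resulting grouping with a g x 2 Pearson
  chi-square, Bonferroni-adjusted by the number of ways to cut c ordinal
  categories into g contiguous groups, C(c-1, g-1); the node splits into
  the merged groups iff the adjusted p-value is below ``alpha_split``,
  every child holds at least ``min_child`` cases, and the node itself holds
  at least ``min_parent`` cases;
* children are grown recursively until ``max_depth``.

Chi-square tests are Pearson without continuity correction (expected counts
below 5 raise a warning, not an exact test), matching the classic
algorithm.  Ties in the merge step are broken toward the lower score
interval so the tree is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb, inf

import numpy as np
from scipy import stats

from .scoring import StratificationScheme

__all__ = [
    "ChaidParams",
    "ChaidNode",
    "chi2_test",
    "merge_categories",
    "split_node",
    "grow_tree",
    "extract_boundaries",
    "render_tree",
]


@dataclass(frozen=True)
class ChaidParams:
    """Stopping and significance parameters of the tree-growing process."""

    max_depth: int = 3
    min_parent: int = 1000
    min_child: int = 500
    alpha_split: float = 0.05
    alpha_merge: float = 0.05

    def __post_init__(self):
        if self.max_depth < 1 or self.min_parent < 1 or self.min_child < 1:
            raise ValueError("depth and node-size minima must be positive")
        if not (0 < self.alpha_split <= 1 and 0 < self.alpha_merge <= 1):
            raise ValueError("significance levels must be in (0, 1]")


@dataclass
class ChaidNode:
    """A node of the grown tree over a contiguous score interval."""

    score_low: int
    score_high: float            # inf for the open-ended top interval
    n: int
    n_events: int
    depth: int = 0
    split_p: float | None = None
    children: list["ChaidNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def event_rate(self) -> float:
        return self.n_events / self.n if self.n else 0.0

    def leaves(self) -> list["ChaidNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def label(self) -> str:
        if self.score_high is inf:
            return f">={self.score_low}"
        if self.score_low == self.score_high:
            return str(self.score_low)
        return f"{self.score_low}-{int(self.score_high)}"

    def to_dict(self) -> dict:
        return {
            "interval": self.label(),
            "n": self.n,
            "n_events": self.n_events,
            "event_rate": self.event_rate,
            "split_p": self.split_p,
            "children": [c.to_dict() for c in self.children],
        }


def chi2_test(events: np.ndarray, totals: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (g x 2, no continuity correction) on grouped counts.

    *events* and *totals* are per-group event counts and group sizes.
    Returns (statistic, p).  Degenerate tables (an all-zero margin) return
    (0, 1).
    """
    events = np.asarray(events, dtype=float)
    totals = np.asarray(totals, dtype=float)
    table = np.column_stack([events, totals - events])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        warnings.warn("chi-square expected count below 5; p-value is approximate",
                      stacklevel=2)
    stat = float(((table - expected) ** 2 / expected).sum())
    df = len(events) - 1
    return stat, float(stats.chi2.sf(stat, df))


def _pair_p(events: np.ndarray, totals: np.ndarray, i: int) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = chi2_test(events[i:i + 2], totals[i:i + 2])
    return p


def merge_categories(values: np.ndarray, events: np.ndarray, totals: np.ndarray,
                     alpha_merge: float = 0.05
                     ) -> list[tuple[int, int, int, int]]:
    """Merge adjacent ordinal categories that the outcome cannot distinguish.

    Inputs are per-category: the sorted distinct score values, event counts
    and sizes.  Adjacent pairs are merged most-similar-first (largest 2x2
    chi-square p, ties toward the lower score) while the largest p exceeds
    ``alpha_merge``.  Returns contiguous groups as tuples
    ``(low_value, high_value, n_events, n)``.
    """
    lows = list(np.asarray(values, dtype=int))
    highs = list(np.asarray(values, dtype=int))
    ev = list(np.asarray(events, dtype=int))
    tot = list(np.asarray(totals, dtype=int))
    while len(lows) > 1:
        ps = [_pair_p(np.array(ev), np.array(tot), i) for i in range(len(lows) - 1)]
        best = int(np.argmax(ps))  # argmax takes the first (lowest-score) maximum
        if ps[best] <= alpha_merge:
            break
        highs[best] = highs[best + 1]
        ev[best] += ev[best + 1]
        tot[best] += tot[best + 1]
        del lows[best + 1], highs[best + 1], ev[best + 1], tot[best + 1]
    return list(zip(lows, highs, ev, tot))


def _node_categories(scores: np.ndarray, outcome: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    values, inverse = np.unique(scores, return_inverse=True)
    totals = np.bincount(inverse, minlength=len(values))
    events = np.bincount(inverse, weights=outcome, minlength=len(values)).astype(int)
    return values, events, totals


def split_node(scores: np.ndarray, outcome: np.ndarray, node: ChaidNode,
               params: ChaidParams) -> None:
    """Attempt one CHAID split of *node*; attaches children in place.

    The node stays a leaf when it is too small, too deep, homogeneous,
    the Bonferroni-adjusted p-value is not significant, or a child would
    fall below ``min_child``.
    """
    if node.depth >= params.max_depth or node.n < params.min_parent:
        return
    mask = (scores >= node.score_low) & (scores <= node.score_high)
    values, events, totals = _node_categories(scores[mask], outcome[mask])
    if len(values) < 2 or events.sum() == 0 or events.sum() == totals.sum():
        return
    groups = merge_categories(values, events, totals, params.alpha_merge)
    g = len(groups)
    if g < 2:
        return
    ev = np.array([gr[2] for gr in groups])
    tot = np.array([gr[3] for gr in groups])
    if (tot < params.min_child).any():
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = chi2_test(ev, tot)
    adj_p = min(1.0, p * comb(len(values) - 1, g - 1))
    if adj_p >= params.alpha_split:
        return
    node.split_p = adj_p
    top = node.score_high
    for i, (low, high, ne, nt) in enumerate(groups):
        child_high = top if i == len(groups) - 1 else high
        node.children.append(ChaidNode(int(low), child_high, int(nt), int(ne),
                                       depth=node.depth + 1))
    for child in node.children:
        split_node(scores, outcome, child, params)


def grow_tree(scores, outcome, params: ChaidParams | None = None) -> ChaidNode:
    """Grow the full tree on integer scores and a 0/1 outcome."""
    params = params or ChaidParams()
    scores = np.asarray(scores, dtype=int)
    outcome = np.asarray(outcome, dtype=int)
    if scores.shape != outcome.shape:
        raise ValueError("scores and outcome must align")
    root = ChaidNode(int(scores.min()), inf, len(scores), int(outcome.sum()), depth=0)
    # the root interval is open at both ends conceptually; represent as [min, inf)
    root.score_low = 0
    split_node(scores, outcome, root, params)
    return root


def extract_boundaries(tree: ChaidNode) -> StratificationScheme:
    """Ordered leaf intervals as a stratification scheme.

    The leaves of a CHAID tree on a single ordinal predictor partition the
    score axis into contiguous intervals; their lower bounds (beyond the
    first) define the class boundaries.
    """
    leaves = sorted(tree.leaves(), key=lambda nd: nd.score_low)
    bounds = [leaf.score_low for leaf in leaves[1:]]
    return StratificationScheme(bounds)


def render_tree(tree: ChaidNode) -> str:
    """Indented text rendering of the grown tree."""
    lines: list[str] = []

    def walk(node: ChaidNode, indent: int) -> None:
        p = "" if node.split_p is None else f"  split p={node.split_p:.3g}"
        lines.append("  " * indent +
                     f"[{node.label()}] n={node.n} deaths={node.n_events} "
                     f"rate={node.event_rate:.4f}{p}")
        for child in node.children:
            walk(child, indent + 1)

    walk(tree, 0)
    return "\n".join(lines)
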