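"""Discriminatory power and concordance statistics for typing partitions.

Typing methods (FTIR clusters, PFGE profiles, MLST clades, ANI groups) each
induce a partition of the isolates.  Two families of statistics are
computed here:

* **Simpson's index of diversity** in the Hunter-Gaston (unbiased) form

      D = 1 - sum_j n_j (n_j - 1) / [N (N - 1)]

  the probability that two isolates drawn without replacement fall in
  different types — the standard measure of a typing method's
  discriminatory power.

* **Pairwise concordance** between two partitions: the Rand index
  (fraction of sample pairs on which the methods agree) and the two
  directional Wallace coefficients (probability that a pair grouped
  together by method A is also grouped together by method B, and vice
  versa).  A Wallace coefficient with an empty denominator (a method that
  groups no pair at all) is vacuously 1 and flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .cluster import Partition

__all__ = ["TypingComparison", "simpson_diversity", "compare_partitions"]


@dataclass
class TypingComparison:
    method_a: str
    method_b: str
    rand_index: float
    wallace_ab: float
    wallace_ba: float
    contingency: pd.DataFrame
    degenerate_ab: bool = False
    degenerate_ba: bool = False
    pair_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method_a": self.method_a,
            "method_b": self.method_b,
            "rand_index": self.rand_index,
            "wallace_ab": self.wallace_ab,
            "wallace_ba": self.wallace_ba,
            "degenerate_ab": self.degenerate_ab,
            "degenerate_ba": self.degenerate_ba,
            "pair_counts": dict(self.pair_counts),
        }


def simpson_diversity(p: Partition) -> float:
    """Hunter-Gaston Simpson's index of diversity of a typing partition."""
    sizes = np.array(p.sizes(), dtype=float)
    n_tot = sizes.sum()
    if n_tot < 2:
        raise ValueError("Simpson's diversity requires at least two samples")
    return float(1.0 - np.sum(sizes * (sizes - 1.0)) / (n_tot * (n_tot - 1.0)))


def compare_partitions(a: Partition, b: Partition,
                       name_a: str = "A", name_b: str = "B") -> TypingComparison:
    """Rand index and directional Wallace coefficients between two typings."""
    if set(a.samples) != set(b.samples):
        raise ValueError("partitions cover different sample sets")
    samples = sorted(a.samples)
    la = [a.assignment[s] for s in samples]
    lb = [b.assignment[s] for s in samples]
    contingency = pd.crosstab(pd.Series(la, name=name_a), pd.Series(lb, name=name_b))

    n11 = n10 = n01 = n00 = 0  # together/together, A-only, B-only, neither
    for i, j in combinations(range(len(samples)), 2):
        same_a = la[i] == la[j]
        same_b = lb[i] == lb[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    total = n11 + n10 + n01 + n00
    rand = (n11 + n00) / total if total else 1.0

    def wallace(together: int, broken: int):
        denom = together + broken
        if denom == 0:
            return 1.0, True  # vacuous: the method groups no pair
        return together / denom, False

    w_ab, deg_ab = wallace(n11, n10)
    w_ba, deg_ba = wallace(n11, n01)
    return TypingComparison(
        method_a=name_a, method_b=name_b,
        rand_index=rand, wallace_ab=w_ab, wallace_ba=w_ba,
        contingency=contingency,
        degenerate_ab=deg_ab, degenerate_ba=deg_ba,
        pair_counts={"n11": n11, "n10": n10, "n01": n01, "n00": n00},
    )
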