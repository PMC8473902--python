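"""Hierarchical cluster analysis of preprocessed spectra.

Implements the spectral typing chain: Euclidean distances, single-linkage
agglomeration, dendrogram cutting, and the automatic cutoff used by
IR-Biotyper-style typing, which selects the dendrogram height maximizing

    score(h) = D(cut(h)) * mean_coherence(cut(h), reference)

where D is the Hunter-Gaston form of Simpson's index of diversity over the
induced sample partition, and the coherence of a reference group (usually a
strain: its technical replicates) is the best-match Jaccard overlap with
the induced clusters.  Coherence is 1 for every group iff the cut
reproduces the reference grouping exactly; Simpson's D rewards splitting.
The product is maximal for the finest partition that keeps every reference
group intact — the typing the instrument software reports.

Single linkage is implemented directly (not delegated) so that the merge
order is fully deterministic: ties are broken toward the pair of clusters
with the lexicographically lowest (minimum-leaf-index, minimum-leaf-index)
representatives.  scipy and minimum-spanning-tree constructions are used as
independent oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .spectra import SpectrumSet

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "Partition",
    "CutoffResult",
    "pairwise_euclidean",
    "single_linkage",
    "cut_dendrogram",
    "coherence",
    "automatic_cutoff",
]


class DistanceMatrix:
    """Symmetric, labeled, zero-diagonal distance matrix."""

    def __init__(self, labels, values):
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = np.maximum((self.values + self.values.T) / 2.0, 0.0)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy())


@dataclass
class Dendrogram:
    """Single-linkage merge tree.

    ``merges`` follows the scipy convention: row t merges nodes ``a`` and
    ``b`` at ``height``, creating node ``n + t``; nodes 0..n-1 are leaves in
    the order of ``leaves``.
    """

    merges: list  # list of (a, b, height)
    leaves: list  # sample ids

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError("a dendrogram over n leaves needs exactly n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("single-linkage merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges], dtype=float)

    @property
    def max_height(self) -> float:
        return float(self.heights[-1]) if self.merges else 0.0

    def leaf_join_height(self, leaf_id) -> float:
        """Height at which a leaf first joins any other cluster."""
        idx = self.leaves.index(leaf_id)
        for a, b, h in self.merges:
            if idx in (a, b):
                return float(h)
            # follow the leaf through internal nodes
        raise AssertionError("unreachable: every leaf is merged")

    def to_linkage(self) -> np.ndarray:
        """scipy-style linkage matrix (with cluster sizes), for plotting."""
        n = len(self.leaves)
        sizes = {i: 1 for i in range(n)}
        rows = []
        for t, (a, b, h) in enumerate(self.merges):
            sizes[n + t] = sizes[a] + sizes[b]
            rows.append([a, b, h, sizes[n + t]])
        return np.array(rows, dtype=float)

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["node_a", "node_b", "height"])

    def to_newick(self) -> str:
        """Ultrametric Newick string; branch lengths from merge heights."""
        n = len(self.leaves)
        height_of = {i: 0.0 for i in range(n)}
        newick = {i: _quote_newick(str(self.leaves[i])) for i in range(n)}
        for t, (a, b, h) in enumerate(self.merges):
            la = h - height_of[a]
            lb = h - height_of[b]
            node = n + t
            newick[node] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
            height_of[node] = h
        return newick[n + len(self.merges) - 1] + ";"


def _quote_newick(label: str) -> str:
    if any(c in label for c in " (),:;'\t\n[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


class Partition:
    """Assignment of samples to type labels."""

    def __init__(self, assignment: dict):
        if not assignment:
            raise ValueError("partition cannot be empty")
        self.assignment = dict(assignment)

    @classmethod
    def from_labels(cls, samples, labels) -> "Partition":
        samples, labels = list(samples), list(labels)
        if len(samples) != len(labels):
            raise ValueError("samples and labels must have equal length")
        return cls(dict(zip(samples, labels)))

    @property
    def samples(self) -> list:
        return list(self.assignment)

    @property
    def n(self) -> int:
        return len(self.assignment)

    def groups(self) -> dict:
        out: dict = {}
        for s, t in self.assignment.items():
            out.setdefault(t, set()).add(s)
        return out

    def sizes(self) -> list:
        return sorted((len(g) for g in self.groups().values()), reverse=True)

    @property
    def n_types(self) -> int:
        return len(set(self.assignment.values()))

    def relabel(self, prefix: str = "T") -> "Partition":
        """Rename types ``T1, T2, ...`` in order of first appearance."""
        seen: dict = {}
        out = {}
        for s, t in self.assignment.items():
            if t not in seen:
                seen[t] = f"{prefix}{len(seen) + 1}"
            out[s] = seen[t]
        return Partition(out)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"sample": self.samples, "type": [self.assignment[s] for s in self.samples]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Partition":
        df = pd.read_csv(path, dtype=str)
        return cls.from_labels(df.iloc[:, 0], df.iloc[:, 1])

    def __eq__(self, other) -> bool:  # equality as partitions, not labelings
        if not isinstance(other, Partition):
            return NotImplemented
        if set(self.samples) != set(other.samples):
            return False
        mine = {frozenset(g) for g in self.groups().values()}
        theirs = {frozenset(g) for g in other.groups().values()}
        return mine == theirs


@dataclass
class CutoffResult:
    """Outcome of the automatic cutoff search."""

    height: float
    score: float
    simpson_d: float
    mean_coherence: float
    partition: Partition
    per_group_coherence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert abs(self.score - self.simpson_d * self.mean_coherence) < 1e-12

    def to_dict(self) -> dict:
        return {
            "cutoff_height": self.height,
            "score": self.score,
            "simpson_diversity": self.simpson_d,
            "mean_coherence": self.mean_coherence,
            "n_types": self.partition.n_types,
            "per_group_coherence": dict(self.per_group_coherence),
        }


# ---------------------------------------------------------------------------


def pairwise_euclidean(sset: SpectrumSet) -> DistanceMatrix:
    """All-vs-all Euclidean distances between spectra on one grid."""
    d = squareform(pdist(sset.intensities, metric="euclidean"))
    return DistanceMatrix(sset.ids, d)


def single_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Single-linkage agglomerative clustering with deterministic ties.

    Cluster distance is the minimum pairwise member distance.  When several
    pairs tie at the minimum, the pair whose clusters have the lowest
    (minimum-leaf-index) representatives merges first.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("clustering requires at least two samples")
    d = dm.values.copy()
    # active cluster id -> (min distance row maintained in d)
    active = list(range(n))  # node ids
    rows = {node: i for i, node in enumerate(active)}  # node -> row in d
    rep = {i: i for i in range(n)}  # node -> min original leaf index
    merges = []
    for t in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                na, nb = active[ai], active[bi]
                dist = d[rows[na], rows[nb]]
                ra, rb = sorted((rep[na], rep[nb]))
                key = (dist, ra, rb)
                if best is None or key < best[0]:
                    best = (key, na, nb)
        (dist, _, _), na, nb = best
        new = n + t
        # single linkage: distance of merged cluster to others is the min
        ia, ib = rows[na], rows[nb]
        d[ia, :] = np.minimum(d[ia, :], d[ib, :])
        d[:, ia] = d[ia, :]
        rows[new] = ia
        rep[new] = min(rep[na], rep[nb])
        active.remove(na)
        active.remove(nb)
        active.append(new)
        merges.append((na, nb, float(dist)))
    return Dendrogram(merges=merges, leaves=list(dm.labels))


def cut_dendrogram(dend: Dendrogram, h: float) -> Partition:
    """Partition induced by applying every merge of height <= h."""
    if h < 0:
        raise ValueError("cut height must be non-negative")
    n = len(dend.leaves)
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, height) in enumerate(dend.merges):
        node = n + t
        if height <= h:
            parent[find(a)] = node
            parent[find(b)] = node
        else:
            # keep the internal node reachable for later merges
            parent[node] = node
    # any merge above h still links *nodes* conceptually; only components
    # formed by merges <= h count.  Leaves route through applied merges only.
    labels = [find(i) for i in range(n)]
    return Partition.from_labels(dend.leaves, labels).relabel()


def coherence(p: Partition, reference: Partition):
    """Best-match Jaccard coherence of each reference group with the clusters.

    For a reference group g (e.g. the replicates of one strain) the
    coherence is ``max_c |g & c| / |g | c|`` over the clusters c of ``p``.
    It is 1 iff some cluster equals g exactly; splitting g or lumping it
    with foreign samples both lower it.

    Returns (per-group dict, mean over groups).
    """
    if set(p.samples) != set(reference.samples):
        raise ValueError("partition and reference cover different samples")
    clusters = list(p.groups().values())
    per_group = {}
    for gname, g in reference.groups().items():
        best = max(len(g & c) / len(g | c) for c in clusters)
        per_group[gname] = best
    mean = float(np.mean(list(per_group.values())))
    return per_group, mean


def _simpson(partition: Partition) -> float:
    # local import-free Hunter-Gaston form; canonical home is typing_stats
    sizes = np.array(partition.sizes(), dtype=float)
    n_tot = sizes.sum()
    if n_tot < 2:
        raise ValueError("Simpson's diversity needs at least two samples")
    return float(1.0 - np.sum(sizes * (sizes - 1.0)) / (n_tot * (n_tot - 1.0)))


def automatic_cutoff(dend: Dendrogram, reference: Partition) -> CutoffResult:
    """Search dendrogram heights for the typing cutoff.

    Candidate heights are the midpoints between consecutive distinct merge
    heights, plus 0 and just above the last merge; cutting at a midpoint
    avoids the ambiguity of cutting exactly at a merge.  The score is
    Simpson's D of the induced sample partition times the mean coherence
    with the reference grouping; ties go to the largest height (the
    coarsest equally good typing).
    """
    if not reference.samples:
        raise ValueError("reference partition is empty")
    if set(reference.samples) != set(dend.leaves):
        raise ValueError("reference must cover exactly the dendrogram leaves")
    hs = sorted(set(dend.heights.tolist()))
    candidates = [0.0]
    candidates += [(a + b) / 2.0 for a, b in zip(hs, hs[1:])]
    top = dend.max_height
    candidates.append(top * (1 + 1e-9) + 1e-12)
    best = None
    for h in candidates:
        part = cut_dendrogram(dend, h)
        d = _simpson(part)
        per_group, mean_coh = coherence(part, reference)
        score = d * mean_coh
        key = (score, h)
        if best is None or key > best[0]:
            best = (key, CutoffResult(h, score, d, mean_coh, part, per_group))
    return best[1]
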