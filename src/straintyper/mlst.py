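"""Seven-locus MLST: locus extraction, concatenated alignment, Jukes-Cantor
distances, neighbor-joining phylogeny with bootstrap supports.

The scheme types strains by the housekeeping genes *clpC*, *fusA*, *gyrB*,
*ileS*, *purF*, *rplB* and *rpoB*.  Each locus is pulled out of an assembly
by local alignment of a reference allele (coverage >= 0.9, identity >= 80%
by default, tolerant of draft-assembly edge truncation), aligned across
strains in the reference coordinate frame, and the loci are concatenated in
the fixed order above.  Pairwise distances use the Jukes-Cantor one-
parameter correction d = -(3/4) ln(1 - 4p/3) with pairwise deletion of
gap/N columns; trees are built with Saitou-Nei neighbor joining and
internal-branch supports from non-parametric bootstrap over alignment
columns.

Sequence-type numbers from public scheme registries are out of scope; the
output is sequence-based clusters and trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import skbio

from .align import AlignParams, Genome, GenomeSeq, best_local_hit, global_align, revcomp
from .cluster import DistanceMatrix

__all__ = [
    "MLST_LOCI",
    "MLSTProfile",
    "PhyloTree",
    "LocusMissingError",
    "extract_locus",
    "build_profile",
    "align_profiles",
    "jc_distance",
    "jc_distance_matrix",
    "nj_tree",
    "bootstrap_supports",
]

#: fixed locus order used for concatenation
MLST_LOCI = ("clpC", "fusA", "gyrB", "ileS", "purF", "rplB", "rpoB")


class LocusMissingError(ValueError):
    """Raised when a locus cannot be located in an assembly."""


@dataclass
class MLSTProfile:
    """Per-strain locus sequences in the fixed scheme order."""

    strain_id: str
    loci: dict  # locus name -> nucleotide sequence (reference orientation)

    def __post_init__(self) -> None:
        missing = [l for l in MLST_LOCI if l not in self.loci]
        if missing:
            raise LocusMissingError(
                f"profile {self.strain_id!r} lacks loci: {', '.join(missing)}"
            )

    @property
    def concatenated(self) -> str:
        return "".join(self.loci[l] for l in MLST_LOCI)


@dataclass
class PhyloTree:
    """Unrooted NJ tree (skbio TreeNode with a trifurcating root).

    ``supports`` maps canonical bipartitions (frozensets of leaf names) to
    bootstrap percentages; ``negative_branches`` records branches whose raw
    NJ length estimate was negative before clamping to zero.
    """

    tree: skbio.TreeNode
    supports: dict = field(default_factory=dict)
    negative_branches: list = field(default_factory=list)

    @property
    def leaf_names(self) -> list:
        return sorted(t.name for t in self.tree.tips())

    def bipartitions(self) -> set:
        """Canonical internal bipartitions (side not containing the
        lexicographically smallest leaf)."""
        return _bipartitions(self.tree)

    def to_newick(self, with_supports: bool = True) -> str:
        tree = self.tree.copy()
        if with_supports and self.supports:
            all_leaves = frozenset(self.leaf_names)
            ref = min(all_leaves)
            for node in tree.non_tips():
                if node.parent is None:
                    continue
                side = frozenset(t.name for t in node.tips())
                canon = side if ref not in side else all_leaves - side
                if canon in self.supports:
                    node.name = str(int(round(self.supports[canon])))
        return str(tree).strip()

    def write(self, path, with_supports: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(with_supports) + "\n")

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        tree = skbio.TreeNode.read(
            source if hasattr(source, "read") else [source]
        )
        return cls(tree=tree)


def _bipartitions(tree: skbio.TreeNode) -> set:
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out = set()
    for node in tree.non_tips():
        if node.parent is None:
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue  # trivial split
        out.add(side if ref not in side else leaves - side)
    return out


# -- locus extraction -------------------------------------------------------


def extract_locus(genome: Genome, reference_allele: GenomeSeq,
                  params: AlignParams = AlignParams(),
                  min_coverage: float = 0.9, min_identity: float = 80.0) -> str:
    """Locate a locus in an assembly by its reference allele.

    The best local hit of the reference against the genome is extended to
    the full reference span (local alignment may trim mutated ends), and
    the corresponding genome subsequence is returned in the reference
    orientation.
    """
    if len(reference_allele) < 100:
        raise ValueError(
            f"reference allele {reference_allele.id!r} shorter than 100 bp"
        )
    hit = best_local_hit(reference_allele, genome, params)
    if hit is None or hit.coverage < min_coverage or hit.identity < min_identity:
        detail = (
            "no alignment found" if hit is None
            else f"best hit coverage {hit.coverage:.2f}, identity {hit.identity:.1f}%"
        )
        raise LocusMissingError(
            f"locus {reference_allele.id!r} not found in {genome.id!r} ({detail})"
        )
    contig = next(c for c in genome.contigs if c.id == hit.subject_id)
    m = len(reference_allele)
    if hit.strand == "+":
        s_start = hit.s_start - hit.q_start
        s_end = hit.s_end + (m - hit.q_end)
    else:
        s_start = hit.s_start - (m - hit.q_end)
        s_end = hit.s_end + hit.q_start
    s_start = max(0, s_start)
    s_end = min(len(contig), s_end)
    seq = contig.sequence[s_start:s_end]
    return revcomp(seq) if hit.strand == "-" else seq


def build_profile(genome: Genome, alleles: dict,
                  params: AlignParams = AlignParams(), **thresholds) -> MLSTProfile:
    """Extract all seven loci of one strain; ``alleles`` maps locus name to
    its reference allele GenomeSeq."""
    loci = {}
    for name in MLST_LOCI:
        if name not in alleles:
            raise LocusMissingError(f"no reference allele provided for {name!r}")
        loci[name] = extract_locus(genome, alleles[name], params, **thresholds)
    return MLSTProfile(genome.id, loci)


def align_profiles(profiles: list, alleles: dict,
                   params: AlignParams = AlignParams()) -> dict:
    """Align each locus across strains and concatenate.

    Every strain's locus sequence is globally aligned to the reference
    allele and projected onto the reference coordinate frame (deletions
    become ``-`` columns; insertions relative to the reference are
    dropped), so all strains share one column space per locus.  Returns
    ``{strain_id: concatenated aligned sequence}``; all values have equal
    length ``sum(len(allele) for allele in scheme order)``.
    """
    if not profiles:
        raise ValueError("no profiles to align")
    out = {p.strain_id: [] for p in profiles}
    for name in MLST_LOCI:
        ref = alleles[name]
        for p in profiles:
            seq = p.loci[name]
            if len(seq) == len(ref) == 0:
                raise ValueError("empty locus")
            if seq == ref.sequence:
                out[p.strain_id].append(seq)
                continue
            _, gapped_ref, gapped_seq = global_align(
                ref, GenomeSeq(f"{p.strain_id}:{name}", seq), params
            )
            projected = "".join(
                s for r, s in zip(gapped_ref, gapped_seq) if r != "-"
            )
            assert len(projected) == len(ref)
            out[p.strain_id].append(projected)
    return {sid: "".join(parts) for sid, parts in out.items()}


# -- distances --------------------------------------------------------------


def _p_distance(a: str, b: str):
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    valid = diffs = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        valid += 1
        if x != y:
            diffs += 1
    if valid == 0:
        raise ValueError("no comparable columns after pairwise deletion")
    return diffs / valid, valid


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) in subs/site.

    p is the proportion of differing sites with pairwise deletion of
    gap and N columns; p >= 0.75 saturates the model and raises.
    """
    p, _ = _p_distance(a, b)
    if p >= 0.75:
        raise ValueError(f"p-distance {p:.3f} >= 0.75: Jukes-Cantor saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _encode_alignment(aligned: dict):
    labels = sorted(aligned)
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must share one length")
    code = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        code[ord(c)] = i
    mat = np.stack([
        code[np.frombuffer(aligned[l].encode("ascii"), dtype=np.uint8)]
        for l in labels
    ])
    return labels, mat  # -1 marks gap/N/ambiguous


def _jc_from_matrix(mat: np.ndarray, saturation: str = "raise") -> np.ndarray:
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] >= 0) & (mat[j] >= 0)
            valid = int(ok.sum())
            if valid == 0:
                raise ValueError("no comparable columns after pairwise deletion")
            p = float(np.sum(mat[i, ok] != mat[j, ok])) / valid
            if p >= 0.75:
                if saturation == "raise":
                    raise ValueError(
                        f"p-distance {p:.3f} >= 0.75: Jukes-Cantor saturated"
                    )
                p = 0.7499  # bootstrap replicates: cap at near-saturation
            d[i, j] = d[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return d


def jc_distance_matrix(aligned: dict, saturation: str = "raise") -> DistanceMatrix:
    """Pairwise JC distances over a dict of aligned sequences."""
    labels, mat = _encode_alignment(aligned)
    return DistanceMatrix(labels, _jc_from_matrix(mat, saturation))


# -- neighbor joining -------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties resolve to the lowest (i, j) index pair in the current
    matrix order.  Negative branch-length estimates are clamped to zero
    (raw values kept in ``negative_branches``).  The returned tree is
    unrooted, represented with a trifurcating root.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least three taxa")
    d = dm.values.copy()
    nodes = [skbio.TreeNode(name=str(lbl)) for lbl in dm.labels]
    negative = []

    def clamp(node, length, desc):
        if length < 0:
            negative.append((desc, float(length)))
            length = 0.0
        node.length = float(length)

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = d[i, j] - li
        parent = skbio.TreeNode()
        clamp(nodes[i], li, nodes[i].name or "internal")
        clamp(nodes[j], lj, nodes[j].name or "internal")
        parent.append(nodes[i])
        parent.append(nodes[j])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [t for t in range(k) if t not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[t] for t in keep] + [parent]
    # closing trifurcation: three-point formulas
    a, b, c = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    root = skbio.TreeNode()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        clamp(node, ln, node.name or "internal")
        root.append(node)
    return PhyloTree(tree=root, negative_branches=negative)


def bootstrap_supports(aligned: dict, n_reps: int = 1000, seed: int = 0,
                       tree: PhyloTree | None = None) -> PhyloTree:
    """Bootstrap supports for the NJ tree of a concatenated alignment.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    alignment is run through JC + NJ and the support of every internal
    bipartition of the original tree is the percentage of replicate trees
    containing it.  Replicate distances that saturate the JC model are
    capped rather than discarded.
    """
    labels, mat = _encode_alignment(aligned)
    if mat.shape[1] < 2:
        raise ValueError("alignment needs at least two columns")
    if tree is None:
        tree = nj_tree(DistanceMatrix(labels, _jc_from_matrix(mat)))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncol = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep = nj_tree(DistanceMatrix(
            labels, _jc_from_matrix(mat[:, cols], saturation="cap")
        ))
        rep_bps = rep.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return tree
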