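"""OrthoANI whole-genome similarity.

Average nucleotide identity between two genomes computed the OrthoANI way:
both genomes are chopped into consecutive non-overlapping fragments
(default 1020 bp; trailing pieces discarded), every fragment of A is
aligned against the whole of B and vice versa, and only *reciprocal best*
fragment pairs — fragment pairs whose best hits land inside each other —
contribute.  OrthoANI is the unweighted arithmetic mean of the reciprocal
pairs' identities, reported in percent.

Reciprocity is resolved at fragment granularity by midpoint containment:
a hit "lands in" the fragment of the target genome that contains the hit's
midpoint.  This rule is deterministic and symmetric, so
``orthoani_pair(a, b) == orthoani_pair(b, a)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignParams, Genome, GenomeSeq, best_local_hit

__all__ = ["OrthoANIParams", "ANIResult", "Fragment", "fragment_genome",
           "orthoani_pair", "ani_matrix"]


@dataclass(frozen=True)
class OrthoANIParams:
    """fragment_length: window size in bp; min_coverage: smallest fraction
    of a fragment that must align for the hit to count."""

    fragment_length: int = 1020
    min_coverage: float = 0.35
    align: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100 bp")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass
class Fragment:
    """One fragment window with its provenance in the source genome."""

    seq: GenomeSeq
    contig_id: str
    index: int  # window index within the contig
    start: int  # 0-based start on the contig


@dataclass
class ANIResult:
    genome_a: str
    genome_b: str
    orthoani: float | None  # percent; None when no reciprocal pairs exist
    n_reciprocal_pairs: int
    pair_identities: list = field(default_factory=list)

    @property
    def undefined(self) -> bool:
        return self.orthoani is None


def fragment_genome(g: Genome, length: int = 1020) -> list:
    """Non-overlapping consecutive windows of exactly ``length`` per contig.

    Trailing pieces shorter than ``length`` are discarded, windows never
    span contig junctions, and fragments that are more than 50% N are
    dropped.
    """
    frags = []
    for contig in g.contigs:
        n_windows = len(contig) // length
        for w in range(n_windows):
            start = w * length
            piece = contig.sequence[start:start + length]
            if piece.count("N") * 2 > length:
                continue
            frags.append(Fragment(
                seq=GenomeSeq(f"{g.id}|{contig.id}|{w}", piece),
                contig_id=contig.id, index=w, start=start,
            ))
    return frags


def _best_fragment_hits(frags, target: Genome, target_frags, p: OrthoANIParams):
    """Map each query fragment to (target fragment key, identity) via its
    best hit's midpoint, dropping hits below the coverage floor."""
    L = p.fragment_length
    valid = {(f.contig_id, f.index) for f in target_frags}
    out = {}
    for f in frags:
        hit = best_local_hit(f.seq, target, p.align)
        if hit is None or hit.coverage < p.min_coverage:
            continue
        widx = int(hit.s_mid // L)
        key = (hit.subject_id, widx)
        if key in valid:
            out[(f.contig_id, f.index)] = (key, hit.identity)
    return out


def orthoani_pair(a: Genome, b: Genome, p: OrthoANIParams = OrthoANIParams()) -> ANIResult:
    """OrthoANI between two genomes (symmetric in its arguments)."""
    fa = fragment_genome(a, p.fragment_length)
    fb = fragment_genome(b, p.fragment_length)
    if not fa or not fb:
        raise ValueError(
            f"genomes must each yield at least one {p.fragment_length} bp fragment"
        )
    a_hits = _best_fragment_hits(fa, b, fb, p)
    b_hits = _best_fragment_hits(fb, a, fa, p)
    identities = []
    n_pairs = 0
    for fa_key in sorted(a_hits):
        fb_key, ident_ab = a_hits[fa_key]
        back = b_hits.get(fb_key)
        if back is not None and back[0] == fa_key:
            identities.append((ident_ab + back[1]) / 2.0)
            n_pairs += 1
    if n_pairs == 0:
        return ANIResult(a.id, b.id, None, 0, [])
    return ANIResult(a.id, b.id, float(np.mean(identities)), n_pairs, identities)


def ani_matrix(genomes: list, p: OrthoANIParams = OrthoANIParams()) -> pd.DataFrame:
    """All-vs-all OrthoANI matrix (percent; diagonal 100)."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("genome ids must be unique")
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            res = orthoani_pair(genomes[i], genomes[j], p)
            if res.undefined:
                raise ValueError(
                    f"OrthoANI undefined for {ids[i]} vs {ids[j]}: "
                    "no reciprocal fragment pairs"
                )
            mat.iloc[i, j] = mat.iloc[j, i] = res.orthoani
    return mat


def plot_ani_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the ANI matrix as an annotated heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(matrix) + 2,) * 2)
    im = ax.imshow(matrix.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix)), matrix.index)
    for i in range(len(matrix)):
        for j in range(len(matrix)):
            ax.text(j, i, f"{matrix.iloc[i, j]:.2f}", ha="center", va="center",
                    color="white", fontsize=8)
    fig.colorbar(im, ax=ax, label="OrthoANI (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
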