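"""Model / Results interface over the typing pipelines.

Three model classes mirror the three arms of a polyphasic typing study;
each is constructed from data, and ``fit()`` returns a results object
carrying the estimates, diagnostics and a ``summary()`` table:

* :class:`SpectralTyping` — FTIR spectra -> preprocessing -> single-linkage
  HCA -> automatic cutoff -> type partition;
* :class:`GenomeSimilarity` — genome assemblies -> all-vs-all OrthoANI;
* :class:`MLSTPhylogeny` — assemblies + reference alleles -> concatenated
  seven-locus alignment -> JC + NJ tree with bootstrap supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cluster as _cluster
from . import mlst as _mlst
from . import orthoani as _ani
from .align import AlignParams, Genome, read_fasta
from .cluster import CutoffResult, Dendrogram, DistanceMatrix, Partition
from .preprocess import PreprocessParams, preprocess_set
from .spectra import SpectrumSet
from .typing_stats import simpson_diversity

__all__ = [
    "SpectralTyping", "SpectralTypingResults",
    "GenomeSimilarity", "GenomeSimilarityResults",
    "MLSTPhylogeny", "MLSTPhylogenyResults",
]


def _rule(title: str, width: int = 64) -> str:
    pad = (width - len(title) - 2) // 2
    return "=" * pad + f" {title} " + "=" * (width - pad - len(title) - 2)


# -- FTIR spectral typing ---------------------------------------------------


class SpectralTyping:
    """FTIR strain-typing model.

    Parameters
    ----------
    spectra : SpectrumSet
        Raw absorbance spectra with strain/species metadata.
    group_by : str
        Metadata column defining the reference grouping whose coherence
        steers the automatic cutoff (default ``"strain"``).
    params : PreprocessParams
        Savitzky-Golay / window / normalization settings.
    """

    def __init__(self, spectra: SpectrumSet, group_by: str = "strain",
                 params: PreprocessParams = PreprocessParams()):
        if group_by not in spectra.meta.columns:
            raise ValueError(f"metadata lacks the grouping column {group_by!r}")
        self.spectra = spectra
        self.group_by = group_by
        self.params = params

    @classmethod
    def from_csv(cls, spectra_path, meta_path, **kwargs) -> "SpectralTyping":
        return cls(SpectrumSet.from_csv(spectra_path, meta_path), **kwargs)

    def fit(self) -> "SpectralTypingResults":
        prep = preprocess_set(self.spectra, self.params)
        dm = _cluster.pairwise_euclidean(prep)
        dend = _cluster.single_linkage(dm)
        reference = Partition.from_labels(
            self.spectra.ids, self.spectra.labels(self.group_by)
        )
        cutoff = _cluster.automatic_cutoff(dend, reference)
        return SpectralTypingResults(
            model=self, preprocessed=prep, distances=dm, dendrogram=dend,
            cutoff=cutoff, reference=reference,
        )


@dataclass
class SpectralTypingResults:
    model: SpectralTyping
    preprocessed: SpectrumSet
    distances: DistanceMatrix
    dendrogram: Dendrogram
    cutoff: CutoffResult
    reference: Partition

    @property
    def partition(self) -> Partition:
        return self.cutoff.partition

    @property
    def n_types(self) -> int:
        return self.partition.n_types

    @property
    def simpson_d(self) -> float:
        return simpson_diversity(self.partition)

    def type_table(self) -> pd.DataFrame:
        """Per-sample table: sample, reference group, assigned FTIR type."""
        rows = [
            {
                "sample": s,
                self.model.group_by: self.reference.assignment[s],
                "ftir_type": self.partition.assignment[s],
            }
            for s in self.distances.labels
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        c = self.cutoff
        lines = [
            _rule("FTIR spectral typing"),
            f"samples:               {len(self.distances)}",
            f"reference grouping:    {self.model.group_by} "
            f"({self.reference.n_types} groups)",
            f"cutoff height:         {c.height:.6g}",
            f"types at cutoff:       {self.n_types}",
            f"Simpson's D (H-G):     {c.simpson_d:.4f}",
            f"mean coherence:        {c.mean_coherence:.4f}",
            f"cutoff score (D*C):    {c.score:.4f}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.preprocessed.to_csv(outdir / "preprocessed.csv")
        self.distances.to_csv(outdir / "distances.csv")
        self.dendrogram.to_merge_table().to_csv(outdir / "merges.csv", index=False)
        (outdir / "dendrogram.nwk").write_text(self.dendrogram.to_newick() + "\n")
        self.partition.to_csv(outdir / "types.csv")


# -- OrthoANI ---------------------------------------------------------------


class GenomeSimilarity:
    """All-vs-all OrthoANI model over a set of genome assemblies."""

    def __init__(self, genomes: list, params: _ani.OrthoANIParams = _ani.OrthoANIParams()):
        if len(genomes) < 2:
            raise ValueError("need at least two genomes")
        self.genomes = list(genomes)
        self.params = params

    @classmethod
    def from_fasta(cls, paths, **kwargs) -> "GenomeSimilarity":
        return cls([read_fasta(p) for p in paths], **kwargs)

    def fit(self) -> "GenomeSimilarityResults":
        ids = [g.id for g in self.genomes]
        matrix = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
        pairs = {}
        for i in range(len(self.genomes)):
            for j in range(i + 1, len(self.genomes)):
                res = _ani.orthoani_pair(self.genomes[i], self.genomes[j], self.params)
                pairs[(ids[i], ids[j])] = res
                if res.undefined:
                    raise ValueError(
                        f"OrthoANI undefined for {ids[i]} vs {ids[j]}"
                    )
                matrix.iloc[i, j] = matrix.iloc[j, i] = res.orthoani
        return GenomeSimilarityResults(model=self, matrix=matrix, pairs=pairs)


@dataclass
class GenomeSimilarityResults:
    model: GenomeSimilarity
    matrix: pd.DataFrame
    pairs: dict

    def summary(self) -> str:
        lines = [_rule("OrthoANI whole-genome similarity"),
                 f"genomes: {len(self.matrix)}", ""]
        lines.append(self.matrix.round(2).to_string())
        lines.append("=" * 64)
        return "\n".join(lines)

    def save(self, outdir, heatmap: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.round(2).to_csv(outdir / "ani_matrix.csv")
        if heatmap:
            _ani.plot_ani_heatmap(self.matrix, outdir / "ani_heatmap.png")

    def grouping(self, threshold: float = 99.99) -> Partition:
        """Partition genomes by single-linkage at an ANI threshold (%)."""
        ids = list(self.matrix.index)
        dm = DistanceMatrix(ids, 100.0 - self.matrix.to_numpy())
        dend = _cluster.single_linkage(dm)
        return _cluster.cut_dendrogram(dend, 100.0 - threshold)


# -- MLST -------------------------------------------------------------------


class MLSTPhylogeny:
    """Seven-locus MLST phylogeny model.

    Parameters
    ----------
    genomes : list of Genome assemblies.
    alleles : dict mapping locus name to its reference allele (GenomeSeq).
    align_params : kernel scoring parameters.
    """

    def __init__(self, genomes: list, alleles: dict,
                 align_params: AlignParams = AlignParams()):
        if len(genomes) < 3:
            raise ValueError("a phylogeny needs at least three strains")
        self.genomes = list(genomes)
        self.alleles = dict(alleles)
        self.align_params = align_params

    @classmethod
    def from_fasta(cls, genome_paths, allele_path, **kwargs) -> "MLSTPhylogeny":
        genomes = [read_fasta(p) for p in genome_paths]
        allele_genome = read_fasta(allele_path)
        alleles = {c.id: c for c in allele_genome.contigs}
        return cls(genomes, alleles, **kwargs)

    def fit(self, bootstrap: int = 1000, seed: int = 0) -> "MLSTPhylogenyResults":
        profiles = [
            _mlst.build_profile(g, self.alleles, self.align_params)
            for g in self.genomes
        ]
        aligned = _mlst.align_profiles(profiles, self.alleles, self.align_params)
        distances = _mlst.jc_distance_matrix(aligned)
        tree = _mlst.nj_tree(distances)
        if bootstrap > 0:
            tree = _mlst.bootstrap_supports(aligned, bootstrap, seed, tree=tree)
        return MLSTPhylogenyResults(
            model=self, profiles=profiles, aligned=aligned,
            distances=distances, tree=tree, n_bootstrap=bootstrap,
        )


@dataclass
class MLSTPhylogenyResults:
    model: MLSTPhylogeny
    profiles: list
    aligned: dict
    distances: DistanceMatrix
    tree: _mlst.PhyloTree
    n_bootstrap: int = 0

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.aligned.values())))

    def clusters(self, threshold: float = 0.0) -> Partition:
        """Partition strains by single-linkage on JC distance <= threshold
        (default: identical concatenated sequences cluster together)."""
        dend = _cluster.single_linkage(self.distances)
        return _cluster.cut_dendrogram(dend, threshold)

    def summary(self) -> str:
        lines = [
            _rule("MLST phylogeny (JC + neighbor joining)"),
            f"strains:              {len(self.profiles)}",
            f"loci:                 {', '.join(_mlst.MLST_LOCI)}",
            f"alignment length:     {self.alignment_length} columns",
            f"bootstrap replicates: {self.n_bootstrap}",
        ]
        if self.tree.supports:
            sup = sorted(self.tree.supports.values())
            lines.append(
                f"internal supports:    min {sup[0]:.0f}%, max {sup[-1]:.0f}%"
            )
        if self.tree.negative_branches:
            lines.append(
                f"clamped branches:     {len(self.tree.negative_branches)} "
                "(negative NJ estimates set to 0)"
            )
        lines.append("tree: " + self.tree.to_newick())
        lines.append("=" * 64)
        return "\n".join(lines)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "concatenated_alignment.fasta", "w") as fh:
            for sid in sorted(self.aligned):
                fh.write(f">{sid}\n{self.aligned[sid]}\n")
        self.distances.to_csv(outdir / "jc_distances.csv")
        self.tree.write(outdir / "nj_tree.nwk")
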