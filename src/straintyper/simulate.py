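"""Synthetic FTIR spectra and genome sets with known ground truth.

The spectral generator emulates the hierarchical variance structure that
strain typing by FTIR relies on: species differ by their whole band
archetype, strains within a species differ only by small perturbations of
the carbohydrate-region bands (1200-900 cm^-1, the cell-wall composition
window), and technical replicates differ by instrument-level nuisance
(white noise, a linear baseline, a multiplicative scale factor).  Spectra
are sums of Gaussian absorption bands A exp(-(nu - mu)^2 / 2 sigma^2) with
centers in three biologically inspired regions (C-H stretch 3000-2800,
amide 1700-1480, carbohydrate 1200-900 cm^-1).

The genome generator plants a uniform-random root genome, derives each
strain by i.i.d. substitutions at a controlled per-site rate, and embeds
the seven MLST loci at recorded, non-overlapping positions with their own
mutation rate.  It returns the realized pairwise identities as a truth
table, so alignment-based estimates downstream can be checked against the
planted divergence.

Everything is driven by a single integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Genome, GenomeSeq, write_fasta
from .mlst import MLST_LOCI
from .spectra import SpectrumSet

__all__ = [
    "SpectraSimConfig",
    "GenomeSimConfig",
    "GenomeSimResult",
    "simulate_spectrum_set",
    "simulate_genomes",
    "CARB_REGION",
]

#: band-center regions (cm^-1): C-H stretch, amide, carbohydrate
BAND_REGIONS = ((3000.0, 2800.0), (1700.0, 1480.0), (1200.0, 900.0))
CARB_REGION = (1200.0, 900.0)

#: default MLST locus lengths (bp), typical housekeeping-fragment sizes
DEFAULT_LOCI = tuple(zip(MLST_LOCI, (507, 498, 489, 519, 474, 441, 513)))


@dataclass(frozen=True)
class SpectraSimConfig:
    """Conditions of a simulated FTIR typing experiment.

    The defaults mirror the acquisition design of a strain-typing run:
    four technical replicates per isolate on a 4000-600 cm^-1 grid with
    4 cm^-1 spacing.  ``strain_effect`` is the relative perturbation of
    carbohydrate-band amplitude/position between strains of one species;
    ``replicate_noise`` is additive white noise in absorbance units
    (instrument-level, ~0.1 mOD); baseline and scale jitter model
    pathlength/deposition variation and are removed by preprocessing.
    """

    n_species: int = 1
    strains_per_species: int = 5
    replicates_per_strain: int = 4
    grid_max: float = 4000.0
    grid_min: float = 600.0
    grid_step: float = 4.0
    n_bands: int = 12
    strain_effect: float = 0.05
    replicate_noise: float = 1e-4
    baseline_drift: float = 0.01
    scale_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_max <= self.grid_min:
            raise ValueError("grid_max must exceed grid_min")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if min(self.n_species, self.strains_per_species, self.n_bands) < 1:
            raise ValueError("counts must be at least 1")
        if self.replicates_per_strain < 1:
            raise ValueError("replicates_per_strain must be >= 1")
        for name in ("strain_effect", "replicate_noise", "baseline_drift",
                     "scale_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_spectrum_set(config: SpectraSimConfig) -> SpectrumSet:
    """Generate the full (species x strain x replicate) spectrum set."""
    c = config
    rng = np.random.default_rng(c.seed)
    wn = np.arange(c.grid_max, c.grid_min - 0.5 * c.grid_step, -c.grid_step)
    ids, rows, meta_rows = [], [], []
    for sp in range(c.n_species):
        # species archetype: bands spread round-robin over the three regions
        centers, amps, widths = [], [], []
        for b in range(c.n_bands):
            hi, lo = BAND_REGIONS[b % len(BAND_REGIONS)]
            centers.append(rng.uniform(lo, hi))
            amps.append(rng.uniform(0.2, 1.0))
            widths.append(rng.uniform(10.0, 30.0))
        centers = np.array(centers)
        amps = np.array(amps)
        widths = np.array(widths)
        carb = (centers >= CARB_REGION[1]) & (centers <= CARB_REGION[0])
        for st in range(c.strains_per_species):
            st_amps = amps.copy()
            st_centers = centers.copy()
            # strain identity lives in the carbohydrate window only
            st_amps[carb] *= 1.0 + c.strain_effect * rng.standard_normal(carb.sum())
            st_centers[carb] += (
                c.strain_effect * widths[carb] * rng.standard_normal(carb.sum())
            )
            clean = np.sum(
                st_amps[:, None]
                * np.exp(-((wn[None, :] - st_centers[:, None]) ** 2)
                         / (2.0 * widths[:, None] ** 2)),
                axis=0,
            )
            strain_id = f"sp{sp + 1}_st{st + 1}"
            for rep in range(c.replicates_per_strain):
                scale = 1.0 + c.scale_jitter * rng.standard_normal()
                intercept = rng.uniform(-c.baseline_drift, c.baseline_drift)
                slope = rng.uniform(-c.baseline_drift, c.baseline_drift)
                nu01 = (wn - c.grid_min) / (c.grid_max - c.grid_min)
                noise = c.replicate_noise * rng.standard_normal(wn.size)
                spec = scale * clean + intercept + slope * nu01 + noise
                sid = f"{strain_id}_r{rep + 1}"
                ids.append(sid)
                rows.append(spec)
                meta_rows.append({
                    "sample": sid, "strain": strain_id,
                    "species": f"sp{sp + 1}", "replicate": rep + 1,
                })
    return SpectrumSet(wn, np.array(rows), ids, pd.DataFrame(meta_rows))


# -- genomes ----------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimConfig:
    """Conditions of a simulated genome set.

    ``divergence`` is the per-site substitution probability of each strain
    from the shared root; the seven MLST loci are embedded at recorded
    non-overlapping positions and mutate at ``locus_mut_rate`` instead.
    """

    genome_length: int = 100_000
    n_strains: int = 4
    divergence: float = 0.01
    mlst_loci: tuple = DEFAULT_LOCI
    locus_mut_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 0.75:
            raise ValueError(
                "divergence must be in [0, 0.75): the Jukes-Cantor correction "
                "is undefined at saturation"
            )
        if not 0 <= self.locus_mut_rate < 0.75:
            raise ValueError("locus_mut_rate must be in [0, 0.75)")
        if self.n_strains < 1 or self.genome_length < 1000:
            raise ValueError("need n_strains >= 1 and genome_length >= 1000")
        n_loci = len(self.mlst_loci)
        for name, length in self.mlst_loci:
            if length >= self.genome_length / max(n_loci, 1):
                raise ValueError(
                    f"locus {name!r} length {length} too large for "
                    f"genome_length {self.genome_length}"
                )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


@dataclass
class GenomeSimResult:
    """Genomes plus the planted ground truth."""

    genomes: list  # list[Genome], one strain each
    truth: pd.DataFrame  # realized pairwise identity (%), strains x strains
    alleles: dict  # locus name -> root (reference) allele GenomeSeq
    locus_truth: dict  # strain id -> {locus name -> planted sequence}
    locus_positions: dict  # locus name -> (start, end), 0-based half-open
    root: str

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for g in self.genomes:
            write_fasta(g, outdir / f"{g.id}.fasta")
        write_fasta(list(self.alleles.values()), outdir / "alleles.fasta")
        self.truth.to_csv(outdir / "truth_identity.csv")
        pd.DataFrame(
            [(n, s, e) for n, (s, e) in self.locus_positions.items()],
            columns=["locus", "start", "end"],
        ).to_csv(outdir / "locus_positions.csv", index=False)


def simulate_genomes(config: GenomeSimConfig) -> GenomeSimResult:
    """Simulate a star phylogeny of strain genomes around a random root."""
    c = config
    rng = np.random.default_rng(c.seed)
    L = c.genome_length
    root = rng.integers(0, 4, size=L, dtype=np.int8)

    # embed loci at evenly spaced, recorded, non-overlapping positions
    n_loci = len(c.mlst_loci)
    positions = {}
    for i, (name, length) in enumerate(c.mlst_loci):
        start = (i + 1) * L // (n_loci + 1)
        positions[name] = (start, start + length)
    starts = sorted(positions.values())
    for (s1, e1), (s2, e2) in zip(starts, starts[1:]):
        assert e1 <= s2, "loci must not overlap"

    rate = np.full(L, c.divergence)
    for start, end in positions.values():
        rate[start:end] = c.locus_mut_rate

    genomes, locus_truth, seqs = [], {}, []
    for s in range(c.n_strains):
        sid = f"strain{s + 1:02d}"
        mutate = rng.random(L) < rate
        shift = rng.integers(1, 4, size=L, dtype=np.int8)
        strain = root.copy()
        strain[mutate] = (strain[mutate] + shift[mutate]) % 4
        seqs.append(strain)
        genomes.append(Genome.single(sid, _decode(strain)))
        locus_truth[sid] = {
            name: _decode(strain[s0:e0]) for name, (s0, e0) in positions.items()
        }

    ids = [g.id for g in genomes]
    truth = pd.DataFrame(100.0, index=ids, columns=ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ident = 100.0 * float(np.mean(seqs[i] == seqs[j]))
            truth.iloc[i, j] = truth.iloc[j, i] = ident

    alleles = {
        name: GenomeSeq(name, _decode(root[s0:e0]))
        for name, (s0, e0) in positions.items()
    }
    return GenomeSimResult(
        genomes=genomes, truth=truth, alleles=alleles,
        locus_truth=locus_truth, locus_positions=positions,
        root=_decode(root),
    )
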