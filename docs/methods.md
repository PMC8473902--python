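# Methods

This note documents the models and algorithms implemented in `straintyper`,
the parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions that make
every run reproducible.

## FTIR spectral typing

### Preprocessing

A raw spectrum is an absorbance trace A(ν) on a uniform, descending
wavenumber grid (default 4,000 → 600 cm⁻¹, 4 cm⁻¹ spacing — the mid-IR
instrument convention). Three steps produce the analysis representation:

1. **Savitzky–Golay second derivative** — each output point is d²A/dν² of a
   least-squares polynomial fitted to a sliding window (`sg_window = 9`
   points, `sg_polyorder = 3`). The derivative is taken with respect to
   wavenumber (units absorbance·cm²), not sample index, so results are
   independent of grid spacing. Order 3 is the common spectroscopy choice;
   for second derivatives its coefficients coincide with order 2. The
   (window−1)/2 = 4 edge points per side are dropped rather than padded:
   the analysis window is interior, so edges never reach it, and padding
   artifacts are avoided. Differentiating twice removes any additive
   baseline of degree ≤ 1 exactly and resolves overlapping bands.
2. **Window cut** — retain 1,300–800 cm⁻¹ inclusive (126 points on the
   default grid), the carbohydrate "fingerprint" region where cell-wall
   composition differences between strains are expressed. Bounds are
   matched by value with half-a-grid-step tolerance.
3. **Vector normalization** — scale to unit Euclidean norm, removing
   pathlength/biomass effects. Together the three steps make the pipeline
   exactly invariant to positive scaling and to additive linear baselines
   (verified to 1e−9 in the test suite).

The step order (derivative → cut → normalize) is a design choice; the cut
window is interior so derivative edge effects cannot leak in, and
normalizing last makes the representation scale-free.

### Clustering and the automatic cutoff

Distances are Euclidean between preprocessed spectra; clustering is
single-linkage agglomeration (cluster distance = minimum member pair
distance), implemented directly so tie-breaking is fully specified: among
tied minimum distances, the pair of clusters whose minimum-leaf-index
representatives are lexicographically lowest merges first. Dendrograms are
therefore byte-reproducible; scipy's linkage and a minimum-spanning-tree
construction are used as independent oracles in the tests.

Cutting the dendrogram at height h applies every merge with height ≤ h and
returns the connected components as a typing partition. The automatic
cutoff scores candidate heights — midpoints between consecutive distinct
merge heights, plus 0 and just above the top merge — by

    score(h) = D(h) × C̄(h)

* **D**, Simpson's index of diversity in the Hunter–Gaston (unbiased)
  form D = 1 − Σ nⱼ(nⱼ−1)/[N(N−1)], computed over the partition of
  *samples* (replicates), since that is what the cut induces.
* **C̄**, the mean coherence of a reference grouping (default: strain).
  The coherence of a reference group g is max_c |g∩c|/|g∪c| over clusters
  c — the best-match Jaccard index. The vendor definition of "coherence"
  is unpublished; best-match Jaccard was chosen because it penalizes both
  splitting a group and lumping it with foreign samples, and its mean is 1
  iff the cut reproduces the reference grouping exactly.

Ties in the score resolve toward the larger height (the coarsest equally
good typing). Midpoints rather than merge heights themselves avoid the
ambiguity of cutting exactly at a merge. D rewards fine partitions, C̄
punishes splitting replicates of one strain; their product peaks at the
finest partition that keeps every strain intact, which is the typing the
cutoff reports. The cutoff *height* is reported as the primary number, with
the score and its two factors alongside.

## OrthoANI

Both genomes are fragmented into consecutive non-overlapping windows of
`fragment_length = 1,020` bp per contig (trailing remainders discarded,
windows never span contig junctions, fragments > 50% N dropped). Every
fragment of A is aligned against the whole of B and vice versa; hits
covering < 35% of their fragment are dropped. A fragment pair (fᴬ, fᴮ) is
*orthologous* when fᴬ's best hit midpoint falls inside fᴮ and fᴮ's best
hit midpoint falls inside fᴬ (midpoint containment is deterministic and
symmetric, so ANI(a,b) = ANI(b,a) exactly). OrthoANI is the unweighted mean
of the reciprocal pairs' identities, each pair contributing the average of
its two directional hit identities. A pair of genomes with no reciprocal
fragments yields an explicitly *undefined* result, never 0. The 1,020
bp / 35% defaults are the standard OrthoANI constants.

## The alignment kernel

A self-contained seed–chain–extend local aligner serves both OrthoANI and
MLST extraction:

* exact k-mer seeds (default k = 15, configurable ≥ 4) found with a 2-bit
  rolling hash index of the subject, both query strands searched; k-mers
  containing N are never indexed, and seeds occurring > 1,000 times are
  skipped as repeats;
* seeds grouped by diagonal (groups at most `band` apart merge) into at
  most 4 candidate regions, scored by seed count;
* each candidate extended by banded affine-gap Smith–Waterman (match +1,
  mismatch −2, gap open −5 for the first gap base, −2 per extension,
  band 32) with full traceback, so identity = matches / aligned columns is
  exact. When no seed exists and the problem is small (≤ 4·10⁶ cells) the
  kernel falls back to an unbanded exact DP.

k = 15 gives adequate sensitivity above ~90% identity — the intra-species
regime ANI operates in. The banded extension trades optimality in
gap-dense alignments for speed; the band is configurable. N is always
scored as a mismatch (conservative identity). Coordinates are 0-based
half-open internally and 1-based inclusive in written reports; reverse-
strand hits carry forward-subject coordinates.

A full affine Needleman–Wunsch (global) mode supports per-locus alignment.

## MLST

Loci (*clpC, fusA, gyrB, ileS, purF, rplB, rpoB*, concatenated in that
fixed order) are located by aligning the reference allele against the
assembly; the best hit must cover ≥ 90% of the allele at ≥ 80% identity
(tolerant of draft-assembly edge truncation; both thresholds
configurable). Because a local alignment may trim mutated allele ends, the
hit is extended to the full reference span before the genome subsequence
is extracted (reverse-complemented to reference orientation when needed).

Cross-strain alignment is reference-anchored: each strain's locus is
globally aligned to the reference allele and projected onto the reference
coordinate frame — deletions become gap columns, insertions relative to
the reference are dropped. This is exact in the substitution-dominated
regime MLST loci live in and fully deterministic; it is *not* a general
progressive MSA, and insertions shared by several strains are not
represented (a known limitation).

Distances use Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), with *pairwise*
deletion of gap/N columns (complete deletion would discard signal with
draft assemblies); p ≥ 0.75 raises a saturation error. Trees are
Saitou–Nei neighbor joining with the standard Q-criterion; ties take the
lowest current index pair; negative branch-length estimates are clamped to
zero with the raw value preserved in a diagnostics list. Bootstrap
supports resample alignment columns with replacement (default 1,000
replicates, seeded), rebuild JC+NJ per replicate, and report the
percentage of replicates containing each internal bipartition of the
original tree; replicate distances that saturate are capped near the
saturation point rather than aborting a replicate. Sequence-type numbers
from public registries are out of scope — output is sequence-based
clusters and trees.

## Typing statistics

Simpson's index of diversity uses the Hunter–Gaston N(N−1) form — the
standard discriminatory-power index in bacterial typing. Method
concordance is quantified by the Rand index and both directional Wallace
coefficients computed from pair counts; a Wallace coefficient with an
empty denominator (a method that groups no pair) is vacuously 1 and
carries an explicit `degenerate` flag so the user sees it.

## Synthetic data

### Spectra

A species archetype is a sum of `n_bands = 12` Gaussian bands with centers
drawn round-robin from three regions — C–H stretch 3,000–2,800, amide
1,700–1,480, carbohydrate 1,200–900 cm⁻¹ — amplitudes U(0.2, 1.0)
absorbance units and widths U(10, 30) cm⁻¹. Strains perturb only the
carbohydrate-region bands: amplitudes by a relative factor
(1 + δ·N(0,1)) and centers by δ·width·N(0,1), with `strain_effect`
δ = 0.05. Replicates add white noise (σ = 1e−4 absorbance, instrument
scale), a random linear baseline (coefficients U(−0.01, 0.01)) and a
multiplicative factor (1 + N(0, 0.02)). Four replicates per strain mirror
a typical acquisition design.

These choices operationalize the biological premise that strain identity
is carried by cell-wall carbohydrate composition: after preprocessing,
≥ 90% of the between-strain squared difference lies inside 1,300–800 cm⁻¹
(a tested invariant). The magnitudes are plausible instrument-scale values
chosen once for a clear separation hierarchy (species ≫ strain ≫
replicate); with them, the automatic cutoff recovers the planted 5-strain
partition in ≥ 19/20 seeds and the 6-species panel exactly. The generator
does **not** model radiative transfer, water-vapor or atmospheric lines,
Mie scattering, detector drift, or the vendor's proprietary processing —
so passing tests demonstrate the pipeline's statistical behavior under the
assumed variance hierarchy, not hardware fidelity. Gaussian (not Voigt)
band shapes are a deliberate simplification: clustering depends on band
positions/amplitudes, not exact line shapes.

### Genomes

A root genome is uniform-random over {A,C,G,T} (no N; N handling is the
aligner's concern). Each strain applies i.i.d. substitutions at
`divergence` per site (default 0.01; values ≥ 0.75 are rejected because
the JC correction downstream is undefined). The seven MLST loci (441–519
bp, typical housekeeping-fragment sizes) are embedded at evenly spaced,
recorded, non-overlapping positions and mutate at `locus_mut_rate`
(default 0.005) instead. The truth table reports realized pairwise Hamming
identity, so ANI accuracy is measured against what was actually planted,
not just the expected rate (for two strains at rate p the expected
difference fraction is 2p(1−p) + (2/3)p²). The phylogeny is a star — all
strains independent from the root — which is exactly what the bootstrap
no-signal property tests require; clade structure is created in tests by
duplicating or re-seeding strains.

## Numerical conventions and degenerate inputs

* All randomness flows through `numpy.random.default_rng(seed)`; same
  config + seed ⇒ byte-identical outputs everywhere, including bootstrap
  supports.
* Grids must be strictly descending and uniform within 1e−6 relative
  tolerance; distance matrices symmetric within 1e−12 with zero diagonal.
* Zero spectra cannot be normalized (error); an all-zero distance matrix
  yields one cluster and cutoff score 0 at every height.
* Dendrogram merge heights are non-decreasing (guaranteed by single
  linkage); cuts at h apply merges with height ≤ h.
* ANI values are reported to two decimals in CSV output; internal
  comparisons keep full precision.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
spectra sets of 20–24 samples × 851 grid points, genomes of 8–100 kb, NJ
problems of 3–8 taxa, bootstrap at 100–200 replicates (the CLI default
remains 1,000). These sizes keep the full validation suite fast while
exercising every code path at the same parameter settings used for larger
inputs; the kernels scale to multi-Mb assemblies via the k-mer index and
banded extension.

## Known limitations

* The banded extension can miss the optimum for alignments with very long
  gaps; widen `band` if that regime matters.
* Reference-anchored locus alignment drops insertions relative to the
  reference allele.
* The coherence definition is this package's operationalization
  (best-match Jaccard); vendor software may weight splitting/lumping
  differently, so cutoff *heights* are comparable only within this
  implementation.
* Confidence intervals for Simpson's D are not implemented.
* OrthoANI here uses its own aligner, not BLASTn; small (≲ 0.1 point)
  differences from BLAST-based implementations are expected.
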