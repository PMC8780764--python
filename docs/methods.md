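# Methods

## Scope and data model

`tucall` infers the transcription-unit (TU) architecture of a bacterial
chromosome from four strand-specific per-base signal tracks: dRNA-Seq 5′-end
counts with and without TAP treatment (TAP(+)/TAP(−)), two biological
replicates of Term-Seq 3′-end counts, and RNA-Seq coverage. All internal
coordinates are 1-based inclusive; bedGraph input (0-based half-open) and
BED6 output are converted at the I/O boundary. Only the first FASTA record
is used (single-chromosome organisms); strand-specific tracks are supplied
as separate plus/minus bedGraph files to avoid sign-convention ambiguity.

## TSS calling

The 5′ ends of primary transcripts carry a triphosphate that TAP converts to
a ligatable monophosphate, so genuine start sites are enriched in TAP(+)
over TAP(−). Parameters (defaults in brackets):

- `max_gap` [100 nt]: nonzero TAP(+) positions closer than this are one
  cluster. The scale reflects promoter spacing, far above single-base end
  jitter.
- `sd_max` [10]: clusters are sub-clustered greedily left to right, growing
  while the population standard deviation of member positions stays below
  this bound. The greedy rule is deterministic and order-independent given
  sorted input; the sub-clustering algorithm itself is a free design choice
  (only the sd bound is fixed), and greedy growth was chosen for
  reproducibility.
- `min_cluster_reads` [3]: a sub-cluster must have **more than** this many
  summed reads to emit its maximum-count position as a TSS. Applying the
  read-count filter at the sub-cluster level (rather than to the 100-bp
  cluster as a whole) is what suppresses lone background ends that chain
  onto a real site's cluster; without it, every such end would be emitted as
  a separate TSS.
- Ties for the sub-cluster maximum resolve to the most-5′ position
  (favouring the longest isoform). The TAP comparison is evaluated at the
  selected position with strict inequality: TAP(−) > TAP(+) discards.

Classification against annotated ORFs uses a window of 500 nt upstream to
100 nt downstream of the start codon (strand-aware). A TSS in the window of
several genes is assigned to the nearest start codon; per gene the
highest-TAP(+) TSS is primary (P), others secondary (S), with ties broken
toward the nearest start codon. Window membership takes precedence over the
internal (I) category, so a TSS a few bases into an ORF is still P/S.
Leaderless flags (5′-UTR < 9 nt, no room for a ribosome-binding site) are
set for primary TSSs only, since UTR statistics are computed from primaries.
A union-with-max merge utility is provided for combining calls from several
growth conditions; no particular merging policy is claimed.

## TEP calling

Term-Seq 3′ ends are first restricted to intergenic space: same-strand gene
bodies mask candidate positions, with each body shrunk by `invasion`
[10 nt] at its 5′ end so that 3′ ends slightly inside the downstream gene
are retained. Candidates are clustered at `max_gap` [10 nt] and scored with
the modified z-score

    μ = mean of the other cluster positions' counts,
    σ = sqrt(mean of their squared counts − μ²),
    Z = (r − μ) / σ,

leave-one-out in *both* moments — excluding the evaluated position from μ
but not from the second moment would make σ ill-defined. Edge contracts: a
singleton cluster scores +∞ (an isolated sharp 3′ end is the strongest
possible termination signal, and discarding it would lose real terminators);
σ = 0 yields +∞ when r exceeds μ, else 0. Candidates need count ≥ 3 and
Z ≥ 3, evaluated per replicate before reconciliation.

Reconciliation: for every pair of overlapping cluster spans across the two
replicates, surviving candidates inside the span intersection are pooled and
the position with the highest replicate-summed count is emitted (ties to the
smaller coordinate). Summed counts are used because neither replicate is
privileged. Spans 103–125 and 113–142 therefore restrict selection to
113–125.

Classification precedence is C > P/S > A > N: a 3′ end in a gene's leader
(between its primary TSS and start codon, at least `min_cis_distance`
[80 nt] from the TSS so a terminator hairpin can form) is cis-regulatory —
biologically a premature-termination signal such as a riboswitch — even when
it is also within 500 nt of an upstream gene's stop. Only the highest-count
C TEP per gene is kept; lower-count ones are dropped outright. P/S
assignment uses a 500-nt downstream window from the stop codon with
per-gene count ranking (ties to the nearest stop).

## TU assembly

From each P/S/I TSS the same-strand gene chain downstream is walked;
consecutive gene–gene gaps must stay ≤ `max_intergenic` [500 bp] (the
distance from the TSS to its first gene is not checked — the TSS was already
assigned within its classification window). For every chain prefix, each
same-strand P/S TEP between the prefix's last stop codon and the next gene
start forms a TU variant (`variants='all'`; `'first'` keeps the nearest TEP
per prefix). Associated genes are those of the prefix, excluding the host
gene for internal TSSs. C TEPs form gene-less TUs with their own gene's
TSSs. A/N TSSs scan `scan_window` [1 kbp] downstream and the nearest
feature wins: a TEP yields a gene-less TU, a gene start re-enters the chain
rule; ties go to the TEP. Gene-less TUs with a same-strand gene start
< 500 bp downstream of the TSS are cis-regulatory, otherwise sRNA.

TU clusters are connected components of the bipartite TU–gene graph;
gene-less TUs are singletons. An optional coverage-continuity filter flags
multi-gene TUs whose internal intergenic gaps average < 10% of the TU's
gene-body coverage — an automated stand-in for visual inspection of
candidate TUs against the RNA-Seq profile.

## Element annotation

- **Read density.** d(x,p) = r(p+x) / max_{|y|≤300} r(p+y) per anchor,
  averaged into D(x) over anchors; anchors with empty windows are skipped.
  Offsets are mirrored on the minus strand so negative x is always upstream.
- **Promoters.** Best IUPAC-consensus match of `TANNNT` in −20..+1 and
  `BTGACN` in −40..−25, at most 2 incompatible sites, ties toward the
  window's 3′ end for −10 and 5′ end for −35. The spacer is the strict gap
  between the −35 element end and the −10 element start (not
  center-to-center), matching the bimodal 12/19-nt reading of spacer-length
  distributions. Consensus scanning localizes printed motifs; de-novo motif
  discovery is out of scope.
- **Nucleotide enrichment.** Per-offset nucleotide frequency of the anchor
  set divided by that of a seeded uniform intergenic background sample
  (window −41..+20 around 3′ ends); T is reported as U; anchors whose
  window leaves the genome are skipped, and a zero background frequency at
  a needed offset is an error.
- **U-richness.** A TEP is U-rich when the 8 transcript-strand nt ending at
  it contain ≥ 4 U. Window length and threshold are free parameters
  calibrated on the synthetic generator; the flag approximates membership
  in a discovered U-rich terminator motif class, it does not reimplement
  motif discovery.
- **Heptamer repeats.** Pairs of 7-mers, each within 1 mismatch of a given
  IUPAC consensus, separated by exactly 4 or 15 nt, within 150 nt upstream
  of a TSS — the canonical spacing of SARP-family activator binding sites.

## Synthetic data generator

The generator produces the conditions the callers assume, with ground truth
for recovery scoring. Defaults: 100-kb genome at 70% GC (i.i.d.
nucleotides), 60 genes of Normal(900, 135) nt length, 40% of TUs spanning
2–3 genes with operon gaps uniform in 1–400 nt, 5′-UTRs from a mixture of a
leaderless point mass near 0 (probability 0.2) and a lognormal with mode
35 nt (σ = 0.45) clipped to 9–300 nt, 3′-UTRs lognormal with mode 60 nt
(σ = 0.5) clipped to 10–400 nt. TUs are laid left to right with inter-TU
buffers uniform in 400–650 nt — wide enough that neighbouring TUs cannot
merge clusters or confuse classification windows, tight enough that an
all-mono-cistronic layout still fits the default genome.

Signals: each TSS contributes Poisson(50) TAP(+) reads and Poisson(5)
TAP(−) reads, each TEP Poisson(40) reads per Term-Seq replicate with
independent jitter. End jitter is peaked (70% at the true base, falling off
within ±1 nt for TSSs and ±2 nt for TEPs) rather than uniform: exact-end
ligation protocols produce sharp single-base pileups, and a flat spread
would contradict the spike-over-cluster model the modified z-score encodes.
Background ends land uniformly at 1 read/kb per strand in every end track.
Coverage is a Poisson(30) plateau between each TSS–TEP pair. Half of the
TEPs are marked U-rich; for those the genome is rewritten after
architecture planting (5–7 U in the last 8 transcript nt, plus a 12-nt
GC inverted repeat upstream as hairpin arms), so sequence-level terminator
signal exists for the annotator.

All randomness derives from a single seed through separate `SeedSequence`
spawn keys per stage, so genome, architecture and profiles are individually
and jointly reproducible.

What the generator does **not** emulate: read-level artefacts (sequencing
error, mappability, rRNA contamination), processed 5′/3′ ends correlated
with gene positions, condition-dependent expression, overlapping or nested
TUs, and genome-scale site densities (dozens of TUs rather than thousands).
Passing recovery tests therefore demonstrates correctness of the calling
logic under the stated noise model, not performance on real libraries —
real data adds correlated noise (e.g. RNA-processing ends near TSSs) that
manual inspection handled in practice and the coverage-continuity filter
only approximates.

## Numerical and testing choices

σ is compared to zero with a 1e-12 guard and the variance is clamped at 0
against floating-point cancellation. Recovery tests pool ten seeded
default-scale simulations (±2 nt matching for TSSs, ±3 nt for TEPs, exact
gene-list matching for TUs, one-to-one greedy nearest matching); the
problem size — ten 100-kb genomes with ~40 TUs each — keeps the whole suite
in a few seconds while giving several hundred planted sites. The z-score
and clustering implementations are checked against independent brute-force
evaluations (direct formula evaluation; O(n²) transitive closure) on
randomized instances with fixed seeds.
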