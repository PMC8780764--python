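"""Synthetic genome, annotation and end-profile generator with ground truth.

Emulates the data a GC-rich actinobacterial transcriptome study produces:
a ~70% GC genome carrying non-overlapping transcription units (TUs); each TU
has one planted TSS (5'-UTR drawn from a leaderless/lognormal mixture), one
planted 3' end (TEP, lognormal 3'-UTR), and one or more genes with operon
gaps below the 500-bp adjacency rule.  Six per-base signal tracks are
simulated: TAP(+)/TAP(-) dRNA-Seq 5' ends (TAP(-) receives only a leak
fraction of the TSS signal), two Term-Seq 3'-end replicates with independent
jitter, and plateau-shaped RNA-Seq coverage between each TSS-TEP pair.
Spurious background ends land uniformly on both strands of every end track.

About half of the planted TEPs are marked U-rich: the genome sequence is
rewritten so the 8 transcript-strand nt ending at the TEP carry >= 5 U(T)
and a 12-nt inverted repeat (terminator hairpin arm) sits upstream.

Everything is deterministic under ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    COVERAGE,
    FIVE_PRIME,
    THREE_PRIME,
    EndProfile,
    GeneAnnotation,
    Genome,
    InputError,
    reverse_complement,
)

# end-position jitter kernels: sharp single-base pileups with light spread,
# as produced by exact 5'/3'-end ligation protocols
_TSS_JITTER_OFFSETS = np.array([-1, 0, 1])
_TSS_JITTER_P = np.array([0.15, 0.70, 0.15])
_TEP_JITTER_OFFSETS = np.array([-2, -1, 0, 1, 2])
_TEP_JITTER_P = np.array([0.05, 0.10, 0.70, 0.10, 0.05])

LIBRARY_TAGS = ("tap_plus", "tap_minus", "termseq_rep1", "termseq_rep2", "rnaseq")


class CapacityError(InputError):
    """The genome cannot hold the requested architecture."""


@dataclass
class SimParams:
    genome_length: int = 100_000
    gc_fraction: float = 0.70
    n_genes: int = 60
    mean_gene_len: int = 900
    operon_fraction: float = 0.4
    tss_signal_mean: float = 50.0
    tap_minus_leak: float = 0.1
    tep_signal_mean: float = 40.0
    noise_end_rate: float = 1.0  # spurious end reads per kb per strand
    coverage_depth: float = 30.0
    leaderless_fraction: float = 0.2
    utr5_mode: float = 35.0
    utr3_mode: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "operon_fraction", "tap_minus_leak", "leaderless_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")
        for name in (
            "genome_length", "n_genes", "mean_gene_len", "tss_signal_mean",
            "tep_signal_mean", "coverage_depth",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.noise_end_rate < 0:
            raise InputError("noise_end_rate must be >= 0")


@dataclass(frozen=True)
class TruthTSS:
    position: int
    strand: str
    category: str  # planted sites are all primary


@dataclass(frozen=True)
class TruthTEP:
    position: int
    strand: str
    category: str
    u_rich: bool


@dataclass(frozen=True)
class TruthTU:
    tss_position: int
    tep_position: int
    strand: str
    gene_ids: tuple[str, ...]
    category: str


@dataclass
class SimulationTruth:
    tss_truth: list[TruthTSS]
    tep_truth: list[TruthTEP]
    tu_truth: list[TruthTU]

    def __post_init__(self) -> None:
        tss = {(t.position, t.strand) for t in self.tss_truth}
        tep = {(t.position, t.strand) for t in self.tep_truth}
        for tu in self.tu_truth:
            if (tu.tss_position, tu.strand) not in tss or (
                tu.tep_position,
                tu.strand,
            ) not in tep:
                raise InputError(f"TU {tu} references unknown truth TSS/TEP")


@dataclass
class SyntheticDataset:
    params: SimParams
    genome: Genome
    genes: list[GeneAnnotation]
    truth: SimulationTruth
    profiles: dict[str, EndProfile]


def _rng(params: SimParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(stream,))
    )


def generate_genome(params: SimParams) -> Genome:
    """i.i.d. nucleotides with P(G) = P(C) = gc_fraction / 2."""
    rng = _rng(params, 0)
    gc = params.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    letters = rng.choice(np.array(list("ACGT")), size=params.genome_length, p=probs)
    return Genome(id=f"synthetic_seed{params.seed}", sequence="".join(letters))


def _lognormal_mode(rng: np.random.Generator, mode: float, sigma: float) -> float:
    mu = np.log(mode) + sigma**2
    return float(rng.lognormal(mu, sigma))


def plant_architecture(
    params: SimParams, genome: Genome
) -> tuple[list[GeneAnnotation], SimulationTruth]:
    """Lay out non-overlapping TUs along the genome and record ground truth.

    Each TU occupies a block [TSS .. TEP] (mirrored on the minus strand) with
    5'-UTR, gene chain (operon gaps uniform 1-400 nt) and 3'-UTR; blocks are
    separated by a buffer so neighbouring TUs cannot interfere with each
    other's clustering or classification windows.
    """
    rng = _rng(params, 1)
    genes: list[GeneAnnotation] = []
    tss_truth: list[TruthTSS] = []
    tep_truth: list[TruthTEP] = []
    tu_truth: list[TruthTU] = []

    cursor = int(rng.integers(400, 800))
    remaining = params.n_genes
    gi = 0
    while remaining > 0:
        n_tu = 1 if rng.random() >= params.operon_fraction else int(rng.integers(2, 4))
        n_tu = min(n_tu, remaining)
        lens = np.clip(
            np.round(rng.normal(params.mean_gene_len, 0.15 * params.mean_gene_len, n_tu)),
            200,
            2 * params.mean_gene_len,
        ).astype(int)
        gaps = rng.integers(1, 401, size=max(n_tu - 1, 0))
        if rng.random() < params.leaderless_fraction:
            utr5 = int(rng.integers(0, 5))
        else:
            utr5 = int(np.clip(round(_lognormal_mode(rng, params.utr5_mode, 0.45)), 9, 300))
        utr3 = int(np.clip(round(_lognormal_mode(rng, params.utr3_mode, 0.5)), 10, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        u_rich = bool(rng.random() < 0.5)

        block = utr5 + int(lens.sum()) + int(gaps.sum()) + utr3
        if cursor + block > params.genome_length - 300:
            raise CapacityError(
                f"genome of length {params.genome_length} too short for "
                f"{params.n_genes} genes ({remaining} unplaced)"
            )

        # transcript-local layout, left to right
        local_genes = []
        off = utr5
        for j in range(n_tu):
            local_genes.append((off, off + int(lens[j]) - 1))
            off += int(lens[j]) + (int(gaps[j]) if j < n_tu - 1 else 0)
        a, b = cursor, cursor + block - 1

        gene_ids = []
        for s_off, e_off in local_genes:
            gi += 1
            gid = f"SAV_{gi:04d}"
            gene_ids.append(gid)
            if strand == "+":
                gstart, gend = a + s_off, a + e_off
            else:
                gstart, gend = a + (block - 1 - e_off), a + (block - 1 - s_off)
            genes.append(GeneAnnotation(gene_id=gid, start=gstart, end=gend, strand=strand))

        tss_pos, tep_pos = (a, b) if strand == "+" else (b, a)
        tss_truth.append(TruthTSS(tss_pos, strand, "P"))
        tep_truth.append(TruthTEP(tep_pos, strand, "P", u_rich))
        tu_truth.append(
            TruthTU(
                tss_pos,
                tep_pos,
                strand,
                tuple(gene_ids),
                "poly_cistronic" if n_tu >= 2 else "mono_cistronic",
            )
        )
        remaining -= n_tu
        cursor = b + 1 + int(rng.integers(400, 650))

    genes.sort(key=lambda g: (g.start, g.end))
    return genes, SimulationTruth(tss_truth, tep_truth, tu_truth)


def apply_terminator_sequences(genome: Genome, truth: SimulationTruth, params: SimParams) -> Genome:
    """Rewrite the genome at U-rich TEPs: >= 5 T in the last 8 transcript nt
    and a 12-nt inverted repeat planted upstream (hairpin arms at offsets
    -40..-29 and -24..-13)."""
    rng = _rng(params, 3)
    seq = list(genome.sequence)

    def put(pos: int, strand: str, off_lo: int, transcript_seq: str) -> None:
        # write transcript-strand nucleotides covering offsets off_lo.. around pos
        if strand == "+":
            lo = pos + off_lo
            frag = transcript_seq
        else:
            lo = pos - (off_lo + len(transcript_seq) - 1)
            frag = reverse_complement(transcript_seq)
        if lo < 1 or lo + len(frag) - 1 > len(seq):
            return
        seq[lo - 1 : lo - 1 + len(frag)] = list(frag)

    for tep in truth.tep_truth:
        if not tep.u_rich:
            continue
        n_t = int(rng.integers(5, 8))
        tail = np.array(list("G") * 8)
        tail[rng.choice(8, size=n_t, replace=False)] = "T"
        put(tep.position, tep.strand, -7, "".join(tail))
        arm = "".join(rng.choice(np.array(list("GC")), size=12))
        put(tep.position, tep.strand, -40, arm)
        put(tep.position, tep.strand, -24, reverse_complement(arm))
    return Genome(id=genome.id, sequence="".join(seq))


def _scatter(arr: np.ndarray, positions: np.ndarray) -> None:
    """Add one count at each (1-based) position, clipped to the genome."""
    positions = np.clip(positions, 1, arr.size)
    np.add.at(arr, positions - 1, 1)


def simulate_profiles(
    truth: SimulationTruth,
    genes: Sequence[GeneAnnotation],
    params: SimParams,
) -> dict[str, EndProfile]:
    """Simulate the five signal tracks (six bedGraph pairs on disk).

    Returns a dict keyed by library tag: ``tap_plus``, ``tap_minus`` (5' ends),
    ``termseq_rep1``, ``termseq_rep2`` (3' ends), ``rnaseq`` (coverage, shared
    by both replicate roles).
    """
    rng = _rng(params, 2)
    L = params.genome_length
    gid = f"synthetic_seed{params.seed}"
    profiles = {
        "tap_plus": EndProfile.zeros(gid, L, FIVE_PRIME, "tap_plus"),
        "tap_minus": EndProfile.zeros(gid, L, FIVE_PRIME, "tap_minus"),
        "termseq_rep1": EndProfile.zeros(gid, L, THREE_PRIME, "termseq_rep1"),
        "termseq_rep2": EndProfile.zeros(gid, L, THREE_PRIME, "termseq_rep2"),
        "rnaseq": EndProfile.zeros(gid, L, COVERAGE, "rnaseq"),
    }

    for tss in truth.tss_truth:
        sign = 1 if tss.strand == "+" else -1
        for tag, mean in (
            ("tap_plus", params.tss_signal_mean),
            ("tap_minus", params.tap_minus_leak * params.tss_signal_mean),
        ):
            n = rng.poisson(mean)
            if n:
                offs = rng.choice(_TSS_JITTER_OFFSETS, size=n, p=_TSS_JITTER_P)
                _scatter(profiles[tag].counts(tss.strand), tss.position + sign * offs)

    for tep in truth.tep_truth:
        sign = 1 if tep.strand == "+" else -1
        for tag in ("termseq_rep1", "termseq_rep2"):
            n = rng.poisson(params.tep_signal_mean)
            if n:
                offs = rng.choice(_TEP_JITTER_OFFSETS, size=n, p=_TEP_JITTER_P)
                _scatter(profiles[tag].counts(tep.strand), tep.position + sign * offs)

    # uniform background ends on both strands of every end track
    n_noise = params.noise_end_rate * L / 1000.0
    for tag in ("tap_plus", "tap_minus", "termseq_rep1", "termseq_rep2"):
        for strand in ("+", "-"):
            k = rng.poisson(n_noise)
            if k:
                _scatter(
                    profiles[tag].counts(strand), rng.integers(1, L + 1, size=k)
                )

    # plateau coverage over each TU span
    cov = profiles["rnaseq"]
    for tu in truth.tu_truth:
        lo = min(tu.tss_position, tu.tep_position)
        hi = max(tu.tss_position, tu.tep_position)
        cov.counts(tu.strand)[lo - 1 : hi] += rng.poisson(
            params.coverage_depth, size=hi - lo + 1
        )
    return profiles


def simulate_dataset(params: SimParams) -> SyntheticDataset:
    """Full generation pipeline: genome -> architecture -> terminator sequence
    rewriting -> signal tracks."""
    genome = generate_genome(params)
    genes, truth = plant_architecture(params, genome)
    genome = apply_terminator_sequences(genome, truth, params)
    profiles = simulate_profiles(truth, genes, params)
    return SyntheticDataset(params, genome, genes, truth, profiles)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _write_bedgraph(path: Path, counts: np.ndarray, chrom: str) -> None:
    with open(path, "w") as fh:
        nz = np.flatnonzero(counts)
        if nz.size == 0:
            return
        run_start = nz[0]
        prev = nz[0]
        val = counts[nz[0]]
        for i in nz[1:]:
            if i == prev + 1 and counts[i] == val:
                prev = i
                continue
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{val}\n")
            run_start, prev, val = i, i, counts[i]
        fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{val}\n")


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write FASTA, GFF3, bedGraph pairs per track, and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = dataset.genome
    with open(outdir / "genome.fasta", "w") as fh:
        fh.write(f">{g.id}\n")
        for i in range(0, g.length, 70):
            fh.write(g.sequence[i : i + 70] + "\n")
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {g.id} 1 {g.length}\n")
        for gene in dataset.genes:
            fh.write(
                f"{g.id}\ttucall_sim\tCDS\t{gene.start}\t{gene.end}\t.\t"
                f"{gene.strand}\t0\tID={gene.gene_id}\n"
            )
    for tag, prof in dataset.profiles.items():
        _write_bedgraph(outdir / f"{tag}.plus.bedgraph", prof.counts_plus, g.id)
        _write_bedgraph(outdir / f"{tag}.minus.bedgraph", prof.counts_minus, g.id)
    t = dataset.truth
    pd.DataFrame([vars(x) for x in t.tss_truth]).to_csv(
        outdir / "truth_tss.tsv", sep="\t", index=False
    )
    pd.DataFrame([vars(x) for x in t.tep_truth]).to_csv(
        outdir / "truth_tep.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "tss_position": x.tss_position,
                "tep_position": x.tep_position,
                "strand": x.strand,
                "gene_ids": ",".join(x.gene_ids),
                "category": x.category,
            }
            for x in t.tu_truth
        ]
    ).to_csv(outdir / "truth_tu.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def match_positions(
    called: Sequence[tuple[int, str]],
    truth: Sequence[tuple[int, str]],
    tolerance: int,
) -> dict:
    """Greedy nearest matching of called to truth sites within a tolerance.

    Each truth site may absorb at most one call and vice versa; returns
    recall, precision and the raw counts.
    """
    unmatched_truth = {}
    for pos, strand in truth:
        unmatched_truth.setdefault(strand, []).append(pos)
    tp = 0
    for pos, strand in sorted(called):
        avail = unmatched_truth.get(strand, [])
        best = None
        for i, t in enumerate(avail):
            d = abs(t - pos)
            if d <= tolerance and (best is None or d < best[0]):
                best = (d, i)
        if best is not None:
            avail.pop(best[1])
            tp += 1
    n_called = len(called)
    n_truth = len(truth)
    return {
        "tp": tp,
        "n_called": n_called,
        "n_truth": n_truth,
        "recall": tp / n_truth if n_truth else float("nan"),
        "precision": tp / n_called if n_called else float("nan"),
    }


def match_tu_gene_lists(assembled, truth_tus: Sequence[TruthTU]) -> dict:
    """Fraction of planted TUs whose exact gene list appears among assembled TUs."""
    assembled_lists = {
        (tu.strand, tuple(tu.gene_ids)) for tu in assembled if tu.gene_ids
    }
    hits = sum(
        1
        for t in truth_tus
        if t.gene_ids and (t.strand, tuple(t.gene_ids)) in assembled_lists
    )
    n = sum(1 for t in truth_tus if t.gene_ids)
    return {"recovered": hits, "n_truth": n, "fraction": hits / n if n else float("nan")}
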