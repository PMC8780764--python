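"""Transcription start site (TSS) calling from dRNA-Seq 5'-end profiles.

dRNA-Seq compares a TAP-treated library (TAP(+), primary 5'-triphosphate ends
converted to ligatable monophosphates) with an untreated library (TAP(-)).
Genuine start sites pile up sharply in TAP(+) and are depleted in TAP(-).

The caller proceeds per strand:

1. cluster nonzero TAP(+) 5'-end positions that lie < ``max_gap`` (100 nt)
   apart;
2. sub-cluster each cluster greedily so the population standard deviation of
   member positions stays < ``sd_max`` (10);
3. keep sub-clusters whose summed read count exceeds ``min_cluster_reads``
   (3) and emit the maximum-count position of each;
4. discard emitted positions whose TAP(-) count exceeds their TAP(+) count.

Called sites are then classified against annotated ORFs as primary (P),
secondary (S), internal (I), antisense (A) or intergenic/orphan (N).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .genome_model import EndProfile, GeneAnnotation, InputError

LEADERLESS_MAX_UTR5 = 9  # 5'-UTR shorter than this => leaderless mRNA


@dataclass
class PositionCluster:
    """A run of signal positions on one strand with their read counts."""

    strand: str
    positions: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.positions.size != self.counts.size:
            raise InputError("positions/counts length mismatch")
        if self.positions.size and (np.diff(self.positions) <= 0).any():
            raise InputError("positions must be strictly increasing")

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class TSSRecord:
    position: int
    strand: str
    tap_plus_count: int
    tap_minus_count: int
    category: str = "U"
    gene_id: Optional[str] = None
    utr5_length: Optional[int] = None
    leaderless: Optional[bool] = None


def _partition_by_gap(positions: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Split sorted positions where a consecutive gap is >= max_gap."""
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) >= max_gap) + 1
    return np.split(positions, breaks)


def cluster_positions(
    profile: EndProfile, strand: str, max_gap: int = 100
) -> list[PositionCluster]:
    """Cluster nonzero positions so members are < ``max_gap`` nt apart."""
    if max_gap < 1:
        raise InputError("max_gap must be >= 1")
    positions = profile.nonzero_positions(strand)
    counts = profile.counts(strand)
    return [
        PositionCluster(strand, chunk, counts[chunk - 1])
        for chunk in _partition_by_gap(positions, max_gap)
    ]


def subcluster_by_stddev(
    cluster: PositionCluster, sd_max: float = 10.0
) -> list[PositionCluster]:
    """Greedy left-to-right sub-clustering under a position-stddev bound.

    Starting at the leftmost unassigned position, the sub-cluster is extended
    rightward as long as the population standard deviation of the member
    positions stays below ``sd_max``.
    """
    if sd_max <= 0:
        raise InputError("sd_max must be > 0")
    out: list[PositionCluster] = []
    pos, cnt = cluster.positions, cluster.counts
    i = 0
    while i < len(pos):
        j = i + 1
        while j < len(pos) and np.std(pos[i : j + 1]) < sd_max:
            j += 1
        out.append(PositionCluster(cluster.strand, pos[i:j], cnt[i:j]))
        i = j
    return out


def call_tss(
    tap_plus: EndProfile,
    tap_minus: EndProfile,
    min_cluster_reads: int = 3,
    max_gap: int = 100,
    sd_max: float = 10.0,
) -> list[TSSRecord]:
    """Call TSSs from a TAP(+)/TAP(-) profile pair; categories left unset."""
    if tap_plus.genome_id != tap_minus.genome_id:
        raise InputError(
            f"profile genome mismatch: {tap_plus.genome_id!r} vs {tap_minus.genome_id!r}"
        )
    records: list[TSSRecord] = []
    for strand in ("+", "-"):
        for cluster in cluster_positions(tap_plus, strand, max_gap=max_gap):
            for sub in subcluster_by_stddev(cluster, sd_max=sd_max):
                if sub.total <= min_cluster_reads:
                    continue
                best = sub.counts.max()
                idx = np.flatnonzero(sub.counts == best)
                # tie -> most-5' position (smallest coord on +, largest on -)
                k = idx[0] if strand == "+" else idx[-1]
                pos = int(sub.positions[k])
                plus_count = int(sub.counts[k])
                minus_count = tap_minus.count_at(pos, strand)
                if minus_count > plus_count:
                    continue
                records.append(
                    TSSRecord(
                        position=pos,
                        strand=strand,
                        tap_plus_count=plus_count,
                        tap_minus_count=minus_count,
                    )
                )
    records.sort(key=lambda r: (r.strand, r.position))
    return records


def _utr5_length(pos: int, gene: GeneAnnotation) -> int:
    """Strand-aware distance TSS -> start codon (negative if TSS is inside)."""
    if gene.strand == "+":
        return gene.start - pos
    return pos - gene.end


def classify_tss(
    tss: Sequence[TSSRecord],
    genes: Sequence[GeneAnnotation],
    up_window: int = 500,
    down_window: int = 100,
) -> list[TSSRecord]:
    """Classify called TSSs as P/S/I/A/N relative to annotated ORFs.

    A TSS within ``up_window`` nt upstream to ``down_window`` nt downstream
    of a same-strand start codon is assigned to the gene with the nearest
    start codon; per gene the highest-TAP(+) TSS is primary (P), the rest
    secondary (S).  Otherwise: inside a same-strand ORF -> internal (I);
    overlapping an opposite-strand ORF -> antisense (A); else orphan (N).
    """
    interim: list[tuple[TSSRecord, Optional[GeneAnnotation]]] = []

    for rec in tss:
        candidates = []
        for g in genes:
            if g.strand != rec.strand:
                continue
            u5 = _utr5_length(rec.position, g)
            if -down_window <= u5 <= up_window:
                candidates.append((abs(u5), g))
        if candidates:
            _, g = min(candidates, key=lambda t: (t[0], t[1].start))
            interim.append((rec, g))
        else:
            interim.append((rec, None))

    # per-gene primary/secondary by TAP(+) count; tie -> nearest start codon
    primary: dict[int, str] = {}
    by_gene: dict[str, list[TSSRecord]] = {}
    for rec, g in interim:
        if g is not None:
            by_gene.setdefault(g.gene_id, []).append(rec)
    gene_by_id = {g.gene_id: g for g in genes}
    for gid, recs in by_gene.items():
        g = gene_by_id[gid]
        best = max(
            recs, key=lambda r: (r.tap_plus_count, -abs(_utr5_length(r.position, g)))
        )
        primary[id(best)] = gid

    out: list[TSSRecord] = []
    for rec, g in interim:
        if g is not None:
            u5 = _utr5_length(rec.position, g)
            cat = "P" if id(rec) in primary else "S"
            out.append(
                replace(
                    rec,
                    category=cat,
                    gene_id=g.gene_id,
                    utr5_length=u5,
                    leaderless=(u5 < LEADERLESS_MAX_UTR5) if cat == "P" else None,
                )
            )
        elif any(
            g.strand == rec.strand and g.contains(rec.position) for g in genes
        ):
            out.append(replace(rec, category="I"))
        elif any(
            g.strand != rec.strand and g.contains(rec.position) for g in genes
        ):
            out.append(replace(rec, category="A"))
        else:
            out.append(replace(rec, category="N"))
    return out


def merge_tss_calls(*call_sets: Sequence[TSSRecord]) -> list[TSSRecord]:
    """Union-merge TSS calls from several libraries, keeping the max-count record
    at each (strand, position).  A utility for multi-condition experiments; no
    particular merging policy is claimed beyond union-with-max."""
    best: dict[tuple[str, int], TSSRecord] = {}
    for calls in call_sets:
        for rec in calls:
            key = (rec.strand, rec.position)
            if key not in best or rec.tap_plus_count > best[key].tap_plus_count:
                best[key] = rec
    return sorted(best.values(), key=lambda r: (r.strand, r.position))
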