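"""Transcript 3'-end position (TEP) calling from Term-Seq profiles.

Term-Seq captures transcript 3' termini at single-base resolution.  Within a
cluster of nearby 3'-end positions, a genuine terminus stands out as a count
spike; it is scored with a modified z-score in which the mean and standard
deviation are computed over the *other* positions of the cluster (leave-one-out
in both the first and second moment):

    mu    = mean of counts excluding the evaluated position
    mu2   = mean of squared counts excluding the evaluated position
    sigma = sqrt(mu2 - mu^2)
    Z     = (r - mu) / sigma

Candidates surviving the count and z-score filters in each biological
replicate are reconciled: for every pair of overlapping clusters across the
two replicates, the candidate with the highest replicate-summed count inside
the span intersection becomes the TEP.

TEPs are classified as primary (P), secondary (S), cis-regulatory (C, a
premature 3' end in a gene's leader, e.g. a riboswitch terminator), antisense
(A) or intergenic (N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .genome_model import EndProfile, GeneAnnotation, InputError
from .tss_caller import PositionCluster, TSSRecord, _partition_by_gap

_SIGMA_EPS = 1e-12


@dataclass
class TEPCandidate:
    position: int
    strand: str
    count: int
    zscore: float
    cluster_span: tuple[int, int]


@dataclass
class TEPRecord:
    position: int
    strand: str
    count: int
    category: str = "U"
    gene_id: Optional[str] = None
    utr3_length: Optional[int] = None
    u_rich: Optional[bool] = None


def modified_zscore(counts: Sequence[float], index: int) -> float:
    """Leave-one-out z-score of ``counts[index]`` within its cluster.

    Edge contracts: a singleton cluster scores +inf (an isolated sharp 3' end
    is inherently enriched); if the remaining positions have zero variance the
    score is +inf when the evaluated count exceeds their mean, else 0.
    """
    counts = np.asarray(counts, dtype=float)
    if not 0 <= index < counts.size:
        raise InputError(f"index {index} out of range for cluster of {counts.size}")
    if counts.size == 1:
        return math.inf
    r = counts[index]
    others = np.delete(counts, index)
    mu = others.mean()
    mu2 = (others**2).mean()
    sigma = math.sqrt(max(mu2 - mu * mu, 0.0))
    if sigma < _SIGMA_EPS:
        return math.inf if r > mu else 0.0
    return float((r - mu) / sigma)


def intergenic_mask(
    genes: Sequence[GeneAnnotation],
    genome_length: int,
    strand: str,
    invasion: int = 10,
) -> np.ndarray:
    """Boolean mask (index i <-> position i+1) of positions outside same-strand
    gene bodies, with each gene body shrunk by ``invasion`` nt at its 5' end
    (3' ends may invade that far into the downstream gene)."""
    mask = np.ones(genome_length, dtype=bool)
    for g in genes:
        if g.strand != strand:
            continue
        if g.strand == "+":
            lo, hi = min(g.start + invasion, g.end + 1), g.end
        else:
            lo, hi = g.start, max(g.end - invasion, g.start - 1)
        if lo <= hi:
            mask[lo - 1 : hi] = False
    return mask


def cluster_3prime_positions(
    profile: EndProfile,
    genes: Sequence[GeneAnnotation],
    strand: str,
    max_gap: int = 10,
    invasion: int = 10,
) -> list[PositionCluster]:
    """Cluster intergenic 3'-end positions lying < ``max_gap`` nt apart."""
    mask = intergenic_mask(genes, profile.genome_length, strand, invasion)
    counts = profile.counts(strand)
    positions = np.flatnonzero((counts > 0) & mask) + 1
    return [
        PositionCluster(strand, chunk, counts[chunk - 1])
        for chunk in _partition_by_gap(positions, max_gap)
    ]


def call_teps_single_replicate(
    profile: EndProfile,
    genes: Sequence[GeneAnnotation],
    min_reads: int = 3,
    min_z: float = 3.0,
    max_gap: int = 10,
    invasion: int = 10,
) -> list[TEPCandidate]:
    """Score every clustered position; keep count >= min_reads and Z >= min_z."""
    out: list[TEPCandidate] = []
    for strand in ("+", "-"):
        for cluster in cluster_3prime_positions(
            profile, genes, strand, max_gap=max_gap, invasion=invasion
        ):
            for i in range(len(cluster)):
                c = int(cluster.counts[i])
                if c < min_reads:
                    continue
                z = modified_zscore(cluster.counts, i)
                if z >= min_z:
                    out.append(
                        TEPCandidate(
                            position=int(cluster.positions[i]),
                            strand=strand,
                            count=c,
                            zscore=z,
                            cluster_span=cluster.span,
                        )
                    )
    return out


def span_intersection(
    span1: tuple[int, int], span2: tuple[int, int]
) -> Optional[tuple[int, int]]:
    """Intersection of two inclusive coordinate spans, or None if disjoint."""
    lo = max(span1[0], span2[0])
    hi = min(span1[1], span2[1])
    return (lo, hi) if lo <= hi else None


def reconcile_replicates(
    cands1: Sequence[TEPCandidate], cands2: Sequence[TEPCandidate]
) -> list[TEPRecord]:
    """Select reproducible TEPs from two biological replicates.

    For every pair of overlapping cluster spans (same strand), candidates
    from both replicates falling inside the span intersection are pooled and
    the position with the highest replicate-summed count is emitted (tie ->
    smaller coordinate).
    """
    out: dict[tuple[str, int], TEPRecord] = {}
    for strand in ("+", "-"):
        c1 = [c for c in cands1 if c.strand == strand]
        c2 = [c for c in cands2 if c.strand == strand]
        spans1 = sorted({c.cluster_span for c in c1})
        spans2 = sorted({c.cluster_span for c in c2})
        for s1 in spans1:
            for s2 in spans2:
                inter = span_intersection(s1, s2)
                if inter is None:
                    continue
                lo, hi = inter
                pooled: dict[int, int] = {}
                for c in c1 + c2:
                    if lo <= c.position <= hi:
                        pooled[c.position] = pooled.get(c.position, 0) + c.count
                if not pooled:
                    continue
                pos = min(pooled, key=lambda p: (-pooled[p], p))
                rec = TEPRecord(position=pos, strand=strand, count=pooled[pos])
                key = (strand, pos)
                if key not in out or rec.count > out[key].count:
                    out[key] = rec
    return sorted(out.values(), key=lambda r: (r.strand, r.position))


def _downstream_distance(pos: int, gene: GeneAnnotation) -> int:
    """Strand-aware distance stop codon -> position (positive downstream)."""
    if gene.strand == "+":
        return pos - gene.end
    return gene.start - pos


def classify_tep(
    teps: Sequence[TEPRecord],
    tss: Sequence[TSSRecord],
    genes: Sequence[GeneAnnotation],
    downstream_max: int = 500,
    min_cis_distance: int = 80,
) -> list[TEPRecord]:
    """Classify TEPs as C/P/S/A/N (in that precedence).

    C: strand-aware between a gene's primary TSS and its start codon, at
    least ``min_cis_distance`` nt from the TSS (room for a terminator
    hairpin); only the highest-count C TEP per gene is kept, the rest are
    dropped from the output.  P/S: within ``downstream_max`` nt downstream of
    a same-strand stop codon, ranked per gene by count.  A: overlapping an
    opposite-strand gene body.  N: everything else.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    primary_tss: dict[str, int] = {
        r.gene_id: r.position for r in tss if r.category == "P" and r.gene_id
    }

    cis: dict[str, list[TEPRecord]] = {}
    rest: list[TEPRecord] = []
    for rec in teps:
        cand = []
        for gid, tpos in primary_tss.items():
            g = gene_by_id[gid]
            if g.strand != rec.strand:
                continue
            if g.strand == "+":
                between = tpos <= rec.position <= g.start
                dist = rec.position - tpos
            else:
                between = g.end <= rec.position <= tpos
                dist = tpos - rec.position
            if between and dist >= min_cis_distance:
                cand.append((abs(rec.position - g.start_codon), gid))
        if cand:
            _, gid = min(cand)
            cis.setdefault(gid, []).append(rec)
        else:
            rest.append(rec)

    out: list[TEPRecord] = []
    for gid, recs in cis.items():
        best = min(recs, key=lambda r: (-r.count, r.position))
        out.append(replace(best, category="C", gene_id=gid))
        # lower-count cis-regulatory TEPs for the same gene are discarded

    by_gene: dict[str, list[tuple[int, TEPRecord]]] = {}
    unplaced: list[TEPRecord] = []
    for rec in rest:
        cand = []
        for g in genes:
            if g.strand != rec.strand:
                continue
            d = _downstream_distance(rec.position, g)
            if 0 <= d <= downstream_max:
                cand.append((d, g))
        if cand:
            d, g = min(cand, key=lambda t: (t[0], t[1].start))
            by_gene.setdefault(g.gene_id, []).append((d, rec))
        else:
            unplaced.append(rec)

    for gid, pairs in by_gene.items():
        best = min(pairs, key=lambda t: (-t[1].count, t[0]))[1]
        for d, rec in pairs:
            cat = "P" if rec is best else "S"
            out.append(replace(rec, category=cat, gene_id=gid, utr3_length=d))

    for rec in unplaced:
        if any(g.strand != rec.strand and g.contains(rec.position) for g in genes):
            out.append(replace(rec, category="A"))
        else:
            out.append(replace(rec, category="N"))

    out.sort(key=lambda r: (r.strand, r.position))
    return out
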