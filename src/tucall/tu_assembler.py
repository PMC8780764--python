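"""Transcription unit (TU) assembly from classified TSSs and TEPs.

A TU is the transcript span from one TSS to one TEP.  Gene-containing TUs are
built by walking same-strand genes downstream of a P/S/I TSS: the admissible
gene chain extends while consecutive intergenic gaps stay within
``max_intergenic`` (500 bp, the classic operon gap assumption), and every
prefix of the chain may pair with a P/S TEP lying between that prefix's last
stop codon and the next gene start.  Cis-regulatory TEPs pair only with TSSs
of their own gene (gene-less TUs).  Antisense/orphan TSSs scan a 1-kbp
downstream window: the nearest feature wins — a TEP yields a gene-less TU, a
gene start re-enters the chain rule.

TUs sharing genes are grouped into TU clusters (connected components of the
TU-gene bipartite graph).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .genome_model import EndProfile, GeneAnnotation, InputError
from .tep_caller import TEPRecord
from .tss_caller import TSSRecord

TU_CATEGORIES = ("mono_cistronic", "poly_cistronic", "cis_regulatory", "sRNA")


@dataclass
class TranscriptionUnit:
    tu_id: str
    tss_position: int
    tep_position: int
    strand: str
    gene_ids: tuple[str, ...]
    category: str = "U"


@dataclass
class TUCluster:
    cluster_id: str
    tu_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]


def _downstream(a: int, b: int, strand: str) -> bool:
    """True if b is strand-aware downstream of (or at) a."""
    return b >= a if strand == "+" else b <= a


def _gap(upstream: GeneAnnotation, downstream: GeneAnnotation) -> int:
    """Intergenic distance between two same-strand adjacent genes."""
    if upstream.strand == "+":
        return downstream.start - upstream.end
    return upstream.start - downstream.end


def _genes_downstream_of(
    genes: Sequence[GeneAnnotation], strand: str, pos: int
) -> list[GeneAnnotation]:
    """Same-strand genes whose stop codon is downstream of pos, 5'->3' order."""
    sel = [
        g
        for g in genes
        if g.strand == strand and _downstream(pos, g.stop_codon, strand)
    ]
    sel.sort(key=lambda g: g.start, reverse=(strand == "-"))
    return sel


def assemble_tus(
    tss: Sequence[TSSRecord],
    teps: Sequence[TEPRecord],
    genes: Sequence[GeneAnnotation],
    max_intergenic: int = 500,
    scan_window: int = 1000,
    variants: str = "all",
) -> list[TranscriptionUnit]:
    """Pair classified TSSs and TEPs into transcription units.

    ``variants='all'`` enumerates every admissible (TSS, TEP) pairing;
    ``'first'`` keeps only the nearest admissible TEP per chain prefix.
    """
    if variants not in ("all", "first"):
        raise InputError(f"variants must be 'all' or 'first', got {variants!r}")
    if any(r.category == "U" for r in tss) or any(r.category == "U" for r in teps):
        raise InputError("assemble_tus requires classified TSS and TEP inputs")

    tus: list[TranscriptionUnit] = []
    seen: set[tuple[str, int, int, tuple[str, ...]]] = set()

    def emit(tss_pos: int, tep_pos: int, strand: str, gene_ids: tuple[str, ...]) -> None:
        key = (strand, tss_pos, tep_pos, gene_ids)
        if key not in seen:
            seen.add(key)
            tus.append(
                TranscriptionUnit(
                    tu_id="",
                    tss_position=tss_pos,
                    tep_position=tep_pos,
                    strand=strand,
                    gene_ids=gene_ids,
                )
            )

    ps_teps = [t for t in teps if t.category in ("P", "S")]

    def chain_pairings(rec: TSSRecord, chain_start_pos: int) -> None:
        """Rule (a): prefix-chain enumeration from a TSS (or scanned gene start)."""
        strand = rec.strand
        chain = _genes_downstream_of(genes, strand, chain_start_pos)
        if not chain:
            return
        # truncate chain at the first gene-gene gap exceeding the limit
        kept = [chain[0]]
        for g in chain[1:]:
            if _gap(kept[-1], g) > max_intergenic:
                break
            kept.append(g)
        for k, gk in enumerate(kept):
            nxt = chain[k + 1] if k + 1 < len(chain) else None
            window_teps = []
            for t in ps_teps:
                if t.strand != strand:
                    continue
                if not _downstream(gk.stop_codon, t.position, strand):
                    continue
                if not _downstream(rec.position, t.position, strand):
                    continue
                if nxt is not None and not _downstream(
                    t.position, nxt.start_codon, strand
                ):
                    continue
                window_teps.append(t)
            if variants == "first" and window_teps:
                window_teps = [
                    min(window_teps, key=lambda t: abs(t.position - gk.stop_codon))
                ]
            covered = tuple(
                g.gene_id
                for g in kept[: k + 1]
                if not (rec.category == "I" and g.contains(rec.position))
            )
            for t in window_teps:
                emit(rec.position, t.position, strand, covered)

    # (a) primary/secondary/internal TSSs
    for rec in tss:
        if rec.category in ("P", "S", "I"):
            chain_pairings(rec, rec.position)

    # (b) cis-regulatory TEPs pair only with TSSs assigned to the same gene
    tss_by_gene: dict[str, list[TSSRecord]] = {}
    for rec in tss:
        if rec.gene_id:
            tss_by_gene.setdefault(rec.gene_id, []).append(rec)
    for t in teps:
        if t.category != "C" or not t.gene_id:
            continue
        for rec in tss_by_gene.get(t.gene_id, []):
            if _downstream(rec.position, t.position, rec.strand):
                emit(rec.position, t.position, rec.strand, ())

    # (c) antisense/orphan TSSs: nearest feature in the downstream scan window
    for rec in tss:
        if rec.category not in ("A", "N"):
            continue
        strand = rec.strand
        tep_dists = [
            abs(t.position - rec.position)
            for t in teps
            if t.strand == strand
            and _downstream(rec.position, t.position, strand)
            and abs(t.position - rec.position) <= scan_window
        ]
        gene_dists = [
            abs(g.start_codon - rec.position)
            for g in genes
            if g.strand == strand
            and _downstream(rec.position, g.start_codon, strand)
            and abs(g.start_codon - rec.position) <= scan_window
        ]
        d_tep = min(tep_dists, default=None)
        d_gene = min(gene_dists, default=None)
        if d_tep is not None and (d_gene is None or d_tep <= d_gene):
            tep_pos = rec.position + d_tep * (1 if strand == "+" else -1)
            emit(rec.position, tep_pos, strand, ())
        elif d_gene is not None:
            gene_pos = rec.position + d_gene * (1 if strand == "+" else -1)
            chain_pairings(rec, gene_pos)

    tus.sort(key=lambda t: (t.strand, t.tss_position, t.tep_position))
    return [replace(t, tu_id=f"TU{i + 1:04d}") for i, t in enumerate(tus)]


def classify_tu(
    tu: TranscriptionUnit,
    genes: Sequence[GeneAnnotation],
    srna_distance: int = 500,
) -> TranscriptionUnit:
    """Categorize one TU by associated gene count; gene-less TUs split into
    cis_regulatory (a same-strand gene starts < ``srna_distance`` nt
    downstream of the TSS) versus sRNA."""
    if len(tu.gene_ids) >= 2:
        return replace(tu, category="poly_cistronic")
    if len(tu.gene_ids) == 1:
        return replace(tu, category="mono_cistronic")
    dists = [
        abs(g.start_codon - tu.tss_position)
        for g in genes
        if g.strand == tu.strand
        and _downstream(tu.tss_position, g.start_codon, tu.strand)
    ]
    if dists and min(dists) < srna_distance:
        return replace(tu, category="cis_regulatory")
    return replace(tu, category="sRNA")


def classify_tus(
    tus: Sequence[TranscriptionUnit],
    genes: Sequence[GeneAnnotation],
    srna_distance: int = 500,
) -> list[TranscriptionUnit]:
    return [classify_tu(t, genes, srna_distance) for t in tus]


def cluster_tus(tus: Sequence[TranscriptionUnit]) -> list[TUCluster]:
    """Group TUs into maximal sets sharing common genes.

    Connected components of the bipartite TU-gene graph; gene-less TUs form
    singleton clusters.
    """
    graph = nx.Graph()
    for t in tus:
        graph.add_node(("tu", t.tu_id))
        for gid in t.gene_ids:
            graph.add_edge(("tu", t.tu_id), ("gene", gid))
    clusters: list[TUCluster] = []
    for comp in nx.connected_components(graph):
        tu_ids = tuple(sorted(n[1] for n in comp if n[0] == "tu"))
        gene_ids = tuple(sorted(n[1] for n in comp if n[0] == "gene"))
        clusters.append(TUCluster(cluster_id="", tu_ids=tu_ids, gene_ids=gene_ids))
    clusters.sort(key=lambda c: c.tu_ids)
    return [
        replace(c, cluster_id=f"TUC{i + 1:04d}") for i, c in enumerate(clusters)
    ]


def cluster_summary(clusters: Sequence[TUCluster]):
    """Per-cluster TU and gene counts (distribution analogues)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "n_tus": [len(c.tu_ids) for c in clusters],
            "n_genes": [len(c.gene_ids) for c in clusters],
        }
    )


def flag_low_coverage_tus(
    tus: Sequence[TranscriptionUnit],
    coverage: EndProfile,
    genes: Sequence[GeneAnnotation],
    min_fraction: float = 0.1,
) -> dict[str, bool]:
    """Coverage-continuity screen: flag a multi-gene TU when the mean RNA-Seq
    coverage over any internal intergenic gap drops below ``min_fraction`` of
    the TU's gene-body mean.  An automated stand-in for inspecting candidate
    TUs against the RNA-Seq profile."""
    gene_by_id = {g.gene_id: g for g in genes}
    flags: dict[str, bool] = {}
    for tu in tus:
        flags[tu.tu_id] = False
        if len(tu.gene_ids) < 2:
            continue
        arr = coverage.counts(tu.strand)
        chain = [gene_by_id[gid] for gid in tu.gene_ids]
        body = np.concatenate([arr[g.start - 1 : g.end] for g in chain])
        body_mean = body.mean() if body.size else 0.0
        if body_mean == 0:
            continue
        for a, b in zip(chain, chain[1:]):
            lo, hi = (a.end + 1, b.start - 1) if tu.strand == "+" else (b.end + 1, a.start - 1)
            if lo > hi:
                continue
            if arr[lo - 1 : hi].mean() < min_fraction * body_mean:
                flags[tu.tu_id] = True
                break
    return flags
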