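"""End-to-end convenience wrappers over the calling stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genome_model import EndProfile, GeneAnnotation
from .synthetic_data import SyntheticDataset
from .tep_caller import (
    TEPRecord,
    call_teps_single_replicate,
    classify_tep,
    reconcile_replicates,
)
from .tss_caller import TSSRecord, call_tss, classify_tss
from .tu_assembler import TranscriptionUnit, TUCluster, classify_tus, cluster_tus, assemble_tus


@dataclass
class PipelineResult:
    tss: list[TSSRecord]
    teps: list[TEPRecord]
    tus: list[TranscriptionUnit]
    clusters: list[TUCluster]


def call_boundaries(
    tap_plus: EndProfile,
    tap_minus: EndProfile,
    termseq_rep1: EndProfile,
    termseq_rep2: EndProfile,
    genes: Sequence[GeneAnnotation],
    **kwargs,
) -> PipelineResult:
    """Run TSS calling, TEP calling, classification, TU assembly and TU
    clustering with default parameters (override via keyword arguments
    prefixed ``tss_``, ``tep_`` or ``tu_``)."""
    tss_kw = {k[4:]: v for k, v in kwargs.items() if k.startswith("tss_")}
    tep_kw = {k[4:]: v for k, v in kwargs.items() if k.startswith("tep_")}
    tu_kw = {k[3:]: v for k, v in kwargs.items() if k.startswith("tu_")}

    tss = classify_tss(call_tss(tap_plus, tap_minus, **tss_kw), genes)
    cands1 = call_teps_single_replicate(termseq_rep1, genes, **tep_kw)
    cands2 = call_teps_single_replicate(termseq_rep2, genes, **tep_kw)
    teps = classify_tep(reconcile_replicates(cands1, cands2), tss, genes)
    tus = classify_tus(assemble_tus(tss, teps, genes, **tu_kw), genes)
    clusters = cluster_tus(tus)
    return PipelineResult(tss=tss, teps=teps, tus=tus, clusters=clusters)


def run_on_dataset(dataset: SyntheticDataset, **kwargs) -> PipelineResult:
    """Run the full boundary pipeline on a synthetic dataset."""
    p = dataset.profiles
    return call_boundaries(
        p["tap_plus"],
        p["tap_minus"],
        p["termseq_rep1"],
        p["termseq_rep2"],
        dataset.genes,
        **kwargs,
    )
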