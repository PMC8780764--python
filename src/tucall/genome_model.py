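"""Domain types and I/O for genomes, annotations, end profiles and result tables.

Coordinates are 1-based inclusive throughout the package (GFF3 convention);
BED output converts to 0-based half-open at the I/O boundary.  Strand-specific
per-base signal is held in :class:`EndProfile` as dense integer arrays, one per
strand, where array index ``i`` corresponds to genomic position ``i + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_ALPHABET = frozenset("ACGTN")
STRANDS = ("+", "-")

FIVE_PRIME = "five_prime_end"
THREE_PRIME = "three_prime_end"
COVERAGE = "coverage"


class InputError(ValueError):
    """Malformed or inconsistent input."""


class AlphabetError(InputError):
    """Sequence contains a character outside {A,C,G,T,N}."""


class BoundsError(InputError):
    """Coordinate outside the genome."""


@dataclass(frozen=True)
class Genome:
    """A single chromosome: identifier plus upper-case ACGTN sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence, start=1) if c in bad
            )
            raise AlphabetError(
                f"invalid character {self.sequence[pos - 1]!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        if start < 1 or end > self.length or start > end:
            raise BoundsError(f"window {start}..{end} outside genome of length {self.length}")
        return self.sequence[start - 1 : end]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated ORF (CDS) with 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise InputError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise BoundsError(f"gene {self.gene_id}: bad interval {self.start}..{self.end}")

    @property
    def start_codon(self) -> int:
        """Genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end

    @property
    def stop_codon(self) -> int:
        """Genomic position of the last base of the stop codon."""
        return self.end if self.strand == "+" else self.start

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class EndProfile:
    """Strand-specific per-base read counts for one library/orientation."""

    genome_id: str
    orientation: str
    library_tag: str
    counts_plus: np.ndarray
    counts_minus: np.ndarray

    def __post_init__(self) -> None:
        self.counts_plus = np.asarray(self.counts_plus, dtype=np.int64)
        self.counts_minus = np.asarray(self.counts_minus, dtype=np.int64)
        if self.counts_plus.shape != self.counts_minus.shape:
            raise InputError("plus/minus tracks differ in length")
        if (self.counts_plus < 0).any() or (self.counts_minus < 0).any():
            raise InputError("negative read count")

    @property
    def genome_length(self) -> int:
        return int(self.counts_plus.size)

    def counts(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.counts_plus
        if strand == "-":
            return self.counts_minus
        raise InputError(f"bad strand {strand!r}")

    def count_at(self, position: int, strand: str) -> int:
        if not 1 <= position <= self.genome_length:
            raise BoundsError(f"position {position} outside genome")
        return int(self.counts(strand)[position - 1])

    def nonzero_positions(self, strand: str) -> np.ndarray:
        """Sorted 1-based positions with count > 0."""
        return np.flatnonzero(self.counts(strand)) + 1

    @classmethod
    def zeros(cls, genome_id: str, length: int, orientation: str, library_tag: str) -> "EndProfile":
        return cls(
            genome_id,
            orientation,
            library_tag,
            np.zeros(length, dtype=np.int64),
            np.zeros(length, dtype=np.int64),
        )

    @classmethod
    def from_dicts(
        cls,
        genome_id: str,
        length: int,
        orientation: str,
        library_tag: str,
        plus: Optional[dict] = None,
        minus: Optional[dict] = None,
    ) -> "EndProfile":
        prof = cls.zeros(genome_id, length, orientation, library_tag)
        for mapping, arr in ((plus, prof.counts_plus), (minus, prof.counts_minus)):
            for pos, c in (mapping or {}).items():
                if not 1 <= pos <= length:
                    raise BoundsError(f"position {pos} outside genome of length {length}")
                arr[pos - 1] = c
        return prof


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genome(path, sequence_id: Optional[str] = None) -> Genome:
    """Read a FASTA genome; the first record is used unless ``sequence_id`` names one."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    if sequence_id is not None:
        matches = [r for r in records if r.id == sequence_id]
        if not matches:
            raise InputError(f"{path}: no record with id {sequence_id!r}")
        rec = matches[0]
    else:
        if len(records) > 1:
            warnings.warn(
                f"{path}: {len(records)} records; using the first ({records[0].id})",
                stacklevel=2,
            )
        rec = records[0]
    return Genome(id=rec.id, sequence=str(rec.seq).upper())


def read_annotation(path, genome: Genome) -> list[GeneAnnotation]:
    """Read CDS features (gene features only if no CDS present) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats = list(db.features_of_type("CDS"))
    if not feats:
        feats = list(db.features_of_type("gene"))
    genes: list[GeneAnnotation] = []
    for i, f in enumerate(feats):
        if f.strand not in STRANDS:
            raise InputError(f"{path}: feature {f.id or i} missing strand")
        if f.end > genome.length or f.start < 1:
            raise BoundsError(
                f"{path}: feature {f.id or i} at {f.start}..{f.end} outside "
                f"genome of length {genome.length}"
            )
        attrs = f.attributes
        gene_id = (
            (attrs.get("ID") or attrs.get("locus_tag") or attrs.get("gene_id") or [None])[0]
            or f"feature_{i + 1}"
        )
        product = (attrs.get("product") or [None])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                start=f.start,
                end=f.end,
                strand=f.strand,
                kind=f.featuretype,
                product=product,
            )
        )
    genes.sort(key=lambda g: (g.start, g.end))
    return genes


def _read_bedgraph_track(path, length: int) -> np.ndarray:
    """Expand one bedGraph file (0-based half-open) to per-base counts."""
    counts = np.zeros(length, dtype=np.int64)
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return counts
    df = df[~df["chrom"].str.startswith(("track", "browser"))]
    for s, e, v in zip(
        df["start"].astype(int), df["end"].astype(int), df["value"]
    ):
        if v < 0:
            raise InputError(f"{path}: negative value {v} in interval {s}-{e}")
        if s < 0 or e > length or s >= e:
            raise BoundsError(f"{path}: interval [{s},{e}) outside genome of length {length}")
        counts[s:e] += int(v)
    return counts


def read_end_profile(
    plus_path,
    minus_path,
    genome_length: int,
    orientation: str,
    library_tag: str,
    genome_id: str = "genome",
) -> EndProfile:
    """Read a strand pair of bedGraph files into a per-base :class:`EndProfile`.

    bedGraph intervals are 0-based half-open; interval ``[s, e)`` maps to 1-based
    positions ``s+1 .. e``.  Overlapping intervals are summed.
    """
    return EndProfile(
        genome_id=genome_id,
        orientation=orientation,
        library_tag=library_tag,
        counts_plus=_read_bedgraph_track(plus_path, genome_length),
        counts_minus=_read_bedgraph_track(minus_path, genome_length),
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

SCHEMA_TAGS = ("tss", "tep", "tu", "tu_cluster")


@dataclass
class FeatureTable:
    """An ordered table of result records with a schema tag."""

    schema_tag: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.schema_tag not in SCHEMA_TAGS:
            raise InputError(f"unknown schema_tag {self.schema_tag!r}")

    def __len__(self) -> int:
        return len(self.frame)


def _record_classes():
    # lazy to avoid circular imports
    from .tss_caller import TSSRecord
    from .tep_caller import TEPRecord
    from .tu_assembler import TranscriptionUnit, TUCluster

    return {
        "tss": TSSRecord,
        "tep": TEPRecord,
        "tu": TranscriptionUnit,
        "tu_cluster": TUCluster,
    }


_SORT_KEYS = {
    "tss": ("strand", "position"),
    "tep": ("strand", "position"),
    "tu": ("strand", "tss_position"),
    "tu_cluster": ("cluster_id",),
}

_LIST_FIELDS = {"gene_ids", "tu_ids"}


def records_to_table(records: Sequence, schema_tag: str) -> FeatureTable:
    cls = _record_classes()[schema_tag]
    cols = [f.name for f in fields(cls)]
    rows = []
    for r in records:
        row = {}
        for name in cols:
            v = getattr(r, name)
            if name in _LIST_FIELDS:
                v = ",".join(v)
            row[name] = v
        rows.append(row)
    frame = pd.DataFrame(rows, columns=cols)
    if rows:
        frame = frame.sort_values(
            list(_SORT_KEYS[schema_tag]), kind="stable"
        ).reset_index(drop=True)
    return FeatureTable(schema_tag=schema_tag, frame=frame)


def table_to_records(table: FeatureTable) -> list:
    cls = _record_classes()[table.schema_tag]
    out = []
    for _, row in table.frame.iterrows():
        kwargs = {}
        for f in fields(cls):
            v = row[f.name]
            if f.name in _LIST_FIELDS:
                v = tuple(str(v).split(",")) if isinstance(v, str) and v else ()
            elif pd.isna(v):
                v = None
            elif f.type in ("int", "Optional[int]", int):
                v = int(v)
            elif f.type in ("float", "Optional[float]", float):
                v = float(v)
            elif f.type in ("bool", "Optional[bool]", bool):
                v = bool(v) if not isinstance(v, str) else v == "True"
            kwargs[f.name] = v
        out.append(cls(**kwargs))
    return out


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a TSV (plus a BED6 companion for tss/tep schemas)."""
    path = Path(path)
    table.frame.to_csv(path, sep="\t", index=False, na_rep="")
    if table.schema_tag in ("tss", "tep") and len(table.frame):
        bed = path.with_suffix(".bed")
        with open(bed, "w") as fh:
            for _, row in table.frame.iterrows():
                pos = int(row["position"])
                name = f"{table.schema_tag}_{pos}{row['strand']}"
                score_col = "tap_plus_count" if table.schema_tag == "tss" else "count"
                fh.write(
                    f"{table.schema_tag}\t{pos - 1}\t{pos}\t{name}\t"
                    f"{int(row[score_col])}\t{row['strand']}\n"
                )


def read_feature_table(path, schema_tag: str) -> FeatureTable:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return FeatureTable(schema_tag=schema_tag, frame=frame)
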