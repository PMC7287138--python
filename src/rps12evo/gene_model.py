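"""Trans-spliced rps12 gene models: annotation I/O, splicing, partitioning.

The plastid rps12 gene is split across the genome: exon 1 sits in the large
single-copy (LSC) region while exons 2-3 reside in the inverted repeats
(IRs), present as two reverse-complementary copies.  Intron II may be absent
(intron-less "type II" alleles, vs intron-containing "type I").  This module
reads per-taxon exon annotations, splices the coding region back together
(collapsing identical IR copies), classifies codons into SC and IR partitions
and threads a protein-level alignment back onto codons.

Coordinates are 0-based half-open on the forward strand of the record;
translation uses NCBI table 11 (plastid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .subst_models import GENETIC_CODE

__all__ = [
    "ExonRecord",
    "GeneModel",
    "SplicedCDS",
    "CodonAlignment",
    "AnnotationFormatError",
    "AnnotationValidationError",
    "IRCopyMismatchError",
    "SpliceError",
    "PartitionError",
    "ThreadingError",
    "read_annotation_table",
    "write_annotation_table",
    "splice_cds",
    "partition_codons",
    "thread_protein_alignment",
]

REGIONS = ("LSC", "IR", "SSC")
ANNOTATION_COLUMNS = [
    "taxon",
    "exon_id",
    "region",
    "start",
    "end",
    "strand",
    "copy_index",
    "intron2_present",
]


class AnnotationFormatError(ValueError):
    pass


class AnnotationValidationError(ValueError):
    pass


class IRCopyMismatchError(ValueError):
    pass


class SpliceError(ValueError):
    pass


class PartitionError(ValueError):
    pass


class ThreadingError(ValueError):
    pass


@dataclass
class ExonRecord:
    taxon: str
    exon_id: int
    region: str
    start: int
    end: int
    strand: str
    copy_index: int = 1

    def __post_init__(self):
        if self.exon_id not in (1, 2, 3):
            raise AnnotationValidationError(
                f"{self.taxon}: exon_id must be 1, 2 or 3, got {self.exon_id}"
            )
        if self.region not in REGIONS:
            raise AnnotationValidationError(
                f"{self.taxon}: region must be one of {REGIONS}, got {self.region!r}"
            )
        if self.end <= self.start:
            raise AnnotationValidationError(
                f"{self.taxon} exon {self.exon_id}: end must exceed start"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(
                f"{self.taxon} exon {self.exon_id}: strand must be '+' or '-'"
            )
        if self.copy_index < 1:
            raise AnnotationValidationError(
                f"{self.taxon} exon {self.exon_id}: copy_index must be >= 1"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    taxon: str
    exons: list[ExonRecord]
    intron2_present: bool

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: (e.exon_id, e.copy_index))

    @property
    def gene_type(self) -> str:
        """'I' = intron-containing, 'II' = intron-less (intron II absent)."""
        return "I" if self.intron2_present else "II"

    @property
    def single_copy_only(self) -> bool:
        return all(e.copy_index == 1 for e in self.exons)

    def exon_ids(self) -> list[int]:
        return sorted({e.exon_id for e in self.exons})

    def exon_copies(self, exon_id: int) -> list[ExonRecord]:
        return [e for e in self.exons if e.exon_id == exon_id]


@dataclass
class SplicedCDS:
    taxon: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def length_aa(self) -> int:
        n = self.length_nt // 3
        return n - 1 if self.ends_with_stop else n

    @property
    def ends_with_stop(self) -> bool:
        return GENETIC_CODE.get(self.sequence[-3:].upper()) == "*"

    def codons(self, drop_terminal_stop: bool = False) -> list[str]:
        seq = self.sequence.upper()
        cods = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if drop_terminal_stop and cods and GENETIC_CODE.get(cods[-1]) == "*":
            cods = cods[:-1]
        return cods

    def translate(self, drop_terminal_stop: bool = True) -> str:
        aa = str(Seq(self.sequence).translate(table=11))
        if drop_terminal_stop and aa.endswith("*"):
            aa = aa[:-1]
        return aa


@dataclass
class CodonAlignment:
    """Taxa x codon-site matrix with an SC/IR partition mask."""

    taxa: list[str]
    rows: list[list[str]]  # each cell a codon or '---'
    partition: Optional[list[str]] = None  # per-codon 'SC' / 'IR'

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must have equal length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("all alignment rows must have equal codon length")
        if self.partition is not None and len(self.partition) != self.ncodons:
            raise ValueError("partition length must equal ncodons")

    @property
    def ncodons(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> list[str]:
        return self.rows[self.taxa.index(taxon)]

    def subset_taxa(self, taxa: Sequence[str]) -> "CodonAlignment":
        part = list(self.partition) if self.partition is not None else None
        return CodonAlignment(
            list(taxa), [list(self.row(t)) for t in taxa], part
        )

    def subset_partition(self, label: str) -> "CodonAlignment":
        if self.partition is None:
            raise PartitionError("alignment carries no partition labels")
        idx = [i for i, p in enumerate(self.partition) if p == label]
        return CodonAlignment(
            list(self.taxa),
            [[row[i] for i in idx] for row in self.rows],
            [label] * len(idx),
        )

    def to_nucleotides(self) -> list[str]:
        return ["".join(row) for row in self.rows]

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for taxon, row in zip(self.taxa, self.rows):
                fh.write(f">{taxon}\n{''.join(row)}\n")

    @classmethod
    def from_fasta(
        cls, path: str, partition: Optional[list[str]] = None
    ) -> "CodonAlignment":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(path, "fasta"):
            seq = str(rec.seq).upper()
            if len(seq) % 3:
                raise ValueError(f"{rec.id}: length not a multiple of 3")
            taxa.append(rec.id)
            rows.append([seq[i : i + 3] for i in range(0, len(seq), 3)])
        return cls(taxa, rows, partition)


# --------------------------------------------------------------------------
# annotation table I/O
# --------------------------------------------------------------------------


def read_annotation_table(path: str) -> list[GeneModel]:
    """Read the tab-delimited exon annotation schema into GeneModels.

    Columns: taxon, exon_id, region, start, end, strand, copy_index,
    intron2_present.  One GeneModel per taxon, exons sorted by (exon_id,
    copy_index).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"annotation table missing columns: {missing}")
    models = []
    for taxon, sub in df.groupby("taxon", sort=True):
        flags = set(_as_bool(v) for v in sub["intron2_present"])
        if len(flags) != 1:
            raise AnnotationValidationError(
                f"{taxon}: inconsistent intron2_present flags"
            )
        exons = [
            ExonRecord(
                taxon=str(taxon),
                exon_id=int(r.exon_id),
                region=str(r.region),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                copy_index=int(r.copy_index),
            )
            for r in sub.itertuples()
        ]
        models.append(GeneModel(str(taxon), exons, intron2_present=flags.pop()))
    return models


def write_annotation_table(models: Iterable[GeneModel], path: str) -> None:
    rows = []
    for gm in models:
        for e in gm.exons:
            rows.append(
                dict(
                    taxon=e.taxon,
                    exon_id=e.exon_id,
                    region=e.region,
                    start=e.start,
                    end=e.end,
                    strand=e.strand,
                    copy_index=e.copy_index,
                    intron2_present=gm.intron2_present,
                )
            )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise AnnotationValidationError(f"cannot parse boolean {v!r}")


# --------------------------------------------------------------------------
# splicing
# --------------------------------------------------------------------------

_AMBIG = set("NRYKMSWBDHV")


def splice_cds(
    record_sequence: str, gene_model: GeneModel, ir_copy: str = "error"
) -> SplicedCDS:
    """Extract and splice a CDS from a genomic record.

    Exon copies (IR duplicates) are oriented to the coding strand and
    compared; differing copies raise :class:`IRCopyMismatchError` unless
    ``ir_copy='tolerate'``, in which case the copy with fewer ambiguous bases
    wins.  The spliced CDS must be a codon multiple with no internal stop.
    """
    record = record_sequence.upper()
    parts = []
    for exon_id in gene_model.exon_ids():
        copies = []
        for exon in gene_model.exon_copies(exon_id):
            if exon.end > len(record):
                raise SpliceError(
                    f"{gene_model.taxon} exon {exon_id} copy {exon.copy_index}: "
                    f"coordinates [{exon.start},{exon.end}) exceed record length "
                    f"{len(record)}"
                )
            seg = record[exon.start : exon.end]
            if exon.strand == "-":
                seg = str(Seq(seg).reverse_complement())
            copies.append(seg)
        parts.append(_resolve_copies(gene_model.taxon, exon_id, copies, ir_copy))
    cds = "".join(parts)
    if len(cds) % 3:
        raise SpliceError(
            f"{gene_model.taxon}: spliced length {len(cds)} is not a codon multiple"
        )
    _check_internal_stops(gene_model.taxon, cds)
    return SplicedCDS(gene_model.taxon, cds)


def _resolve_copies(taxon: str, exon_id: int, copies: list[str], policy: str) -> str:
    first = copies[0]
    for other in copies[1:]:
        if other != first:
            if policy == "tolerate":
                return min(copies, key=lambda s: sum(c in _AMBIG for c in s))
            pos = next(
                (k for k, (a, b) in enumerate(zip(first, other)) if a != b),
                min(len(first), len(other)),
            )
            raise IRCopyMismatchError(
                f"{taxon} exon {exon_id}: IR copy mismatch at spliced-exon "
                f"position {pos}"
            )
    return first


def _check_internal_stops(taxon: str, cds: str) -> None:
    n = len(cds) // 3
    for k in range(n - 1):  # terminal codon may be the stop
        codon = cds[3 * k : 3 * k + 3]
        if GENETIC_CODE.get(codon) == "*":
            raise SpliceError(
                f"{taxon}: internal stop codon {codon} at codon {k + 1}"
            )


# --------------------------------------------------------------------------
# SC/IR codon partition
# --------------------------------------------------------------------------


def partition_codons(gene_model: GeneModel) -> list[str]:
    """Label each codon of the spliced CDS 'SC' (exon 1) or 'IR' (exons 2-3).

    For the standard fern rps12 layout this is codons 1-38 = SC (114 nt) and
    codons 39-123 plus the stop = IR.  Exon 1 must be a codon multiple and,
    for standard records, reside in the LSC; exons 2-3 must jointly be a
    codon multiple.
    """
    exon1 = gene_model.exon_copies(1)
    if not exon1:
        raise PartitionError(f"{gene_model.taxon}: no exon 1 in gene model")
    sc_nt = exon1[0].length
    if any(e.length != sc_nt for e in exon1):
        raise PartitionError(
            f"{gene_model.taxon}: exon 1 copies disagree in length"
        )
    rest_nt = 0
    for eid in gene_model.exon_ids():
        if eid == 1:
            continue
        copies = gene_model.exon_copies(eid)
        if any(e.length != copies[0].length for e in copies):
            raise PartitionError(
                f"{gene_model.taxon}: exon {eid} copies disagree in length"
            )
        rest_nt += copies[0].length
    if sc_nt % 3:
        raise PartitionError(
            f"{gene_model.taxon}: exon 1 length {sc_nt} is not a codon multiple "
            f"(offending exon: 1)"
        )
    if rest_nt % 3:
        raise PartitionError(
            f"{gene_model.taxon}: IR exons total {rest_nt} nt, not a codon "
            f"multiple (offending exons: {[i for i in gene_model.exon_ids() if i != 1]})"
        )
    return ["SC"] * (sc_nt // 3) + ["IR"] * (rest_nt // 3)


# --------------------------------------------------------------------------
# protein-guided threading
# --------------------------------------------------------------------------


def thread_protein_alignment(
    cds_set: Mapping[str, SplicedCDS],
    protein_alignment: Mapping[str, str],
    partition: Optional[list[str]] = None,
    max_gap_fraction: Optional[float] = None,
) -> CodonAlignment:
    """Thread CDSs onto a protein-level alignment (back-translation).

    Each CDS (terminal stop removed) must translate exactly to its ungapped
    alignment row; protein gaps become codon gaps.  Columns whose gap
    fraction exceeds ``max_gap_fraction`` are dropped when the threshold is
    set (off by default).
    """
    taxa = sorted(protein_alignment)
    if set(cds_set) < set(taxa):
        missing = sorted(set(taxa) - set(cds_set))
        raise ThreadingError(f"no CDS for aligned taxa: {missing}")
    ncols = {len(protein_alignment[t]) for t in taxa}
    if len(ncols) != 1:
        raise ThreadingError("protein alignment rows differ in length")

    rows = []
    for taxon in taxa:
        cds = cds_set[taxon]
        codons = cds.codons(drop_terminal_stop=True)
        aa_row = protein_alignment[taxon]
        translated = cds.translate(drop_terminal_stop=True)
        ungapped = aa_row.replace("-", "")
        if translated != ungapped:
            for k, (a, b) in enumerate(zip(translated, ungapped)):
                if a != b:
                    raise ThreadingError(
                        f"{taxon}: translation mismatch at residue {k + 1} "
                        f"({a} vs {b})"
                    )
            raise ThreadingError(
                f"{taxon}: translation length {len(translated)} != ungapped "
                f"alignment row length {len(ungapped)}"
            )
        out, k = [], 0
        for aa in aa_row:
            if aa == "-":
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        rows.append(out)

    aln = CodonAlignment(list(taxa), rows, partition)
    if max_gap_fraction is not None:
        keep = [
            i
            for i in range(aln.ncodons)
            if np.mean([row[i] == "---" for row in aln.rows]) <= max_gap_fraction
        ]
        part = [aln.partition[i] for i in keep] if aln.partition else None
        aln = CodonAlignment(
            aln.taxa, [[row[i] for i in keep] for row in aln.rows], part
        )
    return aln
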