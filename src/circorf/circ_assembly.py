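"""Backsplice records -> circularized spliced sequences.

Reads the backsplice TSV dialect (columns: chr, start, end, reads, symbol,
sample; one row per circRNA x sample), applies the selection filters
(sample support, length, intergenic / read-through exclusion) and extracts
the exonic sequence between the backsplice coordinates for every annotated
transcript of the host gene.

Coordinate conventions: backsplice coordinates and GTF features are 1-based
inclusive throughout this module; BED output elsewhere is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BACKSPLICE_COLUMNS = ["chr", "start", "end", "reads", "symbol", "sample"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircRNARecord:
    """A single backsplice event aggregated over samples."""

    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"
    reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.circ_id}: start {self.start} > end {self.end}"
            )

    @property
    def samples_expressed(self) -> int:
        return sum(1 for v in self.reads.values() if v > 0)

    @property
    def circ_id(self) -> str:
        return f"{self.gene}|{self.chrom}:{self.start}-{self.end}"

    @property
    def window_len(self) -> int:
        return self.end - self.start + 1


@dataclass
class CircTranscript:
    """Exonic sequence between the backsplice coordinates, transcript orientation."""

    parent: CircRNARecord
    isoform_id: str
    spliced_seq: str

    @property
    def length_nt(self) -> int:
        return len(self.spliced_seq)

    @property
    def transcript_id(self) -> str:
        return f"{self.parent.circ_id}|{self.isoform_id}"


@dataclass
class SelectionThresholds:
    min_samples: int = 40
    min_len_nt: int = 150
    exclude_intergenic: bool = True
    exclude_readthrough: bool = True

    def __post_init__(self) -> None:
        if self.min_len_nt < 3:
            raise ValueError("min_len_nt must be >= 3")


@dataclass(frozen=True)
class Rejection:
    circ_id: str
    reason: str


def read_backsplice_tsv(path: str | Path, strand_by_gene: Mapping[str, str] | None = None) -> list[CircRNARecord]:
    """Parse a backsplice TSV into records aggregated by (gene, chrom, start, end).

    The dialect is long-format: one row per circRNA per sample carrying a read
    count.  Strand is not part of the dialect; it is resolved from the
    annotation via *strand_by_gene* (default '+').
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BACKSPLICE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"backsplice TSV missing columns: {missing}")
    records: dict[tuple, CircRNARecord] = {}
    for row in df.itertuples(index=False):
        key = (row.symbol, row.chr, int(row.start), int(row.end))
        rec = records.get(key)
        if rec is None:
            strand = strand_by_gene.get(row.symbol, "+") if strand_by_gene else "+"
            rec = CircRNARecord(
                gene=row.symbol, chrom=row.chr, start=int(row.start),
                end=int(row.end), strand=strand,
            )
            records[key] = rec
        rec.reads[str(row.sample)] = rec.reads.get(str(row.sample), 0) + int(row.reads)
    return list(records.values())


def write_backsplice_tsv(records: Iterable[CircRNARecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for sample, reads in sorted(rec.reads.items()):
            rows.append((rec.chrom, rec.start, rec.end, reads, rec.gene, sample))
    pd.DataFrame(rows, columns=BACKSPLICE_COLUMNS).to_csv(path, sep="\t", index=False)


class Annotation:
    """Indexed view over a GTF: genes, transcripts and exons.

    Backed by gffutils with an in-memory sqlite database.
    """

    def __init__(self, gtf_path: str | Path):
        self.db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        self._genes: dict[str, gffutils.Feature] = {}
        for gene in self.db.features_of_type("gene"):
            self._genes[gene.attributes["gene_id"][0]] = gene

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._genes)

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def gene_strand(self, gene_id: str) -> str:
        return self._genes[gene_id].strand

    def strand_by_gene(self) -> dict[str, str]:
        return {g: f.strand for g, f in self._genes.items()}

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """gene_ids whose span overlaps [start, end] (1-based inclusive)."""
        out = []
        for gid, feat in self._genes.items():
            if feat.seqid == chrom and feat.start <= end and feat.end >= start:
                out.append(gid)
        return sorted(out)

    def transcripts_of(self, gene_id: str) -> list[str]:
        gene = self._genes[gene_id]
        return sorted(
            t.attributes["transcript_id"][0]
            for t in self.db.children(gene, featuretype="transcript")
        )

    def exons_of(self, transcript_id: str) -> list[tuple[int, int]]:
        """Exon (start, end) pairs, 1-based inclusive, sorted by start."""
        exons = [
            (e.start, e.end)
            for e in self.db.children(transcript_id, featuretype="exon")
        ]
        return sorted(exons)


def select_circrnas(
    records: Iterable[CircRNARecord],
    thresholds: SelectionThresholds,
    annotation: Annotation,
) -> tuple[list[CircRNARecord], list[Rejection]]:
    """Apply the selection filters; every rejection carries a reason.

    Filters, in order: zero expression, sample support, annotated host gene
    (intergenic/unannotated exclusion), single-gene window (read-through
    exclusion).  The spliced-length filter belongs to :func:`splice` because
    length is a property of each isoform.
    """
    retained: list[CircRNARecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        n_expr = rec.samples_expressed
        if n_expr == 0:
            rejected.append(Rejection(rec.circ_id, "no expression"))
            continue
        if n_expr < thresholds.min_samples:
            rejected.append(
                Rejection(rec.circ_id, f"samples_expressed {n_expr} < {thresholds.min_samples}")
            )
            continue
        if thresholds.exclude_intergenic and not annotation.has_gene(rec.gene):
            rejected.append(Rejection(rec.circ_id, "intergenic/unannotated"))
            continue
        if thresholds.exclude_readthrough:
            spanned = annotation.genes_overlapping(rec.chrom, rec.start, rec.end)
            others = [g for g in spanned if g != rec.gene]
            if others:
                rejected.append(
                    Rejection(rec.circ_id, f"read-through: window spans {','.join([rec.gene] + others)}")
                )
                continue
        retained.append(rec)
    return retained, rejected


def splice(
    record: CircRNARecord,
    annotation: Annotation,
    genome: Fasta,
    min_len_nt: int = 150,
) -> list[CircTranscript]:
    """Circularized spliced sequence per annotated isoform of the host gene.

    For each transcript with >= 1 exon overlapping the backsplice window,
    exon segments are clipped to [start, end] and concatenated; minus-strand
    genes are reverse-complemented (exon order reversed).  Isoforms shorter
    than *min_len_nt* are dropped.
    """
    out: list[CircTranscript] = []
    strand = record.strand
    chrom_seq = genome[record.chrom]
    for tid in annotation.transcripts_of(record.gene):
        segments: list[str] = []
        for ex_start, ex_end in annotation.exons_of(tid):
            s = max(ex_start, record.start)
            e = min(ex_end, record.end)
            if s > e:
                continue
            # pyfaidx slices are 0-based half-open
            segments.append(str(chrom_seq[s - 1 : e]).upper())
        if not segments:
            continue
        seq = "".join(segments)
        if strand == "-":
            seq = reverse_complement(seq)
        if len(seq) < min_len_nt:
            logger.debug("%s/%s: spliced length %d < %d, dropped",
                         record.circ_id, tid, len(seq), min_len_nt)
            continue
        out.append(CircTranscript(parent=record, isoform_id=tid, spliced_seq=seq))
    if not out:
        logger.warning("%s: no spliced isoform passed (no exon overlap or all too short)",
                       record.circ_id)
    return out


def write_transcript_fasta(transcripts: Iterable[CircTranscript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n{t.spliced_seq}\n")
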