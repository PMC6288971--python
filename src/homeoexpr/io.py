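"""Plain-text sequence and annotation I/O helpers (FASTA, FASTQ, GFF3, TSV)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as Phred+33 FASTQ with constant quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    with open(path) as fh:
        return [(title.split()[0], seq) for title, seq, _qual in FastqGeneralIterator(fh)]


def write_gff3(path: str | Path, features: Iterable[tuple], source: str = "homeoexpr") -> None:
    """Write (seqid, type, start, end, strand, attributes) tuples as GFF3.

    Coordinates are 1-based inclusive, matching the family-table convention.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start, end, strand, attrs in features:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attr_str}\n")
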