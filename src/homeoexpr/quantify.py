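"""Discriminative 3'-UTR read assignment and RPKPM quantification.

Coding sequences of homeologous gene copies are too similar to assign short
reads unambiguously, so quantification is anchored on the divergent 3' UTRs:
each gene contributes one UTR query, and a read is counted for a query only
when it aligns at >= 99% identity (matched bases / read length, gap-tolerant
infix alignment of the read within the query).  A candidate read must share
at least one exact word of ``word_size`` bases with the query (either
strand — libraries are unstranded).  A read whose best identity is reached by
two or more queries is discarded and logged rather than split.

Expression is normalized to RPKPM — reads per kilobase of query per million
library reads: ``matched / (query_len/1000) / (library_size/1e6)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DiscriminativeQuery:
    """A gene's 3'-UTR query used to assign reads among homeologs."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty query sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReadLibrary:
    """A single sequencing library with its design metadata."""

    library_id: str
    reads: list[tuple[str, str]]
    condition: str = ""
    replicate: int = 0

    @property
    def total_reads(self) -> int:
        return len(self.reads)


@dataclass
class AssignmentResult:
    """Read-to-query assignment outcome for one library."""

    library_id: str
    counts: dict[str, int]
    assignments: dict[str, tuple[str, float]]   # read_id -> (gene_id, identity)
    discarded: list[tuple[str, tuple[str, ...]]]  # ambiguous: read_id, tied gene_ids
    unmatched: int
    total_reads: int

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())


def extract_utr3(
    transcript_seq: str,
    cds_end_position: int,
    max_len: int = 300,
    gene_id: str = "?",
) -> DiscriminativeQuery:
    """Extract the 3' UTR downstream of the CDS, truncated to ``max_len``.

    ``cds_end_position`` is the 1-based position of the last CDS base (the
    final base of the stop codon) on the transcript.  Truncation guards
    against assembly artifacts with excessively long UTRs.
    """
    if not (0 < cds_end_position <= len(transcript_seq)):
        raise ValueError(f"{gene_id}: cds_end_position outside transcript")
    utr = transcript_seq[cds_end_position:]
    if not utr:
        raise ValueError(f"{gene_id}: transcript has no 3' UTR downstream of the CDS")
    return DiscriminativeQuery(gene_id=gene_id, sequence=utr[:max_len])


def queries_from_family(family, max_len: int = 300) -> list[DiscriminativeQuery]:
    """Build one discriminative UTR query per simulated family member."""
    return [
        extract_utr3(g.transcript, len(g.cds), max_len=max_len, gene_id=g.gene_id)
        for g in family.genes
    ]


def _words(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def match_reads(
    queries: Sequence[DiscriminativeQuery],
    library: ReadLibrary | Iterable[tuple[str, str]],
    min_identity: float = 0.99,
    word_size: int = 5,
) -> AssignmentResult:
    """Assign each read to at most one query at >= ``min_identity``.

    A read is a candidate for a query when they share at least one exact
    ``word_size``-mer on either strand; candidate identity is
    ``(read_len - edit_distance) / read_len`` under the best gap-tolerant
    infix alignment of the read (or its reverse complement) within the query.
    The read is counted for the single query with the highest identity among
    those above threshold; exact ties are discarded and logged.
    """
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    if not queries:
        raise ValueError("at least one query is required")
    ids = [q.gene_id for q in queries]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene ids among queries")

    if not isinstance(library, ReadLibrary):
        library = ReadLibrary(library_id="library", reads=list(library))

    query_words = [_words(q.sequence.upper(), word_size) for q in queries]
    query_seqs = [q.sequence.upper() for q in queries]

    counts = {gid: 0 for gid in ids}
    assignments: dict[str, tuple[str, float]] = {}
    discarded: list[tuple[str, tuple[str, ...]]] = []
    unmatched = 0
    warned_short = False

    for read_id, read_seq in library.reads:
        read_seq = read_seq.upper()
        rlen = len(read_seq)
        if rlen < 2 * word_size and not warned_short:
            warnings.warn(
                f"{library.library_id}: reads shorter than {2 * word_size} bp "
                "cannot be matched reliably", stacklevel=2)
            warned_short = True
        if rlen < word_size:
            unmatched += 1
            continue
        rc_seq = _revcomp(read_seq)
        # identity >= min_identity  <=>  edit distance <= k_max
        k_max = rlen - int(np.ceil(min_identity * rlen - 1e-9))
        fwd_words = None
        rc_words = None
        best_dist = None
        best_genes: list[str] = []
        for qi, q_words in enumerate(query_words):
            if fwd_words is None:
                fwd_words = _words(read_seq, word_size)
                rc_words = _words(rc_seq, word_size)
            dists = []
            if not q_words.isdisjoint(fwd_words):
                r = edlib.align(read_seq, query_seqs[qi], mode="HW",
                                task="distance", k=k_max)
                if r["editDistance"] >= 0:
                    dists.append(r["editDistance"])
            if not q_words.isdisjoint(rc_words):
                r = edlib.align(rc_seq, query_seqs[qi], mode="HW",
                                task="distance", k=k_max)
                if r["editDistance"] >= 0:
                    dists.append(r["editDistance"])
            if not dists:
                continue
            d = min(dists)
            if best_dist is None or d < best_dist:
                best_dist = d
                best_genes = [ids[qi]]
            elif d == best_dist:
                best_genes.append(ids[qi])
        if best_dist is None:
            unmatched += 1
        elif len(best_genes) > 1:
            discarded.append((read_id, tuple(best_genes)))
        else:
            gid = best_genes[0]
            counts[gid] += 1
            assignments[read_id] = (gid, (rlen - best_dist) / rlen)

    return AssignmentResult(
        library_id=library.library_id, counts=counts, assignments=assignments,
        discarded=discarded, unmatched=unmatched, total_reads=library.total_reads,
    )


def rpkpm(matched_reads: int, query_length: int, library_size: int) -> float:
    """Reads per kilobase of query per million library reads.

    ``matched / (query_length/1000) / (library_size/1e6)`` — normalizes for
    differing UTR query lengths and differing library sizes.
    """
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if matched_reads < 0:
        raise ValueError("matched_reads must be non-negative")
    return matched_reads / (query_length / 1_000.0) / (library_size / 1_000_000.0)


@dataclass
class ExpressionMatrix:
    """Genes x libraries RPKPM values with library metadata and audit trail."""

    values: pd.DataFrame
    counts: pd.DataFrame
    metadata: pd.DataFrame
    discard_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir) -> dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rpkpm": outdir / "expression_rpkpm.tsv",
            "counts": outdir / "matched_counts.tsv",
            "libraries": outdir / "library_metadata.tsv",
            "discards": outdir / "ambiguous_reads.tsv",
        }
        self.values.to_csv(paths["rpkpm"], sep="\t", index_label="gene")
        self.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
        self.metadata.to_csv(paths["libraries"], sep="\t", index=False)
        self.discard_log.to_csv(paths["discards"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


def quantify(
    queries: Sequence[DiscriminativeQuery],
    libraries: Sequence[ReadLibrary],
    min_identity: float = 0.99,
    word_size: int = 5,
) -> ExpressionMatrix:
    """RPKPM matrix over genes x libraries from discriminative read matching."""
    lib_ids = [lib.library_id for lib in libraries]
    if len(lib_ids) != len(set(lib_ids)):
        raise ValueError("duplicate library ids")
    gene_ids = [q.gene_id for q in queries]
    qlen = {q.gene_id: q.length for q in queries}

    count_cols = {}
    value_cols = {}
    meta_rows = []
    discard_rows = []
    for lib in libraries:
        result = match_reads(queries, lib, min_identity=min_identity, word_size=word_size)
        counts = pd.Series({gid: result.counts[gid] for gid in gene_ids})
        count_cols[lib.library_id] = counts
        value_cols[lib.library_id] = pd.Series(
            {gid: rpkpm(int(counts[gid]), qlen[gid], lib.total_reads) for gid in gene_ids}
        )
        meta_rows.append({
            "library": lib.library_id, "condition": lib.condition,
            "replicate": lib.replicate, "total_reads": lib.total_reads,
            "assigned": result.assigned, "ambiguous": len(result.discarded),
            "unmatched": result.unmatched,
        })
        for read_id, tied in result.discarded:
            discard_rows.append({"library": lib.library_id, "read_id": read_id,
                                 "tied_genes": ",".join(tied)})
    return ExpressionMatrix(
        values=pd.DataFrame(value_cols).loc[gene_ids],
        counts=pd.DataFrame(count_cols).loc[gene_ids],
        metadata=pd.DataFrame(meta_rows),
        discard_log=pd.DataFrame(discard_rows, columns=["library", "read_id", "tied_genes"]),
    )
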