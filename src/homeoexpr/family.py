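"""Gene-family data model, structural classification and identity analysis.

The family studied here is a small allopolyploid (hexaploid-wheat style) gene
family: up to three homeologous copies (A, B, D subgenomes) of each paralogous
locus, each gene with two CDS exons separated by a single intron.  Proteins
share a conserved two-transmembrane core and fall into three structural
groups:

* **Group I** — the classical short proteins (core only, ~54–57 aa);
* **Group II** — core plus a C-terminal extension of roughly 14–20 aa;
* **Group III** — core plus a long N-terminal extension of roughly 49–79 aa
  that ends in a run of five valines followed by five prolines.

This module provides exon/intron frame arithmetic, CDS translation,
alignment-based core anchoring and group classification, percent-identity
matrices, single-linkage homeolog grouping, and single-intron gene-structure
inference from a genomic/CDS sequence pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq


class FrameError(ValueError):
    """CDS length arithmetic is inconsistent with a protein-coding frame."""


class StructureError(ValueError):
    """No valid single-intron decomposition of a genomic/CDS pair exists."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class GeneLocus:
    """One annotated family member (a row of the family table).

    Coordinates are 1-based on the pseudomolecule; exon lengths are CDS only
    (UTRs excluded), so the encoded protein length is
    ``(exon1 + exon2) / 3 - 1`` (the terminal stop codon is not translated).
    """

    gene_id: str
    paralog: int
    genome: str
    chromosome: str = ""
    start_codon_pos: int = 0
    orientation: str = "+/+"
    exon1_cds_len: int = 0
    intron_len: int = 0
    exon2_cds_len: int = 0
    aa_len: int = 0
    splice_consensus: bool = True

    @property
    def cds_len(self) -> int:
        return self.exon1_cds_len + self.exon2_cds_len

    @property
    def frame_consistent(self) -> bool:
        """True when the CDS length is a whole number of codons."""
        return self.cds_len % 3 == 0 and self.cds_len >= 6

    @property
    def aa_consistent(self) -> bool:
        """True when the printed protein length matches the frame arithmetic."""
        return (
            self.frame_consistent
            and self.aa_len == protein_length_from_exons(self.exon1_cds_len, self.exon2_cds_len)
        )


@dataclass
class ProteinRecord:
    """A translated product with its core anchoring and structural group."""

    gene_id: str
    sequence: str
    core_start: int = 0          # 0-based, inclusive
    core_end: int = 0            # 0-based, exclusive
    group: str = ""

    @property
    def n_ext_len(self) -> int:
        return self.core_start

    @property
    def c_ext_len(self) -> int:
        return len(self.sequence) - self.core_end


def protein_length_from_exons(exon1_cds_len: int, exon2_cds_len: int) -> int:
    """Protein length (residues) encoded by two CDS exon lengths.

    The exon lengths cover the CDS including the stop codon, so the protein
    has ``(exon1 + exon2)/3 - 1`` residues.

    Raises
    ------
    FrameError
        If the summed CDS length is not a positive multiple of three codons.
    """
    total = exon1_cds_len + exon2_cds_len
    if total % 3 != 0 or total < 6:
        raise FrameError(
            f"CDS of {exon1_cds_len}+{exon2_cds_len}={total} bp is not a whole "
            "number of codons (plus stop)"
        )
    return total // 3 - 1


def translate_cds(nt_sequence: str, gene_id: str = "?") -> str:
    """Translate a complete CDS (ATG...stop) with the standard genetic code.

    Rejects sequences that are out of frame, lack a start or terminal stop,
    or contain internal stop codons.
    """
    seq = nt_sequence.upper()
    if len(seq) % 3 != 0 or len(seq) < 6:
        raise FrameError(f"{gene_id}: CDS length {len(seq)} is not a whole number of codons")
    if not seq.startswith("ATG"):
        raise FrameError(f"{gene_id}: CDS does not start with ATG")
    if seq[-3:] not in standard_dna_table.stop_codons:
        raise FrameError(f"{gene_id}: CDS does not end with a stop codon")
    protein = str(Seq(seq[:-3]).translate(table="Standard"))
    if "*" in protein:
        raise FrameError(f"{gene_id}: internal stop codon at residue {protein.index('*') + 1}")
    return protein


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

def _identity_aligner() -> Align.PairwiseAligner:
    # Global alignment, terminal gaps free; match 1 / mismatch 0,
    # gap open -2 / extend -1.  Identity convention documented in docs/methods.md.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_internal_gap_score = -2.0
    aligner.extend_internal_gap_score = -1.0
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


_ALIGNER = _identity_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of a global alignment with free terminal gaps.

    Identity is matched columns / aligned columns, where aligned columns run
    from the first to the last column in which both sequences participate
    (terminal-gap columns excluded, internal gaps counted).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot compute identity of an empty sequence")
    if seq_a == seq_b:
        return 100.0
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return 0.0
    matches = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)
        seg_a = seq_a[a0:a1]
        seg_b = seq_b[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        columns += a1 - a0
        prev_a_end, prev_b_end = a1, b1
    return 100.0 * matches / columns


def build_identity_matrix(
    records: Mapping[str, str] | Sequence[tuple[str, str]],
    core_spans: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Symmetric percent-identity matrix over a set of sequences.

    Parameters
    ----------
    records
        Mapping (or id/sequence pairs) of sequences; nucleotide or amino acid.
    core_spans
        Optional per-id ``(start, end)`` 0-based spans; when given, identities
        are computed over the core region only (the convention used when
        comparing paralogs whose terminal extensions differ).
    """
    items = list(records.items()) if isinstance(records, Mapping) else list(records)
    ids = [gid for gid, _ in items]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids in identity matrix input")
    if len(ids) < 2:
        raise ValueError("need at least two records")
    seqs = {}
    for gid, seq in items:
        if core_spans is not None:
            s, e = core_spans[gid]
            seq = seq[s:e]
        seqs[gid] = seq
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i, gi in enumerate(ids):
        for gj in ids[i + 1:]:
            ident = pairwise_identity(seqs[gi], seqs[gj])
            mat.loc[gi, gj] = ident
            mat.loc[gj, gi] = ident
    return mat


# ---------------------------------------------------------------------------
# core anchoring and structural groups
# ---------------------------------------------------------------------------

def _core_aligner() -> Align.PairwiseAligner:
    # Smith-Waterman with BLOSUM62: robust core location down to ~40-50%
    # amino-acid identity, where unit match/mismatch scores fragment.
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_CORE_ALIGNER = _core_aligner()


def locate_core(sequence: str, core_reference: str, min_score_fraction: float = 0.2
                ) -> tuple[int, int]:
    """Locate the conserved core within a protein by local alignment.

    Returns the 0-based ``(start, end)`` span of the core in ``sequence``.

    Raises
    ------
    ValueError
        If the best local alignment scores below ``min_score_fraction`` of
        the core reference's self-alignment score (no alignable core →
        unclassifiable).
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    alignment = _CORE_ALIGNER.align(sequence, core_reference)[0]
    self_score = _CORE_ALIGNER.score(core_reference, core_reference)
    if alignment.score < min_score_fraction * self_score:
        raise ValueError("no alignable core region")
    blocks = alignment.aligned[0]
    return int(blocks[0][0]), int(blocks[-1][1])


def classify_group(
    sequence: str,
    core_reference: str,
    n_ext_threshold: int = 25,
    c_ext_threshold: int = 10,
) -> ProteinRecord:
    """Assign a protein to structural Group I, II or III.

    A long N-terminal extension (≥ ``n_ext_threshold`` residues ahead of the
    aligned core) defines Group III; otherwise a C-terminal extension
    (≥ ``c_ext_threshold`` residues past the core) defines Group II; otherwise
    Group I.  Thresholds are midpoints separating the observed extension
    ranges (Group II C-extensions 14–20 aa, Group III N-extensions 49–79 aa,
    Group I none).
    """
    start, end = locate_core(sequence, core_reference)
    n_ext = start
    c_ext = len(sequence) - end
    if n_ext >= n_ext_threshold:
        group = "III"
    elif c_ext >= c_ext_threshold:
        group = "II"
    else:
        group = "I"
    return ProteinRecord(gene_id="", sequence=sequence,
                         core_start=start, core_end=end, group=group)


def core_consensus(sequences: Iterable[str]) -> str:
    """Column-majority consensus of equal-length core proteins (ties → first)."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences for consensus")
    if len({len(s) for s in seqs}) != 1:
        # fall back to the most common length
        from collections import Counter
        target = Counter(len(s) for s in seqs).most_common(1)[0][0]
        seqs = [s for s in seqs if len(s) == target]
    cols = []
    for i in range(len(seqs[0])):
        col = [s[i] for s in seqs]
        best = max(dict.fromkeys(col), key=col.count)
        cols.append(best)
    return "".join(cols)


# ---------------------------------------------------------------------------
# homeolog grouping
# ---------------------------------------------------------------------------

@dataclass
class ParalogGroup:
    """One cluster of putative homeologs with its genome composition."""

    members: list[str]
    genomes: dict[str, str]                     # gene_id -> genome label
    missing_genomes: list[str] = field(default_factory=list)
    duplicated_genomes: list[str] = field(default_factory=list)


def group_family(
    records: Mapping[str, str],
    genome_of: Mapping[str, str],
    homeolog_min_identity: float = 95.0,
    expected_genomes: Sequence[str] = ("A", "B", "D"),
    identity_matrix: pd.DataFrame | None = None,
) -> list[ParalogGroup]:
    """Cluster amino-acid records into paralogous groups of homeologs.

    Single-linkage clustering at ``homeolog_min_identity`` percent amino-acid
    identity.  Each cluster reports which expected genomes are absent; a
    genome represented more than once in a cluster is flagged (warning-level),
    not an error.
    """
    ids = list(records)
    if len(ids) == 1:
        gid = ids[0]
        genome = genome_of.get(gid, "?")
        return [ParalogGroup([gid], {gid: genome},
                             [g for g in expected_genomes if g != genome])]
    if identity_matrix is None:
        identity_matrix = build_identity_matrix(records)
    parent = {gid: gid for gid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, gi in enumerate(ids):
        for gj in ids[i + 1:]:
            if identity_matrix.loc[gi, gj] >= homeolog_min_identity:
                parent[find(gi)] = find(gj)

    clusters: dict[str, list[str]] = {}
    for gid in ids:
        clusters.setdefault(find(gid), []).append(gid)

    groups = []
    for members in clusters.values():
        members = sorted(members)
        genomes = {gid: genome_of.get(gid, "?") for gid in members}
        present = list(genomes.values())
        missing = [g for g in expected_genomes if g not in present]
        duplicated = sorted({g for g in present if present.count(g) > 1})
        groups.append(ParalogGroup(members, genomes, missing, duplicated))
    groups.sort(key=lambda g: g.members[0])
    return groups


# ---------------------------------------------------------------------------
# single-intron gene-structure inference
# ---------------------------------------------------------------------------

def infer_gene_structure(genomic_seq: str, cds_seq: str
                         ) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int], bool]:
    """Recover exon/intron boundaries of a two-exon, one-intron gene.

    The genomic sequence must equal the CDS with exactly one contiguous
    interior segment (the intron) inserted.  Returns 1-based inclusive
    ``(exon1, intron, exon2)`` intervals on the genomic sequence and a flag
    that is True when the intron has consensus GT..AG termini.  Among multiple
    valid decompositions, the leftmost GT..AG split is preferred; if no
    consensus split exists, the leftmost valid split is returned with the
    flag False.
    """
    genomic = genomic_seq.upper()
    cds = cds_seq.upper()
    intron_len = len(genomic) - len(cds)
    if intron_len <= 0:
        raise StructureError("genomic sequence is not longer than the CDS")

    # valid split points k (exon1 length): genomic[:k] == cds[:k] and
    # genomic[k+intron_len:] == cds[k:]; k ranges over the overlap of the
    # common prefix and common suffix, interior only (both exons non-empty).
    lcp = 0
    while lcp < len(cds) and genomic[lcp] == cds[lcp]:
        lcp += 1
    lcs = 0
    while lcs < len(cds) and genomic[len(genomic) - 1 - lcs] == cds[len(cds) - 1 - lcs]:
        lcs += 1
    k_lo = max(1, len(cds) - lcs)
    k_hi = min(lcp, len(cds) - 1)
    if k_lo > k_hi:
        raise StructureError("no single-intron decomposition of genomic vs CDS")

    chosen = None
    for k in range(k_lo, k_hi + 1):
        intron = genomic[k:k + intron_len]
        if intron.startswith("GT") and intron.endswith("AG"):
            chosen, consensus = k, True
            break
    if chosen is None:
        chosen, consensus = k_lo, False
    k = chosen
    exon1 = (1, k)
    intron_iv = (k + 1, k + intron_len)
    exon2 = (k + intron_len + 1, len(genomic))
    return exon1, intron_iv, exon2, consensus


# ---------------------------------------------------------------------------
# family table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["gene", "paralog", "genome", "chromosome", "start_codon",
                  "orientation", "exon1", "intron", "exon2", "aa", "splice_consensus"]


def loci_to_table(loci: Iterable[GeneLocus]) -> pd.DataFrame:
    rows = [
        {
            "gene": l.gene_id, "paralog": l.paralog, "genome": l.genome,
            "chromosome": l.chromosome, "start_codon": l.start_codon_pos,
            "orientation": l.orientation, "exon1": l.exon1_cds_len,
            "intron": l.intron_len, "exon2": l.exon2_cds_len, "aa": l.aa_len,
            "splice_consensus": l.splice_consensus,
        }
        for l in loci
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def table_to_loci(table: pd.DataFrame) -> list[GeneLocus]:
    return [
        GeneLocus(
            gene_id=str(row["gene"]), paralog=int(row["paralog"]),
            genome=str(row["genome"]), chromosome=str(row["chromosome"]),
            start_codon_pos=int(row["start_codon"]), orientation=str(row["orientation"]),
            exon1_cds_len=int(row["exon1"]), intron_len=int(row["intron"]),
            exon2_cds_len=int(row["exon2"]), aa_len=int(row["aa"]),
            splice_consensus=bool(row["splice_consensus"]),
        )
        for _, row in table.iterrows()
    ]
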