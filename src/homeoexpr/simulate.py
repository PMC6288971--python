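"""Synthetic allopolyploid gene families and RNA-seq read libraries.

The generator emulates the structure of a small hexaploid-wheat-style gene
family so that the downstream analysis (homeolog classification, 3'-UTR read
assignment, RPKPM quantification, ANOVA) can be exercised with known ground
truth:

* ten paralogous groups by default, each with homeologous copies in the A, B
  and D subgenomes (one homeolog deliberately absent, mirroring a real family
  in which one B copy was lost);
* a shared two-transmembrane core protein per family, diverged between
  paralogs (core nucleotide identity falling in a configured 62-95% band) and
  only lightly diverged between homeologs (amino-acid identity controlled to
  a 95-100% target);
* Group I/II/III terminal-extension architecture — Group II genes carry
  C-terminal extensions of 14-20 aa, Group III genes carry N-terminal
  extensions of 49-79 aa ending in five valines followed by five prolines;
* one intron per gene with GT..AG termini, placed so that the exon/intron
  boundaries are exactly recoverable from the genomic/CDS pair;
* divergent 3' UTRs (default 10% substitutions/site between homeolog UTRs)
  so that short reads can be assigned to a single homeolog at a 99% identity
  threshold even though the coding regions cannot discriminate;
* unstranded, error-bearing single-end reads drawn multinomially from the
  spliced transcripts, with full per-read provenance.

Divergence model: i.i.d. substitutions from a shared ancestor per paralog
group; no indels inside the CDS (this keeps homeolog identity analytically
controllable: each copy receives k disjoint non-synonymous substitutions, so
a pairwise amino-acid identity of exactly 1 - 2k/L is realized).  All
randomness flows from a single root seed; per-library streams are derived
from (seed, library index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .family import GeneLocus, infer_gene_structure, translate_cds
from .io import write_fasta, write_fastq, write_gff3

_BASES = np.array(list("ACGT"))
_MOTIF = "VVVVVPPPPP"  # junction run at the Group III extension/core boundary

# codon table (standard code) keyed by amino acid, stops excluded
_CODONS: dict[str, list[str]] = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            from Bio.Seq import Seq as _Seq

            _codon = _c1 + _c2 + _c3
            _aa = str(_Seq(_codon).translate())
            if _aa != "*":
                _CODONS.setdefault(_aa, []).append(_codon)

# residue pools: the core is strongly hydrophobic (two transmembrane helices);
# terminal extensions are hydrophobic with charged residues interspersed
_CORE_POOL = list("AVLIFGMWSTPCAVLIFG")
_EXT_POOL = list("AVLIFGSTPKRDEAVLIG")


class SimulationError(ValueError):
    """A configured identity target or weight set cannot be realized."""


@dataclass
class SimConfig:
    """Parameters of the synthetic family and read generator.

    Defaults are the study conditions the analysis assumes: ten paralogous
    groups across the A/B/D genomes with the B copy of paralog 2 absent,
    300-bp 3' UTRs diverging at 10%/site between homeologs, 100-bp unstranded
    reads with 0.5% substitution errors.
    """

    n_paralog_groups: int = 10
    genomes: tuple[str, ...] = ("A", "B", "D")
    homeolog_aa_identity_target: float | Mapping[int, float] = 97.0
    paralog_core_nt_identity_range: tuple[float, float] = (62.0, 95.0)
    core_aa_len: int = 54
    utr3_length: int = 300
    utr3_divergence: float = 0.10
    homeolog_syn_rate: float = 0.02
    intron_length_range: tuple[int, int] = (90, 200)
    group_assignment: Mapping[int, str] | None = None
    group2_cext_aa: tuple[int, int] = (14, 20)
    group3_next_aa: tuple[int, int] = (49, 79)
    missing_homeologs: tuple[tuple[int, str], ...] = ((2, "B"),)
    read_length: int = 100
    error_rate: float = 0.005
    library_sizes: int | Mapping[str, int] = 100_000
    expression_profiles: Mapping[str, Mapping[str, float]] | None = None
    n_replicates: int = 3
    replicate_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.utr3_length:
            raise SimulationError("read_length must not exceed utr3_length")
        if not (0 <= self.utr3_divergence < 1):
            raise SimulationError("utr3_divergence must be in [0, 1)")
        if not (0 <= self.error_rate < 1):
            raise SimulationError("error_rate must be in [0, 1)")
        lo, hi = self.paralog_core_nt_identity_range
        if not (0 < lo <= hi <= 100):
            raise SimulationError("paralog_core_nt_identity_range must be within (0, 100]")

    def group_of(self, paralog: int) -> str:
        """Structural group of a paralog (default mirrors the wheat family)."""
        if self.group_assignment is not None:
            return self.group_assignment.get(paralog, "I")
        if paralog == 9:
            return "III"
        if paralog in (3, 6, 7, 10):
            return "II"
        return "I"

    def homeolog_target(self, paralog: int) -> float:
        t = self.homeolog_aa_identity_target
        if isinstance(t, Mapping):
            t = t.get(paralog, 97.0)
        t = float(t)
        if not (0 < t <= 100):
            raise SimulationError(f"homeolog identity target {t} out of (0, 100]")
        return t


@dataclass
class SimulatedGene:
    """One simulated family member with its full structure."""

    gene_id: str
    paralog: int
    genome: str
    group: str
    cds: str                    # full CDS including stop codon
    intron: str
    intron_pos: int             # exon1 CDS length (bp before the intron)
    utr3: str
    core_start: int             # 0-based residue span of the conserved core
    core_end: int

    @property
    def protein(self) -> str:
        return translate_cds(self.cds, self.gene_id)

    @property
    def genomic(self) -> str:
        return self.cds[: self.intron_pos] + self.intron + self.cds[self.intron_pos:]

    @property
    def transcript(self) -> str:
        return self.cds + self.utr3

    def to_locus(self) -> GeneLocus:
        return GeneLocus(
            gene_id=self.gene_id, paralog=self.paralog, genome=self.genome,
            exon1_cds_len=self.intron_pos, intron_len=len(self.intron),
            exon2_cds_len=len(self.cds) - self.intron_pos,
            aa_len=len(self.cds) // 3 - 1, splice_consensus=True,
        )


@dataclass
class FamilyBundle:
    """A simulated family plus the reference core used for classification."""

    genes: list[SimulatedGene]
    core_reference: str
    config: SimConfig

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> dict[str, SimulatedGene]:
        return {g.gene_id: g for g in self.genes}

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}

    def cds_seqs(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.genes}

    def genomic_seqs(self) -> dict[str, str]:
        return {g.gene_id: g.genomic for g in self.genes}

    def utr_seqs(self) -> dict[str, str]:
        return {g.gene_id: g.utr3 for g in self.genes}

    def transcripts(self) -> dict[str, str]:
        return {g.gene_id: g.transcript for g in self.genes}

    def genome_of(self) -> dict[str, str]:
        return {g.gene_id: g.genome for g in self.genes}

    def core_spans(self) -> dict[str, tuple[int, int]]:
        return {g.gene_id: (g.core_start, g.core_end) for g in self.genes}

    def loci(self) -> list[GeneLocus]:
        return [g.to_locus() for g in self.genes]

    def gff3_features(self) -> list[tuple]:
        feats = []
        for g in self.genes:
            k, ilen, glen = g.intron_pos, len(g.intron), len(g.genomic)
            feats.append((g.gene_id, "gene", 1, glen, "+", {"ID": g.gene_id}))
            feats.append((g.gene_id, "exon", 1, k, "+", {"Parent": g.gene_id, "ID": f"{g.gene_id}.e1"}))
            feats.append((g.gene_id, "intron", k + 1, k + ilen, "+", {"Parent": g.gene_id}))
            feats.append((g.gene_id, "exon", k + ilen + 1, glen, "+", {"Parent": g.gene_id, "ID": f"{g.gene_id}.e2"}))
        return feats

    def write(self, outdir) -> dict[str, str]:
        """Write the family bundle as FASTA/GFF3 files; returns paths."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genomic": outdir / "family_genomic.fasta",
            "cds": outdir / "family_cds.fasta",
            "utr3": outdir / "family_utr3.fasta",
            "protein": outdir / "family_protein.fasta",
            "gff3": outdir / "family_structure.gff3",
        }
        write_fasta(paths["genomic"], self.genomic_seqs())
        write_fasta(paths["cds"], self.cds_seqs())
        write_fasta(paths["utr3"], self.utr_seqs())
        write_fasta(paths["protein"], self.proteins())
        write_gff3(paths["gff3"], self.gff3_features())
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int, pool: Sequence[str]) -> str:
    return "".join(rng.choice(list(pool), size=length))


def _protein_to_cds(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> str:
    """I.i.d. substitutions at the given per-site rate (always to a new base)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _mutate_cds_nt(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Substitute CDS sites i.i.d., resampling any codon that becomes a stop.

    The ATG start is never touched.  The input has no stop codon.
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for ci in range(1, len(codons)):
        codon = list(codons[ci])
        for p in range(3):
            if rng.random() < rate:
                codon[p] = [b for b in "ACGT" if b != codon[p]][rng.integers(3)]
        attempt = "".join(codon)
        while _CODON_AA[attempt] == "*":
            p = int(rng.integers(3))
            codon[p] = [b for b in "ACGT" if b != codon[p]][rng.integers(3)]
            attempt = "".join(codon)
        codons[ci] = attempt
    return "".join(codons)


_CODON_AA = {}
for _aa, _clist in _CODONS.items():
    for _codon in _clist:
        _CODON_AA[_codon] = _aa
for _stop in ("TAA", "TAG", "TGA"):
    _CODON_AA[_stop] = "*"


def _nonsyn_substitute(rng: np.random.Generator, codon: str) -> str:
    """A single-nucleotide change producing a different, non-stop amino acid."""
    aa = _CODON_AA[codon]
    while True:
        p = int(rng.integers(3))
        b = "ACGT"[int(rng.integers(4))]
        if b == codon[p]:
            continue
        new = codon[:p] + b + codon[p + 1:]
        if _CODON_AA[new] not in ("*", aa):
            return new


def _syn_substitute(rng: np.random.Generator, codon: str) -> str | None:
    """A single-nucleotide synonymous change, or None if the codon has none."""
    aa = _CODON_AA[codon]
    options = []
    for p in range(3):
        for b in "ACGT":
            if b == codon[p]:
                continue
            new = codon[:p] + b + codon[p + 1:]
            if _CODON_AA[new] == aa:
                options.append(new)
    if not options:
        return None
    return options[int(rng.integers(len(options)))]


def _nonsyn_count_for_target(length_aa: int, target_pct: float, paralog: int) -> int:
    """Substitutions per homeolog copy realizing a pairwise identity target.

    Two copies carrying k disjoint substitutions each are 100*(1 - 2k/L)
    percent identical.  Fails explicitly when no integer k lands within
    2 percentage points of the target.
    """
    desired = length_aa * (1 - target_pct / 100.0) / 2.0
    k = int(round(desired))
    achieved = 100.0 * (1 - 2 * k / length_aa)
    if abs(achieved - target_pct) > 2.0:
        raise SimulationError(
            f"paralog group {paralog}: homeolog identity target {target_pct}% "
            f"unreachable with protein length {length_aa} (closest {achieved:.1f}%)"
        )
    return k


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

def simulate_family(config: SimConfig) -> FamilyBundle:
    """Generate the gene family bundle described by ``config``.

    One ancestral core CDS is generated for the whole family and diverged per
    paralog group into the configured nucleotide-identity band; Group II/III
    paralogs then gain terminal extensions; homeologous copies receive
    controlled amino-acid substitutions (disjoint between copies, so the
    pairwise identity target is hit within rounding), synonymous-only
    nucleotide noise, an individual GT..AG intron and a diverged 3' UTR.
    Configured missing homeologs are omitted.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.paralog_core_nt_identity_range
    # per-paralog nt divergence from the family root; pairwise paralog
    # identity is then roughly 1 - (r_i + r_j), spanning the configured band
    r_lo = (100.0 - hi) / 100.0 / 2.0
    r_hi = (100.0 - lo) / 100.0 / 2.0

    root_core_protein = "M" + _random_protein(rng, config.core_aa_len - 1, _CORE_POOL)
    root_core_cds = "ATG" + _protein_to_cds(rng, root_core_protein[1:])

    missing = set(config.missing_homeologs)
    genes: list[SimulatedGene] = []

    for paralog in range(1, config.n_paralog_groups + 1):
        group = config.group_of(paralog)
        r_p = float(rng.uniform(r_lo, r_hi))
        core_cds = _mutate_cds_nt(rng, root_core_cds, r_p)

        # paralog-level terminal extensions (shared by the homeologs)
        next_len = 0
        cext_len = 0
        ext_n_cds = ""
        ext_c_cds = ""
        if group == "II":
            cext_len = int(rng.integers(config.group2_cext_aa[0], config.group2_cext_aa[1] + 1))
            ext_c_cds = _protein_to_cds(rng, _random_protein(rng, cext_len, _EXT_POOL))
        elif group == "III":
            next_len = int(rng.integers(config.group3_next_aa[0], config.group3_next_aa[1] + 1))
            body = _random_protein(rng, next_len - 1 - len(_MOTIF), _EXT_POOL)
            ext_protein = "M" + body + _MOTIF
            ext_n_cds = "ATG" + _protein_to_cds(rng, ext_protein[1:])

        if group == "III":
            paralog_cds = ext_n_cds + core_cds + ext_c_cds
            core_start = next_len
        else:
            paralog_cds = core_cds + ext_c_cds
            core_start = 0
        core_end = core_start + config.core_aa_len
        n_codons = len(paralog_cds) // 3
        length_aa = n_codons

        target = config.homeolog_target(paralog)
        k = _nonsyn_count_for_target(length_aa, target, paralog)

        # codon indices eligible for non-synonymous divergence: not the start
        # codon and not the valine/proline junction run of Group III genes
        protected = set(range(1)) | (
            set(range(next_len - len(_MOTIF), next_len)) if group == "III" else set()
        )
        eligible = [i for i in range(1, n_codons) if i not in protected]
        present = [g for g in config.genomes if (paralog, g) not in missing]
        if k * len(present) > len(eligible):
            raise SimulationError(
                f"paralog group {paralog}: identity target {target}% needs "
                f"{k * len(present)} substitution sites but only {len(eligible)} are eligible"
            )
        chosen = rng.choice(len(eligible), size=k * len(present), replace=False)
        site_sets = [
            [eligible[int(chosen[c])] for c in range(gi * k, (gi + 1) * k)]
            for gi in range(len(present))
        ]

        ancestral_utr = _random_dna(rng, config.utr3_length)
        stop_codon = ("TAA", "TGA", "TAG")[int(rng.integers(3))]

        for gi, genome in enumerate(present):
            codons = [paralog_cds[i:i + 3] for i in range(0, len(paralog_cds), 3)]
            for ci in site_sets[gi]:
                codons[ci] = _nonsyn_substitute(rng, codons[ci])
            # synonymous-only nucleotide noise between homeologs
            n_syn = int(round(config.homeolog_syn_rate * n_codons))
            tries = 0
            applied = 0
            while applied < n_syn and tries < 20 * n_codons:
                tries += 1
                ci = int(rng.integers(1, n_codons))
                new = _syn_substitute(rng, codons[ci])
                if new is not None and new != codons[ci]:
                    codons[ci] = new
                    applied += 1
            cds = "".join(codons) + stop_codon

            utr3 = _mutate_dna(rng, ancestral_utr, config.utr3_divergence / 2.0)
            gene_id = f"g{paralog}-{genome}"
            gene = _add_intron(rng, gene_id, paralog, genome, group, cds,
                               utr3, core_start, core_end, config)
            genes.append(gene)

    return FamilyBundle(genes=genes, core_reference=root_core_protein, config=config)


def _add_intron(rng, gene_id, paralog, genome, group, cds, utr3,
                core_start, core_end, config: SimConfig) -> SimulatedGene:
    """Place one GT..AG intron so its boundaries are exactly recoverable.

    The leftmost-GT..AG tie-break of the structure-inference routine must
    select the true split; intron position/sequence are resampled until the
    round trip is exact (a handful of tries at most in practice).
    """
    lo, hi = config.intron_length_range
    for _attempt in range(200):
        intron_len = int(rng.integers(lo, hi + 1))
        margin = min(30, len(cds) // 3)
        intron_pos = int(rng.integers(margin, len(cds) - margin))
        intron = "GT" + _random_dna(rng, intron_len - 4) + "AG"
        gene = SimulatedGene(
            gene_id=gene_id, paralog=paralog, genome=genome, group=group,
            cds=cds, intron=intron, intron_pos=intron_pos, utr3=utr3,
            core_start=core_start, core_end=core_end,
        )
        exon1, intron_iv, _exon2, consensus = infer_gene_structure(gene.genomic, cds)
        if consensus and exon1[1] == intron_pos:
            return gene
    raise SimulationError(f"{gene_id}: could not place a uniquely recoverable intron")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimTruth:
    """Ground truth emitted by the read simulator."""

    reads: pd.DataFrame       # read_id, library, gene, start, strand, n_errors
    counts: pd.DataFrame      # genes x libraries, true source-read counts

    def write(self, path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)


@dataclass
class ReadSimResult:
    libraries: dict[str, list[tuple[str, str]]]
    truth: SimTruth

    def write(self, outdir) -> dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for lib_id, reads in self.libraries.items():
            p = outdir / f"{lib_id}.fastq"
            write_fastq(p, reads)
            paths[lib_id] = str(p)
        tp = outdir / "read_truth.tsv"
        self.truth.write(tp)
        paths["truth"] = str(tp)
        return paths


def expression_design(
    family: FamilyBundle,
    config: SimConfig,
) -> tuple[dict[str, dict[str, float]], pd.DataFrame]:
    """Expand per-condition expression profiles into per-library weights.

    Profiles map condition -> gene (or paralog id as string) -> mean weight.
    Each replicate library receives log-normal multiplicative noise of scale
    ``replicate_sigma`` per gene, emulating biological replicates.  Returns
    (weights per library, library metadata table).
    """
    gene_ids = [g.gene_id for g in family.genes]
    profiles = config.expression_profiles
    if profiles is None:
        # default: all genes at weight 1 in a single "control" condition
        profiles = {"control": {gid: 1.0 for gid in gene_ids}}
    rng = np.random.default_rng([config.seed, 7_777])
    weights: dict[str, dict[str, float]] = {}
    meta_rows = []
    for cond in profiles:
        prof = profiles[cond]
        for rep in range(1, config.n_replicates + 1):
            lib_id = f"{cond}_r{rep}"
            noise = rng.lognormal(0.0, config.replicate_sigma, size=len(gene_ids))
            w = {}
            for gi, gid in enumerate(gene_ids):
                base = prof.get(gid)
                if base is None:
                    base = prof.get(str(family.by_id()[gid].paralog), 0.0)
                w[gid] = float(base) * float(noise[gi])
            weights[lib_id] = w
            meta_rows.append({"library": lib_id, "condition": cond, "replicate": rep})
    meta = pd.DataFrame(meta_rows)
    return weights, meta


def simulate_reads(
    family: FamilyBundle,
    truth_weights: Mapping[str, Mapping[str, float]],
    config: SimConfig,
) -> ReadSimResult:
    """Draw unstranded error-bearing reads from the spliced transcripts.

    Per library, reads are allocated to genes multinomially with probability
    proportional to weight x transcript length; start positions are uniform,
    strand is random, and substitution errors occur i.i.d. at
    ``config.error_rate`` per base.  Deterministic given ``config.seed``.
    """
    transcripts = family.transcripts()
    gene_ids = list(transcripts)
    read_len = config.read_length
    lib_sizes = config.library_sizes

    libraries: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    count_cols = {}

    for lib_index, lib_id in enumerate(truth_weights):
        w = truth_weights[lib_id]
        missing_genes = [gid for gid in gene_ids if gid not in w]
        if missing_genes:
            raise ValueError(f"{lib_id}: weights missing for {missing_genes[:3]}...")
        size = lib_sizes[lib_id] if isinstance(lib_sizes, Mapping) else int(lib_sizes)
        probs = np.array([w[gid] * len(transcripts[gid]) for gid in gene_ids], dtype=float)
        if probs.sum() <= 0:
            raise SimulationError(f"{lib_id}: total expression weight is zero")
        probs = probs / probs.sum()
        rng = np.random.default_rng([config.seed, 1_000 + lib_index])
        counts = rng.multinomial(size, probs)

        reads: list[tuple[str, str]] = []
        read_no = 0
        for gid, n_reads in zip(gene_ids, counts):
            if n_reads == 0:
                continue
            tseq = transcripts[gid]
            max_start = len(tseq) - read_len
            starts = rng.integers(0, max_start + 1, size=n_reads)
            strands = rng.random(n_reads) < 0.5
            n_errs = rng.binomial(read_len, config.error_rate, size=n_reads)
            for start, minus, n_err in zip(starts, strands, n_errs):
                seq = tseq[start:start + read_len]
                if minus:
                    seq = _revcomp(seq)
                if n_err > 0:
                    arr = list(seq)
                    for pos in rng.choice(read_len, size=n_err, replace=False):
                        arr[pos] = [b for b in "ACGT" if b != arr[pos]][int(rng.integers(3))]
                    seq = "".join(arr)
                read_no += 1
                rid = f"{lib_id}.{read_no:07d}"
                reads.append((rid, seq))
                truth_rows.append((rid, lib_id, gid, int(start), "-" if minus else "+", int(n_err)))
        libraries[lib_id] = reads
        count_cols[lib_id] = pd.Series(counts, index=gene_ids)

    truth_df = pd.DataFrame(
        truth_rows, columns=["read_id", "library", "gene", "start", "strand", "n_errors"]
    )
    counts_df = pd.DataFrame(count_cols)
    return ReadSimResult(libraries=libraries, truth=SimTruth(reads=truth_df, counts=counts_df))
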