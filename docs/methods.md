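# Methods

## Problem setting

Hexaploid wheat-type genomes carry up to three homeologous copies (A, B, D
subgenomes) of each gene. For a small, highly conserved gene family —
short hydrophobic proteins with a two-transmembrane core, here called the
Esi3/RCI2/PMP3 type family — the coding sequences of homeologs are so
similar (≥95% amino-acid identity, with several paralogous groups at 100%)
that short RNA-seq reads cannot be attributed to a single copy from the CDS.
The analysis implemented here resolves homeolog-specific expression by
anchoring read assignment on the divergent 3′ UTRs, and then tests
expression differences between homeologs and conditions.

The package is organized as a library (`src/homeoexpr/`) with numbered
analysis drivers (`analysis/01…05`) that run the study end to end on
synthetic data with known ground truth.

## Synthetic family generator (`homeoexpr.simulate`)

The generator is first-class, tested code: it defines the study conditions
under which every downstream claim is verified.

**Family structure.** Ten paralogous groups by default, each with A/B/D
homeologs, and the B copy of group 2 deliberately absent (29 genes).
Structural groups mirror the family being modeled: groups 1, 2, 4, 5, 8 are
Group I (core only, default 54 aa), groups 3, 6, 7, 10 are Group II
(C-terminal extension of 14–20 aa), and group 9 is Group III (N-terminal
extension of 49–79 aa whose last ten residues are five valines followed by
five prolines, the junction motif diagnostic of this group).

**Divergence model.** One ancestral core CDS is generated for the family;
each paralog's core is derived by i.i.d. nucleotide substitutions (stop
codons resampled, ATG protected) at a per-paralog rate drawn so that
pairwise paralog core nucleotide identities fall in the configured 62–95%
band. There are no indels inside the CDS, which keeps identity analytically
controllable. Homeolog copies then receive exactly *k* non-synonymous
single-nucleotide codon changes at codon positions disjoint between the
three copies, with *k* chosen so that pairwise amino-acid identity
100·(1 − 2k/L) is within rounding of the configured target (default 97%;
a target unreachable within 2 percentage points raises an error naming the
paralog group). Synonymous-only substitutions (default rate 0.02/codon) add
realistic silent nucleotide divergence, so a 100% amino-acid identity target
still yields distinct CDSs. The Group III junction motif and the start codon
are excluded from substitution.

**Gene structure.** Every gene receives one intron (default 90–200 bp,
GT..AG termini) at a random interior CDS position splitting the CDS into two
exons, as in the modeled family. Intron position and sequence are resampled
(bounded retries) until the leftmost-GT..AG inference rule recovers the true
boundaries exactly, so structure inference can be property-tested for exact
recovery.

**UTRs.** Each paralog has a random ancestral 3′ UTR (default 300 bp);
homeolog copies are mutated at `utr3_divergence/2` per site each, realizing
the configured *pairwise* divergence (default 0.10/site). At 10% divergence,
100-bp reads cross the 99% identity threshold for their own UTR but
essentially never for a sibling homeolog's; at 0% divergence all reads tie
and are discarded as ambiguous — both regimes are exercised in tests.

**Reads.** Unstranded single-end reads (default 100 bp) are allocated to
genes multinomially with probability ∝ weight × transcript length
(transcript = CDS + 3′ UTR), start positions uniform, strand fair,
substitution errors i.i.d. at `error_rate` (default 0.005); no indel errors,
no coverage bias, no paired ends. FASTQ qualities are a constant Phred+33
'I'. Replicate libraries receive per-gene log-normal weight noise
(σ = 0.15) to emulate biological replication. All randomness derives from a
single root seed; each library uses a `default_rng([seed, 1000+index])`
stream, so outputs are byte-identical under a fixed seed.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: indel sequencing errors and real error
profiles, positional coverage bias, intron retention or alternative
splicing, UTR length variation between homeologs, chimeric or contaminating
reads, and genomic DNA carryover. Read length and error rate of the original
libraries are not public; the defaults are declared, not inferred.

## Family model (`homeoexpr.family`)

* **Frame arithmetic.** Exon lengths cover the CDS including the stop codon,
  so protein length = (exon1+exon2)/3 − 1. The packaged 29-row printed
  family table satisfies this on 27 rows; the two exceptions (Esi3-7-B,
  Esi3-7-D) are flagged in `datasets.DISCORDANT_ROWS` as printed
  inconsistencies and excluded from the arithmetic checks.
* **Identity convention.** Global alignment with free terminal gaps,
  match 1 / mismatch 0, internal gap open −2 / extend −1; identity =
  matched columns / aligned columns from the first to the last aligned
  position (terminal-gap columns excluded, internal gaps counted). The
  original study never states its convention; this one is symmetric,
  bounded in [0, 100], and exact on the simulator's indel-free sequences.
* **Core anchoring.** The conserved core is located by Smith–Waterman with
  BLOSUM62 (open −11 / extend −1) against a core reference (for simulated
  families the ancestral core; for arbitrary input a consensus of the
  shortest members). An alignment scoring below 0.2 of the reference's
  self-score is "unclassifiable". Unit match/mismatch scores were tried
  first and fragment below ~70% identity, hence the substitution matrix.
* **Group classification.** N-extension ≥ 25 aa ⇒ Group III, else
  C-extension ≥ 10 aa ⇒ Group II, else Group I. The thresholds are
  midpoints separating the observed ranges (Group II C-extensions 14–20 aa,
  Group III N-extensions 49–79 aa, Group I none), so the call is stable
  under a few residues of terminal noise.
* **Homeolog grouping.** Single-linkage clustering at ≥95% amino-acid
  identity; each cluster reports absent genomes; duplicated genomes within
  a cluster are flagged, not fatal.
* **Structure inference.** Valid splits of the CDS into prefix+suffix with
  genomic = prefix + intron + suffix are enumerated from the common
  prefix/suffix lengths; among valid splits the leftmost GT..AG split is
  preferred (deterministic tie-break), otherwise the leftmost split with the
  consensus flag false. Coordinates are 1-based inclusive.

## Quantification (`homeoexpr.quantify`)

A read is a candidate for a UTR query when it shares ≥1 exact word of
`word_size` (default 5) bases on either strand — libraries are unstranded,
so the reverse complement is always searched. Candidate identity is
(read_len − d)/read_len where d is the minimum edit distance of the best
gap-tolerant infix alignment of the read (or its reverse complement) within
the query, computed with edlib; the brute-force all-pairs DP oracle in the
test suite is an independent NumPy implementation. Distances above
read_len − ceil(min_identity·read_len) cannot reach the threshold and are
capped for speed; such reads are reported unmatched without a best-identity
value. A read is counted for the single query with the highest identity
among those ≥ `min_identity` (default 0.99); exact ties are discarded and
logged, keeping counts integral and conservative. Reads shorter than
2×word_size trigger a warning; shorter than word_size are unmatched by
construction. The identity denominator is the read length (the convention of
the clustering tool whose parameters — word size 5, cutoff 0.99 — the
pipeline mirrors).

**RPKPM** = matched_reads / (query_len/1000) / (library_size/10⁶), reads per
kilobase of query per million library reads. The printed formula chain
"reads / length / library / 10⁶" is read as this standard normalization:
taken literally (dividing *by* 10⁶ twice) it would produce values ~10⁻¹⁴,
irreconcilable with reported magnitudes of order 10²; the name and the
reported values fix the interpretation. Library size is the total record
count of the library.

## Statistics (`homeoexpr.stats`)

* **ANOVA.** Classical fixed-effects sums of squares for balanced designs,
  computed directly with NumPy; unbalanced designs are rejected rather than
  silently choosing a sums-of-squares type, and zero residual variance is an
  explicit error. Cross-checked in tests against `statsmodels.anova_lm`
  (two-way) and `scipy.stats.f_oneway` (one-way) to 1e-10 relative.
  Analyses run on untransformed RPKPM by default.
* **Duncan's multiple range test.** Protected (run after a significant
  omnibus ANOVA; otherwise all groups share one letter), α = 0.05 by
  default. For span p the critical range is
  R_p = q(1−(1−α)^(p−1), p, df_error) · √(MSE/n) with studentized-range
  quantiles from `scipy.stats.studentized_range`. A range is declared
  non-significant when its extreme difference ≤ R_p or when it is contained
  in a longer non-significant range; letters mark the maximal homogeneous
  stretches of the descending-sorted means. R_p is non-decreasing in p, and
  two groups closer than R_2 always share a letter.
* **Fold changes.** RPKPM ratios use (t+c₀)/(c+c₀) with pseudocount
  c₀ = 0.1 RPKPM, chosen so that strong inductions from near-zero baselines
  are reportable without division by zero. Log2 microarray values are
  background-subtracted and floored at zero before differencing
  (2^((t−bg)₊−(c−bg)₊)); the background constant is a parameter (3.4 and
  3.3 are both used by the upstream datasets this convention mirrors).

## Pipeline and problem sizes

`run_pipeline` executes simulate → classify → quantify → stats → figures,
failing fast with the stage named, and writes a JSON run report with the
package version, seed, a lossless config echo, per-stage record counts and
SHA-256 checksums of every output; identical config+seed reproduces
identical checksums. The analysis drivers use 4 000-read libraries
(3 replicates × 2 conditions), a scale at which RPKPM shares recover true
abundance shares to a few percent; the parameter-recovery check in the
acceptance suite uses 100 000-read libraries over 20 seeds, and the ANOVA
calibration uses 2 000 null simulations — sizes chosen to make the
stochastic checks stable at desk scale.

## Known limitations

* Identity control is exact only because the generator forbids CDS indels;
  real homeologs can differ by in-frame indels the family model would
  handle (alignment-based identity) but the generator never produces.
* The UTR word filter at word size 5 is a formality at realistic UTR
  lengths (a 300-bp query contains ~30% of all 1 024 possible 5-mers), so
  nearly every read reaches the alignment stage; filtering power comes from
  the 99% identity threshold.
* Reads overlapping the CDS/UTR junction align only partially to the query
  and are unmatched; quantification therefore uses reads fully contained in
  the UTR (up to one edit), which is absorbed by the shared query length in
  homeolog ratio comparisons.
* Balanced designs only; mixed models and multiple-testing correction
  across genes are out of scope, as is microarray preprocessing (log2
  values are consumed pre-normalized).
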