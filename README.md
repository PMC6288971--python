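# homeoexpr

Homeolog-resolved expression analysis of an allopolyploid gene family.

Hexaploid wheat carries up to three homeologous copies (A, B and D
subgenomes) of every gene. For small, highly conserved families such as the
Esi3/RCI2/PMP3 membrane proteins, homeologs are 95–100% identical in their
coding sequence, so short RNA-seq reads cannot be attributed to a single
copy from the CDS alone. This package implements the full analysis that
resolves the problem with the divergent **3′ UTRs**:

1. **Synthetic family generator** — allopolyploid gene families with
   controlled identity structure (ten paralogous groups × A/B/D homeologs,
   one copy deliberately absent, Group I/II/III terminal-extension
   architecture, one GT..AG intron per gene, divergent 3′ UTRs) plus
   unstranded error-bearing read libraries with per-read ground truth.
2. **Family model** — exon/intron frame arithmetic, CDS translation,
   alignment-based structural classification (Group I: ~54-aa
   two-transmembrane core; Group II: +14–20-aa C-terminal extension;
   Group III: +49–79-aa N-terminal extension ending in five valines and
   five prolines), percent-identity matrices, single-linkage homeolog
   clustering at 95% identity, and exact single-intron structure inference.
3. **Quantification** — reads are assigned to a gene's 3′-UTR query when
   they align at ≥99% identity (word size 5, both strands); ambiguous ties
   are discarded and logged. Expression is normalized to **RPKPM**:

   ```
   RPKPM = matched_reads / (query_length / 1000) / (library_size / 10^6)
   ```

   reads per kilobase of UTR query per million library reads.
4. **Statistics** — balanced two-way/one-way fixed-effects ANOVA, Duncan's
   multiple range test with shared-letter displays
   (R_p = q(1−(1−α)^(p−1), p, df)·√(MSE/n)), and fold-change conventions for
   RPKPM ratios (pseudocount-guarded) and background-subtracted log2
   microarray values.
5. **Pipeline/CLI** — `homeoexpr` with `simulate`, `classify`, `quantify`,
   `stats`, `run` and `report` subcommands; a seeded run reproduces
   byte-identical outputs, recorded as SHA-256 checksums in a run report.

The package also ships the printed 29-member wheat family annotation table
(`homeoexpr.datasets.wheat_family_table`) and a deterministic synthetic
stand-in for the curated protein/CDS set with the same identity structure
(`homeoexpr.datasets.synthetic_curated_family`).

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
default synthetic family (29 genes, six 4 000-read libraries: control vs
osmotic stress, three replicates each):

```sh
cd analysis
python 01_simulate_family.py
python 02_family_structure.py
python 03_quantify_expression.py
python 04_differential_expression.py
python 05_figures.py
```

which prints:

```
simulated 29 genes in 10 paralogous groups (structural groups I/II/III)
missing homeologs: ['g2-B']
...
structural classification: 29/29 genes match the generating group
homeolog clustering at 95% identity: 10 paralogous groups; 1 group(s) with an absent genome (['B'])
single-intron structure inference: 29/29 exact boundary recoveries
...
assigned 10993/24000 reads (45.8%; 0 ambiguous discarded)
median relative error of per-gene abundance shares vs truth: 7.5%
...
two-way ANOVA: condition effect significant for 9/10 paralogous groups; genome x condition interaction for 7
strongest stress induction: g1-B at 6.6-fold (30555.6 -> 200555.6 RPKPM)
```

Reading the numbers: all 29 simulated proteins are classified into their
generating structural group and cluster into the ten paralogous groups with
the B copy of group 2 correctly flagged absent; about half of all reads
fall inside a 3′ UTR and are assigned (the rest come from the
indistinguishable CDS and stay unassigned); the RPKPM matrix recovers the
true per-gene abundance shares to a few percent; and the ANOVA/Duncan layer
detects the simulated stress inductions. Tables land under `results/`,
heavyweight FASTA/FASTQ under `scratch/`.

Library use in code:

```python
from homeoexpr import SimConfig, simulate_family, pairwise_identity

family = simulate_family(SimConfig(seed=1))
prot = family.proteins()
pairwise_identity(prot["g1-A"], prot["g1-B"])   # ~97.0 (homeologs)
pairwise_identity(prot["g1-A"], prot["g3-A"])   # ~50-90  (paralogs)
```

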