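"""Simulate the study's gene family and stress-experiment read libraries.

Generates the default 29-member allopolyploid family (ten paralogous groups,
B copy of group 2 absent), a two-condition (control vs osmotic stress)
design with three replicate libraries each, and writes the sequence bundle
and FASTQ libraries under scratch/ with summary tables under results/.
"""

from common import outdir, study_family, study_reads, SCRATCH

from homeoexpr.family import loci_to_table


def main() -> None:
    family = study_family()
    reads, meta = study_reads(family)

    family.write(SCRATCH / "sim" / "family")
    reads.write(SCRATCH / "sim" / "reads")

    out = outdir("01_family")
    table = loci_to_table(family.loci())
    table["group"] = [g.group for g in family.genes]
    table.to_csv(out / "simulated_family_table.tsv", sep="\t", index=False)
    meta = meta.copy()
    meta["reads"] = [len(reads.libraries[lib]) for lib in meta["library"]]
    meta.to_csv(out / "libraries.tsv", sep="\t", index=False)
    reads.truth.counts.to_csv(out / "true_read_counts.tsv", sep="\t", index_label="gene")

    groups = sorted({g.group for g in family.genes})
    print(f"simulated {len(family)} genes in {table['paralog'].nunique()} paralogous "
          f"groups (structural groups {'/'.join(groups)})")
    print(f"missing homeologs: "
          f"{[f'g{p}-{g}' for p, g in family.config.missing_homeologs]}")
    print(f"{len(reads.libraries)} libraries x {meta['reads'].iloc[0]} reads "
          f"written under {SCRATCH / 'sim'}")
    print(f"tables under {out}")


if __name__ == "__main__":
    main()
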