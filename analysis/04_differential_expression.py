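"""Differential expression: ANOVA, Duncan letters and fold changes.

Per paralogous group: a two-way ANOVA (genome x condition) on RPKPM values,
per-condition Duncan multiple-range letters across homeologs, and
stress/control fold changes per gene.
"""

import pandas as pd

from common import outdir, study_family, study_reads

from homeoexpr.quantify import ReadLibrary, quantify, queries_from_family
from homeoexpr.stats import anova_duncan, fold_change_rpkpm, two_way_anova


def main() -> None:
    family = study_family()
    reads, meta = study_reads(family)
    out = outdir("04_stats")

    queries = queries_from_family(family)
    cond_of = dict(zip(meta["library"], meta["condition"]))
    libraries = [ReadLibrary(lib, r, condition=cond_of[lib])
                 for lib, r in reads.libraries.items()]
    matrix = quantify(queries, libraries)

    long = matrix.values.T.reset_index(names="library").melt(
        id_vars="library", var_name="gene", value_name="value")
    long["condition"] = long["library"].map(cond_of)
    by_id = family.by_id()
    long["paralog"] = [by_id[g].paralog for g in long["gene"]]
    long["genome"] = [by_id[g].genome for g in long["gene"]]

    anova_rows, letter_rows, fold_rows = [], [], []
    n_interaction_sig = 0
    for paralog, sub in long.groupby("paralog"):
        if sub["genome"].nunique() >= 2:
            res = two_way_anova(sub, factor_a="genome", factor_b="condition")
            n_interaction_sig += res.p_value("interaction") < 0.05
            for row in res.rows:
                anova_rows.append({"paralog": paralog, "source": row.source,
                                   "df": row.df, "F": row.F, "p": row.p})
        for cond, csub in sub.groupby("condition"):
            if csub["genome"].nunique() < 2:
                continue
            _, mrt = anova_duncan(csub, factor="genome")
            for genome, letters in mrt.letters.items():
                letter_rows.append({"paralog": paralog, "condition": cond,
                                    "genome": genome,
                                    "mean_rpkpm": float(mrt.means[genome]),
                                    "letters": letters})
        for gene, gsub in sub.groupby("gene"):
            control = gsub.loc[gsub["condition"] == "control", "value"].mean()
            stress = gsub.loc[gsub["condition"] == "stress", "value"].mean()
            fold_rows.append({"gene": gene, "control_rpkpm": control,
                              "stress_rpkpm": stress,
                              "fold_change": fold_change_rpkpm(stress, control)})

    anova = pd.DataFrame(anova_rows)
    anova.to_csv(out / "anova.tsv", sep="\t", index=False)
    pd.DataFrame(letter_rows).to_csv(out / "duncan_letters.tsv", sep="\t", index=False)
    folds = pd.DataFrame(fold_rows).sort_values("fold_change", ascending=False)
    folds.to_csv(out / "fold_changes.tsv", sep="\t", index=False)

    cond_sig = anova[(anova["source"] == "condition") & (anova["p"] < 0.05)]
    print(f"two-way ANOVA: condition effect significant for "
          f"{cond_sig['paralog'].nunique()}/{anova['paralog'].nunique()} paralogous "
          f"groups; genome x condition interaction for {n_interaction_sig}")
    top = folds.iloc[0]
    print(f"strongest stress induction: {top['gene']} at "
          f"{top['fold_change']:.1f}-fold ({top['control_rpkpm']:.1f} -> "
          f"{top['stress_rpkpm']:.1f} RPKPM)")
    print(f"tables under {out}")


if __name__ == "__main__":
    main()
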