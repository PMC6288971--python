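"""Expression figures: per-paralog bar charts with Duncan letters.

One chart per paralogous group, homeologs side by side per condition, with
replicate-SD error bars and Duncan letters above the bars.
"""

import pandas as pd

from common import outdir, study_family, study_reads

from homeoexpr.pipeline import make_figures
from homeoexpr.quantify import ReadLibrary, quantify, queries_from_family
from homeoexpr.stats import anova_duncan


def main() -> None:
    family = study_family()
    reads, meta = study_reads(family)
    out = outdir("05_figures")

    cond_of = dict(zip(meta["library"], meta["condition"]))
    libraries = [ReadLibrary(lib, r, condition=cond_of[lib])
                 for lib, r in reads.libraries.items()]
    matrix = quantify(queries_from_family(family), libraries)

    long = matrix.values.T.reset_index(names="library").melt(
        id_vars="library", var_name="gene", value_name="value")
    long["condition"] = long["library"].map(cond_of)
    by_id = family.by_id()
    long["paralog"] = [by_id[g].paralog for g in long["gene"]]
    long["genome"] = [by_id[g].genome for g in long["gene"]]
    letter_rows = []
    for (paralog, cond), sub in long.groupby(["paralog", "condition"]):
        if sub["genome"].nunique() < 2:
            continue
        _, mrt = anova_duncan(sub, factor="genome")
        for genome, letters in mrt.letters.items():
            letter_rows.append({"paralog": paralog, "condition": cond,
                                "genome": genome, "letters": letters})
    letters = pd.DataFrame(letter_rows)

    paths = make_figures(matrix, letters, cond_of, family, out)
    print(f"wrote {len(paths)} per-paralog expression charts under {out}")


if __name__ == "__main__":
    main()
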