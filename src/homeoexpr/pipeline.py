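"""End-to-end pipeline: simulate -> classify -> quantify -> stats -> report.

The pipeline is a thin, reproducible orchestration of the library modules:
given one configuration (and one seed) it writes the family bundle, read
libraries, classification tables, RPKPM expression matrix, ANOVA/Duncan
results and fold changes under an output directory, plus a run report with
per-stage record counts and SHA-256 checksums of every output file.
Re-running with the same configuration and seed reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .family import build_identity_matrix, classify_group, group_family, loci_to_table
from .quantify import ReadLibrary, queries_from_family, quantify
from .simulate import FamilyBundle, SimConfig, expression_design, simulate_family, simulate_reads
from .stats import anova_duncan, fold_change_rpkpm, two_way_anova

logger = logging.getLogger("homeoexpr")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    min_identity: float = 0.99
    word_size: int = 5
    max_utr_len: int = 300
    alpha: float = 0.05
    pseudocount: float = 0.1
    background: float = 3.4
    make_figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        # one root seed drives everything
        object.__setattr__(self.sim, "seed", self.seed)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim_data = dict(data.pop("sim", {}))
        for key in ("genomes", "paralog_core_nt_identity_range", "intron_length_range",
                    "group2_cext_aa", "group3_next_aa"):
            if key in sim_data and isinstance(sim_data[key], list):
                sim_data[key] = tuple(sim_data[key])
        if "missing_homeologs" in sim_data:
            sim_data["missing_homeologs"] = tuple(
                (int(p), str(g)) for p, g in sim_data["missing_homeologs"])
        if "group_assignment" in sim_data and sim_data["group_assignment"] is not None:
            sim_data["group_assignment"] = {
                int(k): str(v) for k, v in sim_data["group_assignment"].items()}
        return cls(sim=SimConfig(**sim_data), **data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        data = asdict(self)
        sim = data["sim"]
        if sim.get("group_assignment") is not None:
            sim["group_assignment"] = {int(k): v for k, v in sim["group_assignment"].items()}
        return data


@dataclass
class RunReport:
    """Reproducibility record of one pipeline run."""

    version: str
    seed: int
    config: dict[str, Any]
    stage_counts: dict[str, int]
    checksums: dict[str, str]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_profiles(family: FamilyBundle) -> dict[str, dict[str, float]]:
    """Two-condition demo design: per-paralog baselines and stress inductions.

    Baselines differ between homeologs (the A copy slightly dominant) and a
    few paralogs are strongly stress-induced, emulating the qualitative
    pattern of an osmotic-stress experiment.
    """
    induction = {1: 20.0, 2: 6.0, 3: 10.0, 4: 2.0, 5: 0.5, 7: 2.0}
    genome_bias = {"A": 1.0, "B": 0.7, "D": 0.5}
    control = {}
    stress = {}
    for g in family.genes:
        base = 1.0 + (g.paralog % 5)
        w = base * genome_bias.get(g.genome, 1.0)
        control[g.gene_id] = w
        stress[g.gene_id] = w * induction.get(g.paralog, 1.0)
    return {"control": control, "stress": stress}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order; fail fast with the offending stage named."""
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    outputs: dict[str, str] = {}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("simulate")
        family = simulate_family(config.sim)
        sim_cfg = config.sim
        if sim_cfg.expression_profiles is None:
            sim_cfg = SimConfig(**{**asdict(sim_cfg),
                                   "expression_profiles": _default_profiles(family)})
        weights, lib_meta = expression_design(family, sim_cfg)
        reads = simulate_reads(family, weights, sim_cfg)
        outputs.update(family.write(outdir / "family"))
        outputs.update(reads.write(outdir / "reads"))
        stage_counts["genes"] = len(family)
        stage_counts["libraries"] = len(reads.libraries)
        stage_counts["reads"] = sum(len(r) for r in reads.libraries.values())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    try:
        stage("classify")
        proteins = family.proteins()
        records = {gid: classify_group(seq, family.core_reference)
                   for gid, seq in proteins.items()}
        groups = group_family(proteins, family.genome_of(),
                              expected_genomes=config.sim.genomes)
        aa_matrix = build_identity_matrix(proteins)
        core_matrix = build_identity_matrix(
            proteins, core_spans={gid: (r.core_start, r.core_end)
                                  for gid, r in records.items()})
        fam_dir = outdir / "family"
        table = loci_to_table(family.loci())
        table["group"] = [records[g].group for g in table["gene"]]
        table.to_csv(fam_dir / "family_table.tsv", sep="\t", index=False)
        aa_matrix.to_csv(fam_dir / "identity_aa.tsv", sep="\t", index_label="gene")
        core_matrix.to_csv(fam_dir / "identity_core_aa.tsv", sep="\t", index_label="gene")
        outputs["family_table"] = str(fam_dir / "family_table.tsv")
        outputs["identity_aa"] = str(fam_dir / "identity_aa.tsv")
        outputs["identity_core_aa"] = str(fam_dir / "identity_core_aa.tsv")
        stage_counts["paralog_groups"] = len(groups)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'classify' failed: {exc}") from exc

    try:
        stage("quantify")
        queries = queries_from_family(family, max_len=config.max_utr_len)
        cond_of = dict(zip(lib_meta["library"], lib_meta["condition"]))
        rep_of = dict(zip(lib_meta["library"], lib_meta["replicate"]))
        libraries = [
            ReadLibrary(library_id=lib_id, reads=lib_reads,
                        condition=cond_of[lib_id], replicate=int(rep_of[lib_id]))
            for lib_id, lib_reads in reads.libraries.items()
        ]
        matrix = quantify(queries, libraries, min_identity=config.min_identity,
                          word_size=config.word_size)
        outputs.update(matrix.write(outdir / "expression"))
        stage_counts["expression_cells"] = int(matrix.values.size)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'quantify' failed: {exc}") from exc

    try:
        stage("stats")
        stats_dir = outdir / "stats"
        stats_dir.mkdir(exist_ok=True)
        long = matrix.values.T.reset_index(names="library").melt(
            id_vars="library", var_name="gene", value_name="value")
        long["condition"] = long["library"].map(cond_of)
        long["paralog"] = [family.by_id()[g].paralog for g in long["gene"]]
        long["genome"] = [family.by_id()[g].genome for g in long["gene"]]

        anova_rows = []
        letter_rows = []
        fold_rows = []
        conditions = sorted(long["condition"].unique())
        for paralog, sub in long.groupby("paralog"):
            if sub["genome"].nunique() >= 2 and sub["condition"].nunique() >= 2:
                res = two_way_anova(sub, value="value", factor_a="genome",
                                    factor_b="condition")
                for row in res.rows:
                    anova_rows.append({"paralog": paralog, "source": row.source,
                                       "df": row.df, "F": row.F, "p": row.p})
            # per-condition Duncan letters across homeologs
            for cond, csub in sub.groupby("condition"):
                if csub["genome"].nunique() < 2:
                    continue
                _, mrt = anova_duncan(csub, value="value", factor="genome",
                                      alpha=config.alpha)
                for genome, letter in mrt.letters.items():
                    letter_rows.append({"paralog": paralog, "condition": cond,
                                        "genome": genome,
                                        "mean": float(mrt.means[genome]),
                                        "letters": letter})
            if len(conditions) >= 2:
                control, treated = conditions[0], conditions[-1]
                for gene, gsub in sub.groupby("gene"):
                    c = gsub.loc[gsub["condition"] == control, "value"].mean()
                    t = gsub.loc[gsub["condition"] == treated, "value"].mean()
                    fold_rows.append({"gene": gene,
                                      "control_rpkpm": c, "treated_rpkpm": t,
                                      "fold_change": fold_change_rpkpm(
                                          t, c, config.pseudocount)})
        pd.DataFrame(anova_rows).to_csv(stats_dir / "anova.tsv", sep="\t", index=False)
        pd.DataFrame(letter_rows).to_csv(stats_dir / "duncan_letters.tsv", sep="\t", index=False)
        pd.DataFrame(fold_rows).to_csv(stats_dir / "fold_changes.tsv", sep="\t", index=False)
        outputs["anova"] = str(stats_dir / "anova.tsv")
        outputs["duncan_letters"] = str(stats_dir / "duncan_letters.tsv")
        outputs["fold_changes"] = str(stats_dir / "fold_changes.tsv")
        stage_counts["anova_tests"] = len(anova_rows)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'stats' failed: {exc}") from exc

    if config.make_figures:
        try:
            stage("figures")
            letters = pd.read_csv(stats_dir / "duncan_letters.tsv", sep="\t")
            figure_paths = make_figures(matrix, letters, cond_of, family,
                                        outdir / "figures")
            for i, p in enumerate(figure_paths):
                outputs[f"figure_{i}"] = p
            stage_counts["figures"] = len(figure_paths)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'figures' failed: {exc}") from exc

    checksums = {name: _sha256(p) for name, p in sorted(outputs.items())}
    report = RunReport(version=__version__, seed=config.seed,
                       config=config.to_dict(), stage_counts=stage_counts,
                       checksums=checksums)
    report.write(outdir / "run_report.json")
    logger.info("pipeline complete: %s", stage_counts)
    return report


def make_figures(matrix, letters: pd.DataFrame, cond_of: Mapping[str, str],
                 family: FamilyBundle, outdir: str | Path) -> list[str]:
    """Per-paralog bar charts: homeologs side by side per condition.

    Bars are replicate means with standard-deviation error bars; Duncan
    letters from the per-condition post-hoc test are drawn above the bars.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if matrix.values.empty:
        return []
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = family.by_id()
    known_paralogs = {by_id[g].paralog for g in matrix.values.index}
    if not letters.empty and not set(letters["paralog"]) <= known_paralogs:
        raise ValueError("letters refer to paralogs absent from the expression matrix")

    long = matrix.values.T.reset_index(names="library").melt(
        id_vars="library", var_name="gene", value_name="rpkpm")
    long["condition"] = long["library"].map(cond_of)
    long["paralog"] = [by_id[g].paralog for g in long["gene"]]
    long["genome"] = [by_id[g].genome for g in long["gene"]]

    paths = []
    for paralog, sub in long.groupby("paralog"):
        stats = sub.groupby(["condition", "genome"])["rpkpm"].agg(["mean", "std"]).reset_index()
        conditions = sorted(stats["condition"].unique())
        genomes = sorted(stats["genome"].unique())
        fig, ax = plt.subplots(figsize=(1.8 + 1.4 * len(conditions), 3.2))
        width = 0.8 / max(len(genomes), 1)
        for gi, genome in enumerate(genomes):
            xs, means, stds, labs = [], [], [], []
            for ci, cond in enumerate(conditions):
                row = stats[(stats["condition"] == cond) & (stats["genome"] == genome)]
                if row.empty:
                    continue
                xs.append(ci + gi * width)
                means.append(float(row["mean"].iloc[0]))
                stds.append(float(row["std"].iloc[0]) if pd.notna(row["std"].iloc[0]) else 0.0)
                lrow = letters[(letters["paralog"] == paralog)
                               & (letters["condition"] == cond)
                               & (letters["genome"] == genome)]
                labs.append(lrow["letters"].iloc[0] if not lrow.empty else "")
            bars = ax.bar(xs, means, width=width, yerr=stds, capsize=2, label=genome)
            for x, m, sd, lab in zip(xs, means, stds, labs):
                ax.text(x, m + sd, lab, ha="center", va="bottom", fontsize=8)
        ax.set_xticks([i + width * (len(genomes) - 1) / 2 for i in range(len(conditions))])
        ax.set_xticklabels(conditions)
        ax.set_ylabel("RPKPM")
        ax.set_title(f"paralog group {paralog}")
        ax.legend(title="genome", fontsize=8)
        fig.tight_layout()
        path = outdir / f"paralog_{paralog:02d}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(str(path))
    return paths
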