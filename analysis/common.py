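"""Shared study configuration for the numbered analysis drivers.

One deterministic configuration drives every step, so each driver can be run
on its own: the simulated inputs are regenerated in memory from the same
seed.  Heavyweight sequence output (FASTA/FASTQ) goes under scratch/,
summary tables under results/.
"""

from __future__ import annotations

from pathlib import Path

from homeoexpr.pipeline import _default_profiles
from homeoexpr.simulate import SimConfig, expression_design, simulate_family, simulate_reads

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 2024
LIBRARY_SIZE = 4_000   # reads per library; enough for stable RPKPM at desk scale
N_REPLICATES = 3


def study_config(**overrides) -> SimConfig:
    base = dict(seed=SEED, library_sizes=LIBRARY_SIZE, n_replicates=N_REPLICATES)
    base.update(overrides)
    return SimConfig(**base)


def study_family():
    return simulate_family(study_config())


def study_reads(family=None):
    family = family or study_family()
    cfg = study_config(expression_profiles=_default_profiles(family))
    weights, meta = expression_design(family, cfg)
    return simulate_reads(family, weights, cfg), meta


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
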