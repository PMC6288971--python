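"""Packaged datasets: the published family table and a synthetic curated set.

``wheat_family_table`` is the printed annotation table of the hexaploid-wheat
Esi3/RCI2/PMP3 family (29 members, ten paralogous groups across the A/B/D
genomes): chromosome-arm placement, start-codon position, orientation, CDS
exon and intron lengths, and protein length.  Two rows of the printed table
(Esi3-7-B and Esi3-7-D) are internally inconsistent with the frame arithmetic
aa = (exon1+exon2)/3 - 1 and are flagged here.

``synthetic_curated_family`` is a deterministic SYNTHETIC stand-in for the
curated 29-sequence protein/CDS set, generated by the family simulator so
that it reproduces the published identity structure: ten paralogous groups,
the B copy of group 2 absent, Group I homeolog triplets at 100% amino-acid
identity, all homeolog pairs at >= 95%, and paralog pairs well below the
homeolog clustering threshold.  It is not the published sequence set.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .family import GeneLocus, table_to_loci
from .simulate import FamilyBundle, SimConfig, simulate_family

#: rows of the printed family table whose aa column contradicts the frame
#: arithmetic (see module docstring)
DISCORDANT_ROWS = ("Esi3-7-B", "Esi3-7-D")

#: structural group of each paralogous group in the published family
WHEAT_GROUP_ASSIGNMENT = {1: "I", 2: "I", 4: "I", 5: "I", 8: "I",
                          3: "II", 6: "II", 7: "II", 10: "II", 9: "III"}

_CURATED_SEED = 20181211  # frozen; the stand-in is a fixed reference object


def wheat_family_table() -> pd.DataFrame:
    """The printed 29-member family annotation table as a DataFrame."""
    with resources.files("homeoexpr.data").joinpath("wheat_family_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"splice_consensus": bool})


def wheat_family_loci() -> list[GeneLocus]:
    return table_to_loci(wheat_family_table())


def synthetic_curated_family() -> FamilyBundle:
    """Deterministic synthetic stand-in for the curated 29-sequence set.

    Group I paralogs (1, 2, 4, 5, 8) are generated with homeolog triplets at
    exactly 100% amino-acid identity (nucleotide divergence is synonymous
    only); the remaining groups at a 97% homeolog target, comfortably above
    the 95% clustering threshold.  The B copy of paralog group 2 is absent,
    for a total of 29 records.
    """
    targets = {p: (100.0 if g == "I" else 97.0)
               for p, g in WHEAT_GROUP_ASSIGNMENT.items()}
    config = SimConfig(
        n_paralog_groups=10,
        homeolog_aa_identity_target=targets,
        group_assignment=WHEAT_GROUP_ASSIGNMENT,
        missing_homeologs=((2, "B"),),
        seed=_CURATED_SEED,
    )
    return simulate_family(config)
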