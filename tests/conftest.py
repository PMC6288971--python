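"""Shared fixtures: simulated families, read sets, and alignment oracle."""

from __future__ import annotations

import numpy as np
import pytest

from homeoexpr.simulate import FamilyBundle, SimConfig, simulate_family, simulate_reads

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def infix_edit_distance(read: str, query: str) -> int:
    """Brute-force infix (glocal) edit distance: read aligned within query.

    Full dynamic program with free leading/trailing gaps in the query;
    vectorized over query positions with the diff-array trick for the
    in-row (insertion) dependency.  Independent of the edlib path used by
    the implementation.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    n = len(q)
    js = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int32)
    for i, ch in enumerate(read.encode(), start=1):
        base = np.empty(n + 1, dtype=np.int32)
        base[0] = i
        base[1:] = np.minimum(prev[1:] + 1, prev[:-1] + (q != ch))
        # resolve cur[j] = min(base[j], cur[j-1] + 1) via prefix minimum
        cur = np.minimum.accumulate(base - js) + js
        prev = cur
    return int(prev.min())


def oracle_assign(queries, reads, min_identity=0.99):
    """All-pairs brute-force read assignment (no word filter).

    Returns {read_id: gene_id} for assigned reads and the set of read ids
    discarded as ambiguous ties.
    """
    assigned = {}
    ambiguous = set()
    for read_id, seq in reads:
        rlen = len(seq)
        best = None
        best_genes = []
        for q in queries:
            d = min(infix_edit_distance(seq, q.sequence),
                    infix_edit_distance(revcomp(seq), q.sequence))
            if (rlen - d) / rlen < min_identity:
                continue
            if best is None or d < best:
                best, best_genes = d, [q.gene_id]
            elif d == best:
                best_genes.append(q.gene_id)
        if best is None:
            continue
        if len(best_genes) > 1:
            ambiguous.add(read_id)
        else:
            assigned[read_id] = best_genes[0]
    return assigned, ambiguous


@pytest.fixture(scope="session")
def default_family() -> FamilyBundle:
    return simulate_family(SimConfig(seed=11))


@pytest.fixture(scope="session")
def triplet_family() -> FamilyBundle:
    """A single paralogous group with all three homeologs present."""
    cfg = SimConfig(seed=11, n_paralog_groups=1, missing_homeologs=())
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def triplet_reads(triplet_family):
    """Small error-bearing library from the homeolog triplet, with truth."""
    cfg = SimConfig(seed=11, n_paralog_groups=1, missing_homeologs=(),
                    library_sizes=400)
    weights = {"lib1": {g.gene_id: w for g, w in
                        zip(triplet_family.genes, (1.0, 2.0, 4.0))}}
    return simulate_reads(triplet_family, weights, cfg)
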