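"""Family model: frame arithmetic, translation, classification, identity,
homeolog grouping and single-intron structure inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeoexpr.datasets import DISCORDANT_ROWS, wheat_family_loci, wheat_family_table
from homeoexpr.family import (
    FrameError,
    StructureError,
    build_identity_matrix,
    classify_group,
    core_consensus,
    group_family,
    infer_gene_structure,
    pairwise_identity,
    protein_length_from_exons,
    translate_cds,
)
from homeoexpr.simulate import SimConfig, simulate_family


class TestFrameArithmetic:
    @pytest.mark.parametrize(
        "e1,e2,expected",
        [(81, 84, 54),    # published Esi3-1-B row
         (240, 84, 107),  # published Esi3-9-A row
         (3, 3, 1)],      # one codon plus stop
    )
    def test_protein_length_from_exons(self, e1, e2, expected):
        assert protein_length_from_exons(e1, e2) == expected

    @pytest.mark.parametrize("e1,e2", [(82, 84), (1, 3), (0, 0)])
    def test_out_of_frame_rejected(self, e1, e2):
        with pytest.raises(FrameError):
            protein_length_from_exons(e1, e2)

    def test_published_table_rows_consistent(self):
        """Every frame-consistent printed row matches aa=(e1+e2)/3-1 except
        the two flagged discordant rows."""
        for locus in wheat_family_loci():
            assert locus.frame_consistent
            expected = protein_length_from_exons(locus.exon1_cds_len, locus.exon2_cds_len)
            if locus.gene_id in DISCORDANT_ROWS:
                assert expected != locus.aa_len
            else:
                assert expected == locus.aa_len, locus.gene_id


class TestTranslate:
    @pytest.mark.parametrize("cds,protein", [("ATGTAA", "M"), ("ATGGTGTAG", "MV")])
    def test_minimal_cds(self, cds, protein):
        assert translate_cds(cds) == protein

    @pytest.mark.parametrize("cds", ["ATGTA", "TTGGTGTAG", "ATGGTG", "ATGTAAGTGTAA"])
    def test_invalid_cds_rejected(self, cds):
        with pytest.raises(FrameError):
            translate_cds(cds)

    def test_simulator_round_trip(self, default_family):
        """CDS translation length equals the exon-length arithmetic."""
        for gene in default_family.genes:
            locus = gene.to_locus()
            assert len(gene.protein) == protein_length_from_exons(
                locus.exon1_cds_len, locus.exon2_cds_len)


class TestPairwiseIdentity:
    def test_identical_and_simple(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0
        assert pairwise_identity("AAAA", "AAAT") == 75.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_terminal_gaps_free(self):
        # prefix/suffix overhangs are not counted as aligned columns
        assert pairwise_identity("ACGT", "TTACGTTT") == 100.0

    def test_simulated_homeolog_target(self, default_family):
        """Homeolog pairs generated at a 97% aa target land within 2 points."""
        prot = default_family.proteins()
        by_paralog = {}
        for g in default_family.genes:
            by_paralog.setdefault(g.paralog, []).append(g.gene_id)
        for members in by_paralog.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    assert pairwise_identity(prot[a], prot[b]) == pytest.approx(97.0, abs=2.0)


class TestIdentityMatrix:
    def test_symmetric_diagonal_and_range(self, default_family):
        mat = build_identity_matrix(default_family.proteins())
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 100.0)
        assert ((mat.values >= 0) & (mat.values <= 100)).all()

    def test_identical_records(self):
        mat = build_identity_matrix({"a": "MKV", "b": "MKV"})
        assert mat.loc["a", "b"] == 100.0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            build_identity_matrix([("a", "MKV"), ("a", "MKV")])

    def test_core_equals_full_for_extension_free_pairs(self, default_family):
        """Core-restricted identity equals full-length identity for Group I."""
        g1 = {g.gene_id: g for g in default_family.genes if g.group == "I"}
        seqs = {gid: g.protein for gid, g in g1.items()}
        spans = {gid: (g.core_start, g.core_end) for gid, g in g1.items()}
        full = build_identity_matrix(seqs)
        core = build_identity_matrix(seqs, core_spans=spans)
        assert np.allclose(full.values, core.values)


class TestClassifyGroup:
    def test_published_style_lengths(self, default_family):
        """54-aa core-only proteins are Group I; 20-aa C-extension Group II;
        79-aa N-extension Group III."""
        core = default_family.core_reference
        rng = np.random.default_rng(0)
        ext = "".join(rng.choice(list("AVLIKRDEST"), size=79))
        assert classify_group(core, core).group == "I"
        assert classify_group(core + ext[:20], core).group == "II"
        assert classify_group(ext[:69] + "VVVVVPPPPP" + core, core).group == "III"

    def test_simulator_groups_recovered(self, default_family):
        for gene in default_family.genes:
            rec = classify_group(gene.protein, default_family.core_reference)
            assert rec.group == gene.group, gene.gene_id

    def test_extension_accounting(self, default_family):
        for gene in default_family.genes:
            rec = classify_group(gene.protein, default_family.core_reference)
            assert rec.n_ext_len + (rec.core_end - rec.core_start) + rec.c_ext_len \
                == len(gene.protein)

    @given(noise=st.text(alphabet="AVLIKR", min_size=0, max_size=2))
    @settings(max_examples=20, deadline=None)
    def test_stable_under_short_terminal_noise(self, noise):
        """Appending <=2 C-terminal residues never flips a Group I call."""
        fam = simulate_family(SimConfig(seed=11))
        gene = next(g for g in fam.genes if g.group == "I")
        rec = classify_group(gene.protein + noise, fam.core_reference)
        assert rec.group == "I"

    def test_unclassifiable_without_core(self, default_family):
        with pytest.raises(ValueError):
            classify_group("MKKKKKKKKKKKKKKKKKK", default_family.core_reference)


class TestGroupFamily:
    def test_singleton(self):
        groups = group_family({"x-A": "MAVILF"}, {"x-A": "A"})
        assert len(groups) == 1
        assert groups[0].missing_genomes == ["B", "D"]

    def test_simulated_family_clusters(self, default_family):
        groups = group_family(default_family.proteins(), default_family.genome_of())
        assert len(groups) == 10
        flagged = [g for g in groups if g.missing_genomes]
        assert len(flagged) == 1
        assert flagged[0].missing_genomes == ["B"]
        assert all(m.startswith("g2-") for m in flagged[0].members)

    def test_duplicate_genome_flagged_not_fatal(self):
        seqs = {"x-A": "MAVILFWGPS", "x-A2": "MAVILFWGPS", "x-B": "MAVILFWGPS"}
        genomes = {"x-A": "A", "x-A2": "A", "x-B": "B"}
        groups = group_family(seqs, genomes)
        assert len(groups) == 1
        assert groups[0].duplicated_genomes == ["A"]


class TestInferGeneStructure:
    def test_constructed_consensus(self):
        e1, e2 = "ATGGCCTTC", "GATTACTGA"
        intron = "GT" + "C" * 20 + "AG"
        exon1, intron_iv, exon2, consensus = infer_gene_structure(e1 + intron + e2, e1 + e2)
        assert consensus
        assert exon1 == (1, 9)
        assert intron_iv == (10, 33)
        assert exon2 == (34, 42)

    def test_non_consensus_intron_flagged(self):
        # exon/intron boundary chosen shift-unambiguous: e1 ends 'A', the
        # intron starts 'C' and ends 'C' before e2's 'G'
        e1, e2 = "ATGGCCTTA", "GATTACTGA"
        intron = "CT" + "G" * 20 + "AC"
        exon1, intron_iv, exon2, consensus = infer_gene_structure(e1 + intron + e2, e1 + e2)
        assert not consensus
        assert exon1[1] == 9

    def test_no_decomposition_rejected(self):
        with pytest.raises(StructureError):
            infer_gene_structure("ACGT", "ACGTACGT")
        with pytest.raises(StructureError):
            infer_gene_structure("TTTTTTTTTT", "ACGTAC")

    @pytest.mark.parametrize("seed", range(4))
    def test_simulator_boundaries_recovered_exactly(self, seed):
        fam = simulate_family(SimConfig(seed=seed))
        for g in fam.genes:
            exon1, intron_iv, exon2, consensus = infer_gene_structure(g.genomic, g.cds)
            assert consensus
            assert exon1 == (1, g.intron_pos)
            assert intron_iv == (g.intron_pos + 1, g.intron_pos + len(g.intron))


def test_core_consensus_majority():
    assert core_consensus(["MAV", "MAV", "MIV"]) == "MAV"


def test_wheat_table_structure():
    table = wheat_family_table()
    assert len(table) == 29
    assert table["paralog"].nunique() == 10
    # the one non-consensus splice site in the published table
    assert set(table.loc[~table["splice_consensus"], "gene"]) == {"Esi3-9-B"}
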