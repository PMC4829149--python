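import textwrap

import pytest

from metapep import data_io
from metapep.data_io import (AbundanceMatrix, AnnotationMaps,
                             DataFormatError, ModuleDefinition,
                             PeptideObservation, SampleMeta,
                             validate_metadata)

import pandas as pd


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

class TestPeptideTable:
    def test_identity_read(self, tmp_path):
        p = _write(tmp_path, "pep.tsv", """\
            sample_id\tpeptide\tspectral_count
            s1\tPEPTIDEK\t2
            s1\tAAAR\t1
            s2\tPEPTIDEK\t4
            """)
        obs = data_io.read_peptide_table(p)
        assert len(obs) == 3
        assert obs[0] == PeptideObservation("s1", "AAAR", 1)

    def test_duplicates_summed_with_warning(self, tmp_path, caplog):
        p = _write(tmp_path, "pep.tsv", """\
            sample_id\tpeptide\tspectral_count
            s1\tPEPTIDEK\t2
            s1\tPEPTIDEK\t3
            """)
        with caplog.at_level("WARNING", logger="metapep"):
            obs = data_io.read_peptide_table(p)
        assert obs == [PeptideObservation("s1", "PEPTIDEK", 5)]
        assert any("duplicate" in r.message for r in caplog.records)

    def test_zero_count_rejected(self, tmp_path):
        p = _write(tmp_path, "pep.tsv", """\
            sample_id\tpeptide\tspectral_count
            s1\tPEPTIDEK\t0
            """)
        with pytest.raises(DataFormatError, match=">= 1"):
            data_io.read_peptide_table(p)

    def test_bad_residue_names_peptide(self, tmp_path):
        p = _write(tmp_path, "pep.tsv", """\
            sample_id\tpeptide\tspectral_count
            s1\tPEPTIXEZ\t1
            """)
        with pytest.raises(DataFormatError, match="PEPTIXEZ"):
            data_io.read_peptide_table(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, "pep.tsv", """\
            sample_id\tpeptide\tspectral_count
            s1\tAAAK\t1
            s1 only-one-field
            """)
        with pytest.raises(DataFormatError, match=":3"):
            data_io.read_peptide_table(p)

    def test_round_trip_and_order(self, tmp_path):
        obs = [PeptideObservation("s2", "AAAK", 3),
               PeptideObservation("s1", "CCCK", 1),
               PeptideObservation("s1", "AAAK", 2)]
        p = tmp_path / "out.tsv"
        data_io.write_peptide_table(obs, p)
        back = data_io.read_peptide_table(p)
        assert back == sorted(obs, key=lambda o: (o.sample_id, o.peptide))


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

class TestMetadata:
    def test_round_trip(self, tmp_path):
        meta = [SampleMeta("s1", "u1", 1, "placebo"),
                SampleMeta("s2", "u1", 2, "placebo"),
                SampleMeta("s3", "u2", 1, "probiotic")]
        p = tmp_path / "meta.tsv"
        data_io.write_sample_metadata(meta, p)
        assert data_io.read_sample_metadata(p) == meta

    def test_bad_time_point(self):
        with pytest.raises(DataFormatError):
            SampleMeta("s1", "u1", 4, "placebo")

    def test_group_constant_within_subject(self):
        with pytest.raises(DataFormatError, match="both groups"):
            validate_metadata([SampleMeta("s1", "u1", 1, "placebo"),
                               SampleMeta("s2", "u1", 2, "probiotic")])

    def test_one_sample_per_time_point(self):
        with pytest.raises(DataFormatError, match="time_point"):
            validate_metadata([SampleMeta("s1", "u1", 1, "placebo"),
                               SampleMeta("s2", "u1", 1, "placebo")])


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

class TestTaxonomy:
    def test_linear_tree_depth(self, tmp_path):
        p = _write(tmp_path, "tax.tsv", """\
            taxon_id\tparent_id\trank\tname
            r\tr\troot\troot
            d\tr\tdomain\tBacteria
            p\td\tphylum\tFirmicutes
            g\tp\tgenus\tGenus
            s\tg\tspecies\tSpecies
            """)
        tree = data_io.read_taxonomy(p)
        assert tree.depth("s") == 4 and tree.root == "r"

    def test_orphan_error(self, tmp_path):
        p = _write(tmp_path, "tax.tsv", """\
            taxon_id\tparent_id\trank\tname
            r\tr\troot\troot
            x\tmissing\tgenus\tX
            """)
        with pytest.raises(DataFormatError, match="'x'"):
            data_io.read_taxonomy(p)

    def test_multiple_roots_error(self, tmp_path):
        p = _write(tmp_path, "tax.tsv", """\
            taxon_id\tparent_id\trank\tname
            r1\tr1\troot\troot
            r2\tr2\troot\troot2
            """)
        with pytest.raises(DataFormatError, match="multiple roots"):
            data_io.read_taxonomy(p)

    def test_cycle_error(self, tmp_path):
        p = _write(tmp_path, "tax.tsv", """\
            taxon_id\tparent_id\trank\tname
            r\tr\troot\troot
            a\tb\tgenus\tA
            b\ta\tgenus\tB
            """)
        with pytest.raises(DataFormatError, match="cycle|orphan"):
            data_io.read_taxonomy(p)

    def test_taxdump_dialect(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text(
            "1\t|\t1\t|\tno rank\t|\n"
            "2\t|\t1\t|\tsuperkingdom\t|\n"
            "1239\t|\t2\t|\tphylum\t|\n")
        (tmp_path / "names.dmp").write_text(
            "1\t|\troot\t|\t\t|\tscientific name\t|\n"
            "2\t|\tBacteria\t|\t\t|\tscientific name\t|\n"
            "1239\t|\tFirmicutes\t|\t\t|\tscientific name\t|\n")
        tree = data_io.read_taxonomy(tmp_path)
        assert tree.rank("2") == "domain"
        assert tree.name("1239") == "Firmicutes"
        assert tree.find_by_name("Bacteria") == "2"

    def test_round_trip(self, small_tree, tmp_path):
        p = tmp_path / "tax.tsv"
        data_io.write_taxonomy(small_tree, p)
        back = data_io.read_taxonomy(p)
        assert back.nodes == small_tree.nodes


# ---------------------------------------------------------------------------
# module definitions
# ---------------------------------------------------------------------------

class TestModuleDefinitions:
    def test_single_pathway(self, tmp_path):
        p = _write(tmp_path, "gmm.txt", """\
            MF0001\tglycolysis
            K00001
            K00002
            K00003
            ///
            """)
        mods = data_io.read_module_definitions(p)
        assert len(mods) == 1
        assert len(mods[0].pathways) == 1
        assert len(mods[0].pathways[0]) == 3

    def test_alternative_kos_in_step(self, tmp_path):
        p = _write(tmp_path, "gmm.txt", """\
            MF0001\tm
            K00001,K00002
            ///
            """)
        mods = data_io.read_module_definitions(p)
        assert mods[0].pathways[0][0] == frozenset({"K00001", "K00002"})

    def test_alternative_pathways(self, tmp_path):
        p = _write(tmp_path, "gmm.txt", """\
            MF0001\tm
            K00001
            //
            K00002
            K00003
            ///
            """)
        mods = data_io.read_module_definitions(p)
        assert len(mods[0].pathways) == 2

    def test_malformed_ko(self, tmp_path):
        p = _write(tmp_path, "gmm.txt", "MF0001\tm\nK1\n///\n")
        with pytest.raises(DataFormatError, match="K1"):
            data_io.read_module_definitions(p)

    def test_empty_pathway(self, tmp_path):
        p = _write(tmp_path, "gmm.txt", "MF0001\tm\n//\nK00001\n///\n")
        with pytest.raises(DataFormatError, match="empty pathway"):
            data_io.read_module_definitions(p)

    def test_round_trip(self, tmp_path):
        mods = [ModuleDefinition("MF0001", "module one",
                                 ((frozenset({"K00001", "K00002"}),
                                   frozenset({"K00003"})),
                                  (frozenset({"K00004"}),))),
                ModuleDefinition("MF0002", "module two",
                                 ((frozenset({"K00005"}),),))]
        p = tmp_path / "gmm.txt"
        data_io.write_module_definitions(mods, p)
        assert data_io.read_module_definitions(p) == mods


# ---------------------------------------------------------------------------
# abundance matrices & annotation maps
# ---------------------------------------------------------------------------

class TestAbundanceMatrix:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 0.0]},
                          index=["K00001", "K00002"])
        m = AbundanceMatrix(df, scale="counts")
        p = tmp_path / "m.tsv"
        data_io.write_abundance_matrix(m, p)
        back = data_io.read_abundance_matrix(p)
        assert back.scale == "counts"
        pd.testing.assert_frame_equal(back.df, m.df)

    def test_percent_must_sum_to_100(self):
        df = pd.DataFrame({"s1": [40.0, 50.0]}, index=["a", "b"])
        with pytest.raises(DataFormatError, match="sum to 100"):
            AbundanceMatrix(df, scale="percent")

    def test_percent_with_unassigned_remainder_allowed(self):
        df = pd.DataFrame({"s1": [40.0, 60.0]}, index=["a", "unassigned"])
        AbundanceMatrix(df, scale="percent")  # does not raise

    def test_negative_rejected(self):
        df = pd.DataFrame({"s1": [-1.0]}, index=["a"])
        with pytest.raises(DataFormatError):
            AbundanceMatrix(df)


class TestAnnotationMaps:
    def test_round_trip(self, small_tree, tmp_path):
        maps = AnnotationMaps(
            peptide_to_taxa={"AAAK": frozenset({"B_fragilis"})},
            peptide_to_kos={"AAAK": frozenset({"K00001"})},
            peptide_to_cogs={"AAAK": frozenset({("COG0001", "GE")})},
            ko_domain={"K00001": "bacterial"})
        paths = data_io.write_annotation_maps(maps, tmp_path)
        back = data_io.read_annotation_maps(
            taxa_path=paths["taxa"], ko_path=paths["ko"],
            cog_path=paths["cog"], ko_domain_path=paths["ko_domain"],
            tree=small_tree)
        assert back == maps

    def test_taxon_missing_from_tree(self, small_tree):
        maps = AnnotationMaps(
            peptide_to_taxa={"AAAK": frozenset({"no_such"})})
        with pytest.raises(DataFormatError, match="no_such"):
            maps.validate(small_tree)

    def test_ambiguous_flagging(self):
        maps = AnnotationMaps(peptide_to_cogs={
            "AAAK": frozenset({("COG1", "G"), ("COG2", "E")}),
            "CCCK": frozenset({("COG3", "G")})})
        assert maps.ambiguous_peptides() == frozenset({"AAAK"})


def test_config_reader(tmp_path):
    p = tmp_path / "sim.cfg"
    p.write_text("n_subjects = 4  # comment\n\nseed=7\n")
    assert data_io.read_config(p) == {"n_subjects": "4", "seed": "7"}
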