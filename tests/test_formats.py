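"""Readers/writers: FASTA round-trips, taxdump, domain tables,
trusted cutoffs, hit tables, metadata validation."""

import gzip

import pytest
from hypothesis import given, settings, strategies as st

from ferretforge.formats import (
    AlignmentHit,
    PfamHit,
    SequenceRecord,
    parse_domtbl,
    parse_hit_table,
    parse_hmm_thresholds,
    parse_taxdump,
    read_fasta,
    read_metadata,
    strip_pfam_version,
    write_fasta,
)

DOMTBL = """\
# target name        accession   tlen query name  accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description
#------------------- ---------- ----- ----------  ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- -----------
seq1 - 210 Ribosomal_S7 PF00001.21 155 1e-10 55.0 0.1 1 1 2e-12 2e-10 54.0 0.1 1 155 1 210 1 210 0.98 some protein
seq1 - 210 Pkinase PF00069.26 264 1e-06 30.2 0.0 1 1 1e-07 1e-06 29.0 0.0 1 100 1 100 1 100 0.90 some protein
seq2 - 88 Ribosomal_L2 PF00181.24 120 3e-20 77.5 0.2 1 1 1e-21 3e-20 76.0 0.2 1 88 1 88 1 88 0.99
#
"""


class TestFasta:
    def test_canonical_parse(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1 desc\nacgt\n")
        (rec,) = read_fasta(p, "nt")
        assert rec == SequenceRecord("s1", "desc", "nt", "ACGT")

    def test_amino_acid_records_keep_stops_and_x(self, tmp_path):
        p = tmp_path / "a.faa"
        p.write_text(">a\nMK*\n>b\nLLX\n")
        recs = read_fasta(p, "aa")
        assert [r.residues for r in recs] == ["MK*", "LLX"]

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p, "nt")

    def test_illegal_symbol_names_record_and_symbol(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">weird\nAC!T\n")
        with pytest.raises(ValueError, match="weird"):
            read_fasta(p, "nt")

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "a.fasta.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">s1\nMKL\n")
        assert read_fasta(p, "aa")[0].residues == "MKL"

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.from_regex(r"[A-Za-z0-9_.|-]{1,20}", fullmatch=True),
                st.text(
                    alphabet=st.characters(
                        whitelist_categories=("L", "N"), max_codepoint=127
                    ),
                    max_size=20,
                ),
                st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX*", min_size=1, max_size=80),
            ),
            min_size=1,
            max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    def test_round_trip_preserves_records(self, tmp_path_factory, entries):
        """write(read(f)) preserves (seq_id, description, residues)."""
        records = [SequenceRecord(i, d, "aa", s) for i, d, s in entries]
        path = tmp_path_factory.mktemp("fa") / "rt.fasta"
        write_fasta(records, path)
        assert read_fasta(path, "aa") == records


class TestTaxdump:
    @staticmethod
    def _write(tmp_path, node_rows, name_rows):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        nodes.write_text(
            "".join(f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, p, r in node_rows)
        )
        names.write_text(
            "".join(
                f"{t}\t|\t{n}\t|\t\t|\tscientific name\t|\n" for t, n in name_rows
            )
        )
        return nodes, names

    def test_two_node_tree(self, tmp_path):
        nodes, names = self._write(
            tmp_path, [(1, 1, "no rank"), (2, 1, "superkingdom")],
            [(1, "root"), (2, "Bacteria")],
        )
        tree = parse_taxdump(nodes, names)
        assert len(tree) == 2 and tree.root == 1
        assert tree.name(2) == "Bacteria"

    def test_orphan_parent_is_error(self, tmp_path):
        nodes, names = self._write(
            tmp_path, [(1, 1, "no rank"), (5, 99, "species")], [(1, "root")]
        )
        with pytest.raises(ValueError, match="orphan taxid 5"):
            parse_taxdump(nodes, names)

    def test_duplicate_taxid_is_error(self, tmp_path):
        nodes, names = self._write(
            tmp_path, [(1, 1, "no rank"), (2, 1, "clade"), (2, 1, "clade")],
            [(1, "root")],
        )
        with pytest.raises(ValueError, match="duplicate"):
            parse_taxdump(nodes, names)

    def test_every_node_walks_to_root(self, tree):
        """Parent-chains from all nodes of a generated fixture reach the
        root within the node count."""
        for taxid in tree:
            path = tree.lineage(taxid)
            assert path[0] == tree.root and path[-1] == taxid
            assert len(path) <= len(tree)
            for parent, child in zip(path, path[1:]):
                assert tree.node(child).parent == parent

    def test_merged_taxids_resolve(self, tmp_path):
        nodes, names = self._write(
            tmp_path, [(1, 1, "no rank"), (2, 1, "clade")], [(1, "root")]
        )
        merged = tmp_path / "merged.dmp"
        merged.write_text("7\t|\t2\t|\n")
        tree = parse_taxdump(nodes, names, merged)
        assert tree.resolve(7) == 2
        with pytest.raises(KeyError):
            tree.resolve(8)


class TestDomtbl:
    def test_comment_only_file_yields_no_hits(self, tmp_path):
        p = tmp_path / "t.domtblout.tab"
        p.write_text("# header\n# more\n")
        assert parse_domtbl(p) == []

    def test_field_mapping_and_order(self, tmp_path):
        p = tmp_path / "t.domtblout.tab"
        p.write_text(DOMTBL)
        hits = parse_domtbl(p)
        assert len(hits) == 3
        assert hits[0] == PfamHit("seq1", "PF00001", "Ribosomal_S7", 55.0, 1e-10)
        assert [h.seq_id for h in hits] == ["seq1", "seq1", "seq2"]

    def test_short_row_reports_line_number(self, tmp_path):
        p = tmp_path / "t.domtblout.tab"
        p.write_text("# h\nseq1 - 210 Pkinase PF00069.26\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_domtbl(p)


class TestHmmThresholds:
    HMM = (
        "HMMER3/f [3.3]\nNAME  Ribosomal_S7\nACC   PF00001.21\n"
        "TC    20.40 20.40;\n//\n"
        "HMMER3/f [3.3]\nNAME  Pkinase\nACC   PF00069.26\n"
        "TC    25.00 25.00;\n//\n"
        "HMMER3/f [3.3]\nNAME  Orphan\nACC   PF09999.1\n//\n"
    )

    def test_accession_to_first_tc_value(self, tmp_path):
        p = tmp_path / "p.hmm"
        p.write_text(self.HMM)
        thresholds = parse_hmm_thresholds(p)
        assert thresholds["PF00001"] == pytest.approx(20.40)
        assert len(thresholds) == 2

    def test_profile_without_tc_is_warned_and_lookup_fails(self, tmp_path):
        p = tmp_path / "p.hmm"
        p.write_text(self.HMM)
        thresholds = parse_hmm_thresholds(p)
        assert thresholds.missing == ["PF09999"]
        with pytest.raises(KeyError):
            thresholds["PF09999"]

    def test_version_suffix_stripping(self):
        assert strip_pfam_version("PF00001.21") == "PF00001"
        assert strip_pfam_version("PF00001") == "PF00001"


class TestHitTable:
    def test_four_column_dialect(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\t7\t50.0\t1e-20\n")
        table = parse_hit_table(p)
        assert table.hits == [AlignmentHit("q1", 7, 50.0, 1e-20)]

    def test_twelve_column_dialect_with_map(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            "q1\tref9\t99.0\t100\t1\t0\t1\t100\t1\t100\t1e-30\t200.0\n"
            "q1\tref0\t99.0\t100\t1\t0\t1\t100\t1\t100\t1e-30\t150.0\n"
            "q2\tmissing\t99.0\t100\t1\t0\t1\t100\t1\t100\t1e-30\t150.0\n"
        )
        table = parse_hit_table(p, taxid_map={"ref9": 12, "ref0": 13})
        assert [h.subject_taxid for h in table.hits] == [12, 13]
        assert table.n_dropped == 1

    def test_twelve_column_without_map_is_error(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\tr\t9\t1\t0\t0\t1\t9\t1\t9\t1e-5\t40\n")
        with pytest.raises(ValueError, match="taxid map"):
            parse_hit_table(p)

    def test_unparseable_number_is_error_not_skip(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\t7\tNOTANUMBER\t1e-20\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_hit_table(p)


class TestMetadata:
    def test_missing_required_column_is_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("entry_id,tax_id\n1,9\n")
        with pytest.raises(ValueError, match="missing metadata column"):
            read_metadata(p)

    def test_duplicate_entry_id_is_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "entry_id,marferret_name,tax_id,data_type,seq_type,n_seqs_raw,accepted\n"
            "1,a,9,TSA,aa,10,Y\n1,b,9,TSA,aa,10,Y\n"
        )
        with pytest.raises(ValueError, match="duplicate entry_id"):
            read_metadata(p)

    def test_extra_columns_preserved(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "entry_id,marferret_name,tax_id,data_type,seq_type,n_seqs_raw,accepted,pub_year\n"
            "1,a,9,genome,aa,10,Y,2021\n"
        )
        df = read_metadata(p)
        assert "pub_year" in df.columns
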