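"""Table readers/writers: HMMER3 tabular, ko_list, counts, pathway definitions."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from biogeopath import formats
from biogeopath.formats import ParseError, SchemaError
from biogeopath.model import (
    Component,
    CountMode,
    CountRecord,
    Cycle,
    HmmHit,
    PathwayDefinition,
    Route,
    ScoreType,
)


class TestHmmTable:
    def test_tblout_columns_map_to_hit_fields(self, tblout_file):
        hits = formats.read_hmm_table(tblout_file, "tblout")
        assert len(hits) == 3
        h = hits[0]
        assert (h.gene_id, h.family_id) == ("g1", "K00392")
        assert h.full_score == 210.3
        assert h.dom_score == 209.0
        assert h.evalue == 1e-50

    def test_domtblout_scores_come_from_domain_columns(self, tmp_path):
        # 22 fixed columns + description; per-domain score is column 14
        row = (
            "g1 - 350 dmdA - 310 1e-140 460.2 0.0 1 2 1e-70 2e-69 455.9 0.0 "
            "5 300 10 320 8 330 0.97 demethylase"
        )
        path = tmp_path / "hits.domtblout"
        path.write_text("# comment\n" + row + "\n")
        (hit,) = formats.read_hmm_table(path, "domtblout")
        assert (hit.gene_id, hit.family_id) == ("g1", "dmdA")
        assert hit.evalue == 1e-140
        assert hit.full_score == 460.2
        assert hit.dom_score == 455.9

    def test_comment_only_file_yields_empty_list(self, tmp_path):
        path = tmp_path / "empty.tblout"
        path.write_text("# nothing here\n# at all\n")
        assert formats.read_hmm_table(path, "tblout") == []

    @pytest.mark.parametrize(
        "row",
        [
            "g1 - K00392 - 1e-50 NOTANUMBER 0.1 1e-49 209.0 0.1 1 1 0 0 1 1 1 1 x",
            "g1 - K00392 - 1e-50",  # too few columns
        ],
    )
    def test_malformed_row_reports_line_number(self, tmp_path, row):
        path = tmp_path / "bad.tblout"
        path.write_text("# header\n" + row + "\n")
        with pytest.raises(ParseError, match=":2"):
            formats.read_hmm_table(path, "tblout")

    def test_unknown_dialect_is_usage_error(self, tblout_file):
        with pytest.raises(ValueError, match="dialect"):
            formats.read_hmm_table(tblout_file, "csv")

    def test_duplicate_gene_family_rows_all_returned(self, tmp_path):
        row = "g1 - K00392 - 1e-50 210.3 0.1 1e-49 209.0 0.1 1 1 0 0 1 1 1 1 x"
        path = tmp_path / "dup.tblout"
        path.write_text(row + "\n" + row + "\n")
        assert len(formats.read_hmm_table(path, "tblout")) == 2

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1, allow_nan=False),
                st.floats(min_value=-50, max_value=5000, allow_nan=False),
                st.floats(min_value=-50, max_value=5000, allow_nan=False),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_round_trip_preserves_values(self, tmp_path_factory, rows):
        hits = [
            HmmHit(f"g{i}", f"K{i:05d}", full, dom, ev)
            for i, (ev, full, dom) in enumerate(rows)
        ]
        path = tmp_path_factory.mktemp("rt") / "hits.tblout"
        formats.write_hmm_table(hits, path, "tblout")
        back = formats.read_hmm_table(path, "tblout")
        assert back == hits


class TestKoThresholds:
    def test_numeric_rows_parse_with_score_type(self, ko_list_file):
        entries = formats.read_ko_thresholds(ko_list_file)
        assert entries["K00392"].threshold == 150.0
        assert entries["K00392"].score_type is ScoreType.FULL
        assert entries["K00380"].score_type is ScoreType.DOMAIN
        assert entries["K00381"].definition.startswith("sulfite reductase")

    def test_dash_threshold_flagged_threshold_less(self, ko_list_file):
        entries = formats.read_ko_thresholds(ko_list_file)
        assert not entries["K99999"].has_threshold
        assert entries["K99999"].threshold is None

    def test_missing_columns_is_schema_error(self, tmp_path):
        path = tmp_path / "ko_list"
        path.write_text("knum\tdefinition\nK00001\tx\n")
        with pytest.raises(SchemaError, match="threshold"):
            formats.read_ko_thresholds(path)

    def test_round_trip(self, ko_list_file, tmp_path):
        entries = formats.read_ko_thresholds(ko_list_file)
        out = tmp_path / "ko_list2"
        formats.write_ko_thresholds(entries, out)
        assert formats.read_ko_thresholds(out) == entries


class TestCountsTable:
    def test_reads_mode(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("gene_id\tlength\treads\ng1\t300\t30\n")
        (rec,) = formats.read_counts_table(path)
        assert rec.mode is CountMode.READS
        assert (rec.gene_id, rec.length, rec.count) == ("g1", 300, 30.0)

    def test_coverage_mode(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("gene_id\tlength\tavg_coverage\ng1\t300\t12.5\n")
        (rec,) = formats.read_counts_table(path)
        assert rec.mode is CountMode.COVERAGE
        assert rec.coverage == 12.5

    @pytest.mark.parametrize(
        "header,row",
        [
            ("gene_id\tlength\treads\tavg_coverage", "g1\t300\t30\t12.5"),
            ("gene_id\tlength", "g1\t300"),
        ],
    )
    def test_both_or_neither_quantity_column_rejected(self, tmp_path, header, row):
        path = tmp_path / "counts.tsv"
        path.write_text(header + "\n" + row + "\n")
        with pytest.raises(SchemaError):
            formats.read_counts_table(path)

    def test_nonpositive_length_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("gene_id\tlength\treads\ng1\t0\t30\n")
        with pytest.raises(ValueError, match="length"):
            formats.read_counts_table(path)

    def test_round_trip(self, tmp_path):
        records = [
            CountRecord("g1", 300, count=30.0),
            CountRecord("g2", 451, count=0.25),
        ]
        path = tmp_path / "counts.tsv"
        formats.write_counts_table(records, path)
        assert formats.read_counts_table(path) == records


class TestPathwayDefinitions:
    def _write(self, tmp_path, rows):
        path = tmp_path / "defs.tsv"
        header = "pathway_id\tdisplay_name\tcycle\troute_index\tcomponent_index\tfamilies"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_two_route_definition(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                "asr\tASR\tsulfur\t1\t1\tK00392",
                "asr\tASR\tsulfur\t2\t1\tK00380",
                "asr\tASR\tsulfur\t2\t2\tK00381",
            ],
        )
        (d,) = formats.read_pathway_definitions(path)
        assert len(d.routes) == 2
        assert [r.n for r in d.routes] == [1, 2]
        assert d.cycle is Cycle.SULFUR

    def test_multi_alternative_component(self, tmp_path):
        path = self._write(
            tmp_path,
            ["cleave\tDMSP cleavage\tDMSP\t1\t1\tDddD,DddK,DddL,DddP,DddQ,DddW,DddY,Alma1"],
        )
        (d,) = formats.read_pathway_definitions(path)
        assert len(d.routes) == 1
        assert len(d.routes[0].components[0].families) == 8

    def test_empty_component_is_schema_error(self, tmp_path):
        path = self._write(tmp_path, ["p\tP\tsulfur\t1\t1\t,"])
        with pytest.raises(SchemaError, match="empty component"):
            formats.read_pathway_definitions(path)

    def test_duplicate_pathway_interleaved_rows_ok_but_gap_in_indices_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            ["p\tP\tsulfur\t1\t1\tK1", "p\tP\tsulfur\t3\t1\tK2"],
        )
        with pytest.raises(SchemaError, match="route indices"):
            formats.read_pathway_definitions(path)

    def test_round_trip(self, tmp_path):
        defs = [
            PathwayDefinition(
                "p1",
                "Pathway one",
                Cycle.NITROGEN,
                (
                    Route((Component.of("K1"), Component.of("K2", "K3"))),
                    Route((Component.of("K4"),)),
                ),
            )
        ]
        path = tmp_path / "defs.tsv"
        formats.write_pathway_definitions(defs, path)
        assert formats.read_pathway_definitions(path) == defs


class TestHitInvariants:
    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            HmmHit("g", "K", 1.0, 1.0, -1e-10)

    def test_non_finite_score_rejected(self):
        with pytest.raises(ValueError):
            HmmHit("g", "K", math.inf, 1.0, 0.0)

    def test_empty_ids_rejected(self):
        with pytest.raises(ValueError):
            HmmHit("", "K", 1.0, 1.0, 0.0)
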