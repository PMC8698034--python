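"""Parser, serializer and cluster-table I/O for the domain notation."""

import json
from io import StringIO

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterline import (
    GeneratorConfig,
    NotationError,
    SchemaError,
    TableValidationError,
    count_modules,
    generate_cluster,
    parse_orf_architecture,
    read_cluster_table,
    serialize_orf_architecture,
    write_cluster_table,
)


class TestParsing:
    def test_two_nrps_extension_modules_with_release(self):
        orf = parse_orf_architecture("C/A_ser_/T-C/A_pro_/T-Te", "12-31")
        mods = orf.modules
        assert [m.role for m in mods] == ["extension", "extension"]
        assert mods[0].labels == ("C", "A", "T")
        assert mods[0].find("A").specificity == "ser"
        # the trailing release segment folds into the final module
        assert mods[1].labels == ("C", "A", "T", "Te")
        assert mods[1].find("A").specificity == "pro"

    def test_loading_module(self):
        orf = parse_orf_architecture("CoL/ACP", "qnmA1")
        assert len(orf.modules) == 1
        assert orf.modules[0].role == "loading"
        assert orf.modules[0].labels == ("CoL", "ACP")

    def test_release_merge_normalizes_both_spellings(self):
        hyphenated = parse_orf_architecture("KS/AT_m_/ACP-Te", "1-1098")
        slashed = parse_orf_architecture("KS/AT_m_/ACP/Te", "1-1098")
        assert hyphenated.notation() == slashed.notation() == "KS/AT_m_/ACP/Te"
        assert len(hyphenated.modules) == 1

    def test_leading_ellipsis_standalone_domain(self):
        orf = parse_orf_architecture("…KR", "16-1")
        assert orf.left_truncated and not orf.right_truncated
        assert not orf.modules
        assert [t.label for t in orf.trailing_standalones] == ["KR"]

    def test_ascii_ellipsis_trailing(self):
        orf = parse_orf_architecture("KS/AT...", "14-64")
        assert orf.right_truncated
        assert orf.modules[0].labels == ("KS", "AT")

    @pytest.mark.parametrize("bad", ["", "   ", "…", "A_", "KS//ACP", "A_x_y_"])
    def test_malformed_strings_raise(self, bad):
        with pytest.raises(NotationError):
            parse_orf_architecture(bad, "bad")

    @pytest.mark.parametrize(
        "dialect", ["AT_m_", "ATm", "AT_m"], ids=["closed", "bare", "open"]
    )
    def test_subscript_dialects_normalize(self, dialect):
        orf = parse_orf_architecture(f"KS/{dialect}/ACP", "x")
        at = orf.modules[0].find("AT")
        assert at.specificity == "malonyl"
        assert orf.notation() == "KS/AT_m_/ACP"

    def test_substrate_with_hyphen(self):
        orf = parse_orf_architecture("C/A_b-ala_/T", "21-50")
        assert orf.modules[0].find("A").specificity == "b-ala"
        assert orf.notation() == "C/A_b-ala_/T"

    def test_unknown_code_preserved_as_x(self):
        orf = parse_orf_architecture("KS/FooBar/ACP", "x")
        tokens = list(orf.domain_tokens())
        assert [t.label for t in tokens] == ["KS", "X", "ACP"]
        assert tokens[1].raw == "FooBar"
        assert "FooBar" in orf.notation()

    def test_standalone_didomain_is_standalone_module(self):
        orf = parse_orf_architecture("A/T-C", "8-247")
        assert [m.role for m in orf.modules] == ["standalone"]
        assert [t.label for t in orf.trailing_standalones] == ["C"]

    def test_domain_conservation(self, tp_a0316):
        # every domain in the input appears exactly once in the structure
        for cluster in tp_a0316:
            for orf in cluster.orfs:
                n_parsed = len(list(orf.domain_tokens()))
                rebuilt = parse_orf_architecture(orf.notation(), orf.orf_id)
                assert len(list(rebuilt.domain_tokens())) == n_parsed


class TestRoundTrip:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_serialize_parse_identity_on_generated_clusters(self, seed):
        kind = ("t1pks", "nrps", "pks_nrps")[seed % 3]
        cluster = generate_cluster(
            GeneratorConfig(seed=seed, n_modules=(2, 12)), kind=kind
        )
        for orf in cluster.orfs:
            text = serialize_orf_architecture(orf)
            again = parse_orf_architecture(text, orf.orf_id)
            assert serialize_orf_architecture(again) == text
            assert [m.labels for m in again.modules] == [
                m.labels for m in orf.modules
            ]

    def test_fixture_architectures_round_trip(self, tp_a0316, tp_a0468, qnm):
        clusters = list(tp_a0316) + list(tp_a0468) + [qnm]
        for cluster in clusters:
            for orf in cluster.orfs:
                text = orf.notation()
                assert parse_orf_architecture(text, orf.orf_id).notation() == text


class TestClusterTables:
    def test_both_strain_fixtures_hold_fifteen_clusters(
        self, tp_a0316, tp_a0468
    ):
        assert len(tp_a0316.clusters) == 15
        assert len(tp_a0468.clusters) == 15

    def test_quinolidomicin_ortholog_has_33_modules(self, tp_a0316, tp_a0468):
        assert count_modules(tp_a0316.get("t1pks-2")) == 33
        assert count_modules(tp_a0468.get("t1pks-2")) == 33

    def test_qnm_reference_has_34_positions(self, qnm):
        mods = qnm.counted_modules()
        assert len(mods) == 34
        assert [m.index_label for m in mods] == ["L"] + [
            str(i) for i in range(1, 34)
        ]
        assert mods[0].notation() == "CoL/ACP"
        assert mods[4].notation() == "KS/AT_m_/DH/KR/ACP"  # module 4
        assert mods[-1].notation() == "KS/AT_m_/KR/ACP/Te"

    def test_count_modules_equals_per_orf_sum(self, tp_a0316):
        for cluster in tp_a0316:
            per_orf = sum(
                len([m for m in orf.modules if m.role != "standalone"])
                for orf in cluster.orfs
            )
            assert count_modules(cluster) == per_orf

    def test_incomplete_flag_propagates(self, tp_a0316):
        assert not tp_a0316.get("t1pks-4").complete
        assert not tp_a0316.get("nrps-4").complete
        assert tp_a0316.get("nrps-5").complete

    def test_small_nrps_cluster_module_counts(self, tp_a0316):
        assert count_modules(tp_a0316.get("nrps-5")) == 2

    def test_empty_table_yields_no_inventories(self):
        stream = StringIO(
            "strain_id\tcluster_id\tdeclared_type\tcomplete_flag\torf_id"
            "\tarchitecture\tannotation\n"
        )
        assert read_cluster_table(stream) == []

    def test_missing_column_is_schema_error(self):
        stream = StringIO("strain_id\tcluster_id\n")
        with pytest.raises(SchemaError):
            read_cluster_table(stream)

    def test_duplicate_orf_row_is_validation_error(self):
        header = (
            "strain_id\tcluster_id\tdeclared_type\tcomplete_flag\torf_id"
            "\tarchitecture\tannotation\n"
        )
        row = "S\tc1\tnrps\t\to1\tC/A/T\t\n"
        with pytest.raises(TableValidationError):
            read_cluster_table(StringIO(header + row + row))

    def test_tsv_and_json_dialects_agree(self, tmp_path, tp_a0316):
        json_path = tmp_path / "inv.json"
        write_cluster_table([tp_a0316], json_path, dialect="json")
        (roundtrip,) = read_cluster_table(json_path, dialect="json")
        assert [c.cluster_id for c in roundtrip] == [
            c.cluster_id for c in tp_a0316
        ]
        for c_new, c_old in zip(roundtrip, tp_a0316):
            assert [o.notation() for o in c_new.orfs] == [
                o.notation() for o in c_old.orfs
            ]
            assert c_new.complete == c_old.complete
        data = json.loads(json_path.read_text())
        assert data[0]["strain_id"] == "TP-A0316"
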