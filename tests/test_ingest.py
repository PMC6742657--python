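"""Peptide-table reading, filtering, normalization, and PTM-site annotation."""

import numpy as np
import pandas as pd
import pytest

from mechanoprot.ingest import (
    ExperimentDesign,
    annotate_ptm_sites,
    default_registry,
    filter_by_confidence,
    filter_by_peptide_count,
    log_and_normalize,
    read_gmt,
    read_peptide_table,
    write_peptide_table,
)

from conftest import make_table


class TestReadPeptideTable:
    def test_parses_fixture(self, peptide_csv):
        table = read_peptide_table(peptide_csv)
        assert len(table) == 3
        assert table.sample_ids == ["ctrl_d1", "strain_d1"]
        mods = table.modifications_of(table.df.iloc[0])
        assert mods == [(2, 79.966, "phospho")]

    def test_empty_cell_is_missing_not_zero(self, peptide_csv):
        table = read_peptide_table(peptide_csv)
        assert np.isnan(table.df.loc[1, "strain_d1"])
        assert table.df.loc[1, "ctrl_d1"] == 1500.0

    def test_unknown_sample_column_is_hard_error(self, peptide_csv, two_sample_design):
        design = ExperimentDesign(
            pd.DataFrame(
                {"sample_id": ["ctrl_d1", "other"], "group": ["control", "strain"], "donor": ["d1", "d1"]}
            ),
            "control",
        )
        with pytest.raises(ValueError, match="strain_d1"):
            read_peptide_table(peptide_csv, design)

    def test_modification_offset_beyond_peptide_is_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "peptide_id,sequence,modifications,accession,unique,score,s1\n"
            "p1,VSSR,9:phospho,P1,True,30.0,1000.0\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_peptide_table(path)

    def test_round_trip_is_byte_identical(self, peptide_csv, tmp_path):
        table = read_peptide_table(peptide_csv)
        out = tmp_path / "rt.csv"
        write_peptide_table(table, out)
        assert out.read_bytes() == peptide_csv.read_bytes()


class TestConfidenceFilter:
    def test_score_to_p_mapping_and_bh(self):
        # scores chosen so p = 0.01, 0.02, 0.04, 0.5 -> q = .04, .04, .0533, .5
        scores = [-10 * np.log10(p) for p in (0.01, 0.02, 0.04, 0.5)]
        table = make_table(
            [{"peptide_id": f"p{i}", "score": s, "s1": 100.0} for i, s in enumerate(scores)],
            ["s1"],
        )
        kept = filter_by_confidence(table, fdr_threshold=0.2)
        assert sorted(kept.df["peptide_id"]) == ["p0", "p1", "p2"]

    def test_ties_share_one_fate(self):
        table = make_table(
            [{"peptide_id": f"p{i}", "score": 6.0, "s1": 10.0} for i in range(5)], ["s1"]
        )
        # p = 10^-0.6 = 0.251 -> q = 0.251 for all: all removed at 0.2, kept at 0.3
        assert len(filter_by_confidence(table, 0.3)) == 5
        with_strict = filter_by_confidence(table, 0.2)
        assert len(with_strict) == 0

    def test_invalid_inputs(self):
        table = make_table([{"peptide_id": "p", "s1": 1.0}], ["s1"])
        with pytest.raises(ValueError):
            filter_by_confidence(table, 0.0)
        empty = make_table([], ["s1"]) if False else table
        empty = table.copy()
        empty.df = empty.df.iloc[:0]
        with pytest.raises(ValueError):
            filter_by_confidence(empty, 0.2)


class TestPeptideCountFilter:
    def _protein(self, acc, seqs, unique=True):
        return [
            {"peptide_id": f"{acc}_{i}", "sequence": s, "accession": acc, "unique": unique, "s1": 10.0}
            for i, s in enumerate(seqs)
        ]

    def test_boundary_inclusive(self):
        rows = self._protein("A", ["AAAAAAA", "CCCCCCC"]) + self._protein(
            "B", ["DDDDDDD", "EEEEEEE", "FFFFFFF"]
        )
        out = filter_by_peptide_count(make_table(rows, ["s1"]), min_unique=3)
        assert set(out.df["accession"]) == {"B"}

    def test_distinct_sequences_counted_not_rows(self):
        # 5 rows but only 2 distinct unique sequences -> removed
        rows = self._protein("A", ["AAAAAAA", "AAAAAAA", "AAAAAAA", "CCCCCCC", "CCCCCCC"])
        out = filter_by_peptide_count(make_table(rows, ["s1"]), min_unique=3)
        assert len(out) == 0

    def test_non_unique_peptides_do_not_count(self):
        rows = self._protein("A", ["AAAAAAA", "CCCCCCC", "DDDDDDD"], unique=False)
        out = filter_by_peptide_count(make_table(rows, ["s1"]), min_unique=3)
        assert len(out) == 0

    def test_idempotent(self):
        rows = self._protein("A", ["AAAAAAA", "CCCCCCC"]) + self._protein(
            "B", ["DDDDDDD", "EEEEEEE", "FFFFFFF"]
        )
        once = filter_by_peptide_count(make_table(rows, ["s1"]), 3)
        twice = filter_by_peptide_count(once, 3)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestLogAndNormalize:
    def test_median_subtraction(self):
        table = make_table(
            [
                {"peptide_id": "p1", "s1": 2.0},
                {"peptide_id": "p2", "s1": 4.0},
                {"peptide_id": "p3", "s1": 8.0},
            ],
            ["s1"],
        )
        out = log_and_normalize(table)
        assert np.allclose(out.df["s1"], [-1.0, 0.0, 1.0])

    def test_missing_cells_stay_missing_and_samples_center_independently(self):
        table = make_table(
            [
                {"peptide_id": "p1", "s1": 2.0},
                {"peptide_id": "p2", "s1": 4.0},
                {"peptide_id": "p3", "s2": 64.0},
                {"peptide_id": "p4", "s2": 256.0},
            ],
            ["s1", "s2"],
        )
        out = log_and_normalize(table)
        assert np.isnan(out.df.loc[0, "s2"]) and np.isnan(out.df.loc[2, "s1"])
        for s in ("s1", "s2"):
            col = out.df[s].dropna()
            assert abs(np.median(col)) < 1e-12

    def test_every_sample_median_zero_random(self):
        rng = np.random.default_rng(5)
        rows = [
            {"peptide_id": f"p{i}", "s1": float(v1), "s2": float(v2)}
            for i, (v1, v2) in enumerate(zip(rng.lognormal(10, 2, 51), rng.lognormal(8, 1, 51)))
        ]
        out = log_and_normalize(make_table(rows, ["s1", "s2"]))
        for s in ("s1", "s2"):
            assert abs(np.median(out.df[s])) < 1e-12

    def test_empty_sample_errors(self):
        table = make_table([{"peptide_id": "p1", "s1": 2.0}], ["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            log_and_normalize(table)


class TestAnnotatePtmSites:
    def test_substring_arithmetic(self):
        table = make_table(
            [{"peptide_id": "p1", "sequence": "VSSR", "modifications": "2:phospho", "accession": "P1", "s1": 1.0}],
            ["s1"],
        )
        anns = annotate_ptm_sites(table, {"P1": "MKVSSR"})
        assert len(anns) == 1
        assert anns[0].site == "S4" and not anns[0].ambiguous

    def test_repeated_peptide_is_ambiguous(self):
        table = make_table(
            [{"peptide_id": "p1", "sequence": "VSSR", "modifications": "2:phospho", "accession": "P1", "s1": 1.0}],
            ["s1"],
        )
        anns = annotate_ptm_sites(table, {"P1": "MKVSSRAAVSSR"})
        assert anns[0].ambiguous and anns[0].site == "S4"  # leftmost match

    def test_mbbr_label_on_cysteine(self):
        table = make_table(
            [{"peptide_id": "p1", "sequence": "ACDK", "modifications": "2:mBBr", "accession": "P1", "s1": 1.0}],
            ["s1"],
        )
        anns = annotate_ptm_sites(table, {"P1": "MACDK"})
        assert anns[0].label == "mBBr" and anns[0].residue == "C"
        assert default_registry().get("mBBr").mass_delta == 133.053

    def test_peptide_not_in_protein_errors(self):
        table = make_table(
            [{"peptide_id": "p1", "sequence": "WWWW", "modifications": "1:phospho", "accession": "P1", "s1": 1.0}],
            ["s1"],
        )
        with pytest.raises(ValueError, match="WWWW"):
            annotate_ptm_sites(table, {"P1": "MKVSSR"})


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("pw1\tdesc\tP1\tP2\tP3\npw2\tdesc\tP4\tP5\n")
    gmt = read_gmt(path)
    assert gmt == {"pw1": {"P1", "P2", "P3"}, "pw2": {"P4", "P5"}}
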