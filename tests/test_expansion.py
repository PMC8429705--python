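"""Domain counting, Fisher exact testing, BH-FDR, z-score matrices."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from ipskit import DataError, InputError
from ipskit.expansion import (
    DomainCountMatrix,
    DomainExpansionTest,
    bh_fdr,
    build_count_matrix,
    call_expansions,
    domain_zscores,
    fisher_exact_two_sided,
    fisher_expansion_test,
    read_hmmscan_tblout,
)

from conftest import fisher_oracle


def annotations(rows):
    return pd.DataFrame(rows, columns=["species", "protein_id", "domain_accession"])


class TestBuildCountMatrix:
    def test_repeated_domain_in_one_protein_counts_once(self):
        ann = annotations([("sp1", "p1", "PF1")] * 3)
        matrix = build_count_matrix(ann, {"sp1": 10})
        assert matrix.counts.loc["sp1", "PF1"] == 1

    def test_empty_annotations_give_all_zero_matrix(self):
        ann = annotations([])
        matrix = build_count_matrix(ann, {"sp1": 10, "sp2": 10})
        assert matrix.counts.shape[1] == 0 or (matrix.counts.to_numpy() == 0).all()

    def test_hand_enumerated_fixture(self):
        ann = annotations(
            [
                ("sp1", "p1", "d1"), ("sp1", "p1", "d2"),
                ("sp1", "p2", "d1"), ("sp1", "p2", "d2"),
                ("sp1", "p3", "d1"),
            ]
        )
        matrix = build_count_matrix(ann, {"sp1": 5})
        assert matrix.counts.loc["sp1", "d1"] == 3
        assert matrix.counts.loc["sp1", "d2"] == 2

    def test_idempotent_under_row_duplication(self):
        rows = [("sp1", "p1", "d1"), ("sp1", "p2", "d1"), ("sp2", "p9", "d2")]
        once = build_count_matrix(annotations(rows), {"sp1": 5, "sp2": 5})
        twice = build_count_matrix(annotations(rows * 4), {"sp1": 5, "sp2": 5})
        assert once.counts.equals(twice.counts)

    def test_missing_gene_total_rejected(self):
        with pytest.raises(InputError, match="sp2"):
            build_count_matrix(annotations([("sp2", "p1", "d1")]), {"sp1": 5})

    def test_count_above_gene_total_rejected(self):
        counts = pd.DataFrame({"d1": [7]}, index=["sp1"])
        with pytest.raises(DataError):
            DomainCountMatrix(counts=counts, gene_totals=pd.Series({"sp1": 5}))

    def test_tblout_reader_collapses_to_annotation_rows(self, tmp_path):
        path = tmp_path / "scan.tblout"
        path.write_text(
            "#                  --- full sequence ----\n"
            "# target name  accession  query name  accession  E-value\n"
            "GH48   PF02011.20  prot1  -  1e-30\n"
            "GH48   PF02011.20  prot1  -  2e-10\n"
            "p450   PF00067.21  prot2  -  1e-50\n"
        )
        df = read_hmmscan_tblout(path, species="Ityp")
        matrix = build_count_matrix(df, {"Ityp": 10})
        assert matrix.counts.loc["Ityp", "PF02011"] == 1
        assert matrix.counts.loc["Ityp", "PF00067"] == 1


class TestFisherExact:
    def test_balanced_table_is_null(self):
        assert fisher_exact_two_sided(5, 95, 5, 95) == pytest.approx(1.0)

    def test_empty_margin_returns_one(self):
        assert fisher_exact_two_sided(0, 100, 0, 100) == 1.0

    @pytest.mark.parametrize(
        "table",
        [(5, 95, 1, 99), (10, 90, 2, 98), (0, 50, 5, 45), (3, 0, 0, 3),
         (17, 83, 17, 83), (40, 19960, 5, 19995)],
    )
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact_two_sided(*table) == pytest.approx(
            fisher_oracle(*table), abs=1e-12
        )

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 40, size=4)
            ours = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            theirs = sp_stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_one_sided_upper_tail(self):
        p_greater = fisher_exact_two_sided(9, 1, 1, 9, alternative="greater")
        expected = sum(
            math.comb(10, x) * math.comb(10, 10 - x) / math.comb(20, 10)
            for x in range(9, 11)
        )
        assert p_greater == pytest.approx(expected, rel=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_two_sided(-1, 2, 3, 4)


class TestFisherExpansionTest:
    def test_identical_rows_are_null(self):
        counts = pd.DataFrame({"d1": [5, 5, 5]}, index=["f", "b1", "b2"])
        totals = pd.Series({"f": 100, "b1": 100, "b2": 100})
        res = fisher_expansion_test(
            DomainCountMatrix(counts=counts, gene_totals=totals), "f"
        )
        row = res.loc["d1"]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.p_value == pytest.approx(1.0)
        assert row.direction == "none"

    def test_all_zero_domain_is_null(self):
        counts = pd.DataFrame({"d1": [0, 0, 0]}, index=["f", "b1", "b2"])
        totals = pd.Series({"f": 100, "b1": 100, "b2": 100})
        res = fisher_expansion_test(
            DomainCountMatrix(counts=counts, gene_totals=totals), "f"
        )
        assert res.loc["d1", "p_value"] == 1.0
        assert res.loc["d1", "direction"] == "none"

    def test_rounded_mean_background_table(self, small_count_matrix):
        res = fisher_expansion_test(small_count_matrix, "focal")
        # background of PF_A: mean(5, 6, 4, 5) = 5.0
        assert res.loc["PF_A", "bg_mean"] == pytest.approx(5.0)
        assert res.loc["PF_A", "p_value"] == pytest.approx(
            fisher_oracle(40, 960, 5, 995), abs=1e-12
        )
        assert res.loc["PF_A", "direction"] == "up"
        assert res.loc["PF_D", "direction"] == "down"

    def test_pooled_background_variant(self, small_count_matrix):
        res = fisher_expansion_test(small_count_matrix, "focal", background="pooled")
        assert res.loc["PF_A", "p_value"] == pytest.approx(
            fisher_oracle(40, 960, 20, 3980), abs=1e-12
        )

    def test_unknown_focal_rejected(self, small_count_matrix):
        with pytest.raises(InputError):
            fisher_expansion_test(small_count_matrix, "nope")


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_returned_in_input_order(self):
        q = bh_fdr([0.9, 0.001, 0.5])
        assert q[1] == min(q)

    def test_monotone_along_sorted_p_and_bounded(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])


class TestCallExpansions:
    def frame(self, p, direction):
        return pd.DataFrame(
            {
                "focal_count": 10, "bg_mean": 5.0, "odds_ratio": 2.0,
                "p_value": p, "direction": direction,
            },
            index=pd.Index([f"d{i}" for i in range(len(p))], name="domain"),
        )

    def test_sub_alpha_up_called_expanded(self):
        out = call_expansions(self.frame([0.049], ["up"]), alpha=0.05)
        assert bool(out["expanded"].iloc[0])

    def test_direction_gate_blocks_contractions(self):
        out = call_expansions(self.frame([0.049], ["down"]), alpha=0.05)
        assert not bool(out["expanded"].iloc[0])

    def test_alpha_validated(self):
        with pytest.raises(InputError):
            call_expansions(self.frame([0.5], ["up"]), alpha=1.5)

    def test_model_facade_recovers_planted_domain(self, small_count_matrix):
        results = DomainExpansionTest(small_count_matrix, "focal").fit()
        assert results.expanded_domains == ["PF_A"]
        assert "expanded:      1 domains" in results.summary()
        z = results.zscores()
        assert list(z.index) == ["PF_A"]


class TestDomainZscores:
    def matrix(self, data, species=("a", "b", "c")):
        counts = pd.DataFrame(data, index=list(species))
        totals = pd.Series(1000, index=counts.index)
        return DomainCountMatrix(counts=counts, gene_totals=totals)

    def test_hand_computed_row(self):
        z = domain_zscores(self.matrix({"d1": [1, 2, 3]}))
        assert z.loc["d1"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_all_zero(self):
        z = domain_zscores(self.matrix({"d1": [4, 4, 4]}))
        assert z.loc["d1"].tolist() == [0.0, 0.0, 0.0]

    def test_rows_standardized(self, rng):
        data = {f"d{i}": rng.integers(0, 50, size=6).tolist() for i in range(20)}
        z = domain_zscores(self.matrix(data, species=list("abcdef")))
        nonconst = z[(z != 0).any(axis=1)]
        assert np.allclose(nonconst.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(nonconst.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_column_permutation_equivariance(self):
        m = self.matrix({"d1": [1, 5, 9], "d2": [2, 2, 8]})
        z = domain_zscores(m)
        perm = ["c", "a", "b"]
        m_perm = DomainCountMatrix(
            counts=m.counts.loc[perm], gene_totals=m.gene_totals.loc[perm]
        )
        z_perm = domain_zscores(m_perm)
        assert z_perm[perm].equals(z[perm])
        assert z_perm.loc["d1", "c"] == z.loc["d1", "c"]


class TestMatrixIO:
    def test_tsv_round_trip(self, small_count_matrix, tmp_path):
        path = tmp_path / "matrix.tsv"
        small_count_matrix.to_tsv(path)
        again = DomainCountMatrix.from_tsv(path)
        assert again.counts.equals(small_count_matrix.counts)
        assert again.gene_totals.equals(small_count_matrix.gene_totals)
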