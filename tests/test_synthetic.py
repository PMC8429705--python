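"""Generators: determinism, composition bounds, accounting identities."""

import math

import numpy as np
import pytest

from ipskit import (
    ExpansionSimSpec,
    GenomeSpec,
    InputError,
    ReadSimSpec,
    fragment_genome,
    generate_genome,
    simulate_domain_counts,
    simulate_expression,
    simulate_reads,
)
from ipskit.expression import ExpressionMatrix, tpm_from_counts


class TestGenerateGenome:
    def test_rejects_empty_genome(self):
        with pytest.raises(InputError):
            generate_genome(GenomeSpec(length_bp=0, gc_fraction=0.5, seed=1))

    def test_deterministic_under_seed(self):
        a = generate_genome(GenomeSpec(10_000, 0.35, seed=1))
        b = generate_genome(GenomeSpec(10_000, 0.35, seed=1))
        assert a[0].seq == b[0].seq
        c = generate_genome(GenomeSpec(10_000, 0.35, seed=2))
        assert a[0].seq != c[0].seq

    def test_length_and_alphabet(self):
        g = generate_genome(GenomeSpec(5_000, 0.4, seed=3))
        assert len(g[0].seq) == 5_000
        assert set(g[0].seq) <= set("ACGT")

    def test_gc_fraction_within_three_standard_errors(self):
        n, gc = 100_000, 0.352
        g = generate_genome(GenomeSpec(n, gc, seed=7))
        observed = (g[0].seq.count("G") + g[0].seq.count("C")) / n
        se = math.sqrt(gc * (1 - gc) / n)
        assert abs(observed - gc) < 3 * se


class TestFragmentGenome:
    def test_single_contig_no_planting_is_identity(self):
        g = generate_genome(GenomeSpec(1_000, 0.5, seed=1))
        contigs, truth = fragment_genome(g, 1, "TTAGG", 0, seed=0)
        assert len(contigs) == 1
        assert contigs[0].seq == g[0].seq
        assert truth.empty

    def test_length_accounting(self):
        g = generate_genome(GenomeSpec(1_000, 0.5, seed=2))
        contigs, truth = fragment_genome(g, 4, "TTAGG", 10, seed=3)
        assert len(contigs) == 4
        assert contigs.total_length == 1_000 + 10 * 5 * len(truth)

    def test_concatenation_reconstructs_genome(self):
        g = generate_genome(GenomeSpec(2_000, 0.35, seed=5))
        contigs, truth = fragment_genome(g, 5, "TTAGG", 8, seed=5)
        pieces = []
        for contig in contigs:
            seq = contig.seq
            planted = truth[truth.contig_id == contig.id]
            for _, row in planted.iterrows():
                if row.terminus == "5p":
                    seq = seq[5 * row.copies :]
                else:
                    seq = seq[: -5 * row.copies]
            pieces.append(seq)
        assert "".join(pieces) == g[0].seq

    def test_too_many_contigs_rejected(self):
        g = generate_genome(GenomeSpec(10, 0.5, seed=1))
        with pytest.raises(InputError):
            fragment_genome(g, 11, "TTAGG", 0, seed=0)


class TestSimulateReads:
    def test_read_count_arithmetic(self):
        g = generate_genome(GenomeSpec(1_000, 0.5, seed=1))
        reads = simulate_reads(g, ReadSimSpec(coverage=1, read_length_bp=100))
        assert len(reads) == 10

    def test_error_free_reads_match_template(self):
        g = generate_genome(GenomeSpec(2_000, 0.4, seed=2))
        reads = simulate_reads(
            g, ReadSimSpec(coverage=2, read_length_bp=50, error_rate=0.0, seed=4)
        )
        genome = g[0].seq
        for read in reads:
            origin = int(read.id.split(":")[-1])
            assert genome[origin : origin + 50] == read.seq

    def test_substitution_rate_within_stated_bounds(self):
        g = generate_genome(GenomeSpec(100_000, 0.352, seed=11))
        reads = simulate_reads(
            g, ReadSimSpec(coverage=50, read_length_bp=100, error_rate=0.01, seed=11)
        )
        genome = g[0].seq
        mismatches = total = 0
        for read in reads:
            origin = int(read.id.split(":")[-1])
            template = genome[origin : origin + 100]
            mismatches += sum(a != b for a, b in zip(read.seq, template))
            total += 100
        assert 0.007 <= mismatches / total <= 0.013

    def test_invalid_coverage_rejected(self):
        g = generate_genome(GenomeSpec(1_000, 0.5, seed=1))
        with pytest.raises(InputError):
            simulate_reads(g, ReadSimSpec(coverage=0, read_length_bp=50))


class TestSimulateDomainCounts:
    TOTALS = (18_000, 20_000, 22_000, 19_000, 21_000)

    def test_zero_rate_gives_all_zero_matrix(self):
        counts, _, _ = simulate_domain_counts(
            ExpansionSimSpec(5, 50, self.TOTALS, baseline_rate=0.0, seed=1)
        )
        assert (counts.to_numpy() == 0).all()

    def test_null_grand_mean_near_baseline_rate(self):
        counts, _, _ = simulate_domain_counts(
            ExpansionSimSpec(5, 200, self.TOTALS, baseline_rate=5.0, seed=2)
        )
        assert 4.0 <= counts.to_numpy().mean() <= 6.0

    def test_planted_cells_exceed_background(self):
        expanded = {f"PF{i + 1:05d}": ("sp01", 8.0) for i in range(10)}
        counts, _, truth = simulate_domain_counts(
            ExpansionSimSpec(5, 100, self.TOTALS, 5.0, expanded_set=expanded, seed=3)
        )
        focal_cells = counts.loc["sp01", truth.domain]
        bg_cells = counts.drop(index="sp01")[truth.domain]
        assert focal_cells.mean() > bg_cells.to_numpy().mean()

    def test_fold_change_at_most_one_rejected(self):
        with pytest.raises(InputError):
            simulate_domain_counts(
                ExpansionSimSpec(
                    5, 10, self.TOTALS, 5.0,
                    expanded_set={"PF00001": ("sp01", 1.0)}, seed=1,
                )
            )

    def test_counts_bounded_by_gene_totals(self):
        counts, totals, _ = simulate_domain_counts(
            ExpansionSimSpec(3, 30, (5, 10, 15), baseline_rate=20.0, seed=4)
        )
        assert counts.le(totals, axis=0).to_numpy().all()


class TestSimulateExpression:
    def test_minimal_shape(self):
        counts, lengths = simulate_expression(1, 1, seed=1)
        assert counts.shape == (1, 1)
        assert len(lengths) == 1

    def test_deterministic_under_seed(self):
        a, la = simulate_expression(100, 12, seed=5)
        b, lb = simulate_expression(100, 12, seed=5)
        assert a.equals(b) and la.equals(lb)

    def test_tpm_round_trip_columns_sum_to_one_million(self):
        counts, lengths = simulate_expression(100, 12, seed=5)
        tpm = tpm_from_counts(ExpressionMatrix(counts, "raw_count"), lengths)
        assert np.allclose(tpm.values.sum(axis=0), 1e6, atol=1e-3)
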