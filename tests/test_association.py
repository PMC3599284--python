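import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from setcorr import association as assoc
from setcorr.enrichment import EnrichmentMatrix, enrichment_matrix
from setcorr.io_formats import ExpressionMatrix, GeneSet, read_association_table, \
    write_association_table
from setcorr.preprocess import PreparedGeneSet


def prepared_set(name, members, is_down=False):
    return PreparedGeneSet(GeneSet(name, ".", tuple(members), is_down),
                           tuple(members))


def random_expr(rng, n_genes, n_samples):
    return ExpressionMatrix(tuple(f"G{i:03d}" for i in range(n_genes)),
                            tuple(f"S{j:03d}" for j in range(n_samples)),
                            rng.normal(size=(n_genes, n_samples)))


class TestSpearman:
    def test_monotone_identity_and_reversal(self):
        assert assoc.spearman_rho([1, 2, 3], [10, 20, 30]) == 1.0
        assert assoc.spearman_rho([1, 2, 3], [30, 20, 10]) == -1.0

    def test_tied_inputs_match_midrank_pearson(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert assoc.spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_random_tied_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 21))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            expected = stats.spearmanr(x, y).statistic
            assert assoc.spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(assoc.spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_length_errors(self):
        with pytest.raises(ValueError):
            assoc.spearman_rho([1, 2], [1, 2])
        with pytest.raises(ValueError):
            assoc.spearman_rho([1, 2, 3], [1, 2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=15, unique=True),
           st.lists(st.integers(-50, 50), min_size=4, max_size=15, unique=True))
    def test_invariant_under_increasing_transforms(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n], float), np.array(ys[:n], float)
        base = assoc.spearman_rho(x, y)
        assert assoc.spearman_rho(np.exp(x / 50), y) == pytest.approx(base, abs=1e-12)
        assert assoc.spearman_rho(x, y ** 3) == pytest.approx(base, abs=1e-12)


class TestCenterAndRank:
    def test_relative_rank_arithmetic(self):
        # the 879,685th strongest of 80,705,030 coefficients -> top 1.1%
        rel = assoc.relative_rank_from_position(879_685, 80_705_030)
        assert round(rel, 3) == 0.011

    def test_zero_centered_example(self):
        # rho (0.8, -0.6, 0.2, -0.4): center 0, magnitude order 0.8 > 0.6 > 0.4 > 0.2
        center, rel = assoc.center_and_rank(np.array([[0.8, -0.6, 0.2, -0.4]]))
        assert center == pytest.approx(0.0)
        np.testing.assert_allclose(rel[0], [0.25, 0.50, 1.00, 0.75])

    def test_single_entry(self):
        center, rel = assoc.center_and_rank(np.array([[0.3]]))
        assert rel[0, 0] == 1.0 and center == 0.3

    def test_magnitude_ties_get_average_ranks(self):
        # center 0; magnitudes (0.5, 0.5, 0.1): tied top pair -> rank 1.5 each
        _, rel = assoc.center_and_rank(np.array([[0.5, -0.5, 0.1, -0.1]]))
        np.testing.assert_allclose(rel[0], [1.5 / 4, 1.5 / 4, 3.5 / 4, 3.5 / 4])

    def test_nan_excluded_from_distribution(self):
        center, rel = assoc.center_and_rank(np.array([[0.8, np.nan, -0.8]]))
        assert center == pytest.approx(0.0)
        assert np.isnan(rel[0, 1])
        np.testing.assert_allclose(rel[0, [0, 2]], [0.75, 0.75])

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            assoc.center_and_rank(np.array([[np.nan]]))

    def test_monotone_in_magnitude(self, rng):
        rho = rng.uniform(-1, 1, size=(10, 7))
        center, rel = assoc.center_and_rank(rho)
        mag = np.abs(rho - center).ravel()
        order = np.argsort(mag)
        assert (np.diff(rel.ravel()[order]) <= 1e-15).all()


class TestCorrelationMatrix:
    def test_gene_equal_to_scores_correlates_perfectly(self, rng):
        expr = random_expr(rng, 4, 8)
        enr = enrichment_matrix(expr, [prepared_set("S", ["G000", "G001"])])
        # overwrite one gene's expression with the set's score profile
        values = expr.values.copy()
        values[3] = enr.z[0]
        expr2 = ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)
        index = assoc.correlation_matrix(expr2, enr)
        assert index.rho[3, 0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("gene_block", [1, 2, 3])
    def test_chunk_invariance_small(self, rng, gene_block):
        expr = random_expr(rng, 3, 6)
        enr = enrichment_matrix(expr, [prepared_set("A", ["G000"]),
                                       prepared_set("B", ["G001", "G002"])])
        full = assoc.correlation_matrix(expr, enr, gene_block=3)
        other = assoc.correlation_matrix(expr, enr, gene_block=gene_block)
        np.testing.assert_array_equal(full.rho, other.rho)
        np.testing.assert_array_equal(full.relative_rank, other.relative_rank)

    def test_matches_pairwise_scalar_oracle(self, rng):
        expr = random_expr(rng, 10, 8)
        sets = [prepared_set(f"S{k}", [f"G{i:03d}" for i in
                                       rng.choice(10, 3, replace=False)])
                for k in range(4)]
        enr = enrichment_matrix(expr, sets)
        index = assoc.correlation_matrix(expr, enr)
        for g in range(10):
            for k in range(4):
                expected = assoc.spearman_rho(expr.values[g], enr.z[k])
                assert index.rho[g, k] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_gives_nan_row(self, rng):
        expr = random_expr(rng, 4, 6)
        values = expr.values.copy()
        values[2] = 1.0
        expr2 = ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)
        enr = enrichment_matrix(expr2, [prepared_set("S", ["G000", "G001"])])
        index = assoc.correlation_matrix(expr2, enr)
        assert np.isnan(index.rho[2, 0])
        assert index.n_finite == 3

    def test_sample_order_mismatch_rejected(self, rng):
        expr = random_expr(rng, 4, 6)
        enr = enrichment_matrix(expr, [prepared_set("S", ["G000", "G001"])])
        swapped = EnrichmentMatrix(enr.set_names,
                                   tuple(reversed(enr.sample_ids)), enr.z)
        with pytest.raises(ValueError, match="sample order"):
            assoc.correlation_matrix(expr, swapped)


class TestRankGeneSetsForGene:
    def index(self):
        rho = np.array([[-0.9, 0.5, 0.1, 0.3],
                        [0.2, -0.1, 0.05, 0.15]])
        return assoc.AssociationIndex.from_rho(
            ("G1", "G2"), ("X_DN", "B", "C", "D"), rho,
            is_down=[True, False, False, False])

    def test_down_set_outranks_and_flips(self):
        records = assoc.rank_gene_sets_for_gene(self.index(), "G1")
        top = records[0]
        assert top.set_name == "X_DN"
        assert top.rho == pytest.approx(-0.9)
        assert top.reported_rho == pytest.approx(0.9)
        assert top.flipped is True
        assert [r.relative_rank for r in records] == sorted(
            r.relative_rank for r in records)

    def test_flip_is_an_involution(self):
        rec = assoc.rank_gene_sets_for_gene(self.index(), "G1")[0]
        assert -rec.reported_rho == pytest.approx(rec.rho)
        assert abs(rec.reported_rho) == abs(rec.rho)

    def test_k_clamped_and_exclude(self):
        index = self.index()
        assert len(assoc.rank_gene_sets_for_gene(index, "G1", k=100)) == 4
        records = assoc.rank_gene_sets_for_gene(index, "G1", exclude=["X_DN"])
        assert [r.set_name for r in records][0] != "X_DN"
        assert len(records) == 3

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError, match="NOPE"):
            assoc.rank_gene_sets_for_gene(self.index(), "NOPE")

    def test_perfect_unique_correlation_ranks_first(self):
        # one gene at rho = 1.0 against its only set; all other pairs weak,
        # so that pair is the global magnitude maximum -> rank 1 of n_finite
        rho = np.array([[1.0], [0.2], [-0.3], [0.1], [-0.2]])
        index = assoc.AssociationIndex.from_rho(
            tuple(f"G{i}" for i in range(5)), ("S",), rho)
        top = assoc.rank_gene_sets_for_gene(index, "G0")[0]
        assert top.set_name == "S"
        assert top.rho == 1.0
        assert top.relative_rank == pytest.approx(1 / index.n_finite)


class TestRankGenesForGeneSet:
    def test_non_member_matches_full_set_correlation(self, rng):
        expr = random_expr(rng, 8, 12)
        p = prepared_set("S", ["G000", "G001", "G002"])
        enr = enrichment_matrix(expr, [p])
        records = {r.gene: r for r in assoc.rank_genes_for_gene_set(expr, p)}
        rec = records["G005"]
        assert rec.loo_applied is False
        assert rec.rho == pytest.approx(
            assoc.spearman_rho(expr.row("G005"), enr.z[0]), abs=1e-12)
        assert records["G000"].loo_applied is True

    def test_planted_module_genes_precede_background(self, rng):
        # 3 planted co-regulated genes (not in the set) vs pure-noise background
        n_samples = 60
        latent = rng.normal(size=n_samples)
        members = {f"M{i}": 1.0 * latent + 0.1 * rng.normal(size=n_samples)
                   for i in range(5)}
        planted = {f"P{i}": 1.0 * latent + 0.1 * rng.normal(size=n_samples)
                   for i in range(3)}
        noise = {f"N{i}": rng.normal(size=n_samples) for i in range(6)}
        rows = {**members, **planted, **noise}
        expr = ExpressionMatrix(tuple(rows), tuple(f"S{j}" for j in range(n_samples)),
                                np.array(list(rows.values())))
        p = prepared_set("MOD", list(members))
        records = assoc.rank_genes_for_gene_set(expr, p, loo=True)
        non_members = [r.gene for r in records if r.gene not in members]
        assert set(non_members[:3]) == set(planted)

    def test_too_small_set_rejected(self, rng):
        expr = random_expr(rng, 5, 6)
        with pytest.raises(ValueError, match="m >= 3"):
            assoc.rank_genes_for_gene_set(expr, prepared_set("S", ["G000", "G001"]))


class TestGeneSetFrequency:
    def test_one_gene_counts_every_set_once(self, rng):
        rho = rng.uniform(-1, 1, size=(1, 5))
        index = assoc.AssociationIndex.from_rho(
            ("G1",), tuple(f"S{k}" for k in range(5)), rho)
        counts = assoc.gene_set_frequency(index, top_n=5)
        assert (counts == 1).all() and counts.sum() == 5

    def test_counts_definition(self):
        # SET_A is in the top-2 of 3 of the 4 genes
        rho = np.array([[0.9, 0.8, 0.1],
                        [0.7, 0.2, 0.6],
                        [-0.9, -0.5, 0.1],
                        [0.05, 0.5, 0.6]])
        index = assoc.AssociationIndex.from_rho(
            tuple(f"G{i}" for i in range(4)), ("SET_A", "SET_B", "SET_C"), rho)
        counts = assoc.gene_set_frequency(index, top_n=2)
        assert counts["SET_A"] == 3
        assert counts.sum() == 4 * 2

    def test_recount_from_serialized_table(self, tmp_path, rng):
        rho = rng.uniform(-1, 1, size=(12, 6))
        index = assoc.AssociationIndex.from_rho(
            tuple(f"G{i:02d}" for i in range(12)),
            tuple(f"S{k}" for k in range(6)), rho)
        counts = assoc.gene_set_frequency(index, top_n=3)
        path = tmp_path / "assoc.tsv"
        write_association_table(index, path, top_k=3)
        frame = read_association_table(path)
        recounted = frame["gene_set"].value_counts()
        for name in index.set_names:
            assert counts[name] == recounted.get(name, 0)

    def test_top_n_below_one_rejected(self):
        index = assoc.AssociationIndex.from_rho(("G",), ("S",), [[0.5]])
        with pytest.raises(ValueError):
            assoc.gene_set_frequency(index, top_n=0)
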