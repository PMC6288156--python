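import numpy as np
import pandas as pd
import pytest

from seedtrace import diffexpr, seeding, synthetic_data as sd
from seedtrace.io_prep import ExpressionMatrix
from seedtrace.seeding import call_seeding_focus, hcluster, seeding_de, top_variable


def log2_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit="log2counts")


class TestTopVariable:
    def test_k_equals_total_identity(self, rng):
        expr = log2_matrix(rng.normal(0, 1, (10, 5)))
        assert set(top_variable(expr, 10)) == set(expr.gene_ids)

    def test_single_high_variance_gene(self):
        vals = np.ones((5, 4))
        vals[2] = [0, 10, -10, 5]
        expr = log2_matrix(vals)
        assert top_variable(expr, 1) == ["g2"]

    def test_matches_sort_oracle(self, rng):
        expr = log2_matrix(rng.normal(0, 1, (100, 8)))
        var = expr.data.var(axis=1, ddof=1)
        oracle = list(var.sort_values(ascending=False, kind="stable").index[:30])
        assert set(top_variable(expr, 30)) == set(oracle)

    def test_bad_k_rejected(self, rng):
        expr = log2_matrix(rng.normal(0, 1, (4, 3)))
        with pytest.raises(ValueError):
            top_variable(expr, 0)
        with pytest.raises(ValueError):
            top_variable(expr, 5)


def reference_agglomeration(points, method="complete"):
    """O(n^3) agglomerative clustering used as an independent oracle.

    Returns the merge history as a list of (frozenset, frozenset, height).
    """
    from scipy.spatial.distance import cdist

    clusters = {i: frozenset([i]) for i in range(len(points))}
    d = cdist(points, points)
    merges = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                if method == "complete":
                    dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
                else:
                    dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[2]:
                    best = (a, b, dist)
        a, b, dist = best
        merges.append((clusters[a], clusters[b], dist))
        clusters[min(a, b)] = clusters.pop(a) | clusters.pop(b)
    return merges


class TestHCluster:
    def test_line_geometry_first_merge(self):
        expr = log2_matrix(np.array([[0.0, 1.0, 10.0]]))
        dend = hcluster(expr)
        first = dend.merge[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_duplicated_sample_zero_height(self):
        vals = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]])
        dend = hcluster(log2_matrix(vals))
        assert dend.merge[0][2] == pytest.approx(0.0)
        assert {int(dend.merge[0][0]), int(dend.merge[0][1])} == {0, 1}

    @pytest.mark.parametrize("method", ["complete", "average"])
    def test_matches_reference_agglomeration(self, rng, method):
        expr = log2_matrix(rng.normal(0, 2, (30, 6)))
        dend = hcluster(expr, method=method)
        oracle = reference_agglomeration(expr.data.to_numpy().T, method=method)
        heights = sorted(m[2] for m in oracle)
        np.testing.assert_allclose(np.sort(dend.merge[:, 2]), heights, atol=1e-9)
        # first merge joins the same pair
        first_pair = oracle[0][0] | oracle[0][1]
        assert {int(dend.merge[0][0]), int(dend.merge[0][1])} == set(first_pair)

    def test_two_sample_minimum(self):
        with pytest.raises(ValueError):
            hcluster(log2_matrix(np.ones((3, 1))))

    def test_newick_export_contains_all_samples(self, rng):
        expr = log2_matrix(rng.normal(0, 1, (10, 4)))
        nwk = hcluster(expr).to_newick()
        assert nwk.endswith(";")
        for s in expr.sample_ids:
            assert s in nwk


@pytest.fixture(scope="module")
def world():
    cfg = sd.SimulationConfig(seed=3)
    expr, ann, truth = sd.gen_multifocal_counts(cfg)
    return diffexpr.normalized_log2(expr), ann, truth


class TestCallSeedingFocus:
    def test_planted_focus_recovered(self, world):
        log2, ann, truth = world
        eligible = [
            pid
            for pid in ann["patient_id"].unique()
            if (ann[(ann.patient_id == pid) & (ann.tissue_type == "CAN")].shape[0] >= 2)
            and (ann[(ann.patient_id == pid) & (ann.tissue_type == "MET")].shape[0] >= 1)
        ]
        for pid in eligible:
            call = call_seeding_focus(log2, ann, pid)
            assert call.status == "resolved"
            assert call.seeding_focus == truth.seeding_focus_per_patient[pid]
            assert set(call.support) == set(seeding.DEFAULT_K_LIST)

    def test_ineligible_patient(self, world):
        log2, ann, _ = world
        # PT2 has a single tumour focus in the discovery design
        assert call_seeding_focus(log2, ann, "PT2").status == "ineligible"

    def test_column_order_invariance(self, world):
        log2, ann, truth = world
        rng = np.random.default_rng(0)
        shuffled = log2.subset_samples(list(rng.permutation(log2.sample_ids)))
        call = call_seeding_focus(shuffled, ann, "PT5")
        assert call.status == "resolved"
        assert call.seeding_focus == truth.seeding_focus_per_patient["PT5"]

    def test_k_list_permutation_stability(self, world):
        log2, ann, _ = world
        a = call_seeding_focus(log2, ann, "PT5", k_list=(500, 100, 50))
        b = call_seeding_focus(log2, ann, "PT5", k_list=(50, 500, 100))
        assert a.status == b.status == "resolved"
        assert a.seeding_focus == b.seeding_focus

    def test_exchangeable_foci_mostly_unresolved(self):
        """No seeding signal and no clone inheritance: foci are exchangeable,
        so the stringent all-K agreement should usually fail."""
        unresolved = 0
        total = 0
        for seed in range(6):
            cfg = sd.SimulationConfig(
                n_genes=2000, seed=seed, n_clone_genes=0, seeding_lfc=0.0
            )
            expr, ann, _ = sd.gen_multifocal_counts(cfg)
            log2 = diffexpr.normalized_log2(expr)
            for call in seeding.call_all_patients(log2, ann):
                if call.status == "ineligible":
                    continue
                total += 1
                if call.status == "unresolved":
                    unresolved += 1
        assert unresolved > total / 2


class TestSeedingDE:
    def test_identical_groups_empty_panels(self, rng):
        counts = pd.DataFrame(
            np.tile(rng.poisson(60.0, (40, 3)), (1, 2)).astype(float),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(6)],
        )
        expr = ExpressionMatrix(counts, unit="counts")
        _, broad, strict = seeding_de(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert len(broad) == 0 and len(strict) == 0

    def test_nesting_on_multifocal_world(self, small_discovery):
        """Strict panel nests in the broad one even with clone-marker noise."""
        _, expr, ann, truth = small_discovery
        ann_i = ann.set_index("sample_id")
        seed_samples, nonseed = [], []
        for pid, focus in truth.seeding_focus_per_patient.items():
            mine = ann_i[(ann_i.patient_id == pid) & (ann_i.tissue_type == "CAN")]
            if len(mine) < 2:
                continue
            for sid, row in mine.iterrows():
                (seed_samples if row["focus_label"] == focus else nonseed).append(sid)
        _, broad, strict = seeding_de(expr, seed_samples, nonseed)
        assert set(strict.gene_ids) <= set(broad.gene_ids)

    def test_planted_shift_recovered_three_vs_three(self, rng):
        """20 genes shifted by |log2fc| = 2 between 3 seeding and 3 non-seeding
        foci (NB dispersion 0.1): the strict FDR < 0.01 panel recalls >= 80%."""
        n_genes, n_plant = 500, 20
        mu = rng.gamma(3.0, 40.0, n_genes)
        shift = np.ones(n_genes)
        shift[:n_plant] = 2.0 ** -2
        r = 1 / 0.1
        counts = np.column_stack(
            [rng.negative_binomial(r, r / (r + mu * shift)) for _ in range(3)]
            + [rng.negative_binomial(r, r / (r + mu)) for _ in range(3)]
        ).astype(float)
        expr = ExpressionMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"s{j}" for j in range(6)]),
            unit="counts",
        )
        _, broad, strict = seeding_de(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        planted = {f"g{i}" for i in range(n_plant)}
        assert set(strict.gene_ids) <= set(broad.gene_ids)
        assert len(set(strict.gene_ids) & planted) / n_plant >= 0.8

    def test_empty_side_rejected(self, rng):
        expr = ExpressionMatrix(
            pd.DataFrame(rng.poisson(10.0, (5, 2)).astype(float), columns=["a", "b"]),
            unit="counts",
        )
        with pytest.raises(ValueError):
            seeding_de(expr, [], ["a", "b"])
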