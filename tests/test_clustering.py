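import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from scstrmix.cell_sim import CellProfile, DropModel, MixtureDataset, assemble_mixture
from scstrmix.clustering import (
    FeatureMatrix,
    _normalized_values,
    cluster_em,
    cluster_kmeans,
    encode_profiles,
    estimate_noc,
    estimate_noc_ibs,
    pairwise_distances,
    silhouette_coefficient,
)
from scstrmix.freq_panel import synthesize_frequency_table
from scstrmix.genotype_sim import RelationshipSpec, simulate_contributors


def simulate(panel, counts, D=0.0, e=0.0, seed=0, ploidy="diploid",
             kind="unrelated-set"):
    rng = np.random.default_rng(seed)
    spec = RelationshipSpec(kind=kind, n_contributors=len(counts))
    contribs = simulate_contributors(spec, panel, fst=0.01, rng=rng)
    ds = assemble_mixture(contribs, list(counts), panel, DropModel(D=D, e=e),
                          rng, ploidy=ploidy)
    return ds, contribs


def truth_labels(ds, contribs):
    ids = [c.contributor_id for c in contribs]
    return np.array([ids.index(c.truth_contributor) for c in ds.cells])


def random_noisy_matrix(rng, n=15, d=8, missing=0.2):
    values = rng.normal(size=(n, d)) * 3 + 10
    mask = rng.random((n, d)) >= missing
    values = np.where(mask, values, np.nan)
    return FeatureMatrix(values=values, mask=mask,
                         slot_names=tuple(f"s{i}" for i in range(d)),
                         cell_ids=tuple(f"c{i}" for i in range(n)))


class TestEncodeProfiles:
    def test_shape_and_packing(self, panel21):
        ds, _ = simulate(panel21, (20, 20), D=0.2, e=0.01, seed=1)
        m = encode_profiles(ds)
        assert m.values.shape == (40, 42)
        # observed slot values are sorted ascending within each locus
        for i, cell in enumerate(ds.cells):
            for j, locus in enumerate(panel21.loci):
                obs = cell.calls[locus]
                stored = m.values[i, 2 * j: 2 * j + 2]
                if len(obs) == 2:
                    assert stored[0] <= stored[1]
                elif len(obs) == 1:
                    assert not np.isnan(stored[0]) and np.isnan(stored[1])

    def test_missing_slots_masked(self, panel21):
        ds, _ = simulate(panel21, (10, 10), D=0.5, e=0.0, seed=2)
        m = encode_profiles(ds)
        assert (~m.mask).any()
        assert np.isnan(m.values[~m.mask]).all()

    def test_haploid_has_l_slots(self, panel21):
        ds, _ = simulate(panel21, (5, 5), ploidy="haploid", seed=3)
        assert encode_profiles(ds).values.shape == (10, 21)


class TestClusterEm:
    def test_separable_duplicates_recovered(self, panel21):
        ds, contribs = simulate(panel21, (10, 10), seed=4)
        m = encode_profiles(ds)
        res = cluster_em(m, 2, seed=0)
        truth = truth_labels(ds, contribs)
        agree = max((res.assignment == truth).mean(),
                    (res.assignment != truth).mean())
        assert agree == 1.0

    def test_log_likelihood_non_decreasing_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            m = random_noisy_matrix(rng)
            res = cluster_em(m, 3, seed=trial)
            path = np.array(res.objective_path)
            assert np.all(np.diff(path) >= -1e-7)

    def test_k1_single_cluster(self, panel21):
        ds, _ = simulate(panel21, (4, 4), seed=6)
        res = cluster_em(encode_profiles(ds), 1, seed=0)
        assert res.k == 1
        assert set(res.assignment) == {0}
        assert res.silhouette is None

    def test_k_above_n_rejected(self, panel21):
        ds, _ = simulate(panel21, (2, 2), seed=7)
        with pytest.raises(ValueError):
            cluster_em(encode_profiles(ds), 5, seed=0)

    def test_deterministic_for_seed(self, panel21):
        ds, _ = simulate(panel21, (10, 10), D=0.2, e=0.01, seed=8)
        m = encode_profiles(ds)
        a = cluster_em(m, 3, seed=42)
        b = cluster_em(m, 3, seed=42)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert a.objective == b.objective


class TestClusterKmeans:
    def test_two_duplicated_points_partitioned_exactly(self, tiny_panel):
        cells = []
        for i in range(4):
            calls = {"LA": (8.0, 8.0), "LB": (9.0, 9.0)} if i < 2 else \
                    {"LA": (10.0, 10.0), "LB": (8.0, 8.0)}
            cells.append(CellProfile(cell_id=f"c{i}", ploidy="diploid", calls=calls))
        ds = MixtureDataset(cells=tuple(cells), panel=tiny_panel)
        res = cluster_kmeans(encode_profiles(ds), 2, seed=0)
        assert res.objective == pytest.approx(0.0)
        assert res.assignment[0] == res.assignment[1]
        assert res.assignment[2] == res.assignment[3]
        assert res.assignment[0] != res.assignment[2]

    def test_objective_non_increasing_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for trial in range(20):
            m = random_noisy_matrix(rng, missing=0.1)
            res = cluster_kmeans(m, 3, seed=trial)
            path = np.array(res.objective_path)
            assert np.all(np.diff(path) <= 1e-9)

    def test_identical_cells_reseed_to_nonempty_clusters(self, tiny_panel):
        calls = {"LA": (8.0, 9.0), "LB": (9.0, 10.0)}
        cells = tuple(
            CellProfile(cell_id=f"c{i}", ploidy="diploid", calls=calls)
            for i in range(5)
        )
        ds = MixtureDataset(cells=cells, panel=tiny_panel)
        res = cluster_kmeans(encode_profiles(ds), 2, seed=0)
        sizes = np.bincount(res.assignment, minlength=2)
        assert np.all(sizes > 0)
        assert res.objective == pytest.approx(0.0)


def silhouette_oracle(dist, labels):
    """Textbook silhouette from an explicit distance matrix (brute force)."""
    n = len(labels)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in own])
        b = min(
            np.mean([dist[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(scores))


class TestSilhouette:
    def test_tight_far_clusters_score_high(self, panel21):
        ds, contribs = simulate(panel21, (10, 10), seed=10)
        m = encode_profiles(ds)
        assert silhouette_coefficient(m, truth_labels(ds, contribs)) > 0.9

    def test_matches_brute_force_oracle_on_small_fixtures(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            m = random_noisy_matrix(rng, n=8, d=5, missing=0.25)
            labels = rng.integers(0, 3, size=8)
            if len(set(labels.tolist())) < 2:
                continue
            dist = pairwise_distances(m)
            ours = silhouette_coefficient(m, labels, dist=dist)
            assert ours == pytest.approx(silhouette_oracle(dist, labels), abs=1e-12)

    def test_matches_sklearn_on_complete_data(self):
        rng = np.random.default_rng(12)
        m = random_noisy_matrix(rng, n=12, d=6, missing=0.0)
        labels = rng.integers(0, 3, size=12)
        dist = pairwise_distances(m, normalize=False)
        ours = silhouette_coefficient(m, labels, dist=dist)
        ref = silhouette_score(np.where(m.mask, m.values, 0.0), labels,
                               metric="euclidean")
        assert ours == pytest.approx(float(ref), abs=1e-10)

    def test_all_singletons_score_zero(self):
        rng = np.random.default_rng(13)
        m = random_noisy_matrix(rng, n=5, d=4, missing=0.0)
        assert silhouette_coefficient(m, np.arange(5)) == 0.0

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(14)
        m = random_noisy_matrix(rng, n=10, d=6)
        labels = rng.integers(0, 3, size=10)
        permuted = (labels + 1) % 3
        assert silhouette_coefficient(m, labels) == pytest.approx(
            silhouette_coefficient(m, permuted)
        )

    def test_single_cluster_rejected(self):
        rng = np.random.default_rng(15)
        m = random_noisy_matrix(rng, n=4, d=3)
        with pytest.raises(ValueError):
            silhouette_coefficient(m, np.zeros(4, dtype=int))


class TestEstimateNoc:
    def test_noiseless_separable_two_contributors(self, panel21):
        ds, _ = simulate(panel21, (20, 20), seed=16)
        est = estimate_noc(encode_profiles(ds), "em", seed=0)
        assert est.noc == 2

    def test_per_k_bookkeeping(self, panel21):
        ds, _ = simulate(panel21, (10, 10), seed=17)
        est = estimate_noc(encode_profiles(ds), "kmeans", k_min=2, k_max=6, seed=0)
        assert sorted(est.per_k_scores) == [2, 3, 4, 5, 6]
        assert est.best_clustering.k == est.noc

    def test_noiseless_em_exact_for_two_and_three_contributors(self, panel21):
        for n_contrib, counts in ((2, (3, 3)), (3, (3, 3, 3))):
            for seed in range(20):
                ds, _ = simulate(panel21, counts, seed=100 + seed)
                est = estimate_noc(encode_profiles(ds), "em", seed=seed)
                assert est.noc == n_contrib

    def test_too_few_cells_rejected(self, panel21):
        ds, _ = simulate(panel21, (1, 0), seed=18)
        with pytest.raises(ValueError):
            estimate_noc(encode_profiles(ds), "em")


class TestEstimateNocIbs:
    def test_identical_cells_one_component(self, tiny_panel):
        calls = {"LA": (8.0, 9.0), "LB": (9.0, 10.0)}
        cells = tuple(
            CellProfile(cell_id=f"c{i}", ploidy="diploid", calls=calls)
            for i in range(6)
        )
        ds = MixtureDataset(cells=cells, panel=tiny_panel)
        assert estimate_noc_ibs(ds, min_same_source_ibs=3).noc == 1

    def test_two_unrelated_contributors_resolved_at_threshold_24(self, panel21):
        correct = 0
        reps = 200
        for seed in range(reps):
            ds, _ = simulate(panel21, (10, 10), D=0.2, e=0.01, seed=300 + seed)
            correct += estimate_noc_ibs(ds, min_same_source_ibs=24).noc == 2
        assert correct / reps >= 0.95

    def test_max_threshold_isolates_non_duplicates(self, panel21):
        ds, _ = simulate(panel21, (3, 3), D=0.2, e=0.01, seed=19)
        est = estimate_noc_ibs(ds, min_same_source_ibs=42)
        # only exact duplicates could join; with drop-out they are all distinct
        assert est.noc == ds.n_cells

    def test_haploid_input_warns(self, panel21):
        ds, _ = simulate(panel21, (3, 3), ploidy="haploid", seed=20)
        with pytest.warns(UserWarning, match="haploid"):
            estimate_noc_ibs(ds)
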