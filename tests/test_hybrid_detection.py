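import warnings

import numpy as np
import pytest

from _helpers import (
    delta_direct,
    dendropy_rf,
    random_symmetric_matrix,
    score_direct,
)
from lexinet import (
    DetectionParameters,
    DistanceMatrix,
    default_parameters,
    detect_at_step,
    estimate_alpha,
    hybridization_score,
    infer_network,
    inject_hybrid,
    iterate_removal,
    least_squares,
    neighbor_deviation,
    nj_tree,
    select_neighbors,
)
from lexinet.synthetic_data import SimulationSpec, random_additive_matrix

PERMISSIVE = DetectionParameters(0.0, 0.1, 0.9)


def convex_case(seed=5, alpha=0.3, n=8):
    spec = SimulationSpec(n_taxa=n, seed=seed)
    _, D = random_additive_matrix(spec)
    j = int(np.argmax([D.d("L1", l) for l in D.labels]))
    p1, p2 = "L1", D.labels[j]
    return inject_hybrid(D, p1, p2, alpha, "HYB"), p1, p2


class TestEstimateAlpha:
    def test_exact_on_convex_construction(self):
        Dh, p1, p2 = convex_case(alpha=0.3)
        a = estimate_alpha(Dh, "HYB", p1, p2)
        assert a == pytest.approx(0.3, abs=1e-12)
        assert least_squares(Dh, "HYB", p1, p2, a) == pytest.approx(0.0, abs=1e-20)

    def test_symmetric_construction_gives_half(self, worked_dm):
        # the worked example is invariant under mirroring the two lineages
        assert estimate_alpha(worked_dm, "L4", "L3", "L5") == pytest.approx(0.5)

    def test_degenerate_donors_return_nan(self):
        # i and j with identical rows: sum X_k^2 == 0
        vals = np.array(
            [
                [0, 1, 2, 2, 3],
                [1, 0, 2, 2, 3],
                [2, 2, 0, 1, 3],
                [2, 2, 1, 0, 3],
                [3, 3, 3, 3, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(("h", "x", "i", "j", "k"), vals)
        assert np.isnan(estimate_alpha(dm, "h", "i", "j"))

    def test_requires_five_nodes_and_distinct_labels(self, rng):
        D = random_symmetric_matrix(4, rng)
        with pytest.raises(ValueError):
            estimate_alpha(D, "T0", "T1", "T2")
        D5 = random_symmetric_matrix(5, rng)
        with pytest.raises(ValueError):
            estimate_alpha(D5, "T0", "T0", "T2")


class TestLeastSquares:
    def test_zero_at_truth_positive_nearby(self):
        Dh, p1, p2 = convex_case(alpha=0.4)
        assert least_squares(Dh, "HYB", p1, p2, 0.4) == pytest.approx(0.0, abs=1e-18)
        assert least_squares(Dh, "HYB", p1, p2, 0.5) > 1e-6

    def test_grid_search_minimum_at_closed_form(self, rng):
        grid = np.linspace(-1.0, 2.0, 301)  # step 0.01
        for _ in range(10):
            D = random_symmetric_matrix(6, rng)
            a = estimate_alpha(D, "T0", "T1", "T2")
            assert -1.0 < a < 2.0
            ls_grid = [least_squares(D, "T0", "T1", "T2", g) for g in grid]
            g_best = grid[int(np.argmin(ls_grid))]
            assert abs(g_best - a) <= 0.01 + 1e-12


class TestHybridizationScore:
    def test_additive_quartet_zero(self):
        # topology ((i,h),(j,k)): the four-point condition zeroes one term
        vals = np.array(
            [
                [0, 2, 5, 6],
                [2, 0, 5, 6],
                [5, 5, 0, 3],
                [6, 6, 3, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(("i", "h", "j", "k"), vals)
        assert hybridization_score(dm, "h", "i", "j") == pytest.approx(0.0)

    def test_shift_of_h_row_moves_score_by_epsilon(self, rng):
        D = random_symmetric_matrix(6, rng)
        base = hybridization_score(D, "T0", "T1", "T2")
        assert base == pytest.approx(score_direct(D, "T0", "T1", "T2"))
        eps = 0.37
        vals = D.values.copy()
        for k in range(D.n):
            if D.labels[k] not in ("T0", "T1", "T2"):
                vals[k, 0] += eps
                vals[0, k] += eps
        shifted = DistanceMatrix(D.labels, vals)
        assert hybridization_score(shifted, "T0", "T1", "T2") == pytest.approx(
            base + eps
        )

    def test_equidistant_taxa_zero(self):
        vals = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(("h", "i", "j", "k"), vals)
        assert hybridization_score(dm, "h", "i", "j") == 0.0


class TestNeighborDeviation:
    def test_zero_for_true_neighbors_every_h(self):
        spec = SimulationSpec(n_taxa=8, seed=2)
        _, D = random_additive_matrix(spec)
        i, j = select_neighbors(D)  # a true cherry on additive input
        for h in D.labels:
            if h in (i, j):
                continue
            assert delta_direct(D, i, j, h) == pytest.approx(0.0, abs=1e-9)
        _, delta = neighbor_deviation(D, i, j)
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_argmax_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            D = random_symmetric_matrix(5, rng)
            h0, delta = neighbor_deviation(D, "T0", "T1")
            per_h = {
                h: delta_direct(D, "T0", "T1", h)
                for h in D.labels
                if h not in ("T0", "T1")
            }
            best = max(sorted(per_h), key=lambda h: abs(per_h[h]))
            assert h0 == best
            assert delta == pytest.approx(per_h[best])

    def test_symmetric_taxa_have_equal_delta(self):
        # x and y are exchangeable: same distances to everyone
        vals = np.array(
            [
                [0, 4, 2, 2, 5],
                [4, 0, 3, 3, 6],
                [2, 3, 0, 1, 4],
                [2, 3, 1, 0, 4],
                [5, 6, 4, 4, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(("i", "j", "x", "y", "z"), vals)
        assert delta_direct(dm, "i", "j", "x") == pytest.approx(
            delta_direct(dm, "i", "j", "y")
        )


class TestDetectAtStep:
    def test_none_when_min_score_unreachable(self):
        Dh, p1, p2 = convex_case()
        params = DetectionParameters(1e9, 0.1, 0.9)
        i, j = select_neighbors(Dh)
        assert detect_at_step(Dh, i, j, params) is None

    def test_accepts_injected_hybrid_at_parent_pair(self):
        Dh, p1, p2 = convex_case(seed=5, alpha=0.3)
        # evaluate at a pair containing parent p1 and its closest relative
        partner = min(
            (l for l in Dh.labels if l not in (p1, p2, "HYB")),
            key=lambda l: Dh.d(p1, l),
        )
        i, j = sorted((p1, partner))
        cand = detect_at_step(Dh, i, j, PERMISSIVE)
        assert cand is not None
        assert cand.h == "HYB"
        assert {cand.i, cand.j} == {p1, p2}
        assert cand.alpha == pytest.approx(0.3, abs=0.05)
        assert cand.ls < cand.delta**2

    def test_small_matrices_skip_detection(self, rng):
        D = random_symmetric_matrix(4, rng)
        assert detect_at_step(D, "T0", "T1", PERMISSIVE) is None


class TestInferNetwork:
    def test_additive_matrix_gives_plain_nj(self):
        spec = SimulationSpec(n_taxa=9, seed=4)
        _, D = random_additive_matrix(spec)
        net = infer_network(D, PERMISSIVE)
        assert net.n_reticulations == 0
        assert dendropy_rf(net.tree.newick(), nj_tree(D).newick()) == 0

    def test_degenerates_to_nj_with_unreachable_score(self, rng):
        # arbitrary (non-additive) matrices: same topology as plain NJ
        for _ in range(50):
            D = random_symmetric_matrix(int(rng.integers(5, 9)), rng)
            net = infer_network(D, DetectionParameters(1e9, 0.1, 0.9))
            assert net.n_reticulations == 0
            assert dendropy_rf(net.tree.newick(), nj_tree(D).newick()) == 0

    def test_worked_example_single_balanced_reticulation(self, worked_dm):
        net = infer_network(worked_dm, PERMISSIVE)
        assert net.n_reticulations == 1
        r = net.reticulations[0]
        assert r.recipient == "L4"
        assert {r.donor1, r.donor2} == {"L3", "L5"}
        assert r.degree1 == pytest.approx(0.5)
        assert r.degree2 == pytest.approx(0.5)
        assert "L4" not in net.tree.leaf_labels

    def test_degrees_sum_to_one_exactly(self):
        Dh, p1, p2 = convex_case(seed=9, alpha=0.37)
        net = infer_network(Dh, PERMISSIVE)
        for r in net.reticulations:
            assert r.degree1 + r.degree2 == 1.0

    def test_reticulation_count_monotone_in_min_score(self):
        for seed in (301, 305, 311):
            rng = np.random.default_rng(seed)
            spec = SimulationSpec(n_taxa=10, seed=int(rng.integers(2**31)))
            _, D = random_additive_matrix(spec)
            labs = list(D.labels)
            p1, p2 = rng.choice(labs, size=2, replace=False)
            Dh = inject_hybrid(D, str(p1), str(p2), 0.5, "HYB")
            counts = [
                infer_network(Dh, DetectionParameters(ms, 0.1, 0.9)).n_reticulations
                for ms in (0.0, 0.05, 0.1, 0.5, 1e9)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_small_matrix_warns_and_returns_tree(self):
        spec = SimulationSpec(n_taxa=4, seed=1)
        _, D = random_additive_matrix(spec)
        with pytest.warns(UserWarning, match="greater than"):
            net = infer_network(D, PERMISSIVE)
        assert net.n_reticulations == 0
        assert net.tree.n_leaves == 4

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            DetectionParameters(0.0, 0.9, 0.1)
        assert default_parameters(10).min_score == 0.0
        assert default_parameters(84).alpha_min == 0.25


class TestIterateRemoval:
    def test_no_hybrids_identical_to_single_run(self):
        spec = SimulationSpec(n_taxa=8, seed=6)
        _, D = random_additive_matrix(spec)
        single = infer_network(D, PERMISSIVE)
        iterated = iterate_removal(D, PERMISSIVE, max_rounds=4)
        assert iterated.n_reticulations == single.n_reticulations == 0
        assert iterated.tree.newick() == single.tree.newick()

    def test_max_rounds_one_equals_infer_network(self):
        Dh, *_ = convex_case(seed=12, alpha=0.45)
        one = iterate_removal(Dh, PERMISSIVE, max_rounds=1)
        direct = infer_network(Dh, PERMISSIVE)
        assert [r.recipient for r in one.reticulations] == [
            r.recipient for r in direct.reticulations
        ]

    def test_pruning_exposes_additional_reticulation(self):
        # chained convex hybrids where one event only surfaces after the
        # first run's recipients are removed from the input matrix
        rng = np.random.default_rng(10)
        spec = SimulationSpec(n_taxa=10, seed=10)
        _, Dt = random_additive_matrix(spec)
        labs = list(Dt.labels)
        p1, p2, p3 = (str(x) for x in rng.choice(labs, size=3, replace=False))
        aB = float(rng.uniform(0.3, 0.7))
        aA = float(rng.uniform(0.3, 0.7))
        DB = inject_hybrid(Dt, p1, p2, aB, "HB")
        DA = inject_hybrid(DB, "HB", p3, aA, "HA")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            first = infer_network(DA, PERMISSIVE)
            both = iterate_removal(DA, PERMISSIVE, max_rounds=3)
        first_recipients = {r.recipient_members for r in first.reticulations}
        all_recipients = {r.recipient_members for r in both.reticulations}
        assert first_recipients < all_recipients
        assert any(r.round > 1 for r in both.reticulations)
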