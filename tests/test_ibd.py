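"""Tests for the ancestry HMM: state spaces, transitions, emissions,
forward-backward posteriors (against an exhaustive-path oracle), haplotypic
probabilities and grid interpolation."""

import numpy as np
import pytest

from polyqtl.ibd import (
    AncestryState,
    emission_prob,
    enumerate_ibd_states,
    expected_dosages,
    haldane,
    haplotype_probs,
    ibd_posterior,
    parent_transition,
    spline_to_grid,
    state_prior,
    transition_matrix,
    IBDProbabilities,
)
from polyqtl.maps import generate_phased_map
from polyqtl.meiosis import genotype_population, simulate_population, true_ibd


def exhaustive_posterior(values, pmap, model, q, eps):
    """Independent oracle: materialize the joint probability of every state
    path and marginalize (no forward-backward recursion)."""
    from polyqtl.ibd import _emission_matrix

    states = enumerate_ibd_states(pmap.ploidy, model == "DR")
    s = len(states)
    m, n = values.shape
    expected = expected_dosages(states, pmap)
    prior = state_prior(pmap.ploidy, model, q)
    trans = [
        transition_matrix(pmap.ploidy, float(d), model, q)
        for d in np.diff(pmap.positions)
    ]
    out = np.zeros((n, m, s))
    for i in range(n):
        emis = [
            _emission_matrix(values[mk, i : i + 1], expected[mk], eps, pmap.ploidy)[0]
            for mk in range(m)
        ]
        # joint tensor over all paths
        joint = prior * emis[0]
        for mk in range(1, m):
            joint = joint[..., :, None] * trans[mk - 1] * emis[mk]
        joint_flat = joint.reshape(-1)
        total = joint_flat.sum()
        axes = list(range(m))
        for mk in range(m):
            marg = joint.sum(axis=tuple(a for a in axes if a != mk))
            out[i, mk] = marg / total
    return out


class TestStateSpaces:
    def test_tetraploid_nodr_36(self):
        assert len(enumerate_ibd_states(4, False)) == 36

    def test_tetraploid_dr_100(self):
        states = enumerate_ibd_states(4, True)
        assert len(states) == 100
        assert sum(s.dr for s in states) == 64  # the extra DR classes

    def test_hexaploid_nodr_400(self):
        # brute-force oracle: C(6,3)^2
        from itertools import combinations

        expected = len(list(combinations(range(6), 3))) ** 2
        assert len(enumerate_ibd_states(6, False)) == expected == 400

    def test_odd_ploidy_rejected(self):
        with pytest.raises(ValueError):
            enumerate_ibd_states(3, False)

    def test_nodr_states_have_distinct_indices(self):
        assert not any(s.dr for s in enumerate_ibd_states(4, False))


class TestTransitionMatrix:
    @pytest.mark.parametrize("model,q", [("noDR", 0.0), ("DR", 0.3)])
    def test_zero_distance_is_identity(self, model, q):
        T = transition_matrix(4, 0.0, model, q)
        assert np.allclose(T, np.eye(T.shape[0]), atol=1e-12)

    @pytest.mark.parametrize("d", [0.01, 1.0, 10.0, 100.0])
    @pytest.mark.parametrize("model,q", [("noDR", 0.0), ("DR", 0.5)])
    def test_rows_stochastic(self, d, model, q):
        T = transition_matrix(4, d, model, q)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert T.min() >= 0

    @pytest.mark.parametrize("model,q", [("noDR", 0.0), ("DR", 0.5)])
    def test_long_distance_limit_matches_closed_form(self, model, q):
        # At d -> inf the Haldane recombination fraction saturates at 1/2:
        # within one meiosis a chromatid still carries its own origin with
        # probability 1/2 (else a uniform other homolog), so the limit
        # kernel is NOT constant-row.  Build that limit independently from
        # the saturated per-chromatid kernel and compare.
        from itertools import permutations

        ploidy = 4
        k_inf = np.full((ploidy, ploidy), 0.5 / (ploidy - 1))
        np.fill_diagonal(k_inf, 0.5)
        from polyqtl.ibd import parent_states

        states = parent_states(ploidy, model == "DR")
        K = np.zeros((len(states), len(states)))
        for i, s in enumerate(states):
            for j, t in enumerate(states):
                K[i, j] = sum(
                    np.prod([k_inf[a - 1, b - 1] for a, b in zip(s, perm)])
                    for perm in set(permutations(t))
                )
        if model == "DR":
            w = np.array(
                [1.0 if len(set(t)) == len(t) else q for t in states]
            )
            K *= w[None, :]
        K /= K.sum(axis=1, keepdims=True)
        T_far = parent_transition(ploidy, 10_000.0, model, q)
        assert np.abs(T_far - K).max() < 1e-6
        # eigen-analysis sanity: the limit rows form an invariant set
        w_eig = np.linalg.eigvals(T_far)
        assert np.isclose(np.max(np.abs(w_eig)), 1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(4, -1.0)

    def test_haldane_limits(self):
        assert haldane(0.0) == 0.0
        assert abs(haldane(10.0) - 0.5 * (1 - np.exp(-0.2))) < 1e-15
        assert haldane(1e9) == pytest.approx(0.5)

    def test_dr_targets_unreachable_at_q_zero(self):
        states = enumerate_ibd_states(4, True)
        T = transition_matrix(4, 5.0, "DR", q=0.0)
        dup = np.array([s.dr for s in states])
        nondup = ~dup
        assert T[np.ix_(nondup, dup)].max() == 0.0


class TestEmission:
    def _state(self):
        return AncestryState((1, 2), (5, 6))

    def test_exact_match_without_error(self):
        alleles = np.array([1, 0, 0, 0, 1, 0, 0, 0])
        st = self._state()  # expected dosage 2
        assert emission_prob(st, alleles, 2, eps=0.0) == 1.0
        assert emission_prob(st, alleles, 3, eps=0.0) == 0.0

    def test_missing_is_uninformative(self):
        alleles = np.array([1, 0, 0, 0, 1, 0, 0, 0])
        for st in enumerate_ibd_states(4, False):
            assert emission_prob(st, alleles, float("nan"), eps=0.5) == 1.0

    def test_mismatch_rate_is_eps_over_ploidy(self):
        alleles = np.zeros(8, dtype=int)
        st = self._state()  # expected dosage 0
        assert emission_prob(st, alleles, 1, eps=0.001) == pytest.approx(0.00025)


class TestPosterior:
    def test_rows_normalized(self, posterior200):
        assert np.allclose(posterior200.probs.sum(axis=2), 1.0, atol=1e-9)
        assert posterior200.probs.min() >= 0

    def test_all_missing_gives_uniform_and_pi_half(self, even_map):
        values = np.full((even_map.n_markers, 3), np.nan)
        with pytest.warns(UserWarning, match="no observed markers"):
            post = ibd_posterior(values, even_map, "noDR")
        assert np.allclose(post.probs, 1.0 / 36)
        pi = haplotype_probs(post).pi
        assert np.allclose(pi, 0.5)

    @pytest.mark.parametrize("model,q", [("noDR", 0.0), ("DR", 0.4)])
    def test_matches_exhaustive_path_oracle_tetraploid(self, model, q):
        pmap = generate_phased_map(4, 3, 30.0, "uniform", None, seed=21)
        pop = simulate_population(pmap, 8, q if model == "DR" else 0.0, seed=22)
        values = genotype_population(pop, pmap, eps=0.0, seed=23).values
        post = ibd_posterior(values, pmap, model, q, eps=0.01)
        oracle = exhaustive_posterior(values, pmap, model, q, eps=0.01)
        assert np.abs(post.probs - oracle).max() < 1e-10

    def test_matches_exhaustive_path_oracle_four_markers_diploid(self):
        pmap = generate_phased_map(2, 4, 40.0, "uniform", None, seed=24)
        pop = simulate_population(pmap, 10, 0.0, seed=25)
        values = genotype_population(pop, pmap, eps=0.0, seed=26).values
        post = ibd_posterior(values, pmap, "noDR", eps=0.005)
        oracle = exhaustive_posterior(values, pmap, "noDR", 0.0, eps=0.005)
        assert np.abs(post.probs - oracle).max() < 1e-10

    def test_dense_informative_map_recovers_truth(self, informative_map):
        pop = simulate_population(informative_map, 40, 0.0, seed=27)
        values = genotype_population(pop, informative_map, eps=0.0, seed=28).values
        post = ibd_posterior(values, informative_map, "noDR", eps=0.001)
        mat, pat = true_ibd(pop, informative_map.positions)
        index = {
            (s.maternal, tuple(h - 4 for h in s.paternal)): k
            for k, s in enumerate(post.states)
        }
        hits = total = 0
        for i in range(40):
            for l in range(informative_map.n_markers):
                k = index[(tuple(mat[i, l]), tuple(pat[i, l]))]
                hits += post.probs[i, l].argmax() == k
                total += 1
        assert hits / total >= 0.99

    def test_accuracy_increases_with_marker_density(self):
        densities = (2, 5, 10, 20)  # markers per homolog
        scores = []
        for dens in densities:
            pmap = generate_phased_map(
                4, dens * 8, 100.0, "uniform", {"1x0": 1.0, "0x1": 1.0}, seed=29
            )
            pop = simulate_population(pmap, 60, 0.0, seed=30)
            values = genotype_population(pop, pmap, eps=0.0, seed=31).values
            post = ibd_posterior(values, pmap, "noDR", eps=0.001)
            mat, pat = true_ibd(pop, pmap.positions)
            index = {
                (s.maternal, tuple(h - 4 for h in s.paternal)): k
                for k, s in enumerate(post.states)
            }
            mass = 0.0
            for i in range(60):
                for l in range(pmap.n_markers):
                    k = index[(tuple(mat[i, l]), tuple(pat[i, l]))]
                    mass += post.probs[i, l, k]
            scores.append(mass / (60 * pmap.n_markers))
        assert all(b > a - 0.02 for a, b in zip(scores, scores[1:]))
        assert scores[-1] > scores[0]

    def test_dr_model_on_bivalent_data_has_little_dr_mass(
        self, even_map, dosages200
    ):
        post = ibd_posterior(dosages200, even_map, "DR", q=0.5, eps=0.001)
        dr_mask = np.array([s.dr for s in post.states])
        mean_dr_mass = post.probs[:, :, dr_mask].sum(axis=2).mean()
        assert mean_dr_mass < 0.02


class TestHaplotypeProbs:
    def test_uniform_posterior_gives_half(self, even_map):
        states = enumerate_ibd_states(4, False)
        ibd = IBDProbabilities(
            probs=np.full((5, 3, 36), 1.0 / 36),
            positions=np.array([0.0, 5.0, 10.0]),
            states=states, ploidy=4, model="noDR", q=0.0, eps=0.0,
        )
        assert np.allclose(haplotype_probs(ibd).pi, 0.5)

    def test_point_mass_posterior(self):
        states = enumerate_ibd_states(4, False)
        k = states.index(AncestryState((1, 2), (5, 6)))
        probs = np.zeros((1, 1, 36))
        probs[0, 0, k] = 1.0
        ibd = IBDProbabilities(
            probs=probs, positions=np.array([1.0]), states=states,
            ploidy=4, model="noDR", q=0.0, eps=0.0,
        )
        pi = haplotype_probs(ibd).pi[0, 0]
        assert np.array_equal(pi, [1, 1, 0, 0, 1, 1, 0, 0])

    def test_per_parent_conservation_on_random_posteriors(self):
        rng = np.random.default_rng(33)
        states = enumerate_ibd_states(4, True)
        probs = rng.random((10, 100, 100))
        probs /= probs.sum(axis=2, keepdims=True)
        ibd = IBDProbabilities(
            probs=probs, positions=np.linspace(0, 99, 100), states=states,
            ploidy=4, model="DR", q=0.5, eps=0.0,
        )
        pi = haplotype_probs(ibd).pi
        assert np.allclose(pi[..., :4].sum(axis=-1), 2.0, atol=1e-9)
        assert np.allclose(pi[..., 4:].sum(axis=-1), 2.0, atol=1e-9)


class TestSplineToGrid:
    def _make_ibd(self, positions, probs):
        states = enumerate_ibd_states(4, False)
        return IBDProbabilities(
            probs=probs, positions=np.asarray(positions, dtype=float),
            states=states, ploidy=4, model="noDR", q=0.0, eps=0.0,
        )

    def test_constant_posterior_stays_constant(self):
        x = np.linspace(0, 20, 11)
        probs = np.tile(np.full(36, 1.0 / 36), (3, 11, 1))
        grid = spline_to_grid(self._make_ibd(x, probs))
        assert np.allclose(grid.probs, 1.0 / 36, atol=1e-9)

    def test_grid_rows_sum_to_one(self, grid200):
        assert np.allclose(grid200.probs.sum(axis=2), 1.0, atol=1e-9)
        assert grid200.probs.min() >= 0
        assert grid200.probs.max() <= 1

    def test_linear_posterior_recovered(self):
        x = np.linspace(0, 50, 26)
        probs = np.zeros((2, 26, 36))
        ramp = 0.2 + 0.01 * x
        probs[:, :, 0] = ramp
        probs[:, :, 1] = 1.0 - ramp
        grid = spline_to_grid(self._make_ibd(x, probs))
        expect0 = 0.2 + 0.01 * grid.positions
        assert np.abs(grid.probs[:, :, 0] - expect0).max() < 1e-3

    def test_close_to_input_at_marker_positions(self, posterior200, grid200):
        # smoothing deviates from the raw posterior but only mildly
        marker_idx = np.round(posterior200.positions).astype(int)
        keep = marker_idx < grid200.probs.shape[1]
        diff = np.abs(
            grid200.probs[:, marker_idx[keep], :]
            - posterior200.probs[:, keep, :]
        )
        assert np.quantile(diff, 0.999) < 0.25

    def test_too_few_positions_rejected(self):
        probs = np.full((1, 1, 36), 1.0 / 36)
        with pytest.raises(ValueError):
            spline_to_grid(self._make_ibd([5.0], probs))

    def test_extrapolation_flagged(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        probs = np.full((1, 6, 36), 1.0 / 36)
        grid = spline_to_grid(self._make_ibd(x, probs))
        assert grid.extrapolated[:10].all()
        assert not grid.extrapolated[10:61].any()
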