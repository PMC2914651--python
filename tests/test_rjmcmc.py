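"""Path likelihoods, proposal mechanics, and sampler correctness."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

import skm
from skm import MCMCConfig, path_log_likelihood
from skm.gradient import truncated_generator
from skm.model_core import build_network
from skm.rjmcmc import (
    FullObservedSampler,
    PartialObservedSampler,
    _build_move,
    _Interval,
    log_acceptance_ratio,
    propose_move,
)
from skm.simulate import ReactionPath


class TestPathLogLikelihood:
    def test_empty_path_total_hazard_decay(self, bd_net):
        # nA = 5 over tau = 2: log pi = -(0.15 + 0.6) * 2 = -1.5
        p = ReactionPath(t0=0.0, t1=2.0, x0=[5], types=[], times=[])
        assert path_log_likelihood(bd_net, bd_net.theta, p) == pytest.approx(-1.5)

    def test_impossible_firing_is_minus_inf(self, bd_net):
        p = ReactionPath(t0=0.0, t1=2.0, x0=[0], types=[0], times=[1.0])  # death at nA=0
        assert path_log_likelihood(bd_net, bd_net.theta, p) == -math.inf

    def test_density_integrates_to_transition_probability(self, bd_net):
        """Sum over exhaustive path enumeration (J <= 3) with simplex
        quadrature of exp(log pi) equals the truncated-CME transition
        probability."""
        theta = np.array([0.5, 0.6])
        net = bd_net.with_theta(theta)
        x0, x1, tau = 2, 2, 0.25

        def seq_integral(types):
            # states along the sequence and their total hazards
            J = len(types)
            states = [x0]
            for r in types:
                states.append(states[-1] + (1 if r == 1 else -1))
            if min(states) < 0 or states[-1] != x1:
                return 0.0
            h0 = [theta[0] * s + theta[1] for s in states]
            fired = [theta[types[j]] if types[j] == 1 else theta[0] * states[j] for j in range(J)]
            if any(f <= 0 for f in fired):
                return 0.0
            logC = float(np.log(fired).sum()) if J else 0.0
            if J == 0:
                return math.exp(-h0[0] * tau)
            # nested trapezoid over the ordered-time simplex
            n = {1: 4000, 2: 260, 3: 60}[J]
            grid = np.linspace(0, tau, n)
            if J == 1:
                vals = np.exp(-(h0[0] * grid + h0[1] * (tau - grid)))
                return math.exp(logC) * np.trapezoid(vals, grid)
            if J == 2:
                t1 = grid[:, None]
                t2 = grid[None, :]
                ok = t2 >= t1
                vals = np.where(
                    ok, np.exp(-(h0[0] * t1 + h0[1] * (t2 - t1) + h0[2] * (tau - t2))), 0.0
                )
                return math.exp(logC) * np.trapezoid(np.trapezoid(vals, grid, axis=1), grid)
            t1 = grid[:, None, None]
            t2 = grid[None, :, None]
            t3 = grid[None, None, :]
            ok = (t2 >= t1) & (t3 >= t2)
            vals = np.where(
                ok,
                np.exp(
                    -(
                        h0[0] * t1
                        + h0[1] * (t2 - t1)
                        + h0[2] * (t3 - t2)
                        + h0[3] * (tau - t3)
                    )
                ),
                0.0,
            )
            inner = np.trapezoid(np.trapezoid(np.trapezoid(vals, grid, axis=2), grid, axis=1), grid)
            return math.exp(logC) * inner

        # the test-local density agrees pointwise with the implementation
        p = ReactionPath(t0=0.0, t1=tau, x0=[2], types=[1, 0], times=[0.05, 0.21])
        h0s = [theta[0] * 2 + theta[1], theta[0] * 3 + theta[1], theta[0] * 2 + theta[1]]
        by_hand = (
            math.log(theta[1])
            + math.log(theta[0] * 3)
            - (h0s[0] * 0.05 + h0s[1] * 0.16 + h0s[2] * (tau - 0.21))
        )
        assert path_log_likelihood(net, theta, p) == pytest.approx(by_hand)

        total = sum(
            seq_integral(types)
            for J in range(4)
            for types in itertools.product((0, 1), repeat=J)
        )
        Q, states = truncated_generator(net, theta, [(0, 30)])
        T = expm(Q.toarray() * tau)
        exact = T[2, 2]
        assert total == pytest.approx(exact, rel=2e-3)


class TestMoves:
    def _interval(self, net, x0, types, times, tau=2.0):
        return _Interval(net, net.theta, x0, 0.0, tau, types, times)

    def test_add_on_empty_path_inserts_whole_mode(self, bd_net, rng):
        itv = self._interval(bd_net, [5], [], [])
        q = np.array([1, 1])
        mv = _build_move(itv, q, 1, rng, math.log(0.25), math.log(0.25))
        assert mv.valid
        assert sorted(mv.types.tolist()) == [0, 1]
        assert (np.diff(mv.times) > 0).all()

    def test_delete_without_matching_events_invalid(self, bd_net, rng):
        itv = self._interval(bd_net, [5], [1], [0.7])  # one birth only
        mv = _build_move(itv, np.array([1, 1]), 2, rng, math.log(0.25), math.log(0.25))
        assert not mv.valid

    def test_shuffle_preserves_type_counts(self, bd_net, rng):
        types = np.array([1, 0, 1, 0, 1])
        times = np.sort(rng.uniform(0, 2, 5))
        itv = self._interval(bd_net, [5], types, times)
        mv = _build_move(itv, np.array([1, 1]), 3, rng, math.log(0.25), math.log(0.25))
        assert np.bincount(mv.types, minlength=2).tolist() == [2, 3]
        assert mv.log_hastings == 0.0

    def test_identity_shuffle_accepted_with_probability_one(self, bd_net):
        p = ReactionPath(t0=0.0, t1=2.0, x0=[5], types=[1, 0], times=[0.5, 1.5])
        from skm.rjmcmc import Move

        identity = Move(3, None, p.types.copy(), p.times.copy(), 0.0, True)
        assert log_acceptance_ratio(bd_net, bd_net.theta, p, p, identity) == pytest.approx(0.0)

    @pytest.mark.parametrize("r_existing", [(0, 0), (2, 1), (5, 5)])
    def test_detailed_balance_add_then_delete(self, bd_net, rng, r_existing):
        """The Hastings corrections of a move and its exact reverse cancel:
        log AR_add(path -> path') + log AR_del(path' -> path) = 0."""
        q = np.array([1, 1])
        types = np.repeat([0, 1], r_existing)
        times = np.sort(rng.uniform(0, 2, types.size))
        itv = self._interval(bd_net, [8], types, times)
        la = math.log(0.25)
        add = _build_move(itv, q, 1, rng, la, la)
        prop = self._interval(bd_net, [8], add.types, add.times)
        rev = _build_move(prop, q, 2, rng, la, la)
        assert add.valid and rev.valid
        assert add.log_hastings + rev.log_hastings == pytest.approx(0.0, abs=1e-10)

    def test_propose_move_roundtrip_on_latent(self, bd_net, rng):
        obs = skm.ObservationSet(times=[0.0, 2.0], species=("A",), counts=[[5], [5]])
        sampler = FullObservedSampler(bd_net, bd_net.theta, obs, MCMCConfig(seed=0))
        latent = sampler.snapshot()
        ns = sampler.nullset
        prop, mv = propose_move(bd_net, latent, 0, ns, MCMCConfig(), rng)
        if mv.valid:
            ar = log_acceptance_ratio(bd_net, bd_net.theta, latent.paths[0], prop, mv)
            assert np.isfinite(ar) or ar == -math.inf


class TestFullSampler:
    def test_theta_to_zero_limit_paths_empty(self, bd_net):
        obs = skm.ObservationSet(times=[0.0, 2.0, 4.0], species=("A",), counts=[[5], [5], [5]])
        tiny = np.array([1e-8, 1e-8])
        sampler = FullObservedSampler(
            bd_net.with_theta(tiny), tiny, obs, MCMCConfig(n_samples=200, burn_in=50, seed=3)
        )
        N, _ = sampler.run()
        assert N.sum() == 0  # empty paths maximize the likelihood as h -> 0

    def test_samples_satisfy_latent_invariants(self, bd_net):
        spec = skm.BenchmarkSpec(model="birth_death", m=6, dt=2.0, seed=21)
        obs, _ = skm.generate_benchmark(spec)
        sampler = FullObservedSampler(
            bd_net, bd_net.theta, obs, MCMCConfig(n_samples=50, burn_in=20, seed=4)
        )
        for latent in sampler.samples():
            for i, p in enumerate(latent.paths):
                p.validate(bd_net)
                np.testing.assert_array_equal(p.x0, latent.obs_states[i])
                np.testing.assert_array_equal(p.end_state(bd_net.A), latent.obs_states[i + 1])
            np.testing.assert_array_equal(latent.obs_states[:, 0], obs.counts[:, 0])

    def test_total_reaction_autocorrelation_decays(self, bd_net):
        obs = skm.ObservationSet(times=[0.0, 2.0], species=("A",), counts=[[20], [22]])
        sampler = FullObservedSampler(
            bd_net, bd_net.theta, obs, MCMCConfig(n_samples=4000, burn_in=200, seed=5)
        )
        counts = np.array([s.total_reactions() for s in sampler.samples()])
        x = counts - counts.mean()
        acf = np.correlate(x, x, "full")[x.size - 1 :] / (x.var() * x.size)
        assert acf[1] < 1.0 and acf[40] < acf[1]
        ess = x.size / (1 + 2 * acf[1:40].sum())
        assert ess > 50


def _gene_switch_net():
    # two gene copies toggling between active (G) and repressed (Gs) states,
    # only the mRNA M is observed; G + Gs = 2 is a known conserved total
    return build_network(
        {
            "species": ["G", "Gs", "M"],
            "reactions": [
                {"name": "R1", "reactants": {"G": 1}, "products": {"Gs": 1}, "theta": 0.5},
                {"name": "R2", "reactants": {"Gs": 1}, "products": {"G": 1}, "theta": 0.7},
                {"name": "R3", "reactants": {"G": 1}, "products": {"G": 1, "M": 1}, "theta": 1.0},
                {"name": "R4", "reactants": {"M": 1}, "products": {}, "theta": 0.5},
            ],
            "conserved": [{"species": ["G", "Gs"], "total": 2}],
        }
    )


class TestPartialSampler:
    def test_samples_satisfy_invariants_and_conservation(self):
        net = skm.autoregulatory_network()
        spec = skm.BenchmarkSpec(
            model="autoreg", theta=skm.AUTOREG_THETA, m=6, dt=0.5, dna_total=10,
            observed=("mRNA", "P", "P2"), seed=33,
        )
        obs, _ = skm.generate_benchmark(spec)
        sampler = PartialObservedSampler(
            net, net.theta, obs, MCMCConfig(n_samples=40, burn_in=30, seed=6)
        )
        obs_idx = list(obs.observed_indices(net))
        for latent in sampler.samples():
            for i, p in enumerate(latent.paths):
                p.validate(net)
                np.testing.assert_array_equal(p.x0, latent.obs_states[i])
                np.testing.assert_array_equal(p.end_state(net.A), latent.obs_states[i + 1])
            np.testing.assert_array_equal(latent.obs_states[:, obs_idx], obs.counts)
            # DNA + DNA.P2 conserved at every observation time
            assert (latent.obs_states[:, 0] + latent.obs_states[:, 1] == 10).all()

    def test_hidden_state_marginal_matches_cme_smoother(self):
        """Marginal of the hidden gene state at the interior observation time
        matches exhaustive truncated-CME smoothing (forward-backward over
        matrix exponentials), with a uniform prior over the conserved-total
        compositions at t_1."""
        net = _gene_switch_net()
        obs = skm.ObservationSet(
            times=[0.0, 1.0, 2.0],
            species=("M",),
            counts=[[1], [3], [2]],
            conserved_totals=((("G", "Gs"), 2),),
        )
        cfg = MCMCConfig(n_samples=40_000, burn_in=2000, seed=7)
        sampler = PartialObservedSampler(net, net.theta, obs, cfg)
        draws = np.array([s.obs_states[1, 0] for s in sampler.samples()])

        Q, states = truncated_generator(net, net.theta, [(0, 2), (0, 2), (0, 18)])
        T = expm(Q.toarray() * 1.0)
        idx = {tuple(s): i for i, s in enumerate(states)}
        starts = [idx[(g, 2 - g, 1)] for g in range(3)]
        mids = [idx[(g, 2 - g, 3)] for g in range(3)]
        ends = [idx[(g, 2 - g, 2)] for g in range(3)]
        fwd = T[np.ix_(starts, mids)].sum(axis=0)  # uniform prior over G(t_1)
        bwd = T[np.ix_(mids, ends)].sum(axis=1)
        post = fwd * bwd
        post = post / post.sum()

        emp = np.bincount(draws, minlength=3) / draws.size
        tv = 0.5 * np.abs(emp - post).sum()
        assert tv < 0.05

    def test_complementary_move_restores_pair_end_state(self):
        net = skm.autoregulatory_network()
        spec = skm.BenchmarkSpec(
            model="autoreg", theta=skm.AUTOREG_THETA, m=5, dt=0.5, dna_total=10,
            observed=("mRNA", "P", "P2"), seed=34,
        )
        obs, _ = skm.generate_benchmark(spec)
        sampler = PartialObservedSampler(
            net, net.theta, obs, MCMCConfig(n_samples=1, burn_in=0, seed=8)
        )
        before = sampler.obs_states.copy()
        rng = np.random.default_rng(9)
        for _ in range(300):
            sampler._pair_update(1, rng)
        # end of the pair (t_3) may only have changed through updates of
        # interval 3 itself; pair updates on interval 1 preserve t_3
        np.testing.assert_array_equal(sampler.obs_states[3], before[3])
        np.testing.assert_array_equal(
            sampler.intervals[1].end_state(net.A), sampler.obs_states[2]
        )
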