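import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist
from scipy.stats import vonmises
from shapely.geometry import Polygon, box

from preyfield import movement_hmm as mh
from preyfield.pipeline import default_hmm_params


def _random_params(r):
    mu = np.sort(r.uniform(50, 1000, 2))
    sd = r.uniform(30, 400, 2)
    m = r.uniform(-math.pi, math.pi, 2)
    kappa = r.uniform(0.05, 8, 2)
    diag = r.uniform(0.2, 0.95, 2)
    d1 = r.uniform(0.1, 0.9)
    return mh.HMMParams(
        step_mean=tuple(mu), step_sd=tuple(sd), turn_mean=tuple(m),
        turn_kappa=tuple(kappa),
        tmat=((diag[0], 1 - diag[0]), (1 - diag[1], diag[1])),
        delta=(d1, 1 - d1))


def _emission_oracle(steps, turns, p):
    """Independent emission densities via scipy.stats distributions."""
    L = len(steps)
    logB = np.zeros((L, 2))
    for k in range(2):
        shape = (p.step_mean[k] / p.step_sd[k]) ** 2
        scale = p.step_sd[k] ** 2 / p.step_mean[k]
        logB[:, k] = gamma_dist.logpdf(steps, a=shape, scale=scale)
        ok = ~np.isnan(turns)
        logB[ok, k] += vonmises.logpdf(turns[ok], kappa=p.turn_kappa[k],
                                       loc=p.turn_mean[k])
    return logB


def _brute_force(steps, turns, p):
    """Log-likelihood and best path by exhaustive path enumeration."""
    L = len(steps)
    logB = _emission_oracle(steps, turns, p)
    logG = np.log(np.asarray(p.tmat))
    logd = np.log(np.asarray(p.delta))
    lls = []
    paths = []
    for path in itertools.product([0, 1], repeat=L):
        ll = logd[path[0]] + logB[0, path[0]]
        for t in range(1, L):
            ll += logG[path[t - 1], path[t]] + logB[t, path[t]]
        lls.append(ll)
        paths.append(path)
    lls = np.asarray(lls)
    return logsumexp(lls), np.asarray(paths[int(np.argmax(lls))])


def _track_df(steps, turns):
    n = len(steps) + 1
    df = pd.DataFrame({
        "t": 300.0 * np.arange(n),
        "x": np.zeros(n), "y": np.zeros(n),
        "step_m": np.concatenate([[np.nan], steps]),
        "turn_rad": np.concatenate([[np.nan], turns]),
    })
    return df


def _random_track(r, L):
    steps = r.uniform(10, 1500, L)
    turns = r.uniform(-math.pi, math.pi, L)
    turns[0] = np.nan
    return steps, turns


class TestForwardOracle:
    def test_forward_matches_exhaustive_enumeration(self):
        r = np.random.default_rng(101)
        for _ in range(20):
            p = _random_params(r)
            L = int(r.integers(3, 7))
            steps, turns = _random_track(r, L)
            ll = mh.forward_loglik([_track_df(steps, turns)], p)
            ll_oracle, _ = _brute_force(steps, turns, p)
            assert abs(ll - ll_oracle) < 1e-8

    def test_viterbi_matches_exhaustive_argmax(self):
        r = np.random.default_rng(202)
        for _ in range(20):
            p = _random_params(r)
            L = int(r.integers(3, 7))
            steps, turns = _random_track(r, L)
            seq = mh.decode(_track_df(steps, turns), p)
            _, best = _brute_force(steps, turns, p)
            assert np.array_equal(seq.states, best)

    def test_posteriors_sum_to_one(self):
        r = np.random.default_rng(303)
        p = _random_params(r)
        steps, turns = _random_track(r, 30)
        seq = mh.decode(_track_df(steps, turns), p)
        assert np.allclose(seq.posteriors.sum(axis=1), 1.0)


class TestDecodeLimits:
    def test_uninformative_emissions_give_stationary_posteriors(self):
        # identical step distributions, kappa ~ 0: posteriors equal the
        # stationary distribution of the transition matrix
        p = mh.HMMParams(step_mean=(300.0, 300.0), step_sd=(150.0, 150.0),
                         turn_mean=(0.0, 0.0), turn_kappa=(1e-12, 1e-12),
                         tmat=((0.9, 0.1), (0.3, 0.7)), delta=(0.75, 0.25))
        r = np.random.default_rng(5)
        steps, turns = _random_track(r, 40)
        seq = mh.decode(_track_df(steps, turns), p)
        # stationary distribution of ((0.9, .1), (.3, .7)) is (0.75, 0.25)
        assert np.allclose(seq.posteriors, [0.75, 0.25], atol=1e-6)

    def test_well_separated_states_decode_accurately(self, rng):
        truth = default_hmm_params()  # 4.7-fold step-mean separation
        correct = total = 0
        for i in range(5):
            tr = mh.simulate_hmm_track(truth, 200, (0.0, 0.0),
                                       seed=int(rng.integers(2**31 - 1)))
            seq = mh.decode(tr, truth)
            ts = tr["state"].to_numpy()[1:]
            correct += (seq.states == ts).sum()
            total += ts.size
        assert correct / total >= 0.90


class TestFit:
    def test_two_state_fit_nests_single_state(self, rng):
        # single-state data: the 2-state fit cannot fall below the 1-state MLE
        p1 = mh.HMMParams(step_mean=(300.0, 300.0), step_sd=(150.0, 150.0),
                          turn_mean=(0.0, 0.0), turn_kappa=(1.0, 1.0),
                          tmat=((0.5, 0.5), (0.5, 0.5)), delta=(0.5, 0.5))
        tracks = [mh.simulate_hmm_track(p1, 120, (0.0, 0.0), seed=s)
                  for s in (1, 2, 3)]
        fit, ll2 = mh.fit_hmm(tracks, seed=0, n_restarts=3)
        # 1-state MLE: fit gamma / von Mises to pooled data directly
        steps = np.concatenate([t["step_m"].to_numpy()[1:] for t in tracks])
        turns = np.concatenate([t["turn_rad"].to_numpy()[2:] for t in tracks])
        a, loc, sc = gamma_dist.fit(steps, floc=0)
        kap, loc_v, _ = vonmises.fit(turns, fscale=1)
        ll1 = gamma_dist.logpdf(steps, a=a, scale=sc).sum() + \
            vonmises.logpdf(turns, kappa=kap, loc=loc_v).sum()
        assert ll2 >= ll1 - 1e-6

    def test_labels_are_permutation_stable(self):
        p = default_hmm_params()
        swapped = mh.HMMParams(
            step_mean=p.step_mean[::-1], step_sd=p.step_sd[::-1],
            turn_mean=p.turn_mean[::-1], turn_kappa=p.turn_kappa[::-1],
            tmat=((p.tmat[1][1], p.tmat[1][0]), (p.tmat[0][1], p.tmat[0][0])),
            delta=p.delta[::-1])
        assert swapped.relabelled() == p.relabelled()
        assert swapped.state_labels[swapped.foraging_state] == "foraging"

    def test_fit_simulate_fit_closes(self, hmm_recovery):
        # refit on a large simulated ensemble recovers the generator within 10%
        assert hmm_recovery["max_rel_err"] < 0.10


class TestSubset:
    def _tracks_by_year(self, n_years=5, n_per_year=14, n_fixes=30):
        p = default_hmm_params()
        out = {}
        s = 0
        for y in range(2015, 2015 + n_years):
            out[y] = [mh.simulate_hmm_track(p, n_fixes, (0.0, 0.0), seed=s + i)
                      for i in range(n_per_year)]
            s += n_per_year
        return out

    def test_ten_per_year_gives_fifty(self):
        by_year = self._tracks_by_year()
        _, _, chosen = mh.fit_on_subset(by_year, n_per_year=10, seed=1,
                                        n_restarts=1)
        assert sum(len(v) for v in chosen.values()) == 50

    def test_small_year_takes_all(self):
        by_year = self._tracks_by_year(n_years=2, n_per_year=8)
        _, _, chosen = mh.fit_on_subset(by_year, n_per_year=10, seed=1,
                                        n_restarts=1)
        assert all(len(v) == 8 for v in chosen.values())

    def test_same_seed_same_subset(self):
        by_year = self._tracks_by_year(n_years=3, n_per_year=14, n_fixes=20)
        _, _, c1 = mh.fit_on_subset(by_year, n_per_year=10, seed=7,
                                    n_restarts=1)
        _, _, c2 = mh.fit_on_subset(by_year, n_per_year=10, seed=7,
                                    n_restarts=1)
        assert c1 == c2


class TestSimulation:
    def test_track_without_land_has_requested_length(self):
        p = default_hmm_params()
        tr = mh.simulate_hmm_track(p, 77, (0.0, 0.0), seed=3)
        assert len(tr) == 77
        assert np.allclose(np.diff(tr["t"]), 300.0)

    def test_tiny_water_region_errors_at_first_fix(self):
        p = default_hmm_params()
        # land everywhere except a 0.5 m pocket around the start
        land = box(-1e6, -1e6, 1e6, 1e6).difference(
            Polygon([(-0.25, -0.25), (0.25, -0.25), (0.25, 0.25),
                     (-0.25, 0.25)]))
        with pytest.raises(RuntimeError, match="fix 1"):
            mh.simulate_hmm_track(p, 10, (0.0, 0.0), land_polygon=land,
                                  seed=0, max_attempts=300)

    def test_start_on_land_rejected(self):
        p = default_hmm_params()
        land = box(-100, -100, 100, 100)
        with pytest.raises(ValueError, match="land"):
            mh.simulate_hmm_track(p, 10, (0.0, 0.0), land_polygon=land, seed=0)

    def test_step_moments_match_kernel(self):
        # 1e5 steps: per-state empirical means within 2% of the gamma means
        p = default_hmm_params()
        tr = mh.simulate_hmm_track(p, 100_001, (0.0, 0.0), seed=12)
        steps = tr["step_m"].to_numpy()[1:]
        states = tr["state"].to_numpy()[1:]
        for k in range(2):
            got = steps[states == k].mean()
            assert abs(got - p.step_mean[k]) / p.step_mean[k] < 0.02

    def test_ensemble_singleton_and_pooled_mean(self):
        p = default_hmm_params()
        single = mh.simulate_ensemble(p, 1, 50, (0.0, 0.0), seed=1)
        assert len(single) == 1
        # sticky states autocorrelate the steps, so the pooled mean needs a
        # large sample before the 2% band is comfortably inside MC noise
        ens = mh.simulate_ensemble(p, 250, 400, (0.0, 0.0), seed=2)
        steps = np.concatenate([t["step_m"].to_numpy()[1:] for t in ens])
        # stationary mixture mean of the two gamma step distributions
        mix = 0.5 * p.step_mean[0] + 0.5 * p.step_mean[1]
        assert abs(steps.mean() - mix) / mix < 0.02

    def test_land_rejection_bias_is_small(self):
        # land strip occupying a corner (<10% of reachable area): pooled step
        # mean within 5% of the no-land run
        p = default_hmm_params()
        land = box(-50_000, -50_000, -3_000, 50_000)
        free = mh.simulate_hmm_track(p, 20_000, (0.0, 0.0), seed=5)
        constrained = mh.simulate_hmm_track(p, 20_000, (0.0, 0.0),
                                            land_polygon=land, seed=5)
        m1 = free["step_m"].to_numpy()[1:].mean()
        m2 = constrained["step_m"].to_numpy()[1:].mean()
        assert abs(m2 - m1) / m1 < 0.05


class TestDomainFilter:
    def _track_with_outside_fraction(self, frac, n=50):
        inside = box(0, 0, 1000, 1000)
        n_out = int(round(frac * n))
        x = np.concatenate([np.full(n - n_out, 500.0), np.full(n_out, 5000.0)])
        return pd.DataFrame({"t": 300.0 * np.arange(n), "x": x,
                             "y": np.full(n, 500.0)}), inside

    def test_thirty_percent_outside_removed(self):
        tr, poly = self._track_with_outside_fraction(0.30)
        assert mh.filter_in_domain([tr], poly) == []

    def test_exactly_twenty_percent_retained(self):
        tr, poly = self._track_with_outside_fraction(0.20)
        assert len(mh.filter_in_domain([tr], poly)) == 1

    def test_all_inside_retained(self):
        tr, poly = self._track_with_outside_fraction(0.0)
        assert len(mh.filter_in_domain([tr], poly)) == 1


def test_params_json_roundtrip(tmp_path):
    p = default_hmm_params()
    path = str(tmp_path / "p.json")
    p.to_json(path)
    assert mh.HMMParams.from_json(path) == p
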