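"""Unit tests for the tract-length model and k-mer-overlap likelihood."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from pedrec.tractmodel import (
    DEFAULT_NCO_RATE,
    KmerData,
    ModelError,
    TractLengthModel,
    TractObservation,
    excluded_counts_vector,
    excluded_kmer_counts,
    fit_geometric,
    initiation_prob,
    log_likelihood,
    multi_tract_tail_prob,
    observed_kmer_counts,
    two_significant_digit_grid,
)
from pedrec.simulate import simulate_tract_observations


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_observed(obs: TractObservation, k_max: int) -> dict[int, int]:
    """Enumerate window starts directly."""
    out: dict[int, int] = {}
    for k in range(1, k_max + 1):
        c = 0
        for s in range(obs.left_flank + 1, obs.first + 1):
            e = s + k - 1
            if e >= obs.last and e < obs.right_flank:
                c += 1
        if c:
            out[k] = c
    return out


def brute_excluded(positions, L: int, k: int) -> int:
    pos = sorted(set(positions))
    c = 0
    for s in range(1, L - k + 2):
        if any(s <= p <= s + k - 1 for p in pos):
            c += 1
    return c


# ---------------------------------------------------------------------------
# o_k
# ---------------------------------------------------------------------------

def test_observed_counts_worked_example():
    obs = TractObservation(80, 100, 150, 200)
    o = observed_kmer_counts(obs)
    assert o[51] == 1          # exactly one 51-window covers 100..150
    assert o[60] == 10
    assert o[119] == 1
    assert 50 not in o and 120 not in o


def test_observed_counts_single_site():
    obs = TractObservation(90, 100, 100, 120)
    o = observed_kmer_counts(obs)
    assert o[1] == 1
    # k-window must avoid both flanks: starts in (90, 100], ends < 120
    assert o[10] == 10
    assert max(o) == 120 - 90 - 1


def test_observed_counts_match_enumeration(rng):
    for _ in range(100):
        lf = int(rng.integers(0, 40))
        first = lf + int(rng.integers(1, 30))
        last = first + int(rng.integers(0, 50))
        rf = last + int(rng.integers(1, 40))
        obs = TractObservation(lf, first, last, rf)
        assert observed_kmer_counts(obs, 150) == brute_observed(obs, 150)


def test_observation_geometry_validated():
    with pytest.raises(ModelError):
        TractObservation(100, 100, 150, 200)   # flank not strictly left
    with pytest.raises(ModelError):
        TractObservation(80, 100, 150, 150)    # flank not strictly right


# ---------------------------------------------------------------------------
# e_k
# ---------------------------------------------------------------------------

def test_excluded_counts_worked_example():
    assert excluded_kmer_counts([100, 105], 1000, 10) == 15
    assert excluded_kmer_counts([100, 105], 1000, 3) == 6


def test_excluded_counts_match_enumeration(rng):
    for _ in range(60):
        L = int(rng.integers(5, 150))
        pos = rng.integers(1, L + 1, size=int(rng.integers(1, 10)))
        t_max = int(rng.integers(1, L + 20))
        vec = excluded_counts_vector(pos, L, t_max)
        for k in range(1, t_max + 1):
            assert vec[k - 1] == brute_excluded(pos, L, k), (L, pos, k)


def test_excluded_counts_empty_and_bounds():
    assert np.all(excluded_counts_vector([], 100, 5) == 0)
    with pytest.raises(ModelError):
        excluded_counts_vector([0], 100, 5)
    with pytest.raises(ModelError):
        excluded_counts_vector([101], 100, 5)
    # windows longer than the chromosome do not exist
    vec = excluded_counts_vector([3], 5, 8)
    assert np.all(vec[5:] == 0)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def test_initiation_probs_sum_to_rate():
    model = TractLengthModel()
    f = model.initiation_probs()
    k = np.arange(1, model.truncation + 1)
    assert float(k @ f) == pytest.approx(model.rate_per_bp, rel=1e-12)
    assert initiation_prob(1, model) == pytest.approx(float(f[0]))
    with pytest.raises(ModelError):
        initiation_prob(model.truncation + 1, model)


def test_pmf_normalised_and_mean():
    model = TractLengthModel("geometric", m1=24.0)
    assert model.pmf().sum() == pytest.approx(1.0)
    # truncation at 10 kb barely affects a mean-24 geometric
    assert model.mean() == pytest.approx(24.0, rel=1e-6)
    mix = TractLengthModel()
    assert mix.mean() > model.mean()


def test_model_validation():
    with pytest.raises(ModelError):
        TractLengthModel(family="weird")
    with pytest.raises(ModelError):
        TractLengthModel(alpha=1.5)
    with pytest.raises(ModelError):
        TractLengthModel(m1=0.5)
    with pytest.raises(ModelError):
        TractLengthModel(m1=100, m2=50)
    with pytest.raises(ModelError):
        TractLengthModel(rate_per_bp=0.0)


def test_tail_fraction_conventions():
    model = TractLengthModel()
    # nontruncated geometric component survival is available in closed form
    geo = TractLengthModel("geometric", m1=50.0)
    q = 1.0 - 1.0 / 50.0
    assert geo.tail_fraction(10, truncated=False) == pytest.approx(q ** 10)
    # site weighting puts more mass on long tracts than tract counting
    for truncated in (True, False):
        t = model.tail_fraction(100, "tracts", truncated=truncated)
        s = model.tail_fraction(100, "sites", truncated=truncated)
        assert s > t > 0
    # monotone decreasing in x
    vals = [model.tail_fraction(x) for x in (0, 10, 100, 1000)]
    assert vals == sorted(vals, reverse=True)
    assert model.tail_fraction(0) == pytest.approx(1.0)
    with pytest.raises(ModelError):
        model.tail_fraction(-1)
    with pytest.raises(ModelError):
        model.tail_fraction(10, weight="bp")


def test_sampling_matches_model(rng):
    model = TractLengthModel(alpha=0.9, m1=30, m2=2000, truncation=5000)
    draws = model.sample(rng, 200_000)
    assert draws.min() >= 1 and draws.max() <= 5000
    assert float(draws.mean()) == pytest.approx(model.mean(), rel=0.02)


def test_two_significant_digit_grid():
    grid = two_significant_digit_grid(10, 100_000)
    assert grid.size == 361
    assert grid[0] == 10 and grid[-1] == 100_000
    assert 24 in grid and 4300 in grid and 99_000 in grid
    assert 101 not in grid and 4305 not in grid


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _toy_data(rng, n=40):
    model = TractLengthModel(alpha=0.99, m1=30, m2=1500, truncation=4000)
    return model, simulate_tract_observations(
        model, rng, marker_density=5e-3, min_tracts=n,
        chrom_length=2_000_000, rate_per_bp=5e-4)


def test_log_likelihood_exact_vs_approx(rng):
    model, data = _toy_data(rng)
    approx = log_likelihood(data, model)
    exact = log_likelihood(data, model, exact_exclusion=True)
    # f_k are tiny, so log(1-f) ~ -f: the two forms agree closely,
    # with the exact product form always the smaller
    assert exact < approx
    assert approx - exact < 1e-3 * abs(approx)


def test_log_likelihood_prefers_generating_model(rng):
    model, data = _toy_data(rng)
    wrong = TractLengthModel("geometric", m1=2000.0, truncation=4000,
                             rate_per_bp=model.rate_per_bp)
    assert log_likelihood(data, model) > log_likelihood(data, wrong)


def test_log_likelihood_rejects_overlong_tract():
    data = KmerData([TractObservation(0, 10, 5000, 6000)],
                    np.zeros(10_000), DEFAULT_NCO_RATE)
    small = TractLengthModel("geometric", m1=20, truncation=100)
    with pytest.raises(ModelError):
        log_likelihood(data, small)


def test_restrict_drops_long_spans():
    tr = [TractObservation(0, 10, 20, 50), TractObservation(0, 10, 500, 600)]
    data = KmerData(tr, np.ones(1000), DEFAULT_NCO_RATE)
    cut = data.restrict(100)
    assert len(cut.tracts) == 1 and cut.t_max == 100


def test_fit_geometric_recovers_mean(rng):
    model = TractLengthModel("geometric", m1=300.0, truncation=10_000)
    data = simulate_tract_observations(
        model, rng, marker_density=1e-3, min_tracts=300,
        chrom_length=20_000_000, rate_per_bp=1e-4)
    fit = fit_geometric(data)
    assert fit.ci_low <= 300 <= fit.ci_high
    assert fit.ci_low < fit.mean < fit.ci_high
    assert abs(fit.mean - 300) / 300 < 0.25


def test_fit_geometric_needs_tracts():
    data = KmerData([], np.ones(100), DEFAULT_NCO_RATE)
    with pytest.raises(ModelError):
        fit_geometric(data)


# ---------------------------------------------------------------------------
# multi-tract tail bound
# ---------------------------------------------------------------------------

def test_multi_tract_tail_matches_binomial():
    p = (1 - 1 / 50) ** 200
    want = float(binom.sf(1, 10, p))
    assert multi_tract_tail_prob(50, 200, 10, 2) == pytest.approx(want,
                                                                  rel=1e-9)


def test_multi_tract_tail_edge_cases():
    assert multi_tract_tail_prob(100, 10, 5, 0) == 1.0
    tiny = multi_tract_tail_prob(300, 9000, 100, 3)
    assert 0 < tiny < 1e-30   # representable despite the extreme tail
    with pytest.raises(ModelError):
        multi_tract_tail_prob(1.0, 10, 5, 1)
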