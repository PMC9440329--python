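import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from cropcast.features import FeatureWindow, build_feature_matrix, WeatherVariable
from cropcast.prospector import (
    binomial_cutoff,
    combo_count,
    combos_array,
    compatibility_matrix,
    count_feature_frequencies,
    enumerate_full_combos,
    screen_features,
    screening_moments,
    select_significant_features,
    simulate_null_selection_rate,
    top_k_regressions,
)
from cropcast.synthetic import make_dataset

# --------------------------------------------------------------- enumeration


def toy_pool():
    """6 features of 2 variables with some same-variable overlaps."""
    names = ["a0102", "a0203", "a0506", "b0102", "b0304", "b0205"]
    wins = {
        "a0102": ("a", FeatureWindow(1, 2)),
        "a0203": ("a", FeatureWindow(2, 3)),
        "a0506": ("a", FeatureWindow(5, 6)),
        "b0102": ("b", FeatureWindow(1, 2)),
        "b0304": ("b", FeatureWindow(3, 4)),
        "b0205": ("b", FeatureWindow(2, 5)),
    }
    return names, wins


def brute_force_valid(names, wins, d):
    """Oracle: filter all subsets by the same-variable month-set rule."""
    out = []
    for combo in itertools.combinations(range(len(names)), d):
        ok = True
        for i, j in itertools.combinations(combo, 2):
            vi, wi = wins[names[i]]
            vj, wj = wins[names[j]]
            if vi == vj and set(wi.months()) & set(wj.months()):
                ok = False
        if ok:
            out.append(combo)
    return out


def test_unconstrained_counts():
    assert combo_count(135, 4) == 13_232_835
    assert combo_count(5, 4) == 5
    names = [f"f{i:02d}01{i:02d}" for i in range(5)]
    assert len(list(enumerate_full_combos(names, 4))) == 5


def test_constrained_enumeration_matches_brute_force():
    names, wins = toy_pool()
    compat = compatibility_matrix(names, wins)
    for d in range(1, 5):
        got = list(enumerate_full_combos(names, d, compat))
        assert got == brute_force_valid(names, wins, d)
        assert combo_count(len(names), d, names, compat) == len(got)


def test_enumeration_deterministic_lexicographic():
    names, wins = toy_pool()
    combos = list(enumerate_full_combos(names, 3))
    assert combos == sorted(combos)


# ------------------------------------------------------------------ top-k


def district_fixture(n_features=6, n_years=20, seed=2, signal=(1, 4)):
    rng = np.random.default_rng(seed)
    years = list(range(2000, 2000 + n_years))
    F = rng.normal(size=(n_years, n_features))
    y = 60 + 0.3 * np.arange(n_years) + F[:, signal[0]] * 3 - F[:, signal[1]] * 2
    feats = pd.DataFrame(F, index=pd.Index(years), columns=[f"f{i}" for i in range(n_features)])
    return pd.Series(y, index=pd.Index(years)), feats


def brute_force_rank(yields, feats, target_year, combos):
    """Oracle: full lstsq fit per combo, censored target year."""
    years = [y for y in yields.index if y != target_year]
    yv = yields.loc[years].to_numpy()
    out = []
    for combo in combos:
        Z = np.column_stack(
            [np.ones(len(years)), years, feats.loc[years].to_numpy()[:, list(combo)]]
        )
        coef, _, _, _ = np.linalg.lstsq(Z, yv, rcond=None)
        resid = yv - Z @ coef
        r2 = 1 - resid @ resid / np.sum((yv - yv.mean()) ** 2)
        out.append((r2, tuple(combo)))
    out.sort(key=lambda t: (-t[0], t[1]))
    return out


def test_top_k_matches_brute_force():
    yields, feats = district_fixture()
    combos = combos_array(list(feats.columns), 2)
    got = top_k_regressions(yields, feats, 2005, combos, k=5, min_years=15)
    oracle = brute_force_rank(yields, feats, 2005, map(tuple, combos))[:5]
    assert [c for _, c in got] == [c for _, c in oracle]
    for (r_got, _), (r_exp, _) in zip(got, oracle):
        assert r_got == pytest.approx(r_exp, rel=1e-8)


def test_top_k_returns_all_when_k_large():
    yields, feats = district_fixture()
    combos = combos_array(list(feats.columns), 2)
    got = top_k_regressions(yields, feats, 2005, combos, k=10_000, min_years=15)
    assert len(got) == len(combos)


def test_planted_noiseless_signal_ranked_first():
    yields, feats = district_fixture(seed=8, signal=(1, 4))
    combos = combos_array(list(feats.columns), 2)
    got = top_k_regressions(yields, feats, 2010, combos, k=1, min_years=15)
    assert got[0][1] == (1, 4)
    assert got[0][0] == pytest.approx(1.0, abs=1e-10)


def test_top_k_censors_target_year():
    yields, feats = district_fixture()
    combos = combos_array(list(feats.columns), 2)
    a = top_k_regressions(yields, feats, 2005, combos, k=5, min_years=15)
    perturbed = yields.copy()
    perturbed.loc[2005] += 100.0
    b = top_k_regressions(perturbed, feats, 2005, combos, k=5, min_years=15)
    assert a == b  # bitwise identical


def test_top_k_skips_short_series():
    yields, feats = district_fixture(n_years=10)
    combos = combos_array(list(feats.columns), 2)
    assert top_k_regressions(yields, feats, 2005, combos, k=5, min_years=17) is None


# ---------------------------------------------------------------- counting


def test_count_frequencies_tally():
    names = ["a", "b", "c", "d", "e"]
    lists = [[(0.9, (0, 1, 2, 3))], [(0.8, (0, 1, 2, 4)), (0.7, (0, 1, 2, 3))]]
    counts = count_feature_frequencies(lists, names)
    assert counts.tolist() == [3, 3, 3, 2, 1]
    n = sum(len(l) for l in lists)
    assert counts.sum() == 4 * n


def test_single_spec_each_feature_once():
    counts = count_feature_frequencies([[(0.5, (0, 1, 2, 3))]], list("abcd"))
    assert (counts == 1).all()


def test_paper_sample_count():
    assert 326 * 23 == 7498


# ---------------------------------------------------------------- binomial


def exact_cdf_oracle(k, n, p):
    """Exact rational binomial CDF by direct summation."""
    p = Fraction(p).limit_denominator(10**6)
    return float(
        sum(Fraction(math.comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(k + 1))
    )


def summation_cutoff_oracle(n, p, confidence):
    acc = 0.0
    logp, log1p = math.log(p), math.log1p(-p)
    for k in range(n + 1):
        acc += math.exp(
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
            + k * logp + (n - k) * log1p
        )
        if acc >= confidence:
            return k
    return n


def test_binomial_cutoff_paper_value():
    assert binomial_cutoff(7498, 4 / 135, 0.999) == 269
    assert summation_cutoff_oracle(7498, 4 / 135, 0.999) == 269


def test_binomial_cutoff_small_exact():
    assert binomial_cutoff(10, 0.5, 0.999) == 9
    assert exact_cdf_oracle(8, 10, 0.5) < 0.999 <= exact_cdf_oracle(9, 10, 0.5)


def test_binomial_cutoff_degenerate():
    assert binomial_cutoff(100, 0.0, 0.999) == 0
    assert binomial_cutoff(0, 0.3, 0.999) == 0


@pytest.mark.parametrize("seed", range(5))
def test_binomial_cutoff_matches_summation(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 2000))
    p = float(rng.uniform(0.001, 0.5))
    conf = float(rng.uniform(0.9, 0.9999))
    assert binomial_cutoff(n, p, conf) == summation_cutoff_oracle(n, p, conf)


def test_screening_moments_paper_values():
    e, s = screening_moments(7498, 4 / 135)
    assert e == pytest.approx(222.163, abs=5e-4)
    assert s == pytest.approx(14.683, abs=5e-4)
    assert screening_moments(100, 0.0) == (0.0, 0.0)


def test_select_significant_rules():
    counts = pd.Series({"a": 222, "b": 222, "c": 0, "d": 0})
    assert select_significant_features(counts, 269) == []
    counts = pd.Series({"a": 270, "b": 0, "c": 0})
    assert select_significant_features(counts, 269) == ["a"]
    # strictly greater than: exactly at threshold is not selected
    counts = pd.Series({"a": 269, "b": 270})
    assert select_significant_features(counts, 269) == ["b"]


def test_null_false_selection_rate():
    rng = np.random.default_rng(77)
    rate = simulate_null_selection_rate(
        7498, 135, 4, confidence=0.999, reps=400, rng=rng, mechanism="binomial"
    )
    assert rate <= 0.001
    # exact drawing mechanism at small n agrees with the design confidence
    rate2 = simulate_null_selection_rate(
        500, 40, 4, confidence=0.999, reps=300, rng=rng, mechanism="draws"
    )
    assert rate2 <= 0.002


# ------------------------------------------------------------- screening run


@pytest.fixture(scope="module")
def screen_setup():
    ds = make_dataset(n_districts=10, n_years=20, seed=3, noise_share=0.3)
    fm = build_feature_matrix(
        ds.weather,
        ds.variables,
        cutoff_month=6,
        window_bounds=(2, 3),
    )
    return ds, fm


def test_screen_features_bookkeeping(screen_setup):
    ds, fm = screen_setup
    res = screen_features(fm, ds.yields, 2000, k=5, d=3, min_years=15)
    assert res.n == 10 * 5  # every district contributes k specs
    assert res.p == pytest.approx(3 / len(fm.feature_names))
    assert res.counts.sum() == 3 * res.n
    e, s = screening_moments(res.n, res.p)
    assert (res.expectation, res.sigma) == (e, s)
    assert res.threshold == binomial_cutoff(res.n, res.p, 0.999)
    for f in res.selected:
        assert res.counts[f] > res.threshold or res.fallback_used


def test_screening_out_of_sample_purity(screen_setup):
    ds, fm = screen_setup
    res = screen_features(fm, ds.yields, 2001, k=5, d=3, min_years=15)
    perturbed = ds.yields.copy()
    perturbed[2001] = perturbed[2001] + 25.0
    res2 = screen_features(fm, perturbed, 2001, k=5, d=3, min_years=15)
    pd.testing.assert_series_equal(res.counts, res2.counts)
    assert res.selected == res2.selected
    assert res.threshold == res2.threshold


def test_screen_parallel_matches_serial(screen_setup):
    ds, fm = screen_setup
    a = screen_features(fm, ds.yields, 2002, k=5, d=2, min_years=15, n_jobs=1)
    b = screen_features(fm, ds.yields, 2002, k=5, d=2, min_years=15, n_jobs=2)
    pd.testing.assert_series_equal(a.counts, b.counts)
    assert a.selected == b.selected
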