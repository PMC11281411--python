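import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from momnet.diffabund import (
    differential_features,
    feature_symptom_heatmap,
    lda_effect_sizes,
    rank_tests,
)
from momnet.tables import AbundanceTable, ConfigError
from oracles import bh_stepup


def table_from(values, layer="metabolite", prefix="met:"):
    values = np.asarray(values, dtype=float)
    return AbundanceTable(
        layer,
        pd.DataFrame(values,
                     index=[f"{prefix}f{i:04d}" for i in range(len(values))],
                     columns=[f"s{j}" for j in range(values.shape[1])]),
    )


def two_groups(n1, n2):
    ids = [f"s{j}" for j in range(n1 + n2)]
    return pd.Series(["case"] * n1 + ["control"] * n2, index=ids)


def test_exact_mannwhitney_on_complete_separation():
    """4 vs 4 with complete separation: the exact two-sided p equals
    2/70 (two extreme orderings out of C(8,4))."""
    table = table_from([[1, 2, 3, 4, 5, 6, 7, 8]])
    res = rank_tests(table, two_groups(4, 4))
    assert res["p"].iloc[0] == pytest.approx(2 / 70, abs=1e-12)


def test_constant_feature_flagged_with_p_one():
    table = table_from([[3.0] * 8, [1, 2, 3, 4, 4, 3, 2, 1]])
    res = rank_tests(table, two_groups(4, 4))
    assert res["p"].iloc[0] == 1.0 and bool(res["constant"].iloc[0])
    assert res["p"].iloc[1] == 1.0 and not bool(res["constant"].iloc[1])


def test_bh_handles_worked_example_and_matches_stepup():
    q = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
    np.testing.assert_allclose(q, [0.03, 0.03, 0.03])
    rng = np.random.default_rng(0)
    for _ in range(1000):
        m = rng.integers(1, 40)
        p = rng.random(m) ** rng.uniform(0.5, 3)
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], bh_stepup(p), rtol=1e-12
        )


def test_exact_and_asymptotic_p_agree_at_n10():
    rng = np.random.default_rng(1)
    for _ in range(30):
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        p_exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
        p_asym = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(p_exact - p_asym) <= 0.01


def test_lda_score_matches_projected_gap_oracle():
    """A feature whose class means differ by ~1000 (after the fixed-total
    scaling) against a tight background scores log10(1000) = 3."""
    rng = np.random.default_rng(0)
    n = 15
    base = np.full((100, 2 * n), 9990.0) + rng.normal(0, 1, size=(100, 2 * n))
    feat = np.concatenate([rng.normal(1000, 1, n),
                           np.abs(rng.normal(0.5, 0.2, n))])
    table = table_from(np.vstack([feat, base]))
    scores = lda_effect_sizes(table, two_groups(n, n), seed=0)
    assert scores.iloc[0] == pytest.approx(3.0, abs=0.3)
    assert scores.iloc[1:].max() < 2.0


def null_community(seed, m=500, n=40, exponent=2.5, cv=0.3):
    """Identical class distributions over a steep rank-abundance curve
    (a few dominant features) with modest within-group dispersion."""
    rng = np.random.default_rng(seed)
    shares = 1.0 / (np.arange(1, m + 1) + 3) ** exponent
    shares /= shares.sum()
    X = shares[:, None] * 1e6 * rng.lognormal(0, cv, size=(m, n))
    return table_from(X)


def test_null_lda_scores_stay_below_cutoff():
    """With identical class distributions the vast majority of features
    stay below the LDA > 2 cutoff; the exceptions are confined to the
    most abundant head of the community (a known property of LEfSe-style
    scores, whose null magnitude scales with abundance)."""
    table = null_community(seed=0)
    scores = lda_effect_sizes(table, two_groups(20, 20), seed=0)
    assert (scores < 2.0).mean() >= 0.95
    above = np.flatnonzero((scores >= 2.0).to_numpy())
    assert above.size == 0 or above.max() < 30  # features are abundance-sorted


def test_null_pass_count_bounded_by_alpha():
    counts = []
    for seed in range(3):
        table = null_community(seed=seed)
        hits = differential_features(table, two_groups(20, 20), seed=seed)
        counts.append(len(hits))
    assert np.mean(counts) <= 0.05 * 500


def test_lda_scores_invariant_to_sample_order():
    table = null_community(seed=2, m=60, n=20)
    groups = two_groups(10, 10)
    scores = lda_effect_sizes(table, groups, seed=7)
    perm = np.random.default_rng(0).permutation(table.sample_ids)
    shuffled = AbundanceTable(table.layer, table.values[list(perm)])
    scores_shuffled = lda_effect_sizes(shuffled, groups.loc[perm], seed=7)
    pd.testing.assert_series_equal(scores, scores_shuffled)


def test_differential_features_monotone_and_degenerate(bench_run):
    _, tables, samples, _ = bench_run
    table = tables[0]
    loose = differential_features(table, samples.group, p_max=0.05,
                                  lda_min=2.0, seed=0)
    tight_lda = differential_features(table, samples.group, p_max=0.05,
                                      lda_min=3.0, seed=0)
    tight_p = differential_features(table, samples.group, p_max=0.001,
                                    lda_min=2.0, seed=0)
    assert set(tight_lda.index) <= set(loose.index)
    assert set(tight_p.index) <= set(loose.index)
    empty = differential_features(table, samples.group, lda_min=np.inf, seed=0)
    assert len(empty) == 0


def test_planted_differential_features_recovered(bench_run):
    """With 3-log2 planted effects at n = 60 per group, recall of the
    planted features at p < 0.05 & LDA > 2 is at least 0.9."""
    _, tables, samples, truth = bench_run
    hit = tot = 0
    for table in tables:
        found = set(differential_features(table, samples.group, seed=0).index)
        planted = {f for f, _ in truth.diff_features
                   if f in set(table.feature_ids)}
        hit += len(planted & found)
        tot += len(planted)
    assert hit / tot >= 0.9


def test_heatmap_perfect_pair_and_empty_cases():
    rng = np.random.default_rng(3)
    feats = rng.lognormal(0, 1, size=(5, 12))
    A = table_from(feats, layer="virome", prefix="vir:")
    sym = pd.DataFrame(
        {s: [stats.rankdata(feats[0])[j]] for j, s in enumerate(A.sample_ids)},
        index=["sym:GSS_pain"],
    )
    hits = feature_symptom_heatmap(A, sym)
    row = hits[(hits["a"] == "vir:f0000") & (hits["b"] == "sym:GSS_pain")]
    assert len(row) == 1 and row["r"].iloc[0] == pytest.approx(1.0)
    assert len(feature_symptom_heatmap(A, sym, r_min=1.01)) == 0
    with pytest.raises(ConfigError):
        feature_symptom_heatmap(A.subset_samples(A.sample_ids[:3]), sym)


def test_heatmap_null_retention_matches_mc_oracle():
    """Retention of independent pairs at |r| > 0.6, p < 0.05 (n = 20)
    matches a direct scipy Monte-Carlo estimate of the null rate."""
    n = 20
    rng = np.random.default_rng(4)
    mc = 5000
    null_hits = 0
    for _ in range(mc):
        r, p = stats.spearmanr(rng.standard_normal(n), rng.standard_normal(n))
        null_hits += (abs(r) > 0.6) and (p < 0.05)
    nominal = null_hits / mc

    A = table_from(rng.lognormal(0, 1, size=(100, n)), "virome", "vir:")
    B = table_from(rng.lognormal(0, 1, size=(100, n)), "bacteria", "bac:")
    kept = feature_symptom_heatmap(A, B)
    frac = len(kept) / (100 * 100)
    se = np.sqrt(nominal * (1 - nominal) * (1 / mc + 1 / 10000))
    assert abs(frac - nominal) < 3 * se + 1e-12
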