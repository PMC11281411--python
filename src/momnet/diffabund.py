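"""Two-class differential abundance: rank tests plus an LDA effect size.

The procedure is a two-class LEfSe-style variant (the study design has no
subclasses, so the subclass Wilcoxon stage is omitted): a two-sided
Mann-Whitney U test per feature with BH adjustment, and a bootstrapped
regularized linear-discriminant effect size on a log10 scale. Features
pass when p < p_max and LDA score > lda_min, and are annotated with the
group they are enriched in.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .netbuild import spearman_matrix
from .tables import AbundanceTable, ConfigError

#: per-sample total that abundances are scaled to before the LDA stage,
#: so scores are comparable to published LEfSe scores.
LDA_TOTAL = 1e6


def _two_group_arrays(table: AbundanceTable, groups: pd.Series):
    labels = groups.reindex(table.sample_ids)
    if labels.isna().any():
        raise ConfigError("group labels missing for some samples")
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ConfigError(f"need exactly 2 groups, got {names}")
    masks = {g: (labels == g).to_numpy() for g in names}
    for g, m in masks.items():
        if m.sum() < 3:
            raise ConfigError(f"group {g!r} has fewer than 3 samples")
    return table.values.to_numpy(dtype=float), names, masks


def rank_tests(table: AbundanceTable, groups: pd.Series) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney U with BH-adjusted q.

    Exact enumeration for group sizes up to 8 without ties; tie-corrected
    normal approximation otherwise. Constant features get p = 1 and a
    ``constant`` flag.
    """
    X, names, masks = _two_group_arrays(table, groups)
    a_mask, b_mask = masks[names[0]], masks[names[1]]
    n1, n2 = int(a_mask.sum()), int(b_mask.sum())
    rows = []
    for i, fid in enumerate(table.feature_ids):
        x, y = X[i, a_mask], X[i, b_mask]
        combined = np.concatenate([x, y])
        if np.all(combined == combined[0]):
            rows.append((fid, n1 * n2 / 2.0, 1.0, True))
            continue
        has_ties = len(np.unique(combined)) < len(combined)
        method = "exact" if (n1 <= 8 and n2 <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append((fid, float(res.statistic), min(float(res.pvalue), 1.0), False))
    out = pd.DataFrame(rows, columns=["feature_id", "U", "p", "constant"])
    out = out.set_index("feature_id")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[["U", "p", "q", "constant"]]


def lda_effect_sizes(
    table: AbundanceTable,
    groups: pd.Series,
    n_boot: int = 30,
    subsample: float = 2 / 3,
    seed: int = 0,
) -> pd.Series:
    """Bootstrapped LDA effect size per feature, on a log10 scale.

    Abundances are scaled to a fixed per-sample total first. Each round
    subsamples a fraction of each class, fits a shrinkage-regularized
    two-class LDA, and scores each feature as the mean of the LDA-weighted
    and raw class-mean differences, floored at 1 before taking log10
    (the LEfSe convention). The reported score is the mean over rounds.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    if not 0.0 < subsample <= 1.0:
        raise ConfigError("subsample must be in (0, 1]")
    _, names, _ = _two_group_arrays(table, groups)
    labels = groups.reindex(table.sample_ids)
    # subsampling draws from the *sorted* sample ids of each class, so the
    # result is invariant to the column order of the input table
    ids_by_class = {g: np.array(sorted(labels.index[labels == g])) for g in names}
    totals = table.values.sum(axis=0)
    totals[totals == 0] = 1.0
    Xs = table.values / totals * LDA_TOTAL  # features x samples
    rng = np.random.default_rng(seed)
    scores = np.zeros((n_boot, Xs.shape[0]))
    used = 0
    for _ in range(n_boot):
        take = []
        for g in names:
            k = max(1, int(round(subsample * len(ids_by_class[g]))))
            take.append(rng.choice(ids_by_class[g], size=k, replace=False))
        sizes = [len(t) for t in take]
        if min(sizes) < 2:
            warnings.warn("bootstrap round skipped: a class had < 2 samples",
                          stacklevel=2)
            continue
        cols = np.concatenate(take)
        y = np.concatenate([np.full(s, gi) for gi, s in enumerate(sizes)])
        sub = Xs[cols].T.to_numpy()  # samples x features
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda.fit(sub, y)
        w = lda.coef_[0]
        norm = np.linalg.norm(w)
        w_unit = w / norm if norm > 0 else w
        m0 = sub[y == 0].mean(axis=0)
        m1 = sub[y == 1].mean(axis=0)
        delta = m0 - m1
        effect = 0.5 * (np.abs(w_unit * delta) + np.abs(delta))
        scores[used] = np.log10(np.maximum(effect, 1.0))
        used += 1
    if used == 0:
        raise ConfigError("all bootstrap rounds were skipped; increase subsample")
    return pd.Series(scores[:used].mean(axis=0), index=table.feature_ids,
                     name="lda_score")


def differential_features(
    table: AbundanceTable,
    groups: pd.Series,
    p_max: float = 0.05,
    lda_min: float = 2.0,
    n_boot: int = 30,
    subsample: float = 2 / 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Features with p < p_max and LDA score > lda_min, with direction.

    Direction is the group with the higher median abundance (higher mean
    breaks median ties).
    """
    tests = rank_tests(table, groups)
    lda = lda_effect_sizes(table, groups, n_boot=n_boot, subsample=subsample,
                           seed=seed)
    X, names, masks = _two_group_arrays(table, groups)
    med = {g: np.median(X[:, masks[g]], axis=1) for g in names}
    mean = {g: X[:, masks[g]].mean(axis=1) for g in names}
    direction = []
    for i in range(X.shape[0]):
        if med[names[0]][i] != med[names[1]][i]:
            direction.append(names[0] if med[names[0]][i] > med[names[1]][i] else names[1])
        elif mean[names[0]][i] != mean[names[1]][i]:
            direction.append(names[0] if mean[names[0]][i] > mean[names[1]][i] else names[1])
        else:
            direction.append("none")
    out = tests.copy()
    out["lda_score"] = lda
    out["direction"] = direction
    keep = (out["p"] < p_max) & (out["lda_score"] > lda_min)
    return out.loc[keep].sort_values("lda_score", ascending=False)


def feature_symptom_heatmap(
    features_a,
    features_b,
    r_min: float = 0.6,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """All pairwise Spearman correlations between two feature/symptom sets,
    retained at |r| > r_min and p < p_max, as a long-form table."""
    corr = spearman_matrix(features_a, features_b)
    r, p, q = corr.r, corr.p, corr.q
    rows = []
    for u in r.index:
        for v in r.columns:
            rv = r.at[u, v]
            if np.isnan(rv):
                continue
            if abs(rv) > r_min and p.at[u, v] < p_max:
                rows.append((u, v, float(rv), float(p.at[u, v]), float(q.at[u, v])))
    return pd.DataFrame(rows, columns=["a", "b", "r", "p", "q"])
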