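"""Alpha/beta diversity and the PERMANOVA group test.

Shannon entropy (natural log by default) per sample, Bray-Curtis
dissimilarity between samples, classical principal-coordinate analysis,
and a seeded permutation PERMANOVA in Anderson's pseudo-F formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable, ConfigError


@dataclass
class DistanceMatrix:
    sample_ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.sample_ids),) * 2:
            raise ConfigError("distance matrix shape mismatch")
        if not np.isfinite(d).all():
            raise ConfigError("distances must be finite")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ConfigError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ConfigError("distance matrix diagonal must be zero")
        self.d = d

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int


def shannon(table: AbundanceTable, base: float | None = None) -> pd.Series:
    """Shannon index H = -sum p_i log p_i per sample (nats by default)."""
    arr = table.values.to_numpy(dtype=float)
    sums = arr.sum(axis=0)
    zero = [s for s, tot in zip(table.sample_ids, sums) if tot <= 0]
    if zero:
        raise ConfigError(f"all-zero samples: {zero[:5]}")
    p = arr / sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=0)
    if base is not None:
        h = h / np.log(base)
    return pd.Series(h, index=table.sample_ids, name="shannon")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) over samples."""
    if table.n_samples < 2:
        raise ConfigError("need at least 2 samples")
    X = table.values.to_numpy(dtype=float).T  # samples x features
    sums = X.sum(axis=1)
    for i in range(len(sums)):
        for j in range(i + 1, len(sums)):
            if sums[i] == 0 and sums[j] == 0:
                raise ConfigError(
                    f"Bray-Curtis undefined for all-zero sample pair "
                    f"({table.sample_ids[i]}, {table.sample_ids[j]})"
                )
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(sample_ids=list(table.sample_ids), d=d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix, k: int = 2):
    """Classical scaling of the Gower-centered matrix.

    Returns (coordinates DataFrame on the first k non-negative axes,
    all eigenvalues in descending order). Negative eigenvalues are
    reported but excluded from the embedding; if fewer than k positive
    axes exist the coordinates are truncated with a warning.
    """
    if k > dist.n - 1:
        raise ConfigError("k must be at most n - 1")
    B = _gower_center(dist.d)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        import warnings

        warnings.warn(
            f"only {n_pos} positive PCoA axes available; truncating to {k_eff}",
            stacklevel=2,
        )
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    frame = pd.DataFrame(
        coords, index=dist.sample_ids,
        columns=[f"PCo{i + 1}" for i in range(k_eff)],
    )
    return frame, eigvals


def _permanova_stats(d2: np.ndarray, labels: np.ndarray):
    """Pseudo-F and R2 from squared distances and integer group labels."""
    n = d2.shape[0]
    groups = np.unique(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = len(groups) - 1
    df_within = n - len(groups)
    F = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total
    return F, r2


def permanova(dist: DistanceMatrix, groups: pd.Series, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA (Adonis) with seeded label permutations.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm), the add-one
    estimator, so p is never zero.
    """
    if n_perm < 99:
        raise ConfigError("n_perm must be at least 99")
    labels = groups.reindex(dist.sample_ids)
    if labels.isna().any():
        raise ConfigError("group labels missing for some samples")
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ConfigError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(uniques[i]) for i in np.flatnonzero(counts < 2)]
        raise ConfigError(f"groups with fewer than 2 samples: {small}")
    d2 = dist.d ** 2
    F_obs, r2 = _permanova_stats(d2, codes)
    rng = np.random.default_rng(seed)
    count_ge = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        F_perm, _ = _permanova_stats(d2, perm)
        if F_perm >= F_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(F_obs), R2=float(r2), p=float(p),
                           n_perm=n_perm)
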