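"""Spearman correlation matrices and co-occurrence network construction.

Networks keep an edge (u, v) iff |r| > r_min AND p < p_max AND q <= q_max,
with r the tie-corrected Spearman coefficient, p its t-distribution
approximation on n-2 degrees of freedom, and q the Benjamini-Hochberg
adjusted p over all pairs tested in the same call (the per-network FDR
family). Three modes mirror the study: ``single`` (one within-layer
network), ``cross`` (virome-bacteria-metabolite, inter-layer edges only)
and ``symptom`` (the cross network augmented with symptom-item nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import (
    AbundanceTable,
    ConfigError,
    SampleTable,
    layer_of,
)

PAPER_THRESHOLDS = {"r_min": 0.8, "p_max": 0.001}
HEATMAP_THRESHOLDS = {"r_min": 0.6, "p_max": 0.05}


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman r, raw p and BH q for one (pair of) feature set(s)."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    symmetric: bool
    n_samples: int

    @property
    def row_ids(self) -> list:
        return list(self.r.index)

    @property
    def col_ids(self) -> list:
        return list(self.r.columns)

    def row_layers(self) -> set:
        return {layer_of(f) for f in self.row_ids}

    def col_layers(self) -> set:
        return {layer_of(f) for f in self.col_ids}


def _as_frame(obj) -> pd.DataFrame:
    if isinstance(obj, AbundanceTable):
        return obj.values
    if isinstance(obj, pd.DataFrame):
        return obj
    raise ConfigError(f"expected AbundanceTable or DataFrame, got {type(obj)!r}")


def symptom_matrix(samples: SampleTable) -> pd.DataFrame:
    """Symptom items as an items x samples matrix for correlation calls."""
    if samples.symptom_items is None:
        raise ConfigError("sample table has no symptom items")
    return samples.symptom_items.T


def _rank_standardize(X: np.ndarray):
    """Mid-ranks standardized to zero mean / unit norm; constant rows NaN."""
    ranks = stats.rankdata(X, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    Z = ranks / norms[:, None]
    Z[constant] = np.nan
    return Z


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.clip(1.0 - r ** 2, 0.0, None)
        t = r * np.sqrt((n - 2) / denom)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.where(np.isnan(r), np.nan, p)


def spearman_matrix(X, Y=None) -> CorrelationMatrix:
    """Tie-corrected Spearman r for every (row, col) pair.

    Within X when Y is absent, between the rows of X and Y otherwise.
    Constant features yield NaN (flagged, excluded from the BH family).
    """
    fx = _as_frame(X)
    symmetric = Y is None
    fy = fx if symmetric else _as_frame(Y)
    shared = [s for s in fx.columns if s in set(fy.columns)]
    if len(shared) < 4:
        raise ConfigError(f"need at least 4 shared samples, got {len(shared)}")
    ax = fx[shared].to_numpy(dtype=float)
    ay = ax if symmetric else fy[shared].to_numpy(dtype=float)
    n = len(shared)
    zx = _rank_standardize(ax)
    zy = zx if symmetric else _rank_standardize(ay)
    r = np.clip(zx @ zy.T, -1.0, 1.0)
    p = _p_from_r(r, n)

    if symmetric:
        iu = np.triu_indices(r.shape[0], 1)
        flat_p = p[iu]
    else:
        flat_p = p.ravel()
    q_flat = np.full(flat_p.shape, np.nan)
    tested = ~np.isnan(flat_p)
    if tested.any():
        q_flat[tested] = multipletests(flat_p[tested], method="fdr_bh")[1]
    if symmetric:
        q = np.full(r.shape, np.nan)
        q[iu] = q_flat
        q[(iu[1], iu[0])] = q_flat
    else:
        q = q_flat.reshape(p.shape)

    idx, cols = fx.index, fy.index
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        symmetric=symmetric,
        n_samples=n,
    )


def _check_mode(corrs: list[CorrelationMatrix], mode: str) -> None:
    if mode == "single":
        if len(corrs) != 1 or not corrs[0].symmetric:
            raise ConfigError("single mode expects exactly one within-layer matrix")
        return
    if mode not in ("cross", "symptom"):
        raise ConfigError(f"unknown mode {mode!r}")
    has_symptom = False
    for c in corrs:
        rl, cl = c.row_layers(), c.col_layers()
        if c.symmetric or (rl & cl):
            raise ConfigError(f"{mode} mode forbids intra-layer matrices")
        if "symptom" in (rl | cl):
            has_symptom = True
            if mode == "cross":
                raise ConfigError("cross mode takes omics layers only")
    if mode == "symptom" and not has_symptom:
        raise ConfigError("symptom mode requires symptom-feature matrices")


def build_network(
    corrs,
    r_min: float = 0.8,
    p_max: float = 0.001,
    q_max: float = 0.05,
    mode: str = "single",
    annotations: dict | None = None,
) -> nx.Graph:
    """Threshold correlation matrices into a signed co-occurrence network.

    ``annotations`` maps feature id -> attribute dict copied onto nodes.
    Isolated nodes are dropped (nodes exist only via passing edges).
    """
    if isinstance(corrs, CorrelationMatrix):
        corrs = [corrs]
    _check_mode(corrs, mode)
    net = nx.Graph()
    for c in corrs:
        r = c.r.to_numpy()
        p = c.p.to_numpy()
        q = c.q.to_numpy()
        with np.errstate(invalid="ignore"):
            passing = (np.abs(r) > r_min) & (p < p_max) & (q <= q_max)
        passing &= ~np.isnan(r)
        rows, cols = np.nonzero(passing)
        for i, j in zip(rows, cols):
            u, v = c.r.index[i], c.r.columns[j]
            if u == v:
                continue
            if c.symmetric and i >= j:
                continue
            rv = float(r[i, j])
            net.add_edge(u, v, r=rv, p=float(p[i, j]), q=float(q[i, j]),
                         sign=1 if rv > 0 else -1, absr=abs(rv))
    for node in net.nodes:
        net.nodes[node]["layer"] = layer_of(node)
        if annotations and node in annotations:
            for key, val in annotations[node].items():
                net.nodes[node][key] = val
    return net


def annotations_from_tables(tables) -> dict:
    """Merge per-table annotation frames into a node-attribute dict."""
    out: dict = {}
    for table in tables:
        if table.annotations is None:
            continue
        for fid, row in table.annotations.iterrows():
            out[fid] = {k: v for k, v in row.items() if pd.notna(v)}
    return out
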