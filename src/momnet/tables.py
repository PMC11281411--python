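"""Containers and TSV/GraphML input-output for abundance tables, sample
metadata and co-occurrence networks.

Feature ids are namespaced by layer (``vir:``, ``bac:``, ``met:``, ``sym:``)
so that ids stay globally unique when layers are merged into one network.
All readers validate strictly and raise :class:`FormatError` rather than
silently coercing malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

LAYERS = ("virome", "bacteria", "metabolite")
SYMPTOM_LAYER = "symptom"
LAYER_PREFIX = {
    "virome": "vir:",
    "bacteria": "bac:",
    "metabolite": "met:",
    "symptom": "sym:",
}
GROUPS = ("case", "control")

EDGE_ATTRS = ("r", "p", "q", "sign")


class FormatError(ValueError):
    """Malformed input table or network file."""


class ConfigError(ValueError):
    """Invalid configuration or contract violation."""


def layer_of(feature_id: str) -> str:
    """Infer the omics layer from a namespaced feature id."""
    for layer, prefix in LAYER_PREFIX.items():
        if feature_id.startswith(prefix):
            return layer
    raise FormatError(f"feature id {feature_id!r} has no recognised layer prefix")


@dataclass
class AbundanceTable:
    """One omics layer: a features x samples matrix of non-negative reals.

    ``annotations`` maps feature ids to per-feature metadata (taxonomy
    string, ``SCFA_producer`` flag, metabolite class); its index must be a
    subset of the feature ids.
    """

    layer: str
    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ConfigError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise FormatError("abundance values must be finite")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative abundance at feature {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if self.annotations is not None:
            extra = self.annotations.index.difference(v.index)
            if len(extra):
                raise FormatError(
                    f"annotations for unknown features: {extra.tolist()[:5]}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise ConfigError(f"unknown sample ids: {sorted(missing)[:5]}")
        return AbundanceTable(self.layer, self.values.loc[:, list(sample_ids)], self.annotations)

    def subset_features(self, feature_ids) -> "AbundanceTable":
        missing = set(feature_ids) - set(self.values.index)
        if missing:
            raise ConfigError(f"unknown feature ids: {sorted(missing)[:5]}")
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[self.annotations.index.intersection(feature_ids)]
        return AbundanceTable(self.layer, self.values.loc[list(feature_ids)], ann)


@dataclass
class SampleTable:
    """Sample metadata: group labels plus per-item ordinal symptom scores.

    ``scale_defs`` maps a scale name (GSS/SDS/SAS) to its ordered item list;
    ``subscale_defs`` optionally maps scale -> subscale name -> item subset
    (e.g. the depression scale's physiological vs psychological items).
    """

    group: pd.Series
    symptom_items: pd.DataFrame | None = None
    scale_defs: dict[str, list[str]] = field(default_factory=dict)
    subscale_defs: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        if self.group.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        all_items = [it for items in self.scale_defs.values() for it in items]
        if len(all_items) != len(set(all_items)):
            raise FormatError("item ids must be unique across scales")
        if self.symptom_items is not None:
            if not self.symptom_items.index.equals(self.group.index):
                missing = self.group.index.difference(self.symptom_items.index)
                if len(missing):
                    raise FormatError(f"samples missing symptom rows: {missing.tolist()[:5]}")
                self.symptom_items = self.symptom_items.loc[self.group.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group.index)

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ConfigError(f"unknown group {group!r}")
        return list(self.group.index[self.group == group])


# The network container is a plain networkx Graph with conventions:
# node attribute "layer" (virome/bacteria/metabolite/symptom) plus optional
# annotation keys; edge attributes r, p, q, sign and "absr" = |r| used as
# the weight in modularity / eigenvector computations.
OmicsNetwork = nx.Graph


def validate_network(net: nx.Graph) -> None:
    """Check the co-occurrence network invariants; raise on violation."""
    if any(u == v for u, v in net.edges):
        raise FormatError("self-loops are not allowed")
    for node, data in net.nodes(data=True):
        if "layer" not in data:
            raise FormatError(f"node {node!r} has no layer attribute")
    for u, v, data in net.edges(data=True):
        for key in EDGE_ATTRS:
            if key not in data:
                raise FormatError(f"edge ({u!r},{v!r}) missing attribute {key!r}")
        if abs(data["r"]) > 1 + 1e-12:
            raise FormatError(f"|r| > 1 on edge ({u!r},{v!r})")


def _strict_float_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    # astype(float) (not pd.to_numeric) so parsing is exact to the last ulp
    out = {}
    for col in df.columns:
        raw = df[col]
        if raw.isna().any():
            row = raw.index[raw.isna()][0]
            raise FormatError(f"{path}: empty cell at row {row!r}, column {col!r}")
        try:
            out[col] = raw.astype(float)
        except (ValueError, TypeError):
            for row, cell in raw.items():
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise FormatError(
                        f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                    ) from None
            raise
    return pd.DataFrame(out, index=df.index)


def read_abundance(path, layer: str, annotations_path=None) -> AbundanceTable:
    """Read a features x samples abundance TSV (first column feature ids).

    An optional sidecar annotation TSV (first column feature ids) supplies
    per-feature metadata.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.hasnans or df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing cells")
    values = _strict_float_frame(df, path)
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
    return AbundanceTable(layer=layer, values=values, annotations=ann)


def write_abundance(table: AbundanceTable, path, annotations_path=None) -> None:
    table.values.to_csv(path, sep="\t", float_format="%.17g")
    if annotations_path is not None and table.annotations is not None:
        table.annotations.to_csv(annotations_path, sep="\t")


def read_metadata(path, scale_defs=None, item_ranges=None,
                  subscale_defs=None) -> SampleTable:
    """Read a sample metadata TSV: sample id, ``group`` column, item columns.

    ``item_ranges`` maps scale name -> (lo, hi) inclusive ordinal bounds;
    out-of-range scores are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in df.columns:
        raise FormatError(f"{path}: missing 'group' column")
    group = df["group"].astype(str)
    scale_defs = scale_defs or {}
    items = [it for its in scale_defs.values() for it in its]
    symptom = None
    if items:
        missing = [it for it in items if it not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing item columns {missing[:5]}")
        symptom = _strict_float_frame(df[items].astype(str), path)
        if item_ranges:
            for scale, (lo, hi) in item_ranges.items():
                block = symptom[scale_defs[scale]]
                if ((block < lo) | (block > hi)).any().any():
                    raise FormatError(
                        f"{path}: {scale} item score outside ordinal range [{lo},{hi}]"
                    )
    return SampleTable(group=group, symptom_items=symptom,
                       scale_defs=scale_defs, subscale_defs=subscale_defs or {})


def write_metadata(samples: SampleTable, path) -> None:
    df = samples.group.to_frame("group")
    if samples.symptom_items is not None:
        df = df.join(samples.symptom_items)
    df.to_csv(path, sep="\t")


def write_network(net: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Serialize a network as GraphML or a one-edge-per-line TSV."""
    validate_network(net)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge_tsv":
        rows = [
            {"u": u, "v": v, **{k: d[k] for k in EDGE_ATTRS}}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["u", "v", *EDGE_ATTRS]).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
    else:
        raise ConfigError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv") -> nx.Graph:
    if format == "graphml":
        net = nx.read_graphml(path)
        return nx.relabel_nodes(net, {n: str(n) for n in net.nodes})
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"u": str, "v": str})
        net = nx.Graph()
        for row in df.itertuples(index=False):
            attrs = {k: getattr(row, k) for k in EDGE_ATTRS}
            attrs["sign"] = int(attrs["sign"])
            attrs["absr"] = abs(attrs["r"])
            net.add_edge(row.u, row.v, **attrs)
        for node in net.nodes:
            net.nodes[node]["layer"] = layer_of(node)
        return net
    raise ConfigError(f"unknown network format {format!r}")
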