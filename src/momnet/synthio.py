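"""Synthetic multiomics data with known planted structure.

The generator emulates a two-group (patient vs healthy-control) gut
multiomics study: a virome layer quantified as RPKM, a bacterial OTU count
layer, and a metabolite intensity layer, plus ordinal symptom-scale items
(gastrointestinal, depression, anxiety) coupled to latent modules.

Correlation structure is planted with a Gaussian latent-factor copula:
features in a block share a latent factor, and per-layer marginals are
applied as monotone quantile transforms of the per-feature Gaussian, so
the target Spearman correlation survives the transform exactly (Spearman
is rank-invariant). Zero inflation defaults to detection-limit censoring
(the lowest ``zero_prob`` quantile of each feature is set to zero), which
is monotone per feature — ``rho_within`` stays the target Spearman of the
observed data, and the zero ties exercise the tie-corrected Spearman path
downstream. Independent Bernoulli masking is available as
``zero_mode="bernoulli"``; it attenuates observed rank correlations below
``rho_within`` (masking changes the estimand, not just the noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    LAYERS,
    LAYER_PREFIX,
    AbundanceTable,
    ConfigError,
    SampleTable,
    write_abundance,
    write_metadata,
)

GSS_ITEMS = [
    "sym:GSS_abdominal_pain",
    "sym:GSS_abdominal_distension",
    "sym:GSS_diarrhea",
    "sym:GSS_urgency",
    "sym:GSS_incomplete_defecation",
    "sym:GSS_stool_frequency",
    "sym:GSS_mucus",
]
SDS_ITEMS = [f"sym:SDS_{i:02d}" for i in range(1, 21)]
SAS_ITEMS = [f"sym:SAS_{i:02d}" for i in range(1, 21)]
SCALE_DEFS = {"GSS": GSS_ITEMS, "SDS": SDS_ITEMS, "SAS": SAS_ITEMS}
# Depression sub-scales: eight physiological and ten psychological items.
SUBSCALE_DEFS = {
    "SDS": {
        "physiological": SDS_ITEMS[:8],
        "psychological": SDS_ITEMS[8:18],
    }
}
# Ordinal grids: GSS items on 0-4, Zung depression/anxiety items on 1-4.
ITEM_RANGES = {"GSS": (0, 4), "SDS": (1, 4), "SAS": (1, 4)}
_GSS_CUTS = np.array([-1.5, -0.5, 0.5, 1.5])
_ZUNG_CUTS = np.array([-1.0, 0.0, 1.0])

# Per-layer marginal parameters: (log-mean location, log-mean spread).
_LAYER_LOGMEAN = {"virome": (1.0, 1.5), "bacteria": (4.0, 1.0), "metabolite": (8.0, 1.0)}


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-Gaussian Pearson correlation yielding Spearman ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the study design (12 patients vs 8 controls); power-
    hungry tests pass larger per-group n explicitly.
    """

    n_case: int = 12
    n_control: int = 8
    n_features_per_layer: dict = field(
        default_factory=lambda: {"virome": 240, "bacteria": 160, "metabolite": 80}
    )
    n_modules: int = 6
    block_size: int = 8
    rho_within: float = 0.9
    cross_layer: bool = True
    n_diff_features: int = 10
    effect_log2fc: float = 2.0
    zero_prob: float = 0.1
    zero_mode: str = "censor"
    dispersion: float = 0.5
    symptom_loading: float = 0.8
    symptom_noise: float = 0.5
    symptom_case_shift: float = 0.5
    n_loading_items: dict = field(
        default_factory=lambda: {"GSS": 4, "SDS": 8, "SAS": 6}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 3 or self.n_control < 3:
            raise ConfigError("need at least 3 samples per group")
        if not 0.0 <= self.rho_within < 1.0:
            raise ConfigError("rho_within must be in [0, 1)")
        if not 0.0 <= self.zero_prob < 1.0:
            raise ConfigError("zero_prob must be in [0, 1)")
        if set(self.n_features_per_layer) - set(LAYERS):
            raise ConfigError(f"layers must be among {LAYERS}")
        for layer, n in self.n_features_per_layer.items():
            if n < 1:
                raise ConfigError(f"{layer}: need at least one feature")
            if self.n_diff_features > n:
                raise ConfigError(f"{layer}: n_diff_features exceeds n features")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.zero_mode not in ("censor", "bernoulli"):
            raise ConfigError("zero_mode must be 'censor' or 'bernoulli'")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    @property
    def sample_ids(self) -> list[str]:
        return [f"case{i + 1:03d}" for i in range(self.n_case)] + [
            f"ctrl{i + 1:03d}" for i in range(self.n_control)
        ]

    @property
    def groups(self) -> pd.Series:
        labels = ["case"] * self.n_case + ["control"] * self.n_control
        return pd.Series(labels, index=self.sample_ids, name="group")


def study_preset(seed: int = 0, **overrides) -> SimConfig:
    """The study's own design: 12 patients vs 8 healthy controls."""
    return SimConfig(seed=seed, **overrides)


def powered_preset(seed: int = 0, **overrides) -> SimConfig:
    """Same 3:2 group proportions at 30 vs 20 samples — enough power for
    both group-specific networks to pass the |r| > 0.8, p < 0.001
    thresholds on planted blocks."""
    kwargs = {"n_case": 30, "n_control": 20}
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth of one simulation run."""

    block_membership: dict  # feature -> block id; 0 means background
    true_edges: set  # frozenset pairs sharing a block
    diff_features: set  # (feature_id, enriched group)
    latent_factors: pd.DataFrame  # samples x blocks
    symptom_blocks: dict = field(default_factory=dict)  # item -> block id

    def true_edges_within(self, layer_prefix: str) -> set:
        return {
            e for e in self.true_edges
            if all(f.startswith(layer_prefix) for f in e)
        }


def _assign_blocks(config: SimConfig) -> dict:
    """Assign ``block_size`` features per block; round-robin over layers
    when blocks may span layers, one layer per block otherwise."""
    layers = [l for l in LAYERS if l in config.n_features_per_layer]
    feature_ids = {
        layer: [f"{LAYER_PREFIX[layer]}f{i + 1:04d}" for i in range(n)]
        for layer, n in config.n_features_per_layer.items()
    }
    membership = {f: 0 for ids in feature_ids.values() for f in ids}
    cursors = {layer: 0 for layer in layers}
    for b in range(1, config.n_modules + 1):
        if config.cross_layer:
            pool = layers
        else:
            pool = [layers[(b - 1) % len(layers)]]
        for k in range(config.block_size):
            layer = pool[k % len(pool)]
            i = cursors[layer]
            if i >= len(feature_ids[layer]):
                raise ConfigError(
                    f"not enough {layer} features to host {config.n_modules} "
                    f"blocks of size {config.block_size}"
                )
            membership[feature_ids[layer][i]] = b
            cursors[layer] += 1
    return membership


def _marginal_counts(u: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mu)
    return stats.nbinom.ppf(u, size, p)


def generate_multiomics(config: SimConfig):
    """Generate one table per layer plus sample metadata and ground truth.

    Block features are monotone transforms of shared latent Gaussian
    factors (counts: negative-binomial quantile coupling with mean
    ``exp(latent)`` scale; intensities/RPKM: log-normal). Differential
    features have their case-group mean shifted by ``effect_log2fc``
    (alternating direction). Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_samples
    sample_ids = config.sample_ids
    case_mask = (config.groups == "case").to_numpy()

    Z = rng.standard_normal((n, config.n_modules))
    membership = _assign_blocks(config)
    a = np.sqrt(spearman_to_pearson(config.rho_within))

    tables: list[AbundanceTable] = []
    diff_features: set = set()
    for layer in (l for l in LAYERS if l in config.n_features_per_layer):
        n_feat = config.n_features_per_layer[layer]
        prefix = LAYER_PREFIX[layer]
        ids = [f"{prefix}f{i + 1:04d}" for i in range(n_feat)]
        background = [f for f in ids if membership[f] == 0]
        layer_diff = background[: config.n_diff_features]
        directions = ["case" if i % 2 == 0 else "control" for i in range(len(layer_diff))]
        diff_features |= set(zip(layer_diff, directions))
        diff_dir = dict(zip(layer_diff, directions))

        eps = rng.standard_normal((n_feat, n))
        g = np.empty((n_feat, n))
        for i, f in enumerate(ids):
            b = membership[f]
            if b > 0:
                g[i] = a * Z[:, b - 1] + np.sqrt(1.0 - a * a) * eps[i]
            else:
                g[i] = eps[i]

        loc, spread = _LAYER_LOGMEAN[layer]
        log_base = rng.normal(loc, spread, size=n_feat)
        # per-sample log-mean shift for planted group-differential features
        shift = np.zeros((n_feat, n))
        ln2 = np.log(2.0)
        for i, f in enumerate(ids):
            if f in diff_dir:
                delta = config.effect_log2fc * ln2
                if diff_dir[f] == "case":
                    shift[i, case_mask] = delta
                else:
                    shift[i, ~case_mask] = delta

        u = np.clip(stats.norm.cdf(g), 1e-12, 1.0 - 1e-12)
        if layer == "bacteria":
            mu = np.exp(log_base[:, None] + shift)
            values = _marginal_counts(u, mu, config.dispersion)
        else:
            values = np.exp(log_base[:, None] + shift + g)

        if config.zero_prob > 0:
            if config.zero_mode == "censor":
                mask = u < config.zero_prob
            else:
                mask = rng.random((n_feat, n)) < config.zero_prob
            values = np.where(mask, 0.0, values)

        ann = pd.DataFrame(index=pd.Index(ids, name="feature_id"))
        ann["block"] = [membership[f] for f in ids]
        if layer == "bacteria":
            # flag roughly a third of OTUs as SCFA producers, block members first
            flags = [(membership[f] > 0) or (i % 3 == 0) for i, f in enumerate(ids)]
            ann["SCFA_producer"] = flags
            ann["taxonomy"] = [f"k__Bacteria;g__Genus{(i % 12) + 1}" for i in range(n_feat)]
        elif layer == "virome":
            fams = ["Microviridae", "Siphoviridae", "Podoviridae", "Myoviridae", "unclassified"]
            ann["taxonomy"] = [fams[i % len(fams)] for i in range(n_feat)]
        else:
            classes = ["amino acid", "bile acid", "indole derivative", "other"]
            ann["metabolite_class"] = [classes[i % len(classes)] for i in range(n_feat)]

        tables.append(
            AbundanceTable(
                layer=layer,
                values=pd.DataFrame(values, index=ids, columns=sample_ids),
                annotations=ann,
            )
        )

    by_block: dict[int, list[str]] = {}
    for f, b in membership.items():
        if b > 0:
            by_block.setdefault(b, []).append(f)
    true_edges = {
        frozenset((u, v))
        for members in by_block.values()
        for i, u in enumerate(members)
        for v in members[i + 1:]
    }
    truth = PlantedTruth(
        block_membership=membership,
        true_edges=true_edges,
        diff_features=diff_features,
        latent_factors=pd.DataFrame(
            Z, index=sample_ids, columns=[f"block{b}" for b in range(1, config.n_modules + 1)]
        ),
    )
    samples = SampleTable(
        group=config.groups,
        scale_defs=dict(SCALE_DEFS),
        subscale_defs={k: dict(v) for k, v in SUBSCALE_DEFS.items()},
    )
    return tables, samples, truth


def default_item_blocks(config: SimConfig) -> dict:
    """Deterministic default mapping of loading items to blocks: the first
    ``n_loading_items[scale]`` items of each scale load, cycling blocks."""
    mapping: dict[str, int] = {}
    for scale, items in SCALE_DEFS.items():
        k = config.n_loading_items.get(scale, 0)
        for j, item in enumerate(items[:k]):
            mapping[item] = (j % config.n_modules) + 1
    return mapping


def generate_symptoms(
    config: SimConfig,
    truth: PlantedTruth,
    item_blocks: dict | None = None,
    loading: float | None = None,
    noise: float | None = None,
) -> SampleTable:
    """Ordinal symptom-scale items coupled to latent modules.

    Loading items are discretized linear combinations of the latent block
    factor plus Gaussian noise; non-loading items are pure noise. Patients
    get an additive severity shift so scale totals differ by group. The
    item->block map is recorded in ``truth.symptom_blocks`` as ground
    truth for symptom-omics edges.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    loading = config.symptom_loading if loading is None else loading
    noise = config.symptom_noise if noise is None else noise
    if item_blocks is None:
        item_blocks = default_item_blocks(config)
    bad = [b for b in item_blocks.values() if not 1 <= b <= config.n_modules]
    if bad:
        raise ConfigError(f"item block ids out of range: {bad}")
    truth.symptom_blocks = dict(item_blocks)

    Z = truth.latent_factors.to_numpy()
    n = Z.shape[0]
    case_mask = (config.groups == "case").to_numpy()

    scores = {}
    for scale, items in SCALE_DEFS.items():
        lo, hi = ITEM_RANGES[scale]
        cuts = _GSS_CUTS if scale == "GSS" else _ZUNG_CUTS
        for item in items:
            b = item_blocks.get(item, 0)
            eps = rng.standard_normal(n)
            if b > 0:
                raw = loading * Z[:, b - 1] + noise * eps
                sd = float(np.hypot(loading, noise))
            else:
                raw = eps
                sd = 1.0
            raw = raw / sd if sd > 0 else raw
            raw = raw + config.symptom_case_shift * case_mask
            scores[item] = lo + np.searchsorted(cuts, raw).clip(0, hi - lo)
    symptom_items = pd.DataFrame(scores, index=config.sample_ids, dtype=float)
    return SampleTable(
        group=config.groups,
        symptom_items=symptom_items,
        scale_defs=dict(SCALE_DEFS),
        subscale_defs={k: dict(v) for k, v in SUBSCALE_DEFS.items()},
    )


def write_simulation(out_dir, config: SimConfig, tables, samples: SampleTable,
                     truth: PlantedTruth) -> None:
    """Serialize a run: one abundance TSV per layer, metadata TSV, the
    planted edge list as TSV, and a JSON echo of the configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for table in tables:
        write_abundance(table, out / f"{table.layer}.tsv",
                        out / f"{table.layer}.annotations.tsv")
    write_metadata(samples, out / "samples.tsv")
    edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in truth.true_edges),
                         columns=["u", "v"])
    edges.to_csv(out / "true_edges.tsv", sep="\t", index=False)
    diffs = pd.DataFrame(sorted(truth.diff_features),
                         columns=["feature_id", "enriched_in"])
    diffs.to_csv(out / "diff_features.tsv", sep="\t", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)
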