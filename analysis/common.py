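"""Shared paths and loaders for the numbered analysis drivers."""

from pathlib import Path

from momnet.synthio import ITEM_RANGES, SCALE_DEFS, SUBSCALE_DEFS
from momnet.tables import LAYERS, read_abundance, read_metadata

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

SEED = 7

# Retention fractions for the feature filter. The study filtered tens of
# thousands of sequencing features to the top 5% (virome) / 15% (OTUs);
# at the generator's desk scale the same intent (drop the sparse tail,
# keep the abundant core) corresponds to milder fractions.
RETENTION = {"virome": 0.6, "bacteria": 0.6, "metabolite": 1.0}

# Simulation used by the drivers: powered preset with more and larger
# cross-layer blocks (richer within-layer networks) and 3-log2 group
# effects so differential features show up in pooled correlations.
SIM_OVERRIDES = {"n_modules": 8, "block_size": 15, "effect_log2fc": 3.0}


def load_tables():
    return [
        read_abundance(DATA_DIR / f"{layer}.tsv", layer,
                       DATA_DIR / f"{layer}.annotations.tsv")
        for layer in LAYERS
    ]


def load_samples():
    return read_metadata(
        DATA_DIR / "samples.tsv",
        scale_defs=SCALE_DEFS,
        item_ranges=ITEM_RANGES,
        subscale_defs=SUBSCALE_DEFS,
    )
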