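"""Generate the synthetic multiomics study used by all downstream steps.

Draws a two-group gut multiomics dataset (virome RPKM, bacterial OTU
counts, metabolite intensities) with planted correlation blocks spanning
layers, planted group-differential features, and symptom-scale items
coupled to latent modules; writes everything under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA_DIR, SEED, SIM_OVERRIDES

from momnet.synthio import (
    generate_multiomics,
    generate_symptoms,
    powered_preset,
    write_simulation,
)

config = powered_preset(seed=SEED, **SIM_OVERRIDES)
tables, samples, truth = generate_multiomics(config)
samples = generate_symptoms(config, truth)
write_simulation(DATA_DIR, config, tables, samples, truth)

print(f"samples: {config.n_case} patients vs {config.n_control} controls")
for table in tables:
    zero_pct = 100 * (table.values.to_numpy() == 0).mean()
    print(f"{table.layer:11s} {table.n_features:4d} features, "
          f"{zero_pct:.1f}% zeros")
print(f"planted: {len(truth.true_edges)} within-block edges, "
      f"{len(truth.diff_features)} differential features, "
      f"{len(truth.symptom_blocks)} loading symptom items")
print(f"wrote {DATA_DIR}")
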