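"""Two-class differential abundance per layer, and the cross-omics
heatmap of differential virome features against symptoms and bacteria.

Rank tests (Mann-Whitney U + BH) combined with the bootstrapped LDA
effect size; features pass at p < 0.05 & LDA score > 2. The retained
correlations use the heatmap thresholds |r| > 0.6, p < 0.05.
Writes results/differential/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS_DIR, SEED, load_samples, load_tables

from momnet.diffabund import differential_features, feature_symptom_heatmap
from momnet.netbuild import symptom_matrix

out_dir = RESULTS_DIR / "differential"
out_dir.mkdir(parents=True, exist_ok=True)

tables = load_tables()
samples = load_samples()

hits = {}
for table in tables:
    found = differential_features(table, samples.group, p_max=0.05,
                                  lda_min=2.0, seed=SEED)
    found.to_csv(out_dir / f"{table.layer}_differential.tsv", sep="\t")
    hits[table.layer] = found
    up = (found["direction"] == "case").sum()
    print(f"{table.layer:11s} {len(found):3d} differential features "
          f"({up} enriched in patients)")

virome = tables[0]
diff_vir = virome.subset_features(list(hits["virome"].index))
sym = symptom_matrix(samples)
heat = feature_symptom_heatmap(diff_vir, sym, r_min=0.6, p_max=0.05)
heat.to_csv(out_dir / "virome_symptom_heatmap.tsv", sep="\t", index=False)
bac = tables[1].subset_features(list(hits["bacteria"].index))
heat_vb = feature_symptom_heatmap(diff_vir, bac.values, r_min=0.6, p_max=0.05)
heat_vb.to_csv(out_dir / "virome_bacteria_heatmap.tsv", sep="\t", index=False)
print(f"retained cross-omics correlations at |r|>0.6, p<0.05: "
      f"{len(heat)} virus-symptom, {len(heat_vb)} virus-bacteria")
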