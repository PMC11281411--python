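"""Build the co-occurrence networks: per-layer (patient and control),
cross-kingdom, and symptom-augmented.

Features first pass the abundance-retention filter, then group-specific
Spearman matrices are thresholded at |r| > 0.8, p < 0.001, BH q <= 0.05.
Symptom edges use the heatmap preset (|r| > 0.6, p < 0.05). Writes
GraphML + edge TSVs under results/networks/.
"""

import itertools
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS_DIR, RETENTION, load_samples, load_tables

from momnet.netbuild import (
    annotations_from_tables,
    build_network,
    spearman_matrix,
    symptom_matrix,
)
from momnet.preprocess import top_fraction
from momnet.tables import write_network

out_dir = RESULTS_DIR / "networks"
out_dir.mkdir(parents=True, exist_ok=True)

tables = load_tables()
samples = load_samples()
annotations = annotations_from_tables(tables)
retained = [top_fraction(t, RETENTION[t.layer]) for t in tables]

for group in ("case", "control"):
    ids = samples.samples_in(group)
    layer_tables = [t.subset_samples(ids) for t in retained]

    for table in layer_tables:
        net = build_network(spearman_matrix(table), mode="single",
                            annotations=annotations)
        write_network(net, out_dir / f"{group}_{table.layer}.graphml",
                      "graphml")
        write_network(net, out_dir / f"{group}_{table.layer}.edges.tsv",
                      "edge_tsv")
        print(f"{group:8s} {table.layer:11s} "
              f"{net.number_of_nodes():4d} nodes "
              f"{net.number_of_edges():5d} edges")

    cross_corrs = [spearman_matrix(a, b)
                   for a, b in itertools.combinations(layer_tables, 2)]
    cross = build_network(cross_corrs, mode="cross", annotations=annotations)
    write_network(cross, out_dir / f"{group}_cross.graphml", "graphml")
    write_network(cross, out_dir / f"{group}_cross.edges.tsv", "edge_tsv")
    print(f"{group:8s} cross-kingdom "
          f"{cross.number_of_nodes():4d} nodes "
          f"{cross.number_of_edges():5d} edges")

    sym = symptom_matrix(samples)[ids]
    sym_corrs = cross_corrs + [spearman_matrix(sym, t.values)
                               for t in layer_tables]
    symnet = build_network(sym_corrs, r_min=0.6, p_max=0.05, q_max=0.05,
                           mode="symptom", annotations=annotations)
    write_network(symnet, out_dir / f"{group}_symptom.graphml", "graphml")
    write_network(symnet, out_dir / f"{group}_symptom.edges.tsv", "edge_tsv")
    n_sym = sum(1 for _, d in symnet.nodes(data=True)
                if d["layer"] == "symptom")
    print(f"{group:8s} symptom-augmented "
          f"{symnet.number_of_nodes():4d} nodes "
          f"({n_sym} symptom factors) {symnet.number_of_edges():5d} edges")
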