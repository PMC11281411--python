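import networkx as nx
import numpy as np
import pandas as pd
import pytest

from momnet.nettopo import (
    ModulePartition,
    centralities,
    compare_node_metrics,
    degree_powerlaw,
    detect_modules,
    module_overlap,
    module_summary,
    positive_edge_fraction,
    score_scales,
    symptom_clustering,
    symptom_edge_counts,
    zi_pi,
)
from momnet.synthio import SCALE_DEFS, SUBSCALE_DEFS
from momnet.tables import ConfigError, SampleTable
from oracles import make_net


def test_star_and_triangle_centralities():
    star = make_net([("vir:c", f"vir:l{i}") for i in range(3)])
    topo = centralities(star)
    assert topo.loc["vir:c", "degree"] == 3
    # center lies on all 3 leaf pairs; normalization divides by (n-1)(n-2)/2
    assert topo.loc["vir:c", "betweenness"] == pytest.approx(3 / 3)
    assert topo.loc["vir:l0", "betweenness"] == 0.0
    tri = make_net([("vir:a", "vir:b"), ("vir:b", "vir:c"), ("vir:c", "vir:a")])
    assert (centralities(tri)["clustering"] == 1.0).all()


def test_cycle_vertex_transitivity():
    cycle = make_net([(f"vir:n{i}", f"vir:n{(i + 1) % 6}") for i in range(6)])
    topo = centralities(cycle)
    for metric in topo.columns:
        assert topo[metric].nunique() == 1


def test_eigenvector_satisfies_fixed_point():
    net = make_net([("vir:a", "vir:b", 0.9), ("vir:b", "vir:c", 0.85),
                    ("vir:c", "vir:a", -0.95), ("vir:c", "vir:d", 0.82)])
    topo = centralities(net)
    x = topo["eigenvector"]
    nodes = list(net.nodes)
    A = nx.to_numpy_array(net, nodelist=nodes, weight="absr")
    v = x.loc[nodes].to_numpy()
    Av = A @ v
    lam = v @ Av
    np.testing.assert_allclose(Av, lam * v, atol=1e-6)


def test_two_disjoint_triangles_partition():
    """Louvain on two disjoint triangles: 2 modules and
    Q = 2 x (3/6 - (6/12)^2) = 0.5."""
    edges = [("vir:a", "vir:b"), ("vir:b", "vir:c"), ("vir:c", "vir:a"),
             ("vir:x", "vir:y"), ("vir:y", "vir:z"), ("vir:z", "vir:x")]
    part = detect_modules(make_net(edges), seed=0)
    assert part.n_modules == 2
    assert part.modularity == pytest.approx(0.5)
    again = detect_modules(make_net(edges), seed=0)
    assert part.membership == again.membership


def test_single_clique_and_quality_floor():
    clique = make_net([(f"vir:n{i}", f"vir:n{j}")
                       for i in range(4) for j in range(i + 1, 4)])
    part = detect_modules(clique, seed=1)
    assert part.n_modules == 1
    assert part.modularity == pytest.approx(0.0)
    with pytest.raises(ConfigError):
        detect_modules(nx.Graph(), seed=0)


def test_zi_pi_hand_values():
    # two triangles bridged through vir:b -- vir:y
    edges = [("vir:a", "vir:b"), ("vir:b", "vir:c"), ("vir:c", "vir:a"),
             ("vir:x", "vir:y"), ("vir:y", "vir:z"), ("vir:z", "vir:x"),
             ("vir:b", "vir:y")]
    net = make_net(edges)
    membership = {"vir:a": 1, "vir:b": 1, "vir:c": 1,
                  "vir:x": 2, "vir:y": 2, "vir:z": 2}
    part = ModulePartition(membership, modularity=0.4, seed=0, resolution=1.0)
    roles = zi_pi(net, part)
    # all links inside own module -> Pi = 0
    assert roles.loc["vir:a", "Pi"] == pytest.approx(0.0)
    # vir:b: k=3, 2 inside / 1 outside -> Pi = 1 - (4/9 + 1/9) = 4/9
    assert roles.loc["vir:b", "Pi"] == pytest.approx(1 - (2 / 3) ** 2 - (1 / 3) ** 2)
    # degree-2 node split across two modules -> Pi = 0.5
    path = make_net([("vir:p", "vir:q"), ("vir:q", "vir:r")])
    part2 = ModulePartition({"vir:p": 1, "vir:q": 1, "vir:r": 2},
                            modularity=0.0, seed=0, resolution=1.0)
    roles2 = zi_pi(path, part2)
    assert roles2.loc["vir:q", "Pi"] == pytest.approx(0.5)
    # within-module degree equal to the module mean -> Zi = 0
    assert roles2.loc["vir:q", "Zi"] == pytest.approx(0.0)
    sym = make_net([("vir:a", "vir:b"), ("vir:b", "vir:c"), ("vir:a", "vir:c")])
    part3 = ModulePartition({"vir:a": 1, "vir:b": 1, "vir:c": 1},
                            modularity=0.0, seed=0, resolution=1.0)
    assert (zi_pi(sym, part3)["Zi"] == 0.0).all()


def test_zi_mean_zero_within_modules_and_pi_range(bench_run):
    from momnet.netbuild import build_network, spearman_matrix

    _, tables, samples, _ = bench_run
    net = build_network(
        spearman_matrix(tables[0].subset_samples(samples.samples_in("case"))),
        mode="single")
    part = detect_modules(net, seed=0)
    roles = zi_pi(net, part)
    assert roles["Pi"].dropna().between(0, 1, inclusive="left").all()
    joined = roles.join(pd.Series(part.membership, name="mod"))
    for _, grp in joined.groupby("mod"):
        if len(grp) >= 2:
            assert abs(grp["Zi"].mean()) < 1e-9


def test_louvain_recovers_planted_blocks(bench_run):
    from sklearn.metrics import adjusted_rand_score

    from momnet.netbuild import build_network, spearman_matrix

    _, tables, samples, truth = bench_run
    case = samples.samples_in("case")
    for table in tables:
        net = build_network(spearman_matrix(table.subset_samples(case)),
                            mode="single")
        part = detect_modules(net, seed=0)
        nodes = [n for n in net.nodes if truth.block_membership.get(n, 0) > 0]
        ari = adjusted_rand_score([truth.block_membership[n] for n in nodes],
                                  [part.membership[n] for n in nodes])
        assert ari >= 0.9


def powerlaw_graph():
    # degree histogram exactly freq = 144 / k^2 for k in {1, 2, 3, 4, 6}
    seq = [6] * 4 + [4] * 9 + [3] * 16 + [2] * 36 + [1] * 144
    return nx.havel_hakimi_graph(seq)


def test_degree_powerlaw_exact_fit_and_degenerate():
    slope, r2 = degree_powerlaw(powerlaw_graph())
    assert slope == pytest.approx(-2.0, abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ConfigError):
        degree_powerlaw(nx.cycle_graph(10))  # a single distinct degree


def test_powerlaw_noise_lowers_r2():
    g = powerlaw_graph()
    # perturb the histogram off the power line: add a clique of degree-4 nodes
    g = nx.disjoint_union(g, nx.complete_graph(5))
    _, r2 = degree_powerlaw(g)
    assert r2 < 1.0 - 1e-6


def test_positive_edge_fraction():
    net = make_net([("vir:a", "vir:b", 0.9), ("vir:c", "vir:d", -0.9),
                    ("vir:e", "vir:f", 0.85), ("vir:g", "vir:h", 0.95)])
    assert positive_edge_fraction(net) == pytest.approx(0.75)
    with pytest.raises(ConfigError):
        positive_edge_fraction(nx.Graph())


def test_module_overlap_matches_set_algebra():
    pa = ModulePartition({f"n{i}": 1 if i < 6 else 2 for i in range(10)},
                         modularity=0.3, seed=0, resolution=1.0)
    pb = ModulePartition({f"n{i}": 1 if i < 3 else (2 if i < 6 else 3)
                          for i in range(10)},
                         modularity=0.3, seed=0, resolution=1.0)
    table = module_overlap(pa, pb, top_k=3)
    for row in table.itertuples():
        set_a = set(pa.members(row.module_a))
        set_b = set(pb.members(row.module_b))
        assert row.shared == len(set_a & set_b)
        assert row.pct_of_union == pytest.approx(
            100 * len(set_a & set_b) / len(set_a | set_b))
    same = module_overlap(pa, pa, top_k=2)
    diag = same[same.module_a == same.module_b]
    assert (diag.shared.to_numpy() == diag.size_a.to_numpy()).all()
    pc = ModulePartition({f"m{i}": 1 for i in range(4)}, modularity=0.0,
                         seed=0, resolution=1.0)
    assert (module_overlap(pa, pc).shared == 0).all()


def test_compare_node_metrics_properties():
    rng = np.random.default_rng(0)
    base = pd.DataFrame(
        rng.random((50, 5)),
        columns=["degree", "betweenness", "closeness", "eigenvector",
                 "clustering"],
        index=[f"vir:n{i}" for i in range(50)],
    )
    equal = compare_node_metrics(base, base.copy())
    np.testing.assert_allclose(equal["p"].to_numpy(), 1.0, atol=1e-9)
    shifted = base + 100.0
    res = compare_node_metrics(shifted, base)
    assert (res["p"] < 0.001).all()
    swapped = compare_node_metrics(base, shifted)
    np.testing.assert_allclose(res["p"], swapped["p"])
    with pytest.raises(ConfigError):
        compare_node_metrics(base, shifted, subset={"unknown:node"})


def test_module_summary_composition_and_shares():
    edges = [(f"vir:a{i}", f"vir:a{(i + 1) % 259}") for i in range(259)]
    edges += [(f"vir:b{i}", f"vir:b{(i + 1) % 41}") for i in range(41)]
    net = make_net(edges)
    for i in range(259):
        net.nodes[f"vir:a{i}"]["taxonomy"] = (
            "Siphoviridae" if i < 84 else "other")
    membership = {n: (1 if n.startswith("vir:a") else 2) for n in net.nodes}
    part = ModulePartition(membership, modularity=0.4, seed=0, resolution=1.0)
    summary = module_summary(net, part, annotation_key="taxonomy")
    assert summary["per_module"]["node_share_pct"].sum() == pytest.approx(100.0)
    comp = summary["composition"][1]
    assert comp["Siphoviridae"] == pytest.approx(100 * 84 / 259)
    single = ModulePartition({n: 1 for n in net.nodes}, modularity=0.0,
                             seed=0, resolution=1.0)
    assert module_summary(net, single)["per_module"]["node_share_pct"].iloc[0] \
        == pytest.approx(100.0)


def test_symptom_clustering_shares():
    edges = [(f"sym:s{i}", f"vir:v{i}") for i in range(48)]
    net = make_net(edges)
    membership = {}
    for i in range(48):
        module = 1 if i < 21 else 2 + (i % 5)
        membership[f"sym:s{i}"] = module
        membership[f"vir:v{i}"] = module
    part = ModulePartition(membership, modularity=0.4, seed=0, resolution=1.0)
    dist = symptom_clustering(net, part)
    assert dist["symptom_pct"].sum() == pytest.approx(100.0)
    assert dist.loc[1, "symptom_pct"] == pytest.approx(100 * 21 / 48)
    one = ModulePartition({n: 1 for n in net.nodes}, modularity=0.0,
                          seed=0, resolution=1.0)
    assert symptom_clustering(net, one)["symptom_pct"].iloc[0] == \
        pytest.approx(100.0)
    no_sym = make_net([("vir:a", "vir:b")])
    with pytest.raises(ConfigError):
        symptom_clustering(no_sym, one)


def test_symptom_edge_counts_by_layer():
    edges = ([(f"sym:s{i}", f"vir:v{i}") for i in range(5)]
             + [(f"sym:s{i}", f"bac:b{i}") for i in range(3)]
             + [("vir:v0", "bac:b0")])
    counts = symptom_edge_counts(make_net(edges))
    assert counts["virome"] == 5 and counts["bacteria"] == 3
    assert counts["total"] == 8


def test_score_scales_zung_convention():
    items = {}
    for scale, defs in SCALE_DEFS.items():
        for item in defs:
            items[item] = [1.0 if scale != "GSS" else 0.0, 2.0]
    frame = pd.DataFrame(items, index=["s1", "s2"])
    samples = SampleTable(
        group=pd.Series(["case", "control"], index=["s1", "s2"]),
        symptom_items=frame,
        scale_defs=dict(SCALE_DEFS),
        subscale_defs={k: dict(v) for k, v in SUBSCALE_DEFS.items()},
    )
    scores = score_scales(samples)
    assert scores.loc["s1", "GSS_total"] == 0.0
    assert scores.loc["s1", "SDS_raw"] == 20
    assert scores.loc["s1", "SDS_index"] == 25  # round(20 x 1.25)
    assert scores.loc["s2", "SAS_index"] == 50  # round(40 x 1.25)
    assert (scores["SDS_physiological"] + scores["SDS_psychological"]
            <= scores["SDS_raw"]).all()
    broken = frame.drop(columns=[SCALE_DEFS["SDS"][0]])
    bad = SampleTable(group=samples.group, symptom_items=broken,
                      scale_defs=dict(SCALE_DEFS))
    with pytest.raises(ConfigError):
        score_scales(bad)
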