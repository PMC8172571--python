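"""Triplet assembly, correlation edges, hub selection, export round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circnet.expression import DeRecord
from circnet.network import (
    CernaTriplet,
    assemble_triplets,
    build_network,
    export_network,
    import_network,
    network_summary,
    pearson_correlation,
    pearson_edges,
    select_hubs,
)


def _pairs(circ_mir, mir_mrna):
    return (
        pd.DataFrame(circ_mir, columns=["circ_id", "mir_id", "site_count"]),
        pd.DataFrame(mir_mrna, columns=["mir_id", "mrna_id", "site_count"]),
    )


# --- assembly ---------------------------------------------------------------

def test_shared_mirna_gives_cartesian_product():
    cm, mg = _pairs(
        [("c1", "m1", 1), ("c2", "m1", 1)],
        [("m1", "g1", 1), ("m1", "g2", 1), ("m1", "g3", 1)],
    )
    trips = assemble_triplets(cm, mg)
    assert len(trips) == 6
    assert trips == sorted(trips, key=lambda t: t.key)


def test_no_shared_mirna_gives_no_triplets():
    cm, mg = _pairs([("c1", "m1", 1)], [("m2", "g1", 1)])
    assert assemble_triplets(cm, mg) == []


def test_assembly_matches_nested_loop_oracle(rng):
    for _ in range(100):
        cm = [(f"c{rng.integers(6)}", f"m{rng.integers(4)}", 1) for _ in range(rng.integers(1, 12))]
        mg = [(f"m{rng.integers(4)}", f"g{rng.integers(6)}", 1) for _ in range(rng.integers(1, 12))]
        cm, mg = list(set(cm)), list(set(mg))
        trips = assemble_triplets(*_pairs(cm, mg))
        expected = sorted(
            {(c, m, g) for c, m, _ in cm for m2, g, _ in mg if m == m2}
        )
        assert [t.key for t in trips] == expected
        # count identity: sum over miRNAs of |circ partners| * |mRNA partners|
        per_mir = {}
        for c, m, _ in cm:
            per_mir.setdefault(m, [set(), set()])[0].add(c)
        for m, g, _ in mg:
            per_mir.setdefault(m, [set(), set()])[1].add(g)
        assert len(trips) == sum(len(a) * len(b) for a, b in per_mir.values())


# --- correlations -----------------------------------------------------------

def test_perfect_anticorrelation():
    x = np.arange(8, dtype=float)
    r, p = pearson_correlation(x, -x)
    assert r == -1.0 and p < 1e-6


def test_orthogonal_vectors_give_zero_r():
    x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
    r, _ = pearson_correlation(x, y)
    assert r == pytest.approx(0.0, abs=1e-12)


def test_pearson_matches_formula_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(4, 30))
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, p = pearson_correlation(x, y)
        r_exp = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
        t = r_exp * np.sqrt((n - 2) / (1 - r_exp**2))
        p_exp = 2 * stats.t.sf(abs(t), n - 2)
        assert r == pytest.approx(r_exp, abs=1e-9)
        assert p == pytest.approx(p_exp, abs=1e-9)


def test_constant_vector_is_flagged_degenerate(sim_dataset):
    mats = {k: m.with_values(m.counts.copy()) for k, m in sim_dataset["matrices"].items()}
    trip = CernaTriplet("circ_0001", "mir_0001", "mrna_0001")
    mats["miRNA"].counts.loc["mir_0001"] = 7  # constant across samples
    out = pearson_edges([trip], mats, "day7")
    assert out[0].degenerate
    hubs, nodes = select_hubs(out)
    assert hubs == [] and nodes == []


def test_too_few_samples_rejected(sim_dataset):
    mats = sim_dataset["matrices"]
    clipped = {
        k: m.with_values(m.counts.iloc[:, :2]) for k, m in mats.items()
    }
    for m in clipped.values():
        m.samples = m.samples.iloc[:2]
    with pytest.raises(ValueError, match="3 samples"):
        pearson_edges([CernaTriplet("circ_0001", "mir_0001", "mrna_0001")], clipped, "day7")


# --- hub selection -----------------------------------------------------------

def _trip(r1=-0.8, p1=0.01, r2=-0.8, p2=0.01, key=("c", "m", "g")):
    return CernaTriplet(*key, r1, p1, r2, p2)


def test_boundary_r_exactly_minus_half_excluded():
    hubs, _ = select_hubs([_trip(r1=-0.5)])
    assert hubs == []
    hubs, _ = select_hubs([_trip(r1=-0.5000001)])
    assert len(hubs) == 1


def test_boundary_p_exactly_alpha_included():
    hubs, _ = select_hubs([_trip(p1=0.05, p2=0.05)])
    assert len(hubs) == 1
    hubs, _ = select_hubs([_trip(p1=0.0500001)])
    assert hubs == []


def test_hub_selection_matches_filter_comprehension_oracle(rng):
    for _ in range(100):
        trips = [
            _trip(
                r1=float(rng.uniform(-1, 0)), p1=float(rng.uniform(0, 0.2)),
                r2=float(rng.uniform(-1, 0)), p2=float(rng.uniform(0, 0.2)),
                key=(f"c{i}", f"m{i}", f"g{i}"),
            )
            for i in range(20)
        ]
        hubs, nodes = select_hubs(trips)
        expected = [
            t for t in trips
            if t.r_circ_mir < -0.5 and t.r_mir_mrna < -0.5
            and t.p_circ_mir <= 0.05 and t.p_mir_mrna <= 0.05
        ]
        assert hubs == expected
        assert nodes == sorted({n for t in expected for n in t.key})


def test_hub_selection_is_monotone_in_thresholds(rng):
    trips = [
        _trip(r1=float(rng.uniform(-1, 0)), p1=float(rng.uniform(0, 0.1)),
              r2=float(rng.uniform(-1, 0)), p2=float(rng.uniform(0, 0.1)),
              key=(f"c{i}", f"m{i}", f"g{i}"))
        for i in range(50)
    ]
    strict, _ = select_hubs(trips, r_max=-0.6, p_max=0.03)
    relaxed, _ = select_hubs(trips, r_max=-0.5, p_max=0.05)
    assert set(t.key for t in strict) <= set(t.key for t in relaxed)


def test_day7_hub_fixture_yields_twelve_nodes():
    """4 circRNA decoys, 3 miRNA cores, 5 mRNA targets across 8 surviving trios."""
    keys = [
        ("c1", "m1", "g1"), ("c2", "m1", "g1"), ("c2", "m1", "g2"),
        ("c1", "m2", "g2"), ("c3", "m2", "g3"), ("c4", "m2", "g3"),
        ("c4", "m3", "g4"), ("c4", "m3", "g5"),
    ]
    hubs, nodes = select_hubs([_trip(key=k) for k in keys])
    assert len(hubs) == 8 and len(nodes) == 12


def test_day28_hub_fixture_yields_nine_nodes():
    keys = [("c1", "m1", "g1"), ("c2", "m2", "g2"), ("c3", "m3", "g3")]
    _, nodes = select_hubs([_trip(key=k) for k in keys])
    assert len(nodes) == 9


# --- graph construction and export ------------------------------------------

def _de(fid, direction):
    return DeRecord(fid, 1.0, 0.01, 0.02, direction)


def _fixture_network(n_circ_down, n_circ_up, n_mir=3, n_mrna=4):
    trips, de_c = [], []
    circ_ids = [f"c{i}" for i in range(n_circ_down + n_circ_up)]
    for i, c in enumerate(circ_ids):
        trips.append(_trip(key=(c, f"m{i % n_mir}", f"g{i % n_mrna}")))
        de_c.append(_de(c, "down" if i < n_circ_down else "up"))
    de = {
        "circRNA": de_c,
        "miRNA": [_de(f"m{i}", "down") for i in range(n_mir)],
        "mRNA": [_de(f"g{i}", "up") for i in range(n_mrna)],
    }
    return build_network(trips, "day7", de)


@pytest.mark.parametrize("down,up,total", [(50, 47, 97), (49, 32, 81)])
def test_network_summary_reproduces_decoy_splits(down, up, total):
    g = _fixture_network(down, up)
    s = network_summary(g)
    assert s["circRNA"] == {"n_down": down, "n_up": up, "n_total": total}


def test_empty_network_summary_is_all_zeros():
    import networkx as nx

    s = network_summary(nx.Graph())
    assert s["edges"] == 0
    assert all(s[sp]["n_total"] == 0 for sp in ("circRNA", "miRNA", "mRNA"))


def test_network_is_bipartite_by_species(sim_dataset):
    from circnet import run_pipeline

    res = run_pipeline(sim_dataset["config"])
    g = build_network(res.triplets["day7"], "day7")
    species = {n: d["species"] for n, d in g.nodes(data=True)}
    for u, v in g.edges:
        assert {species[u], species[v]} in ({"circRNA", "miRNA"}, {"miRNA", "mRNA"})


def test_toy_triplet_exports_three_nodes_two_edges(tmp_path):
    g = build_network([_trip()], "day7")
    path = str(tmp_path / "toy.graphml")
    export_network(g, path)
    g2 = import_network(path)
    assert g2.number_of_nodes() == 3 and g2.number_of_edges() == 2


def test_graphml_round_trip_preserves_attributes(tmp_path):
    g = _fixture_network(3, 2)
    path = str(tmp_path / "net.graphml")
    export_network(g, path)
    g2 = import_network(path)
    assert set(g) == set(g2)
    assert {frozenset(e) for e in g.edges} == {frozenset(e) for e in g2.edges}
    for n in g:
        assert g.nodes[n]["species"] == g2.nodes[n]["species"]
        assert g.nodes[n]["direction"] == g2.nodes[n]["direction"]
    for u, v, d in g.edges(data=True):
        d2 = g2.edges[u, v]
        assert d2["kind"] == d["kind"]
        assert d2["r"] == pytest.approx(d["r"])
        assert d2["p"] == pytest.approx(d["p"])


def test_sif_export_lists_every_edge(tmp_path):
    g = _fixture_network(2, 2)
    path = str(tmp_path / "net.sif")
    export_network(g, path, "sif")
    lines = [l.split("\t") for l in open(path).read().splitlines()]
    assert len(lines) == g.number_of_edges()
    assert all(len(l) == 3 for l in lines)


def test_unknown_export_format_rejected(tmp_path):
    with pytest.raises(ValueError):
        export_network(_fixture_network(1, 1), str(tmp_path / "x"), "xgmml")
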