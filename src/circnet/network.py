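"""ceRNA triplet assembly, correlation edges, hub selection and export.

A ceRNA triplet is (circRNA decoy, miRNA core, mRNA target): the circRNA
and the mRNA carry binding sites for the same miRNA, so the circRNA can
sequester the miRNA and derepress the mRNA. Triplets are the cross product
of the DE-filtered circ-miR and miR-mRNA pair tables joined on the miRNA.

Each triplet's two edges get a Pearson correlation computed across the
samples of one timepoint on log2(normalized + 1) values, with the two-sided
p-value from the exact t transform (n - 2 df). Hub triplets are those whose
two correlations are both below a threshold (default -0.5, strict) with
p-values at most 0.05 (inclusive); hub nodes are the distinct members of
surviving triplets.

Networks are bipartite-by-construction (circ-miR and miR-mRNA edges only)
and export to Cytoscape-loadable GraphML (round-trippable) or SIF.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import DeRecord, ExpressionMatrix

__all__ = [
    "CernaTriplet",
    "assemble_triplets",
    "pearson_edges",
    "select_hubs",
    "build_network",
    "network_summary",
    "export_network",
    "import_network",
]


@dataclass
class CernaTriplet:
    """One decoy/core/target trio with its two signed correlation edges."""

    circ_id: str
    mir_id: str
    mrna_id: str
    r_circ_mir: float = float("nan")
    p_circ_mir: float = float("nan")
    r_mir_mrna: float = float("nan")
    p_mir_mrna: float = float("nan")
    degenerate: bool = False  # a constant expression vector; r undefined

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.circ_id, self.mir_id, self.mrna_id)


def assemble_triplets(
    circ_mir_pairs: pd.DataFrame, mir_mrna_pairs: pd.DataFrame
) -> list[CernaTriplet]:
    """Cross product of the two pair tables joined on the shared miRNA.

    The count satisfies sum over miRNAs of |circ partners| * |mRNA
    partners|; output is sorted lexicographically by (circ, miR, mRNA).
    """
    by_mir: dict[str, list[str]] = {}
    for row in mir_mrna_pairs.itertuples(index=False):
        by_mir.setdefault(row.mir_id, []).append(row.mrna_id)
    triplets = [
        CernaTriplet(row.circ_id, row.mir_id, mrna)
        for row in circ_mir_pairs.itertuples(index=False)
        for mrna in by_mir.get(row.mir_id, [])
    ]
    triplets.sort(key=lambda t: t.key)
    return triplets


def _log_values(matrix: ExpressionMatrix, samples: list[str]) -> pd.DataFrame:
    return np.log2(matrix.counts[samples] + 1.0)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from the exact t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    r = float(np.clip(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy), -1, 1))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * stats.t.sf(abs(t), n - 2))


def pearson_edges(
    triplets: list[CernaTriplet],
    matrices: dict[str, ExpressionMatrix],
    timepoint: str,
    cohort: str = "pooled",
) -> list[CernaTriplet]:
    """Attach circ-miR and miR-mRNA correlations across one timepoint.

    ``cohort`` selects the samples: ``pooled`` (Sham + ICH, default) or
    ``ich`` (ICH only). Constant expression vectors make r undefined; such
    triplets are flagged degenerate and never become hub candidates.
    """
    group = None if cohort == "pooled" else "ICH"
    if cohort not in ("pooled", "ich"):
        raise ValueError(f"unknown cohort {cohort!r}")
    samples = matrices["circRNA"].timepoint_samples(timepoint, group)
    if len(samples) < 3:
        raise ValueError(f"fewer than 3 samples at {timepoint}")
    logs = {sp: _log_values(m, samples) for sp, m in matrices.items()}

    out = []
    for t in triplets:
        circ = logs["circRNA"].loc[t.circ_id].to_numpy()
        mir = logs["miRNA"].loc[t.mir_id].to_numpy()
        mrna = logs["mRNA"].loc[t.mrna_id].to_numpy()
        r1, p1 = pearson_correlation(circ, mir)
        r2, p2 = pearson_correlation(mir, mrna)
        out.append(
            CernaTriplet(
                t.circ_id, t.mir_id, t.mrna_id, r1, p1, r2, p2,
                degenerate=bool(np.isnan(r1) or np.isnan(r2)),
            )
        )
    return out


def select_hubs(
    triplets: list[CernaTriplet], r_max: float = -0.5, p_max: float = 0.05
) -> tuple[list[CernaTriplet], list[str]]:
    """Hub triplets: both r strictly below r_max, both p at most p_max.

    Returns (surviving triplets, sorted distinct hub node ids).
    """
    hubs = [
        t
        for t in triplets
        if not t.degenerate
        and t.r_circ_mir < r_max
        and t.r_mir_mrna < r_max
        and t.p_circ_mir <= p_max
        and t.p_mir_mrna <= p_max
    ]
    nodes = sorted({n for t in hubs for n in t.key})
    return hubs, nodes


def build_network(
    triplets: list[CernaTriplet],
    timepoint: str,
    de_records: dict[str, list[DeRecord]] | None = None,
) -> nx.Graph:
    """Assemble an undirected bipartite-style graph from triplets.

    Nodes carry species, DE direction and adjusted p (when DE tables are
    given); edges carry the pair kind and correlation attributes. circ-mRNA
    edges never occur.
    """
    meta: dict[str, tuple[str, float]] = {}
    if de_records:
        for sp, records in de_records.items():
            for r in records:
                meta[r.feature_id] = (r.direction, r.p_adj)
    g = nx.Graph(timepoint=timepoint)
    for t in triplets:
        for node, species in (
            (t.circ_id, "circRNA"),
            (t.mir_id, "miRNA"),
            (t.mrna_id, "mRNA"),
        ):
            direction, p_adj = meta.get(node, ("ns", float("nan")))
            g.add_node(node, species=species, direction=direction, p_adj=p_adj)
        g.add_edge(
            t.circ_id, t.mir_id, kind="circ-mir",
            r=t.r_circ_mir, p=t.p_circ_mir,
        )
        g.add_edge(
            t.mir_id, t.mrna_id, kind="mir-mrna",
            r=t.r_mir_mrna, p=t.p_mir_mrna,
        )
    return g


def network_summary(network: nx.Graph) -> dict:
    """Node counts per species split by direction, plus the edge count."""
    summary: dict = {"edges": network.number_of_edges()}
    for species in ("circRNA", "miRNA", "mRNA"):
        nodes = [n for n, d in network.nodes(data=True) if d.get("species") == species]
        down = sum(1 for n in nodes if network.nodes[n]["direction"] == "down")
        up = sum(1 for n in nodes if network.nodes[n]["direction"] == "up")
        summary[species] = {"n_down": down, "n_up": up, "n_total": len(nodes)}
    return summary


def export_network(network: nx.Graph, path: str, fmt: str = "graphml") -> None:
    """Write GraphML (attribute-preserving) or SIF (topology only)."""
    if fmt == "graphml":
        g = network.copy()
        # GraphML has no NaN literal portable across readers; drop undefined
        for _, d in g.nodes(data=True):
            if "p_adj" in d and isinstance(d["p_adj"], float) and np.isnan(d["p_adj"]):
                del d["p_adj"]
        for _, _, d in g.edges(data=True):
            for k in ("r", "p"):
                if k in d and isinstance(d[k], float) and np.isnan(d[k]):
                    del d[k]
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(network.edges(data=True)):
                fh.write(f"{u}\t{d.get('kind', 'pair')}\t{v}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(path: str) -> nx.Graph:
    """Read a GraphML file written by :func:`export_network`."""
    return nx.read_graphml(path)
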