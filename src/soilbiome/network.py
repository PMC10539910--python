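"""Co-occurrence networks, modules, Zi-Pi node roles and summary properties.

Edges connect OTU pairs whose Spearman (default) correlation of relative
abundances clears a fixed threshold (|rho| > 0.6 and p < 0.001, the study's
statement of record; no multiple-testing correction unless asked).  Modules
come from greedy (CNM) modularity maximisation on the unweighted, unsigned
graph.  Node roles follow the within-module degree z-score Zi and the
participation coefficient Pi with thresholds Zi = 2.5 and Pi = 0.62:
peripheral, module hub (high Zi), connector (high Pi) or network hub (both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import OtuTable, ValidationError

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def prevalence_filter(table: OtuTable, min_prevalence: float) -> OtuTable:
    """Keep OTUs present (count > 0) in at least ``min_prevalence`` of samples."""
    if not 0 <= min_prevalence <= 1:
        raise ValidationError("min_prevalence must lie in [0, 1]")
    prev = (table.counts > 0).mean(axis=0)
    keep = [o for o, p in zip(table.otu_ids, prev) if p >= min_prevalence]
    if not keep:
        raise ValidationError("prevalence filter removed every OTU")
    return table.select_otus(keep)


@dataclass
class CoNetwork:
    graph: nx.Graph  # nodes = OTU ids; edge attrs: rho, sign, p
    modules: dict[str, int] = field(default_factory=dict)
    modularity: float = 0.0

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node1": a, "node2": b, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "rho", "p", "sign"])


def correlation_network(
    table: OtuTable,
    method: str = "spearman",
    rho_min: float = 0.6,
    p_max: float = 0.001,
    fdr: bool = False,
) -> CoNetwork:
    """Threshold pairwise abundance correlations into an undirected network.

    An edge exists iff |rho| > rho_min and p < p_max (t-approximation for the
    Spearman p-value); the correlation sign is stored.  With ``fdr`` the
    Benjamini-Hochberg-adjusted p is thresholded instead.
    """
    if table.n_samples < 5:
        raise ValidationError("correlation network needs >= 5 samples")
    rel = table.relative_abundances()
    otus = list(table.otu_ids)
    keep = []
    for j, o in enumerate(otus):
        if np.ptp(rel[:, j]) == 0:
            logger.warning("skipping constant OTU %r", o)
        else:
            keep.append(j)
    rel = rel[:, keep]
    otus = [otus[j] for j in keep]
    m = len(otus)
    g = nx.Graph()
    g.add_nodes_from(otus)
    if m >= 2:
        if method == "spearman":
            rho, p = stats.spearmanr(rel)
            rho, p = np.atleast_2d(rho), np.atleast_2d(p)
        elif method == "pearson":
            rho = np.corrcoef(rel, rowvar=False)
            n = rel.shape[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-300, None))
            p = 2 * stats.t.sf(np.abs(t), n - 2)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        iu = np.triu_indices(m, 1)
        pvals = p[iu]
        if fdr:
            pvals = multipletests(pvals, method="fdr_bh")[1]
        for (i, j), pv in zip(zip(*iu), pvals):
            r = rho[i, j]
            if abs(r) > rho_min and pv < p_max:
                g.add_edge(
                    otus[i], otus[j], rho=float(r), p=float(pv),
                    sign="+" if r > 0 else "-",
                )
    return CoNetwork(g)


def detect_modules(net: CoNetwork, seed: int = 0) -> CoNetwork:
    """Greedy (CNM) modularity maximisation; isolated nodes become singletons.

    Tie-breaking is deterministic (node-id order); ``seed`` is accepted for
    interface symmetry and recorded nowhere else.
    """
    g = net.graph
    nodes = sorted(g.nodes)
    modules: dict[str, int] = {}
    if g.number_of_edges() == 0:
        modules = {n: i for i, n in enumerate(nodes)}
        net.modules, net.modularity = modules, 0.0
        return net
    # CNM on the subgraph with edges; isolated nodes appended as singletons
    core = g.subgraph([n for n in nodes if g.degree(n) > 0])
    communities = nx.community.greedy_modularity_communities(core)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    for i, comm in enumerate(communities):
        for n in comm:
            modules[n] = i
    next_id = len(communities)
    for n in nodes:
        if n not in modules:
            modules[n] = next_id
            next_id += 1
    q = nx.community.modularity(
        core, [set(c) for c in communities]
    ) if core.number_of_nodes() else 0.0
    net.modules, net.modularity = modules, float(q)
    return net


def zi_pi(net: CoNetwork) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-module degree against its module; Pi =
    1 - sum_m (k_im / k_i)^2 over modules m.  Isolated nodes get Zi = Pi = 0.
    """
    if not net.modules:
        raise ValidationError("modules not assigned; run detect_modules first")
    g = net.graph
    nodes = sorted(g.nodes)
    mod = net.modules
    # within-module degree for every node
    k_in = {
        n: sum(1 for nb in g.neighbors(n) if mod[nb] == mod[n]) for n in nodes
    }
    by_module: dict[int, list[str]] = {}
    for n in nodes:
        by_module.setdefault(mod[n], []).append(n)
    rows = {}
    for n in nodes:
        members = by_module[mod[n]]
        vals = np.array([k_in[m] for m in members], dtype=float)
        sd = vals.std(ddof=0)
        zi = (k_in[n] - vals.mean()) / sd if sd > 0 else 0.0
        k = g.degree(n)
        if k == 0:
            pi = 0.0
        else:
            counts: dict[int, int] = {}
            for nb in g.neighbors(n):
                counts[mod[nb]] = counts.get(mod[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in counts.values())
        if zi > ZI_THRESHOLD:
            role = "network_hub" if pi > PI_THRESHOLD else "module_hub"
        else:
            role = "connector" if pi > PI_THRESHOLD else "peripheral"
        rows[n] = {"module": mod[n], "degree": k, "Zi": zi, "Pi": pi, "role": role}
    return pd.DataFrame.from_dict(rows, orient="index")


def network_properties(net: CoNetwork) -> dict:
    """Summary record: nodes, links, degrees, path length, modules, roles."""
    g = net.graph
    n_nodes = g.number_of_nodes()
    n_links = g.number_of_edges()
    signs = [d.get("sign", "+") for _, _, d in g.edges(data=True)]
    pos = signs.count("+")
    # average shortest-path distance over connected (reachable) pairs only
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1
    avg_path = total / pairs if pairs else float("nan")  # each pair counted twice either way
    roles = zi_pi(net)["role"].value_counts() if net.modules else pd.Series(dtype=int)
    role_counts = {
        r: int(roles.get(r, 0))
        for r in ["peripheral", "module_hub", "connector", "network_hub"]
    }
    role_pct = {
        f"{r}_pct": 100.0 * c / n_nodes if n_nodes else float("nan")
        for r, c in role_counts.items()
    }
    return {
        "nodes": n_nodes,
        "links": n_links,
        "average_degree": 2 * n_links / n_nodes if n_nodes else float("nan"),
        "average_path_distance": avg_path,
        "modules": len(set(net.modules.values())) if net.modules else None,
        "modularity": net.modularity,
        "positive_pct": 100.0 * pos / n_links if n_links else float("nan"),
        "negative_pct": 100.0 * (n_links - pos) / n_links if n_links else float("nan"),
        **role_counts,
        **role_pct,
    }


def build_network(
    table: OtuTable,
    min_prevalence: float = 1 / 3,
    method: str = "spearman",
    rho_min: float = 0.6,
    p_max: float = 0.001,
    seed: int = 0,
) -> tuple[CoNetwork, pd.DataFrame, dict]:
    """Prevalence filter -> correlation network -> modules -> roles -> summary."""
    filtered = prevalence_filter(table, min_prevalence)
    net = correlation_network(filtered, method=method, rho_min=rho_min, p_max=p_max)
    net = detect_modules(net, seed=seed)
    roles = zi_pi(net)
    if table.taxonomy:
        roles["phylum"] = [table.taxonomy.get(o, "unknown") for o in roles.index]
    return net, roles, network_properties(net)
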