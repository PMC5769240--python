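"""The filtered bipartite eSNP-eGene network.

Edges are thresholded eQTL associations (cis p < 1e-3, trans p < 1e-6 by
default) between SNP nodes (rsIDs) and gene nodes (gene symbols; probes
are collapsed to their symbol). eSNPs absent from the GWAS summary are
dropped, and isolated SNP-gene pairs — edges whose two endpoints both
have degree 1 — are excluded because they create no additional
connections in the network.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class BipartiteNetwork:
    snp_nodes: set
    gene_nodes: set
    edges: set  # (rsid, gene_symbol)
    provenance: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> tuple[Counter, Counter]:
        snp_deg: Counter = Counter()
        gene_deg: Counter = Counter()
        for s, g in self.edges:
            snp_deg[s] += 1
            gene_deg[g] += 1
        return snp_deg, gene_deg

    def to_edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["rsid", "gene_symbol"])

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(sorted(self.snp_nodes), bipartite="snp")
        G.add_nodes_from(sorted(self.gene_nodes), bipartite="gene")
        G.add_edges_from(sorted(self.edges))
        return G


def build_network(
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    cis_p: float = 1e-3,
    trans_p: float = 1e-6,
    isolated_rule: str = "pair",
) -> BipartiteNetwork:
    """Threshold, restrict to GWAS SNPs, collapse probes, drop isolated pairs.

    ``isolated_rule="pair"`` removes edges whose SNP and gene both have
    degree 1 (the default reading of the single-edge exclusion);
    ``"leaf"`` removes edges with any degree-1 endpoint, iterated to a
    fixed point. An empty result carries reason codes in provenance
    rather than raising.
    """
    if isolated_rule not in ("pair", "leaf"):
        raise ValueError("isolated_rule must be 'pair' or 'leaf'")
    prov: dict = {"cis_p": cis_p, "trans_p": trans_p, "isolated_rule": isolated_rule, "reasons": []}
    keep = ((eqtl["mode"] == "cis") & (eqtl["p"] < cis_p)) | (
        (eqtl["mode"] == "trans") & (eqtl["p"] < trans_p)
    )
    sub = eqtl[keep]
    prov["n_eqtl_records_passing"] = int(len(sub))
    if sub.empty:
        prov["reasons"].append("no eQTL records pass the thresholds")
        return BipartiteNetwork(set(), set(), set(), prov)
    in_gwas = sub["rsid"].isin(set(gwas["rsid"]))
    prov["n_records_dropped_not_in_gwas"] = int((~in_gwas).sum())
    sub = sub[in_gwas]
    if sub.empty:
        prov["reasons"].append("no passing eSNP is present in the GWAS summary")
        return BipartiteNetwork(set(), set(), set(), prov)

    probe_support = Counter(zip(sub["rsid"], sub["gene_symbol"]))
    edges = set(probe_support)
    prov["n_edges_before_isolated_removal"] = len(edges)
    prov["n_multi_probe_edges"] = int(sum(1 for v in probe_support.values() if v > 1))

    removed = 0
    while True:
        snp_deg = Counter(s for s, _ in edges)
        gene_deg = Counter(g for _, g in edges)
        if isolated_rule == "pair":
            drop = {(s, g) for s, g in edges if snp_deg[s] == 1 and gene_deg[g] == 1}
        else:
            drop = {(s, g) for s, g in edges if snp_deg[s] == 1 or gene_deg[g] == 1}
        if not drop:
            break
        edges -= drop
        removed += len(drop)
    prov["n_isolated_edges_removed"] = removed
    if not edges:
        prov["reasons"].append("all edges removed as isolated pairs")
    net = BipartiteNetwork(
        snp_nodes={s for s, _ in edges},
        gene_nodes={g for _, g in edges},
        edges=edges,
        provenance=prov,
    )
    return net


def degree_distribution(net: BipartiteNetwork) -> dict:
    """Per-side degree tables plus a hub-concentration tail summary.

    The tail summary is the fraction of edges incident to the top 1% of
    nodes by degree (both sides pooled, at least one node), a simple
    heavy-tail indicator. Also returns log-log histogram tables suitable
    for plotting.
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    snp_deg, gene_deg = net.degrees()
    snp_tab = pd.DataFrame(sorted(snp_deg.items()), columns=["node", "degree"])
    gene_tab = pd.DataFrame(sorted(gene_deg.items()), columns=["node", "degree"])
    all_deg = pd.concat(
        [snp_tab.assign(side="snp"), gene_tab.assign(side="gene")], ignore_index=True
    )
    n_top = max(1, int(np.ceil(0.01 * len(all_deg))))
    top = all_deg.nlargest(n_top, "degree", keep="first")
    hub_fraction = float(top["degree"].sum()) / net.n_edges

    def hist(tab: pd.DataFrame) -> pd.DataFrame:
        h = tab["degree"].value_counts().sort_index()
        return pd.DataFrame(
            {"degree": h.index, "count": h.to_numpy(), "log10_degree": np.log10(h.index), "log10_count": np.log10(h.to_numpy())}
        )

    return {
        "snp_degrees": snp_tab,
        "gene_degrees": gene_tab,
        "hub_fraction": hub_fraction,
        "n_top_nodes": n_top,
        "snp_hist": hist(snp_tab),
        "gene_hist": hist(gene_tab),
    }


def write_edge_list(net: BipartiteNetwork, path) -> None:
    net.to_edge_table().to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> BipartiteNetwork:
    tab = pd.read_csv(path, sep="\t")
    edges = set(zip(tab["rsid"], tab["gene_symbol"]))
    return BipartiteNetwork(
        snp_nodes={s for s, _ in edges}, gene_nodes={g for _, g in edges}, edges=edges
    )


def write_graphml(net: BipartiteNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)
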