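"""Bipartite community detection by Barber-modularity maximisation (BRIM).

Barber's bipartite modularity compares within-community SNP-gene edges to
a degree-preserving bipartite null:

    Q = (1/m) sum_{i in SNPs, j in genes} (A_ij - k_i d_j / m) [c_i = c_j]

BRIM alternates exact one-side updates: with gene labels fixed, Q
decomposes over SNP nodes, so assigning every SNP to its argmax community
simultaneously is optimal for that side (and symmetrically for genes);
Q is therefore non-decreasing across sweeps. Initial labels come from
seeded label propagation on the gene one-mode projection, with SNPs
assigned to the majority community of their gene neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from eqtl_ensemble.binet import BipartiteNetwork


@dataclass
class CommunityAssignment:
    mapping: dict  # node -> community id, contiguous from 1
    sides: dict  # node -> "snp" | "gene"
    q: float
    n_communities: int
    trace: list = field(default_factory=list)  # Q per sweep
    converged: bool = True

    def to_table(self) -> pd.DataFrame:
        rows = [(n, self.sides[n], c) for n, c in sorted(self.mapping.items())]
        return pd.DataFrame(rows, columns=["node", "side", "community"])


def barber_modularity(net: BipartiteNetwork, assign: dict) -> float:
    """Evaluate Q sparsely: edge sum minus community degree products / m^2."""
    missing = (net.snp_nodes | net.gene_nodes) - set(assign)
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(missing)[:3]}")
    m = net.n_edges
    if m == 0:
        raise ValueError("empty network")
    within = sum(1 for s, g in net.edges if assign[s] == assign[g])
    snp_deg, gene_deg = net.degrees()
    K: dict = {}
    D: dict = {}
    for s in net.snp_nodes:
        K[assign[s]] = K.get(assign[s], 0) + snp_deg[s]
    for g in net.gene_nodes:
        D[assign[g]] = D.get(assign[g], 0) + gene_deg[g]
    null = sum(K[c] * D.get(c, 0) for c in K)
    return within / m - null / (m * m)


def initialize_assignment(net: BipartiteNetwork, seed: int = 0) -> dict:
    """Seed labels from the gene-side one-mode projection.

    Genes are linked when they share at least one eSNP (weight = shared
    count); seeded asynchronous label propagation groups them; each SNP
    joins the majority community of its gene neighbours (ties to the
    lowest community id).
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    genes = sorted(net.gene_nodes)
    proj = nx.Graph()
    proj.add_nodes_from(genes)
    snp_neighbors: dict = {}
    for s, g in net.edges:
        snp_neighbors.setdefault(s, []).append(g)
    for gs in snp_neighbors.values():
        gs_sorted = sorted(gs)
        for i in range(len(gs_sorted)):
            for j in range(i + 1, len(gs_sorted)):
                a, b = gs_sorted[i], gs_sorted[j]
                w = proj.get_edge_data(a, b, {}).get("weight", 0)
                proj.add_edge(a, b, weight=w + 1)
    comms = list(nx.community.asyn_lpa_communities(proj, weight="weight", seed=seed))
    comms.sort(key=lambda c: min(c))
    assign: dict = {}
    for cid, comm in enumerate(comms, start=1):
        for g in comm:
            assign[g] = cid
    for s in sorted(net.snp_nodes):
        votes: dict = {}
        for g in snp_neighbors.get(s, []):
            votes[assign[g]] = votes.get(assign[g], 0) + 1
        best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        assign[s] = best
    return assign


def _compact(labels: np.ndarray, *others: np.ndarray) -> int:
    """Relabel 0..C-1 in order of first appearance across all arrays."""
    all_lab = np.concatenate([labels, *others])
    uniq = pd.unique(all_lab)
    remap = {int(c): i for i, c in enumerate(sorted(int(u) for u in uniq))}
    labels[:] = [remap[int(c)] for c in labels]
    for arr in others:
        arr[:] = [remap[int(c)] for c in arr]
    return len(remap)


def brim_fit(
    net: BipartiteNetwork,
    init: dict | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    seed: int = 0,
) -> CommunityAssignment:
    """Alternating exact side updates of Barber modularity.

    Sweeps proceed until Q improves by less than ``tol`` or ``max_iter``
    is reached (then the best-so-far labels are returned with
    ``converged=False``). Nodes are visited in sorted-id order and ties
    break toward the lowest community id; the community count can only
    shrink below the initialisation's label count.
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    if init is None:
        init = initialize_assignment(net, seed=seed)
    snps = sorted(net.snp_nodes)
    genes = sorted(net.gene_nodes)
    missing = set(snps + genes) - set(init)
    if missing:
        raise ValueError(f"init missing nodes: {sorted(missing)[:3]}")
    s_idx = {s: i for i, s in enumerate(snps)}
    g_idx = {g: j for j, g in enumerate(genes)}
    nbr_of_snp: list = [[] for _ in snps]
    nbr_of_gene: list = [[] for _ in genes]
    for s, g in net.edges:
        nbr_of_snp[s_idx[s]].append(g_idx[g])
        nbr_of_gene[g_idx[g]].append(s_idx[s])
    k = np.array([len(nb) for nb in nbr_of_snp], dtype=float)
    d = np.array([len(nb) for nb in nbr_of_gene], dtype=float)
    m = float(net.n_edges)

    s_lab = np.array([init[s] for s in snps], dtype=int)
    g_lab = np.array([init[g] for g in genes], dtype=int)
    n_comm = _compact(s_lab, g_lab)

    def q_value() -> float:
        within = sum((s_lab[i] == g_lab[j]) for i, nb in enumerate(nbr_of_snp) for j in nb)
        K = np.bincount(s_lab, weights=k, minlength=n_comm)
        D = np.bincount(g_lab, weights=d, minlength=n_comm)
        return within / m - float(K @ D) / (m * m)

    trace = [q_value()]
    converged = False
    for _ in range(max_iter):
        # SNP side: argmax_c [#neighbours in c - k_i D_c / m]
        D = np.bincount(g_lab, weights=d, minlength=n_comm)
        for i in range(len(snps)):
            score = -(k[i] / m) * D
            for j in nbr_of_snp[i]:
                score[g_lab[j]] += 1.0
            s_lab[i] = int(np.argmax(score))  # argmax takes the lowest index on ties
        K = np.bincount(s_lab, weights=k, minlength=n_comm)
        for j in range(len(genes)):
            score = -(d[j] / m) * K
            for i in nbr_of_gene[j]:
                score[s_lab[i]] += 1.0
            g_lab[j] = int(np.argmax(score))
        n_comm = _compact(s_lab, g_lab)
        q = q_value()
        trace.append(q)
        if q - trace[-2] < tol:
            converged = True
            break

    mapping = {s: int(s_lab[i]) + 1 for i, s in enumerate(snps)}
    mapping.update({g: int(g_lab[j]) + 1 for j, g in enumerate(genes)})
    sides = {s: "snp" for s in snps}
    sides.update({g: "gene" for g in genes})
    q_final = barber_modularity(net, mapping)
    return CommunityAssignment(
        mapping=mapping,
        sides=sides,
        q=q_final,
        n_communities=n_comm,
        trace=trace,
        converged=converged,
    )


def detect_communities(
    net: BipartiteNetwork,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-10,
    n_random_restarts: int = 3,
) -> CommunityAssignment:
    """Best-of-restarts BRIM: label-propagation init, all-singleton init,
    and a few random initial partitions. Returns the highest-Q fit."""
    fits = [brim_fit(net, init=None, max_iter=max_iter, tol=tol, seed=seed)]
    nodes = sorted(net.snp_nodes) + sorted(net.gene_nodes)
    singleton = {n: i + 1 for i, n in enumerate(nodes)}
    fits.append(brim_fit(net, init=singleton, max_iter=max_iter, tol=tol))
    rng = np.random.default_rng(seed)
    n_lab = max(2, int(np.sqrt(len(nodes))) + 1)
    for _ in range(n_random_restarts):
        rand_init = {n: int(rng.integers(1, n_lab + 1)) for n in nodes}
        fits.append(brim_fit(net, init=rand_init, max_iter=max_iter, tol=tol))
    return max(fits, key=lambda f: f.q)


def locate_seed_communities(
    assign: CommunityAssignment,
    seed_genes: list,
    gwas: pd.DataFrame | None = None,
    gwas_subthresh: float = 1e-4,
) -> dict:
    """Communities containing any of the seed genes, with rosters.

    For each hit community: its SNP and gene rosters, the seed genes it
    holds, and (when a GWAS summary is supplied) the count of member SNPs
    with GWAS p below the sub-threshold level. Absent seed genes are
    reported under ``not_found``.
    """
    gene_nodes = {n for n, side in assign.sides.items() if side == "gene"}
    found = [g for g in seed_genes if g in gene_nodes]
    not_found = [g for g in seed_genes if g not in gene_nodes]
    by_comm: dict = {}
    for g in found:
        by_comm.setdefault(assign.mapping[g], []).append(g)
    sub_p = None
    if gwas is not None:
        sub_p = set(gwas.loc[gwas["p"] < gwas_subthresh, "rsid"])
    records = []
    for cid in sorted(by_comm):
        snps = sorted(n for n, c in assign.mapping.items() if c == cid and assign.sides[n] == "snp")
        genes = sorted(n for n, c in assign.mapping.items() if c == cid and assign.sides[n] == "gene")
        rec = {
            "community_id": cid,
            "seed_genes": sorted(by_comm[cid]),
            "snps": snps,
            "genes": genes,
            "n_snps": len(snps),
            "n_genes": len(genes),
        }
        if sub_p is not None:
            rec["n_subthreshold_snps"] = sum(1 for s in snps if s in sub_p)
        records.append(rec)
    return {"communities": records, "not_found": not_found}


def community_summary(assign: CommunityAssignment, gwas: pd.DataFrame | None = None, gwas_subthresh: float = 1e-4) -> pd.DataFrame:
    """Per-community size table (id, n_snps, n_genes, n_subthreshold_snps)."""
    tab = assign.to_table()
    counts = tab.pivot_table(index="community", columns="side", values="node", aggfunc="count").fillna(0)
    out = pd.DataFrame(
        {
            "community": counts.index,
            "n_snps": counts.get("snp", pd.Series(0, index=counts.index)).astype(int),
            "n_genes": counts.get("gene", pd.Series(0, index=counts.index)).astype(int),
        }
    ).reset_index(drop=True)
    if gwas is not None:
        sub = set(gwas.loc[gwas["p"] < gwas_subthresh, "rsid"])
        snp_tab = tab[tab["side"] == "snp"]
        n_sub = snp_tab.groupby("community")["node"].apply(lambda s: sum(1 for x in s if x in sub))
        out["n_subthreshold_snps"] = out["community"].map(n_sub).fillna(0).astype(int)
    return out
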