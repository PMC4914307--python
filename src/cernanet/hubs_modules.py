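"""Hubs, dense modules (MCODE), gene-set enrichment and function inference.

Hubs are defined per molecular class: the top fraction (default 5%) of each
class by degree on the full heterogeneous network, with the target count
rounded to the nearest integer (half up) and ties at the cutoff degree
broken lexicographically by id.

Module mining implements the MCODE algorithm: each vertex is weighted by
k * density of the highest k-core of its closed neighborhood; complexes are
grown outward from high-weight seeds, admitting neighbors whose weight stays
within ``node_score_cutoff`` of the seed's; post-processing trims each
complex to its 2-core (haircut) and discards complexes lacking one. The
complex score is density * size.

Enrichment is the upper-tail hypergeometric test P(X >= k) of the overlap
between a selection (hubs, module members, network neighborhoods) and a
gene set, within an explicit universe.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cerna_inference import CeRNANetwork
from .data_io import GeneSet, MOLECULE_CLASSES


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class HubSet:
    """Per-class top-degree nodes with the bookkeeping of their selection."""

    hubs: dict  # class -> ordered list of node ids (degree desc, id asc)
    fraction: float
    class_sizes: dict
    cutoff_degrees: dict  # class -> degree of the last selected node

    def all_hubs(self) -> set:
        return {h for members in self.hubs.values() for h in members}

    def counts(self) -> dict:
        return {c: len(members) for c, members in self.hubs.items()}


@dataclass
class ModuleResult:
    members: frozenset
    seed_node: str
    score: float  # density * size
    rank: int = 0


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int  # k
    set_size: int  # K (within the universe)
    selection_size: int  # n
    universe_size: int  # N
    p_value: float
    fold_enrichment: float
    q_value: float | None = None
    overlap_members: frozenset = frozenset()


# ---------------------------------------------------------------------------
# hubs


def identify_hubs(net: CeRNANetwork, fraction: float = 0.05) -> HubSet:
    """Top-``fraction`` nodes of each molecular class by network degree.

    The per-class target count is round-half-up(fraction * class size); a
    class absent from the network contributes an empty hub list.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    graph = net.graph
    hubs: dict[str, list] = {}
    class_sizes: dict[str, int] = {}
    cutoffs: dict[str, int] = {}
    for cls in MOLECULE_CLASSES:
        members = net.nodes_of_class(cls)
        class_sizes[cls] = len(members)
        if not members:
            hubs[cls] = []
            cutoffs[cls] = 0
            continue
        count = round_half_up(fraction * len(members))
        ranked = sorted(members, key=lambda node: (-graph.degree(node), node))
        hubs[cls] = ranked[:count]
        cutoffs[cls] = graph.degree(ranked[count - 1]) if count else 0
    return HubSet(hubs, fraction, class_sizes, cutoffs)


def stage_hub_comparison(hub_sets: dict, molecule_class: str) -> dict:
    """Partition the union of per-condition hubs by membership pattern.

    ``hub_sets`` maps condition label -> HubSet (or a plain set of ids).
    Returns ``shared_all`` (hubs in every condition), ``pairwise_shared``
    (in >= 2 but not all), ``condition_specific`` (exactly one), plus a
    ``membership`` map id -> tuple of conditions and per-pattern counts.
    """
    if len(hub_sets) < 2:
        raise ValueError("need >= 2 conditions to compare")
    per_condition: dict[str, set] = {}
    for label, hs in hub_sets.items():
        per_condition[label] = set(hs.hubs.get(molecule_class, [])) if isinstance(hs, HubSet) else set(hs)
    union = set().union(*per_condition.values())
    membership = {
        node: tuple(sorted(l for l, s in per_condition.items() if node in s))
        for node in union
    }
    n_conditions = len(per_condition)
    shared_all = {n for n, conds in membership.items() if len(conds) == n_conditions}
    specific = {n for n, conds in membership.items() if len(conds) == 1}
    pairwise = union - shared_all - specific
    return {
        "shared_all": shared_all,
        "pairwise_shared": pairwise,
        "condition_specific": specific,
        "membership": membership,
        "counts": {
            "shared_all": len(shared_all),
            "pairwise_shared": len(pairwise),
            "condition_specific": len(specific),
        },
    }


# ---------------------------------------------------------------------------
# MCODE


def _highest_kcore(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """(k, subgraph) of the highest non-empty k-core."""
    if graph.number_of_nodes() == 0:
        return 0, graph
    core_numbers = nx.core_number(graph)
    k = max(core_numbers.values())
    nodes = [n for n, c in core_numbers.items() if c >= k]
    return k, graph.subgraph(nodes)


def mcode_vertex_weights(graph: nx.Graph, degree_cutoff: int = 2) -> dict:
    """MCODE vertex weighting: k * density of the highest k-core of the
    closed neighborhood; vertices below ``degree_cutoff`` weigh 0."""
    weights: dict = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        neighborhood = graph.subgraph(list(graph.neighbors(v)) + [v])
        k, core = _highest_kcore(neighborhood)
        weights[v] = k * nx.density(core)
    return weights


def _grow_complex(
    graph: nx.Graph,
    weights: dict,
    seed: str,
    node_score_cutoff: float,
    max_depth: int,
    used: set,
) -> set:
    threshold = weights[seed] * (1.0 - node_score_cutoff)
    members = {seed}
    frontier = [(seed, 0)]
    while frontier:
        node, depth = frontier.pop(0)
        if depth >= max_depth:
            continue
        for nb in graph.neighbors(node):
            if nb in members or nb in used:
                continue
            if weights[nb] >= threshold:
                members.add(nb)
                frontier.append((nb, depth + 1))
    return members


def mcode_modules(
    net,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density_cutoff: float = 0.2,
) -> list[ModuleResult]:
    """Mine densely connected complexes with the MCODE procedure.

    Stages: (1) vertex weighting (see :func:`mcode_vertex_weights`);
    (2) complex prediction — seeds are taken in decreasing weight order,
    each complex grows breadth-first admitting unused neighbors whose weight
    is >= (1 - node_score_cutoff) * seed weight, up to ``max_depth`` from
    the seed; (3) post-processing — complexes lacking a ``k_core``-core are
    discarded, ``haircut`` trims each complex to its 2-core, ``fluff``
    optionally adds neighbors whose closed-neighborhood density exceeds
    ``fluff_density_cutoff``. Complexes are ranked by score = density * size.
    """
    graph = net.graph if isinstance(net, CeRNANetwork) else net
    if graph.number_of_nodes() == 0:
        return []
    weights = mcode_vertex_weights(graph, degree_cutoff)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    used: set = set()
    complexes: list[tuple[set, str]] = []
    for seed in order:
        if seed in used or weights[seed] <= 0:
            continue
        members = _grow_complex(graph, weights, seed, node_score_cutoff, max_depth, used)
        used |= members
        complexes.append((members, seed))
    results: list[ModuleResult] = []
    for members, seed in complexes:
        sub = graph.subgraph(members)
        core_numbers = nx.core_number(sub) if sub.number_of_nodes() else {}
        if not core_numbers or max(core_numbers.values()) < k_core:
            continue
        if haircut:
            members = {n for n, c in core_numbers.items() if c >= 2}
            sub = graph.subgraph(members)
        if fluff:
            extra = set()
            for v in members:
                for nb in graph.neighbors(v):
                    if nb in members or nb in extra:
                        continue
                    closed = graph.subgraph(list(graph.neighbors(nb)) + [nb])
                    if nx.density(closed) > fluff_density_cutoff:
                        extra.add(nb)
            members = members | extra
            sub = graph.subgraph(members)
        score = nx.density(sub) * sub.number_of_nodes()
        results.append(ModuleResult(frozenset(members), seed, float(score)))
    results.sort(key=lambda r: (-r.score, sorted(r.members)))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


# ---------------------------------------------------------------------------
# enrichment


def hypergeometric_enrichment(
    selection: set, gene_set: GeneSet, universe: set
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``gene_set`` in ``selection``.

    p = P(X >= k) with N = |universe|, K = |gene_set & universe|,
    n = |selection|; fold enrichment = (k/n) / (K/N).
    """
    selection = set(selection)
    universe = set(universe)
    if not selection or not universe:
        raise ValueError("selection and universe must be nonempty")
    stray = selection - universe
    if stray:
        raise ValueError(f"selection not contained in universe: {sorted(stray)[:5]}...")
    in_universe = set(gene_set.members) & universe
    overlap = selection & in_universe
    big_n, big_k, n, k = len(universe), len(in_universe), len(selection), len(overlap)
    # P(X >= k) including k itself; k = 0 gives p = 1
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    fold = (k / n) / (big_k / big_n) if big_k > 0 else float("nan")
    return EnrichmentResult(
        set_name=gene_set.name,
        overlap=k,
        set_size=big_k,
        selection_size=n,
        universe_size=big_n,
        p_value=min(p, 1.0),
        fold_enrichment=fold,
        overlap_members=frozenset(overlap),
    )


def benjamini_hochberg(p_values: list) -> list:
    """BH-adjusted q-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q.tolist()


def enrich_many(
    selection: set, gene_sets: list, universe: set, adjust: bool = True
) -> list:
    """Enrichment of each gene set, ranked by ascending p (BH q optional)."""
    results = [hypergeometric_enrichment(selection, gs, universe) for gs in gene_sets]
    if adjust and results:
        qs = benjamini_hochberg([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = q
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def neighbor_function_inference(
    net: CeRNANetwork,
    lncrna_id: str,
    annotation_sets: list,
    universe: set,
    adjust: bool = True,
) -> list:
    """Guilt-by-association annotation of one lncRNA from its mRNA neighbors.

    The selection is the set of mRNA-class nodes reachable from the lncRNA
    within distance 2 (one hop through a mediating miRNA); when the network
    carries direct lncRNA-mRNA ceRNA edges, direct mRNA neighbors are used
    instead. Each annotation set is tested hypergeometrically against
    ``universe``; results are ranked ascending by p, the first being the
    inferred function.
    """
    graph = net.graph
    if lncrna_id not in graph:
        raise KeyError(f"{lncrna_id!r} not in network")
    has_cerna_edges = any(
        d.get("edge_type") == "lncRNA-mRNA" for _, _, d in graph.edges(data=True)
    )
    if has_cerna_edges:
        reachable = set(graph.neighbors(lncrna_id))
    else:
        lengths = nx.single_source_shortest_path_length(graph, lncrna_id, cutoff=2)
        reachable = set(lengths) - {lncrna_id}
    neighbors = {
        n for n in reachable if graph.nodes[n].get("molecule_class") == "mRNA"
    }
    if not neighbors:
        warnings.warn(f"{lncrna_id}: no mRNA neighbors; nothing to infer", stacklevel=2)
        return []
    return enrich_many(neighbors, annotation_sets, set(universe), adjust=adjust)


def enrichment_to_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "selection_size": r.selection_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "fold_enrichment": r.fold_enrichment,
            }
            for r in results
        ]
    )
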