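"""Inference of miRNA-mediated lncRNA-mRNA ceRNA crosstalk (triplets).

The ceRNA hypothesis predicts that an lncRNA sponging a miRNA de-represses
that miRNA's mRNA targets. Expression-wise this leaves three signatures in a
matched cohort, which this module turns into an operational filter:

1. a candidate lncRNA-mRNA pair is strongly *positively* correlated (above a
   high percentile of the all-pairs Pearson correlation distribution) and the
   two molecules share at least ``min_shared`` validated miRNA regulators;
2. the pair becomes *functional* when at least one shared miRNA is
   *negatively* co-expressed with both the lncRNA and the mRNA.

Functional triplets are integrated into an undirected, typed molecular
network (the lncRNA-associated ceRNA network): for every retained shared
miRNA the miRNA-mRNA and miRNA-lncRNA edges are added; an explicit option
additionally adds the lncRNA-mRNA ceRNA edge itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    ExpressionMatrix,
    InteractionCatalog,
    MatchedExpressionSet,
)

EDGE_TYPES = ("miRNA-mRNA", "miRNA-lncRNA", "lncRNA-mRNA")


@dataclass(frozen=True)
class MirnaArm:
    """Correlations of one shared miRNA with the two ceRNA partners."""

    mirna_id: str
    r_mir_mrna: float
    r_mir_lnc: float
    p_mir_mrna: float
    p_mir_lnc: float


@dataclass(frozen=True)
class CeRNATriplet:
    """One lncRNA-mRNA crosstalk record mediated by >= 1 shared miRNAs."""

    lncrna_id: str
    mrna_id: str
    r_lnc_mrna: float
    arms: tuple  # of MirnaArm, one per shared miRNA
    status: str = "candidate"  # or "functional"

    @property
    def shared_mirnas(self) -> frozenset:
        return frozenset(a.mirna_id for a in self.arms)

    @property
    def key(self) -> tuple:
        return (self.lncrna_id, self.mrna_id)


@dataclass
class CeRNANetwork:
    """Typed, undirected molecular network with triplet provenance.

    Node attribute ``molecule_class`` in {miRNA, lncRNA, mRNA}; edge
    attributes ``edge_type`` (one of :data:`EDGE_TYPES`) and ``triplets``
    (list of contributing (lncrna_id, mrna_id) keys).
    """

    graph: nx.Graph
    condition_label: str = "global"

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges()):
            raise ValueError("ceRNA network must be a simple graph (self-loop found)")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_class(self, molecule_class: str) -> list:
        return sorted(
            n for n, c in self.graph.nodes(data="molecule_class") if c == molecule_class
        )

    def class_counts(self) -> dict:
        counts: dict[str, int] = {}
        for _, c in self.graph.nodes(data="molecule_class"):
            counts[c] = counts.get(c, 0) + 1
        return counts

    def class_pairings(self) -> set:
        """Unordered class pairs realized by at least one edge."""
        return {
            frozenset(
                (
                    self.graph.nodes[u]["molecule_class"],
                    self.graph.nodes[v]["molecule_class"],
                )
            )
            for u, v in self.graph.edges()
        }


@dataclass(frozen=True)
class InferenceOptions:
    """Tunables of the triplet-calling procedure.

    ``percentile`` sets the positive lncRNA-mRNA correlation cutoff as a
    percentile of the all-pairs distribution (default 99); ``fixed_threshold``
    overrides it with an absolute r. ``negativity_rule`` is ``"p05"`` (r < 0
    with two-sided p < ``p_cutoff`` on both miRNA arms) or ``"sign"``
    (r < 0 only). ``cerna_edges`` adds the direct lncRNA-mRNA edge layer.
    """

    percentile: float = 99.0
    fixed_threshold: float | None = None
    min_shared: int = 1
    negativity_rule: str = "p05"
    p_cutoff: float = 0.05
    cerna_edges: bool = False

    def __post_init__(self) -> None:
        if self.negativity_rule not in ("p05", "sign"):
            raise ValueError("negativity_rule must be 'p05' or 'sign'")
        if self.min_shared < 1:
            raise ValueError("min_shared must be >= 1")
        if self.fixed_threshold is not None and not -1 < self.fixed_threshold < 1:
            raise ValueError("fixed_threshold must lie in (-1, 1)")


# ---------------------------------------------------------------------------
# correlation primitives


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p (t approximation, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    """Row-standardize with ddof=1 (constant rows -> NaN rows)."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (values - mean) / sd


def correlation_matrix(a: ExpressionMatrix, b: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson r between rows of ``a`` and rows of ``b``."""
    n = a.n_samples
    if b.n_samples != n:
        raise ValueError("matrices must share the sample dimension")
    if n < 3:
        raise ValueError("need >= 3 samples for correlations")
    za = _zscore_rows(a.values)
    zb = _zscore_rows(b.values)
    r = za @ zb.T / (n - 1)
    np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame(r, index=a.molecule_ids, columns=b.molecule_ids)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with n-2 df."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def correlation_threshold(mset: MatchedExpressionSet, percentile: float = 99.0) -> float:
    """Percentile of the exhaustive lncRNA x mRNA Pearson-r distribution.

    The full correlation matrix is materialized; at desk scale (up to a few
    thousand molecules per class) this is a single dense matrix product.
    """
    if mset.lncrna.n_molecules < 2 or mset.mrna.n_molecules < 2:
        raise ValueError("need >= 2 lncRNAs and >= 2 mRNAs for a correlation distribution")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    r = correlation_matrix(mset.lncrna, mset.mrna).to_numpy().ravel()
    r = r[np.isfinite(r)]  # constant rows yield NaN; excluded from the distribution
    if r.size == 0:
        raise ValueError("no defined lncRNA-mRNA correlations (all rows constant?)")
    return float(np.percentile(r, percentile))


# ---------------------------------------------------------------------------
# triplet calling


def find_candidate_triplets(
    mset: MatchedExpressionSet,
    mrna_catalog: InteractionCatalog,
    lncrna_catalog: InteractionCatalog,
    threshold: float,
    min_shared: int = 1,
) -> list[CeRNATriplet]:
    """Positively co-expressed lncRNA-mRNA pairs sharing validated miRNAs.

    Returns exactly the pairs with r > ``threshold`` and at least
    ``min_shared`` miRNAs that target both molecules according to the two
    catalogs; each triplet carries its full shared-miRNA set (arms without
    correlations yet; those are filled in by the functional filter).
    """
    if not -1 < threshold < 1:
        raise ValueError("threshold must lie in (-1, 1)")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if mrna_catalog.target_class != "mRNA" or lncrna_catalog.target_class != "lncRNA":
        raise ValueError("catalogs must be (mRNA-target, lncRNA-target), in that order")
    r_matrix = correlation_matrix(mset.lncrna, mset.mrna)
    mirnas_by_mrna = mrna_catalog.mirna_index()
    mirnas_by_lnc = lncrna_catalog.mirna_index()
    # only miRNAs with measured expression can mediate a scored triplet
    measured = set(mset.mirna.molecule_ids)
    triplets: list[CeRNATriplet] = []
    r_values = r_matrix.to_numpy()
    lnc_ids = r_matrix.index.tolist()
    mrna_ids = r_matrix.columns.tolist()
    for i, j in np.argwhere(r_values > threshold):
        lnc, gene = lnc_ids[i], mrna_ids[j]
        shared = (
            mirnas_by_lnc.get(lnc, set()) & mirnas_by_mrna.get(gene, set()) & measured
        )
        if len(shared) < min_shared:
            continue
        arms = tuple(
            MirnaArm(m, np.nan, np.nan, np.nan, np.nan) for m in sorted(shared)
        )
        triplets.append(
            CeRNATriplet(lnc, gene, float(r_values[i, j]), arms, status="candidate")
        )
    triplets.sort(key=lambda t: t.key)
    return triplets


def filter_functional_triplets(
    candidates: list[CeRNATriplet],
    mset: MatchedExpressionSet,
    options: InferenceOptions = InferenceOptions(),
) -> list[CeRNATriplet]:
    """Keep candidates whose lncRNA and mRNA are both negatively co-expressed
    with >= 1 shared miRNA; prune each shared set to the passing miRNAs.

    Under the default ``"p05"`` rule an arm passes when r < 0 with two-sided
    p < ``options.p_cutoff`` against *both* partners; ``"sign"`` requires
    negativity only.
    """
    n = mset.n
    lnc_index = {m: i for i, m in enumerate(mset.lncrna.molecule_ids)}
    mrna_index = {m: i for i, m in enumerate(mset.mrna.molecule_ids)}
    mir_index = {m: i for i, m in enumerate(mset.mirna.molecule_ids)}
    z_lnc = _zscore_rows(mset.lncrna.values)
    z_mrna = _zscore_rows(mset.mrna.values)
    z_mir = _zscore_rows(mset.mirna.values)

    def _r_p(za: np.ndarray, zb: np.ndarray) -> tuple[float, float]:
        r = float(np.clip(np.dot(za, zb) / (n - 1), -1.0, 1.0))
        p = float(correlation_pvalues(np.array([r]), n)[0])
        return r, p

    functional: list[CeRNATriplet] = []
    for cand in candidates:
        if cand.lncrna_id not in lnc_index or cand.mrna_id not in mrna_index:
            raise KeyError(
                f"candidate ({cand.lncrna_id}, {cand.mrna_id}) references molecules "
                "absent from the matched expression set"
            )
        passing: list[MirnaArm] = []
        for arm in cand.arms:
            if arm.mirna_id not in mir_index:
                raise KeyError(f"miRNA {arm.mirna_id!r} absent from the expression set")
            zm = z_mir[mir_index[arm.mirna_id]]
            r_mg, p_mg = _r_p(zm, z_mrna[mrna_index[cand.mrna_id]])
            r_ml, p_ml = _r_p(zm, z_lnc[lnc_index[cand.lncrna_id]])
            ok = r_mg < 0 and r_ml < 0
            if ok and options.negativity_rule == "p05":
                ok = p_mg < options.p_cutoff and p_ml < options.p_cutoff
            if ok:
                passing.append(MirnaArm(arm.mirna_id, r_mg, r_ml, p_mg, p_ml))
        if passing:
            functional.append(
                replace(cand, arms=tuple(passing), status="functional")
            )
    return functional


def assemble_network(
    functional: list[CeRNATriplet],
    cerna_edges: bool = False,
    condition_label: str = "global",
) -> CeRNANetwork:
    """Integrate functional triplets into one simple, typed network.

    For each triplet and each retained shared miRNA the miRNA-mRNA and
    miRNA-lncRNA edges are added; ``cerna_edges`` additionally adds the
    lncRNA-mRNA edge. Duplicate edges collapse, accumulating provenance.
    """
    if not functional:
        warnings.warn("no functional triplets: returning empty network", stacklevel=2)
    graph = nx.Graph()
    for trip in functional:
        if trip.status != "functional":
            raise ValueError(f"triplet {trip.key} is not functional")
        graph.add_node(trip.lncrna_id, molecule_class="lncRNA")
        graph.add_node(trip.mrna_id, molecule_class="mRNA")
        edges = []
        for arm in trip.arms:
            graph.add_node(arm.mirna_id, molecule_class="miRNA")
            edges.append((arm.mirna_id, trip.mrna_id, "miRNA-mRNA"))
            edges.append((arm.mirna_id, trip.lncrna_id, "miRNA-lncRNA"))
        if cerna_edges:
            edges.append((trip.lncrna_id, trip.mrna_id, "lncRNA-mRNA"))
        for u, v, etype in edges:
            if graph.has_edge(u, v):
                graph[u][v]["triplets"].append(trip.key)
            else:
                graph.add_edge(u, v, edge_type=etype, triplets=[trip.key])
    return CeRNANetwork(graph, condition_label)


def infer_network(
    mset: MatchedExpressionSet,
    mrna_catalog: InteractionCatalog,
    lncrna_catalog: InteractionCatalog,
    options: InferenceOptions = InferenceOptions(),
    condition_label: str = "global",
) -> dict:
    """Full pipeline on one sample set: threshold -> candidates ->
    functional triplets -> network. Returns a dict with all four products.

    Constant expression rows (zero variance) are dropped up-front with a
    logged count, since their correlations are undefined.
    """
    mirna, n_c1 = mset.mirna.drop_constant_rows()
    lncrna, n_c2 = mset.lncrna.drop_constant_rows()
    mrna, n_c3 = mset.mrna.drop_constant_rows()
    if n_c1 + n_c2 + n_c3:
        warnings.warn(
            f"dropped constant rows: {n_c1} miRNA, {n_c2} lncRNA, {n_c3} mRNA",
            stacklevel=2,
        )
    clean = MatchedExpressionSet(mirna, lncrna, mrna, mset.clinical)
    if options.fixed_threshold is not None:
        threshold = options.fixed_threshold
    else:
        threshold = correlation_threshold(clean, options.percentile)
    candidates = find_candidate_triplets(
        clean, mrna_catalog, lncrna_catalog, threshold, options.min_shared
    )
    functional = filter_functional_triplets(candidates, clean, options)
    network = assemble_network(functional, options.cerna_edges, condition_label)
    return {
        "threshold": threshold,
        "candidates": candidates,
        "functional": functional,
        "network": network,
    }


def condition_specific_networks(
    mset: MatchedExpressionSet,
    mrna_catalog: InteractionCatalog,
    lncrna_catalog: InteractionCatalog,
    group_by: str = "stage",
    options: InferenceOptions = InferenceOptions(),
) -> dict:
    """Re-run the full inference independently per clinical subgroup.

    Samples are grouped on the clinical field ``group_by``; each group with
    >= 3 samples gets its own threshold, triplets and labelled network
    (groups below that size are skipped with a warning). Missing values in
    the grouping field exclude a sample from every group.
    """
    if group_by not in mset.clinical.data.columns:
        raise KeyError(f"clinical field {group_by!r} not present")
    labels = mset.clinical.data[group_by]
    results: dict[str, dict] = {}
    for value in sorted(labels.dropna().unique(), key=str):
        samples = sorted(labels.index[labels == value])
        if len(samples) < 3:
            warnings.warn(
                f"condition {group_by}={value}: only {len(samples)} samples, skipped",
                stacklevel=2,
            )
            continue
        subset = mset.restrict_samples(samples)
        results[str(value)] = infer_network(
            subset, mrna_catalog, lncrna_catalog, options, condition_label=str(value)
        )
    return results


# ---------------------------------------------------------------------------
# tabular / file representations


def triplets_to_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    """One row per triplet: ids, lncRNA-mRNA r, shared miRNAs, status."""
    rows = []
    for t in triplets:
        rows.append(
            {
                "lncrna": t.lncrna_id,
                "mrna": t.mrna_id,
                "r_lnc_mrna": t.r_lnc_mrna,
                "n_shared_mirnas": len(t.arms),
                "shared_mirnas": ",".join(sorted(a.mirna_id for a in t.arms)),
                "status": t.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lncrna", "mrna", "r_lnc_mrna", "n_shared_mirnas", "shared_mirnas", "status"],
    )


def write_network(net: CeRNANetwork, edge_path, node_path) -> None:
    """Edge-list TSV (source, target, edge_type) + node-class sidecar TSV."""
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "edge_type": d["edge_type"]}
            for u, v, d in sorted(net.graph.edges(data=True))
        ]
    )
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        [
            {"node": n, "molecule_class": c}
            for n, c in sorted(net.graph.nodes(data="molecule_class"))
        ]
    )
    nodes.to_csv(node_path, sep="\t", index=False)


def read_network(edge_path, node_path, condition_label: str = "global") -> CeRNANetwork:
    edges = pd.read_csv(edge_path, sep="\t", dtype=str)
    nodes = pd.read_csv(node_path, sep="\t", dtype=str)
    graph = nx.Graph()
    for _, row in nodes.iterrows():
        graph.add_node(row["node"], molecule_class=row["molecule_class"])
    for _, row in edges.iterrows():
        graph.add_edge(
            row["source"], row["target"], edge_type=row.get("edge_type", ""), triplets=[]
        )
    return CeRNANetwork(graph, condition_label)


def write_graphml(net: CeRNANetwork, path) -> None:
    graph = net.graph.copy()
    for _, _, data in graph.edges(data=True):
        if "triplets" in data:
            data["triplets"] = ";".join("|".join(k) for k in data["triplets"])
    nx.write_graphml(graph, path)
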