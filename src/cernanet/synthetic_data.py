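"""Synthetic matched cohorts with planted ceRNA structure and survival.

The generator emulates the statistical structure the inference assumes in a
tumor expression cohort: for each planted triplet a latent miRNA activity
vector drives the miRNA row positively and the planted lncRNA and mRNA rows
negatively, so the lncRNA-mRNA pair is positively correlated while both are
anti-correlated with the shared miRNA(s) — the sponge signature. Background
rows are independent noise; interaction catalogs contain the planted
miRNA->target pairs plus decoy pairs attached to background molecules only,
so the ground truth is unambiguous. Survival times follow an exponential
proportional-hazards model with a linear predictor over planted lncRNA
expression, with independent exponential censoring.

Everything is deterministic under a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cerna_inference import CeRNANetwork
from .data_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    InteractionCatalog,
    MatchedExpressionSet,
)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults describe a desk-scale ovarian-cancer-like cohort: 200 patients,
    a few hundred molecules, 12 planted sponge triplets whose pairwise
    correlations sit far above the 99th-percentile background threshold
    (coupling 0.9, noise SD 0.35 gives planted |r| around 0.85-0.9), stage
    mix dominated by stage III, survival on a months scale with a median
    around three years and roughly a third of patients censored.
    """

    n_samples: int = 200
    n_mirna: int = 30
    n_lncrna: int = 60
    n_mrna: int = 120
    n_planted_triplets: int = 12
    shared_mirnas_per_triplet: int = 2
    coupling_strength: float = 0.9
    noise_sd: float = 0.35
    n_decoy_interactions: int = 300
    stage_proportions: dict = field(
        default_factory=lambda: {"II": 0.15, "III": 0.70, "IV": 0.15}
    )
    planted_cox_coefficients: dict | None = None  # lncRNA id -> beta; None = default 4
    baseline_hazard: float = 0.02  # events per month
    censoring_rate: float = 0.008  # per month
    n_stage_restricted_triplets: int = 0  # extra triplets coupled only in one stage
    restricted_stage: str = "IV"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_mirna", "n_lncrna", "n_mrna", "shared_mirnas_per_triplet"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_triplets < 0 or self.n_stage_restricted_triplets < 0:
            raise ValueError("triplet counts must be non-negative")
        if not 0 < self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        total = sum(self.stage_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("stage_proportions must sum to 1")
        if self.baseline_hazard <= 0 or self.censoring_rate < 0:
            raise ValueError("hazard rates must be positive (censoring may be 0)")
        n_triplets = self.n_planted_triplets + self.n_stage_restricted_triplets
        if n_triplets * self.shared_mirnas_per_triplet > self.n_mirna:
            raise ValueError("not enough miRNAs for the requested planted triplets")
        if n_triplets > self.n_lncrna or n_triplets > self.n_mrna:
            raise ValueError("not enough lncRNAs/mRNAs for the requested planted triplets")


@dataclass
class GroundTruth:
    """What was planted: triplets, survival coefficients, stage labels."""

    planted_triplets: list  # of (lncrna_id, mrna_id, frozenset of miRNA ids)
    planted_cox_coefficients: dict  # lncrna_id -> beta
    stage_assignments: pd.Series  # sample_id -> stage label
    stage_restricted_triplets: list = field(default_factory=list)

    @property
    def planted_pairs(self) -> set:
        return {(l, m) for l, m, _ in self.planted_triplets}

    def to_json(self, path) -> None:
        payload = {
            "planted_triplets": [
                [l, m, sorted(ms)] for l, m, ms in self.planted_triplets
            ],
            "stage_restricted_triplets": [
                [l, m, sorted(ms)] for l, m, ms in self.stage_restricted_triplets
            ],
            "planted_cox_coefficients": self.planted_cox_coefficients,
            "stage_assignments": self.stage_assignments.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _default_cox_coefficients(lnc_ids: list[str]) -> dict:
    # two risky, two protective planted lncRNAs; the rest prognostically null
    betas = [0.8, -0.8, 0.5, -0.5]
    return {l: b for l, b in zip(lnc_ids, betas)}


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[MatchedExpressionSet, InteractionCatalog, InteractionCatalog, GroundTruth]:
    """Generate (matched set, mRNA catalog, lncRNA catalog, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    mir_ids = [f"hsa-miR-{i:03d}" for i in range(spec.n_mirna)]
    lnc_ids = [f"lnc-{i:04d}" for i in range(spec.n_lncrna)]
    mrna_ids = [f"gene-{i:04d}" for i in range(spec.n_mrna)]

    mirna = rng.normal(0.0, 1.0, size=(spec.n_mirna, n))
    lncrna = rng.normal(0.0, 1.0, size=(spec.n_lncrna, n))
    mrna = rng.normal(0.0, 1.0, size=(spec.n_mrna, n))

    # stage labels first, so stage-restricted planting can see them
    stages = list(spec.stage_proportions)
    stage_labels = rng.choice(
        stages, size=n, p=[spec.stage_proportions[s] for s in stages]
    )
    stage_series = pd.Series(stage_labels, index=samples, name="stage")

    k = spec.shared_mirnas_per_triplet
    n_total = spec.n_planted_triplets + spec.n_stage_restricted_triplets
    planted: list[tuple[str, str, frozenset]] = []
    restricted: list[tuple[str, str, frozenset]] = []
    mrna_pairs: set[tuple[str, str]] = set()
    lnc_pairs: set[tuple[str, str]] = set()

    def _plant(t: int, columns: np.ndarray) -> tuple[str, str, frozenset]:
        """Couple triplet ``t``'s rows through a latent activity on ``columns``."""
        m_latent = rng.normal(0.0, 1.0, size=columns.size)
        mirs = mir_ids[t * k : (t + 1) * k]
        for j in range(k):
            mirna[t * k + j, columns] = m_latent + rng.normal(
                0.0, spec.noise_sd, size=columns.size
            )
        lncrna[t, columns] = -spec.coupling_strength * m_latent + rng.normal(
            0.0, spec.noise_sd, size=columns.size
        )
        mrna[t, columns] = -spec.coupling_strength * m_latent + rng.normal(
            0.0, spec.noise_sd, size=columns.size
        )
        for m in mirs:
            mrna_pairs.add((m, mrna_ids[t]))
            lnc_pairs.add((m, lnc_ids[t]))
        return (lnc_ids[t], mrna_ids[t], frozenset(mirs))

    all_cols = np.arange(n)
    for t in range(spec.n_planted_triplets):
        planted.append(_plant(t, all_cols))
    restricted_cols = np.flatnonzero(stage_labels == spec.restricted_stage)
    for t in range(spec.n_planted_triplets, n_total):
        restricted.append(_plant(t, restricted_cols))

    # decoy interactions among background molecules only
    bg_mirs = mir_ids[n_total * k :] or mir_ids
    bg_lncs = lnc_ids[n_total:]
    bg_mrnas = mrna_ids[n_total:]
    for _ in range(spec.n_decoy_interactions):
        m = bg_mirs[rng.integers(len(bg_mirs))]
        if rng.random() < 0.5 and bg_mrnas:
            mrna_pairs.add((m, bg_mrnas[rng.integers(len(bg_mrnas))]))
        elif bg_lncs:
            lnc_pairs.add((m, bg_lncs[rng.integers(len(bg_lncs))]))

    coefs = spec.planted_cox_coefficients
    if coefs is None:
        coefs = _default_cox_coefficients([l for l, _, _ in planted])
    for l in coefs:
        if l not in lnc_ids:
            raise ValueError(f"planted Cox coefficient refers to unknown lncRNA {l!r}")

    lnc_frame = pd.DataFrame(lncrna, index=lnc_ids, columns=samples)
    linear_predictor = np.zeros(n)
    for l, beta in coefs.items():
        linear_predictor += beta * lnc_frame.loc[l].to_numpy()
    hazard = spec.baseline_hazard * np.exp(linear_predictor)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_months = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    age = np.clip(np.round(rng.normal(61.0, 11.0, size=n)), 30, 90)
    grade = rng.choice(["G1/G2", "G3/G4"], size=n, p=[0.25, 0.75])
    residual = rng.choice(["0-10mm", ">10mm"], size=n, p=[0.55, 0.45])
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_months": os_months,
                "event": event,
                "age": age,
                "stage": stage_labels,
                "grade": grade,
                "residual": residual,
            },
            index=pd.Index(samples, name="sample"),
        )
    )

    mset = MatchedExpressionSet(
        ExpressionMatrix(pd.DataFrame(mirna, index=mir_ids, columns=samples), "miRNA"),
        ExpressionMatrix(lnc_frame, "lncRNA"),
        ExpressionMatrix(pd.DataFrame(mrna, index=mrna_ids, columns=samples), "mRNA"),
        clinical,
    )
    truth = GroundTruth(planted, dict(coefs), stage_series, restricted)
    return (
        mset,
        InteractionCatalog(frozenset(mrna_pairs), "mRNA"),
        InteractionCatalog(frozenset(lnc_pairs), "lncRNA"),
        truth,
    )


def planted_gene_sets(truth: GroundTruth, n_extra: int = 0, seed: int = 0) -> list[GeneSet]:
    """Disease-gene-set stand-ins: the planted molecules form one set.

    Useful for exercising enrichment: hubs of an inferred network should
    over-represent the planted set. ``n_extra`` pads the set with fake ids
    that never appear in any network (diluting K without touching overlap).
    """
    rng = np.random.default_rng(seed)
    members = set()
    for l, m, mirs in truth.planted_triplets + truth.stage_restricted_triplets:
        members.add(l)
        members.add(m)
        members.update(mirs)
    for i in range(n_extra):
        members.add(f"unrelated-{rng.integers(10**6):06d}")
    return [GeneSet("planted_disease_genes", frozenset(members), "synthetic ground truth")]


# ---------------------------------------------------------------------------
# deterministic toy graphs for topology / module tests


def _with_classes(graph: nx.Graph, label: str) -> CeRNANetwork:
    for node in graph.nodes:
        graph.nodes[node]["molecule_class"] = "mRNA"
    return CeRNANetwork(nx.relabel_nodes(graph, {n: f"n{n}" for n in graph.nodes}), label)


TOY_GRAPHS = {
    "triangle": "3 nodes, 3 edges (K3)",
    "path3": "3 nodes, 2 edges (a-b-c)",
    "cycle4": "4 nodes, 4 edges (C4); no triangles",
    "star6": "6 nodes, 5 edges (center + 5 leaves)",
    "ring_lattice_20_k4": "20 nodes, 40 edges; every node joined to its 4 nearest ring neighbors",
    "er12": "12 nodes, fixed Erdos-Renyi-like draw (G(12, 0.3), frozen seed)",
    "clique5_plus_3_singletons": "8 nodes, 10 edges; a 5-clique plus 3 isolated nodes",
    "barbell_two_k4_bridge": "9 nodes, 14 edges; two 4-cliques joined through one bridge node",
}


def toy_graph(name: str) -> CeRNANetwork:
    """Deterministic small fixture networks (all nodes classed mRNA).

    Available fixtures and their node/edge counts are listed in
    :data:`TOY_GRAPHS`.
    """
    if name == "triangle":
        g = nx.complete_graph(3)
    elif name == "path3":
        g = nx.path_graph(3)
    elif name == "cycle4":
        g = nx.cycle_graph(4)
    elif name == "star6":
        g = nx.star_graph(5)
    elif name == "ring_lattice_20_k4":
        g = nx.watts_strogatz_graph(20, 4, 0.0)  # p=0: pure ring lattice
    elif name == "er12":
        g = nx.gnp_random_graph(12, 0.3, seed=42)
    elif name == "clique5_plus_3_singletons":
        g = nx.complete_graph(5)
        g.add_nodes_from([5, 6, 7])
    elif name == "barbell_two_k4_bridge":
        g = nx.complete_graph(4)
        g = nx.union(g, nx.complete_graph(4), rename=("a", "b"))
        g.add_edges_from([("a0", "m"), ("b0", "m")])
    else:
        raise KeyError(
            f"unknown toy graph {name!r}; available: {sorted(TOY_GRAPHS)}"
        )
    return _with_classes(g, name)
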