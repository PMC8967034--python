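"""Protein co-expression networks from compositional spectral counts.

Correlations are estimated with the sparCC procedure: pairwise log-ratio
variances t_ij = Var(log(x_i/x_j)) are combined under a sparsity assumption
on the basis correlations to solve for per-component basis variances w_i,
from which rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)). Strongly
correlated pairs are iteratively excluded from the basis system and the
variances re-solved, as in the original estimator.

Modules are mined from the thresholded network by repeatedly extracting an
exact maximum clique as a seed, then attaching each leftover node to the
seed it shares the most edges with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import SampleManifest

logger = logging.getLogger(__name__)

DEFAULT_EDGE_THRESHOLD = 0.3


# ---------------------------------------------------------------------------
# sparCC
# ---------------------------------------------------------------------------

def _log_ratio_variances(x: np.ndarray, pseudocount: float) -> np.ndarray:
    """t_ij = Var over samples of log((x_i+pc)/(x_j+pc)); shape (M, M)."""
    logs = np.log(x + pseudocount)  # (M, N)
    m = logs.shape[0]
    t = np.zeros((m, m))
    for i in range(m):
        diff = logs[i] - logs[i + 1 :]
        t[i, i + 1 :] = diff.var(axis=1, ddof=1)
    return t + t.T


def _solve_basis_variances(t: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Solve for basis variances given the pair-inclusion mask.

    For every included pair, t_ij ~ w_i + w_j under the sparse assumption,
    so sum_j t_ij = deg_i * w_i + sum_{j in pairs(i)} w_j.
    """
    m = t.shape[0]
    a = included.astype(float).copy()
    np.fill_diagonal(a, 0.0)
    degrees = a.sum(axis=1)
    a[np.diag_indices(m)] = np.maximum(degrees, 1.0)
    rhs = (t * included).sum(axis=1)
    omega = np.linalg.solve(a, rhs)
    return np.maximum(omega, 1e-10)


def _correlations_from_variances(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def clr_pearson(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Pearson correlation of centered-log-ratio transformed counts."""
    logs = np.log(counts + pseudocount)
    clr = logs - logs.mean(axis=0, keepdims=True)
    rho = np.corrcoef(clr)
    return np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)


def sparcc(
    counts: np.ndarray | pd.DataFrame,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame | np.ndarray:
    """sparCC correlation matrix for an M x N (components x samples) matrix.

    With fewer than four components the basis system is under-determined and
    the estimator falls back to CLR-Pearson with a warning.
    """
    index = None
    if isinstance(counts, pd.DataFrame):
        index = counts.index
        x = counts.to_numpy(dtype=float)
    else:
        x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("counts must be a 2-D components x samples matrix")
    m, n = x.shape
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation estimation, got {n}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    if m < 4:
        logger.warning("sparCC under-determined for M=%d < 4; falling back to CLR-Pearson", m)
        rho = clr_pearson(x, pseudocount)
        return pd.DataFrame(rho, index=index, columns=index) if index is not None else rho

    t = _log_ratio_variances(x, pseudocount)
    included = ~np.eye(m, dtype=bool)
    omega = _solve_basis_variances(t, included)
    rho = _correlations_from_variances(t, omega)

    for _ in range(n_iterations):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        masked[~included] = 0.0
        i, j = np.unravel_index(int(masked.argmax()), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        # Components excluded from nearly every pair no longer constrain the
        # system; keep at least 2 partners per component.
        omega = _solve_basis_variances(t, included)
        rho = _correlations_from_variances(t, omega)

    return pd.DataFrame(rho, index=index, columns=index) if index is not None else rho


# ---------------------------------------------------------------------------
# Network + modules
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[Hashable]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[Hashable, Hashable, float]]:
        return sorted((min(u, v), max(u, v), d["rho"]) for u, v, d in self.graph.edges(data=True))

    def to_edge_list(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("protein_a\tprotein_b\trho\n")
            for u, v, rho in self.edges:
                handle.write(f"{u}\t{v}\t{rho:.6f}\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class ProteinModule:
    module_id: str
    seed_members: tuple
    attached_members: tuple = ()
    phenotype: str | None = None
    phenotype_fractions: dict = field(default_factory=dict)

    @property
    def members(self) -> tuple:
        return tuple(sorted((*self.seed_members, *self.attached_members)))

    @property
    def size(self) -> int:
        return len(self.seed_members) + len(self.attached_members)


def build_network(
    corr: pd.DataFrame | np.ndarray,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    node_names: Sequence[Hashable] | None = None,
) -> CoexpressionNetwork:
    """Edge iff rho_ij >= threshold; isolated nodes are retained."""
    if isinstance(corr, pd.DataFrame):
        names = list(corr.index)
        values = corr.to_numpy()
    else:
        values = np.asarray(corr)
        names = list(node_names) if node_names is not None else list(range(values.shape[0]))
    if values.shape[0] != values.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")

    graph = nx.Graph()
    graph.add_nodes_from(names)
    m = len(names)
    for i in range(m):
        for j in range(i + 1, m):
            if values[i, j] >= threshold:
                graph.add_edge(names[i], names[j], rho=float(values[i, j]))
    return CoexpressionNetwork(graph=graph, threshold=threshold)


def _maximum_clique(graph: nx.Graph) -> tuple:
    """Exact maximum clique; deterministic tie-break by sorted node tuple."""
    best: tuple = ()
    for clique in nx.find_cliques(graph):
        candidate = tuple(sorted(clique))
        if len(candidate) > len(best) or (len(candidate) == len(best) and candidate < best):
            best = candidate
    return best


def _greedy_clique(graph: nx.Graph) -> tuple:
    """Degree-ordered greedy clique, for very large networks."""
    nodes = sorted(graph.nodes, key=lambda n: (-graph.degree(n), n))
    clique: list = []
    for node in nodes:
        if all(graph.has_edge(node, member) for member in clique):
            clique.append(node)
    return tuple(sorted(clique))


def extract_modules(
    network: CoexpressionNetwork,
    min_clique: int = 3,
    exact: bool = True,
) -> list[ProteinModule]:
    """Iterative maximum-clique seeds + best-shared-edges attachment.

    Seeds are extracted greedily: find a maximum clique of size >=
    ``min_clique``, record it, delete its nodes, repeat. Every remaining
    node connected to at least one seed is attached to the seed it shares
    the most edges with (ties: larger module, then smaller module id).
    """
    graph = network.graph.copy()
    finder = _maximum_clique if exact else _greedy_clique
    seeds: list[tuple] = []
    while graph.number_of_edges() > 0:
        clique = finder(graph)
        if len(clique) < min_clique:
            break
        seeds.append(clique)
        graph.remove_nodes_from(clique)

    modules = [
        ProteinModule(module_id=f"M{idx:04d}", seed_members=seed)
        for idx, seed in enumerate(seeds, start=1)
    ]
    seed_lookup = {m.module_id: set(m.seed_members) for m in modules}

    attached: dict[str, list] = {m.module_id: [] for m in modules}
    leftover = sorted(set(network.graph.nodes) - {n for s in seeds for n in s})
    for node in leftover:
        neighbors = set(network.graph.neighbors(node))
        best_id, best_key = None, None
        for module in modules:
            shared = len(neighbors & seed_lookup[module.module_id])
            if shared == 0:
                continue
            # more shared edges, then larger module, then smaller id
            key = (shared, module.size, [-ord(c) for c in module.module_id])
            if best_key is None or key > best_key:
                best_id, best_key = module.module_id, key
        if best_id is not None:
            attached[best_id].append(node)

    return [
        ProteinModule(
            module_id=m.module_id,
            seed_members=m.seed_members,
            attached_members=tuple(sorted(attached[m.module_id])),
        )
        for m in modules
    ]


def assign_module_phenotype(
    module: ProteinModule,
    normalized_counts: pd.DataFrame,
    manifest: SampleManifest,
    dominance: float = 0.75,
) -> tuple[str | None, dict[str, float]]:
    """Assign the phenotype holding >= ``dominance`` of module spectra, if any."""
    members = [m for m in module.members if m in normalized_counts.index]
    if not members:
        return None, {}
    sub = normalized_counts.loc[members]
    per_sample = sub.sum(axis=0)
    fractions: dict[str, float] = {}
    for sample, value in per_sample.items():
        ph = manifest.phenotype_of(sample)
        fractions[ph] = fractions.get(ph, 0.0) + float(value)
    total = sum(fractions.values())
    if total <= 0:
        return None, {}
    fractions = {ph: v / total for ph, v in fractions.items()}
    top = max(sorted(fractions), key=lambda ph: fractions[ph])
    if fractions[top] >= dominance:
        return top, fractions
    return None, fractions


def suggest_pathways(
    module: ProteinModule,
    network: CoexpressionNetwork,
    annotations: Mapping[Hashable, set[str]],
) -> dict[Hashable, set[str]]:
    """Guilt-by-association pathway suggestions for unannotated members.

    An unannotated protein inherits the union of the pathways of annotated
    proteins it shares a (module-internal) edge with.
    """
    members = set(module.members)
    suggestions: dict[Hashable, set[str]] = {}
    for node in sorted(members):
        if annotations.get(node):
            continue
        pooled: set[str] = set()
        for neighbor in network.graph.neighbors(node):
            if neighbor in members and annotations.get(neighbor):
                pooled |= set(annotations[neighbor])
        if pooled:
            suggestions[node] = pooled
    return suggestions


def modules_to_table(modules: Iterable[ProteinModule]) -> pd.DataFrame:
    rows = []
    for module in modules:
        for node in module.seed_members:
            rows.append({"module_id": module.module_id, "protein_id": node,
                         "role": "seed", "phenotype": module.phenotype or ""})
        for node in module.attached_members:
            rows.append({"module_id": module.module_id, "protein_id": node,
                         "role": "attached", "phenotype": module.phenotype or ""})
    return pd.DataFrame(rows, columns=["module_id", "protein_id", "role", "phenotype"])
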