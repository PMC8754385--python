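"""Edgewise heritability and the network-based statistics (NBS) test.

Heritability is estimated independently for every connectivity edge,
yielding a symmetric node x node h2 matrix. The NBS-style test then asks
whether the largest connected component formed by edges with h2 above a
threshold is bigger than expected when twin identity (zygosity) is
permuted. Component size is measured in edges, with node count reported
alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .ace import h2_from_sq_diffs, lrsd_ace, pair_sq_diffs
from .cohort import TwinCohort
from .containers import FCMatrixStack
from .permutation import dz_indicator_permutations


@dataclass
class H2Matrix:
    """Symmetric node x node heritability matrix (zero diagonal)."""

    values: np.ndarray
    node_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("h2 matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("h2 matrix must be symmetric")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("h2 values must lie in [0, 1]")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ComponentResult:
    """Largest supra-threshold connected component of an h2 matrix."""

    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)
    size_edges: int = 0
    size_nodes: int = 0
    threshold: float = np.nan
    p_perm: float = np.nan

    def to_json(self, path=None) -> str:
        payload = {
            "threshold": self.threshold,
            "size_edges": self.size_edges,
            "size_nodes": self.size_nodes,
            "p_perm": None if np.isnan(self.p_perm) else self.p_perm,
            "nodes": [int(n) for n in self.nodes],
            "edges": [[int(a), int(b)] for a, b in self.edges],
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def edgewise_h2(fc: FCMatrixStack, cohort: TwinCohort) -> H2Matrix:
    """Fit the squared-differences ACE model to every edge of an FC stack."""
    pheno = pd.DataFrame(
        fc.edge_matrix(), index=pd.Index(fc.subject_ids, name="subject_id")
    )
    pheno.columns = [f"edge{k:06d}" for k in range(pheno.shape[1])]
    res = lrsd_ace(pheno, cohort)
    h2 = np.nan_to_num(res["h2"].to_numpy(), nan=0.0)
    n = fc.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    mat = np.zeros((n, n))
    mat[iu, ju] = h2
    mat[ju, iu] = h2
    return H2Matrix(mat, node_meta=fc.node_meta)


def _largest_from_edge_values(
    edge_vals: np.ndarray, tau: float, iu: np.ndarray, ju: np.ndarray, n_nodes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nodes and edges of the largest component after binarizing at > tau.

    Ties are broken by edge count, then node count, then smallest minimum
    node id, so the output is deterministic.
    """
    keep = edge_vals > tau
    if not keep.any():
        return np.array([], dtype=int), np.empty((0, 2), dtype=int), np.zeros(0, dtype=int)
    ei, ej = iu[keep], ju[keep]
    adj = sparse.coo_matrix(
        (np.ones(ei.size), (ei, ej)), shape=(n_nodes, n_nodes)
    ).tocsr()
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    edge_labels = labels[ei]
    edge_counts = np.bincount(edge_labels, minlength=n_comp)
    node_counts = np.bincount(labels, minlength=n_comp)
    # candidate components ranked: most edges, most nodes, smallest min node id
    best, best_key = None, None
    for comp in np.flatnonzero(edge_counts == edge_counts.max()):
        members = np.flatnonzero(labels == comp)
        key = (-edge_counts[comp], -node_counts[comp], members.min())
        if best_key is None or key < best_key:
            best, best_key = comp, key
    members = np.flatnonzero(labels == best)
    emask = edge_labels == best
    edges = np.column_stack([ei[emask], ej[emask]])
    return members, edges, edge_counts


def largest_component(h2m: H2Matrix | np.ndarray, tau: float) -> ComponentResult:
    """Largest connected component of edges with h2 strictly above ``tau``."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must lie in [0, 1]")
    vals = h2m.values if isinstance(h2m, H2Matrix) else np.asarray(h2m, float)
    n = vals.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    members, edges, _ = _largest_from_edge_values(vals[iu, ju], tau, iu, ju, n)
    return ComponentResult(
        nodes=members.tolist(),
        edges=[tuple(e) for e in edges],
        size_edges=len(edges),
        size_nodes=len(members),
        threshold=tau,
    )


def _null_component_sizes(
    d: np.ndarray,
    var_p: np.ndarray,
    cohort: TwinCohort,
    taus: np.ndarray,
    n_perm: int,
    seed: int,
    iu: np.ndarray,
    ju: np.ndarray,
    n_nodes: int,
) -> np.ndarray:
    """(n_perm, n_taus) matrix of largest-component edge counts under the null."""
    rng = np.random.default_rng(seed)
    Z = dz_indicator_permutations(cohort.n_mz_pairs, cohort.n_dz_pairs, n_perm, rng)
    h2_perm, _, _ = h2_from_sq_diffs(d, Z, var_p)  # (n_perm, n_edges)
    h2_perm = np.nan_to_num(h2_perm, nan=0.0)
    out = np.zeros((n_perm, len(taus)), dtype=int)
    for m in range(n_perm):
        for t_idx, tau in enumerate(taus):
            _, _, edge_counts = _largest_from_edge_values(h2_perm[m], tau, iu, ju, n_nodes)
            out[m, t_idx] = edge_counts.max() if edge_counts.size else 0
    return out


def nbs_h2_test(
    fc: FCMatrixStack,
    cohort: TwinCohort,
    tau: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> ComponentResult:
    """Permutation test for a heritable connected component at threshold ``tau``.

    The observed largest component of the edgewise h2 matrix is compared
    with the distribution of largest-component edge counts obtained by
    recomputing the h2 matrix under permuted twin identity (zygosity
    shuffled across pairs): p = (1 + #{perm size >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    comp = largest_component(edgewise_h2(fc, cohort), tau)
    pheno = fc.edge_matrix()
    d, _, var_p = pair_sq_diffs(pheno, cohort)
    iu, ju = fc.edge_index()
    null = _null_component_sizes(
        d, var_p, cohort, np.array([tau]), n_perm, seed, iu, ju, fc.n_nodes
    )[:, 0]
    comp.p_perm = (1.0 + (null >= comp.size_edges).sum()) / (n_perm + 1.0)
    return comp


def threshold_sweep(
    fc: FCMatrixStack,
    cohort: TwinCohort,
    taus,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """NBS test over a grid of thresholds sharing one permutation stream.

    The same permuted h2 matrices are re-thresholded for every tau, so the
    sweep is internally consistent and costs one permutation pass. Returns
    a table with columns tau, size_edges, size_nodes, p_perm.
    """
    taus = np.asarray(list(taus), dtype=float)
    if np.any(np.diff(taus) < 0):
        raise ValueError("taus must be sorted ascending")
    h2m = edgewise_h2(fc, cohort)
    d, _, var_p = pair_sq_diffs(fc.edge_matrix(), cohort)
    iu, ju = fc.edge_index()
    null = _null_component_sizes(d, var_p, cohort, taus, n_perm, seed, iu, ju, fc.n_nodes)
    rows = []
    for t_idx, tau in enumerate(taus):
        comp = largest_component(h2m, tau)
        p = (1.0 + (null[:, t_idx] >= comp.size_edges).sum()) / (n_perm + 1.0)
        rows.append(
            {
                "tau": tau,
                "size_edges": comp.size_edges,
                "size_nodes": comp.size_nodes,
                "p_perm": p,
            }
        )
    return pd.DataFrame(rows)


def component_network_edge_counts(comp: ComponentResult, labels) -> pd.DataFrame:
    """Count component edges within and between large-scale networks."""
    if isinstance(labels, pd.DataFrame):
        labels = labels.set_index("node_id")["network"] if "node_id" in labels else labels
    get = (lambda n: labels[n]) if not isinstance(labels, dict) else labels.__getitem__
    try:
        nets_of_edges = [(get(a), get(b)) for a, b in comp.edges]
        node_nets = {get(n) for n in comp.nodes}
    except (KeyError, IndexError) as err:
        raise ValueError(f"unlabeled node: {err}") from err
    nets = sorted(node_nets | {n for e in nets_of_edges for n in e})
    out = pd.DataFrame(0, index=nets, columns=nets, dtype=int)
    for a, b in nets_of_edges:
        if a == b:
            out.loc[a, a] += 1
        else:
            out.loc[a, b] += 1
            out.loc[b, a] += 1
    return out


def node_overlap(comp: ComponentResult, node_set) -> tuple[int, int]:
    """Component nodes inside vs outside an a-priori node set (e.g. a pain map)."""
    node_set = set(node_set)
    inside = sum(1 for n in comp.nodes if n in node_set)
    return inside, comp.size_nodes - inside
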