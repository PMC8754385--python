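"""Permutation-based family-wise error control and twin-design power.

The permutation scheme shuffles zygosity labels across intact pairs. This
preserves within-pair dependence and the MZ/DZ pair counts while breaking
the differential genetic sharing that identifies additive-genetic variance,
so it is a valid null for any statistic that contrasts MZ with DZ pairs.
All p-values use the (1 + b) / (m + 1) convention and are therefore never
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .ace import _slope_t, boundary_p, pair_sq_diffs
from .cohort import TwinCohort, simulate_cohort
from .simulate import ACEParams, simulate_ace_phenotypes


@dataclass
class PermutationScheme:
    n_perm: int = 1000
    seed: int = 0
    scheme: str = "zygosity_shuffle"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scheme != "zygosity_shuffle":
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")


@dataclass
class ClusterResult:
    """One supra-threshold cluster with its permutation FWE p-value."""

    cluster_id: int
    members: list = field(default_factory=list)
    extent: int = 0
    fwe_p: float = np.nan


def permute_zygosity(cohort: TwinCohort, seed: int) -> TwinCohort:
    """Randomly reassign MZ/DZ labels across pairs, preserving both counts."""
    if cohort.n_pairs < 2:
        raise ValueError("need at least 2 pairs to permute")
    rng = np.random.default_rng(seed)
    pz = cohort.table.groupby("pair_id", sort=False)["zygosity"].first()
    labels = rng.permutation(pz.to_numpy())
    return cohort.with_zygosity(dict(zip(pz.index, labels)))


def dz_indicator_permutations(n_mz: int, n_dz: int, n_perm: int, rng) -> np.ndarray:
    """(n_perm, n_pairs) matrix of permuted DZ indicators with fixed counts."""
    base = np.concatenate([np.zeros(n_mz), np.ones(n_dz)])
    order = np.argsort(rng.random((n_perm, base.size)), axis=1)
    return base[order]


def elementwise_fwe(pheno, cohort: TwinCohort, scheme: PermutationScheme) -> pd.DataFrame:
    """Max-statistic permutation FWE p-values for every phenotype element.

    The observed one-sided A>0 statistic per element is compared against
    the permutation distribution of the maximum statistic over elements:
    p_e = (1 + #{perm: max_e' stat >= stat_e}) / (n_perm + 1).
    """
    d, is_dz, var_p = pair_sq_diffs(pheno, cohort)
    good = var_p > 0
    if not good.all():
        import logging

        logging.getLogger("twinconn").warning(
            "excluding %d degenerate element(s) from FWE", (~good).sum()
        )
    slope, _, t_obs = _slope_t(d[:, good], is_dz)
    rng = np.random.default_rng(scheme.seed)
    Z = dz_indicator_permutations(cohort.n_mz_pairs, cohort.n_dz_pairs, scheme.n_perm, rng)
    _, _, t_perm = _slope_t(d[:, good], Z)
    max_null = t_perm.max(axis=1)  # (n_perm,)
    exceed = (max_null[:, None] >= t_obs[None, :]).sum(axis=0)
    fwe = (1.0 + exceed) / (scheme.n_perm + 1.0)
    cols = pheno.columns if isinstance(pheno, pd.DataFrame) else np.arange(d.shape[1])
    out = pd.DataFrame(
        {"stat_A": np.nan, "p_unadj": np.nan, "fwe_p": np.nan},
        index=pd.Index(cols, name="element"),
    )
    out.loc[out.index[good], "stat_A"] = t_obs
    out.loc[out.index[good], "p_unadj"] = boundary_p(slope, t_obs)
    out.loc[out.index[good], "fwe_p"] = fwe
    return out


def _components_of(members: np.ndarray, adjacency: sparse.spmatrix) -> list:
    """Connected components of the subgraph induced by ``members``."""
    if members.size == 0:
        return []
    sub = adjacency[members][:, members]
    n_comp, labels = connected_components(sub, directed=False)
    return [members[labels == k] for k in range(n_comp)]


def _as_adjacency(adjacency, n_elements: int) -> sparse.csr_matrix:
    if sparse.issparse(adjacency):
        return adjacency.tocsr()
    try:
        import networkx as nx

        if isinstance(adjacency, nx.Graph):
            return nx.to_scipy_sparse_array(adjacency, nodelist=range(n_elements)).tocsr()
    except ImportError:  # pragma: no cover
        pass
    return sparse.csr_matrix(np.asarray(adjacency))


def cluster_fwe(
    pheno,
    cohort: TwinCohort,
    adjacency,
    scheme: PermutationScheme,
    forming_p: float = 0.05,
) -> list[ClusterResult]:
    """Cluster-extent FWE inference on the element-wise A>0 statistic map.

    Elements with parametric p below ``forming_p`` are grouped into
    connected clusters under ``adjacency`` (an element graph: scipy sparse
    matrix, dense 0/1 array or networkx graph over element indices). The
    null distribution of the maximum cluster extent is built by zygosity
    permutation; each observed cluster gets fwe_p = (1 + #{perm: max
    extent >= its extent}) / (n_perm + 1).
    """
    d, is_dz, var_p = pair_sq_diffs(pheno, cohort)
    n_elem = d.shape[1]
    adj = _as_adjacency(adjacency, n_elem)
    if adj.shape[0] != n_elem:
        raise ValueError("adjacency must cover all elements")

    slope, _, t_obs = _slope_t(d, is_dz)
    p_obs = boundary_p(slope, t_obs)
    supra = np.flatnonzero(p_obs < forming_p)
    clusters = _components_of(supra, adj)

    rng = np.random.default_rng(scheme.seed)
    Z = dz_indicator_permutations(cohort.n_mz_pairs, cohort.n_dz_pairs, scheme.n_perm, rng)
    slope_p, _, t_p = _slope_t(d, Z)
    p_perm = boundary_p(slope_p, t_p)
    null_max = np.zeros(scheme.n_perm, dtype=int)
    for m in range(scheme.n_perm):
        comps = _components_of(np.flatnonzero(p_perm[m] < forming_p), adj)
        null_max[m] = max((len(c) for c in comps), default=0)

    out = []
    for k, members in enumerate(sorted(clusters, key=len, reverse=True)):
        extent = len(members)
        fwe = (1.0 + (null_max >= extent).sum()) / (scheme.n_perm + 1.0)
        out.append(ClusterResult(cluster_id=k, members=members.tolist(), extent=extent, fwe_p=fwe))
    return out


def twin_power_curve(
    n_mz: int,
    n_dz: int,
    a_grid,
    alpha: float = 0.05,
    n_rep: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Simulated power of the A>0 test across additive-genetic fractions.

    For each ``a`` in the grid, ``n_rep`` independent phenotypes with
    (A, C, E) = (a, 0, 1 - a) are generated on a fresh cohort of
    ``n_mz`` + ``n_dz`` pairs and tested with the squared-differences
    regression at level ``alpha``. Returns the power table and the
    additive-genetic fraction at which power first crosses 0.80 (linear
    interpolation between grid points; NaN if never reached).
    """
    a_grid = list(a_grid)
    if not a_grid:
        raise ValueError("a_grid must be nonempty")
    if any(not 0 <= a < 1 for a in a_grid):
        raise ValueError("additive fractions must lie in [0, 1)")
    cohort = simulate_cohort(n_mz, n_dz, seed=seed)
    rows = []
    for k, a in enumerate(a_grid):
        params = [ACEParams(A=a, C=0.0, E=1.0 - a)] * n_rep
        pheno = simulate_ace_phenotypes(cohort, params, seed=seed + 10_000 + k)
        d, is_dz, _ = pair_sq_diffs(pheno, cohort)
        slope, _, t = _slope_t(d, is_dz)
        p = boundary_p(slope, t)
        rows.append({"a": a, "power": float((p < alpha).mean())})
    table = pd.DataFrame(rows)

    crossing = np.nan
    pw = table["power"].to_numpy()
    if pw[0] >= 0.8:
        crossing = float(table["a"].iloc[0])
    else:
        for k in range(1, len(pw)):
            if pw[k] >= 0.8:
                a0, a1 = table["a"].iloc[k - 1], table["a"].iloc[k]
                crossing = float(a0 + (0.8 - pw[k - 1]) * (a1 - a0) / (pw[k] - pw[k - 1]))
                break
    return table, crossing
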