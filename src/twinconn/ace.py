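"""ACE variance decomposition for twin phenotypes.

Two estimators are provided. :func:`falconer_ace` is the classical contrast
of twin-pair correlations (A = 2(rMZ - rDZ), C = 2 rDZ - rMZ, E = 1 - rMZ).
:func:`lrsd_ace` is the non-iterative regression of squared within-pair
differences on zygosity: with d_p = (y_p1 - y_p2)^2 and z = 1 for DZ pairs,

    E[d | z] = 2 sigma2_E + z * sigma2_A,

so the intercept halves to the unique-environment variance and the slope is
the additive-genetic variance; the shared-environment variance follows from
the pooled phenotypic variance. The one-sided test for A > 0 uses the
regression t statistic with a boundary null of 1/2 point mass at zero plus
1/2 chi-square(1) on the squared statistic. Both estimators report
heritability h2 = A / (A + C + E).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .cohort import TwinCohort


@dataclass
class ACEEstimate:
    """Constrained variance components with the raw (unconstrained) values."""

    A: float
    C: float
    E: float
    h2: float
    raw_A: float = np.nan
    raw_C: float = np.nan
    raw_E: float = np.nan
    stat_A: float = np.nan
    p_A: float = np.nan


def _constrain(raw_a, raw_e, total):
    """Truncate negative components, A first, preserving the total where possible."""
    a = np.maximum(raw_a, 0.0)
    c = np.maximum(total - a - raw_e, 0.0)
    e = np.maximum(raw_e, 0.0)
    return a, c, e


def falconer_ace(r_mz: float, r_dz: float) -> ACEEstimate:
    """ACE estimates from observed MZ and DZ twin-pair correlations."""
    if not (-1 <= r_mz <= 1 and -1 <= r_dz <= 1):
        raise ValueError("correlations must lie in [-1, 1]")
    raw_a = 2.0 * (r_mz - r_dz)
    raw_c = 2.0 * r_dz - r_mz
    raw_e = 1.0 - r_mz
    a, c, e = _constrain(raw_a, raw_e, 1.0)
    tot = a + c + e
    h2 = a / tot if tot > 0 else np.nan
    return ACEEstimate(A=a, C=c, E=e, h2=h2, raw_A=raw_a, raw_C=raw_c, raw_E=raw_e)


def _as_array(pheno, cohort: TwinCohort) -> np.ndarray:
    """Align a phenotype matrix to cohort row order; returns subjects x elements."""
    if isinstance(pheno, pd.DataFrame):
        missing = set(cohort.subject_ids) - set(pheno.index)
        if missing:
            raise ValueError(f"phenotypes missing for subjects: {sorted(missing)[:5]}")
        arr = pheno.loc[list(cohort.subject_ids)].to_numpy(float)
    else:
        arr = np.asarray(pheno, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != cohort.n_subjects:
            raise ValueError("phenotype rows must match cohort subjects")
    return arr


def residualize_covariates(pheno: np.ndarray, covariates) -> np.ndarray:
    """Remove covariate effects (with intercept) from each element by OLS."""
    X = np.column_stack([np.ones(pheno.shape[0]), np.asarray(covariates, float)])
    beta, *_ = np.linalg.lstsq(X, pheno, rcond=None)
    return pheno - X @ beta


def pair_sq_diffs(pheno, cohort: TwinCohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Squared within-pair differences and pooled variance per element.

    Returns ``(d, is_dz, var_p)``: d has shape (n_pairs, n_elements),
    ``is_dz`` is the DZ indicator per pair, ``var_p`` the pooled sample
    variance per element across all subjects.
    """
    arr = _as_array(pheno, cohort)
    first, second, is_dz = cohort.pair_index()
    d = (arr[first] - arr[second]) ** 2
    var_p = arr.var(axis=0, ddof=1)
    return d, is_dz.astype(float), var_p


def _slope_t(d: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of d on [1, z] per element: slope, intercept and t for slope > 0.

    ``z`` may be a single indicator vector or an (n_perm, n_pairs) matrix of
    permuted indicators; slope/intercept/t then gain a leading perm axis.
    """
    d = np.atleast_2d(d)
    n = d.shape[0]
    z2 = np.atleast_2d(z)  # (n_perm, n_pairs)
    zbar = z2.mean(axis=1, keepdims=True)
    zc = z2 - zbar
    szz = (zc**2).sum(axis=1, keepdims=True)
    dbar = d.mean(axis=0)
    slope = (zc @ d) / szz
    intercept = dbar[None, :] - slope * zbar
    sstot = ((d - dbar) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.maximum(sstot[None, :] - slope**2 * szz, 0.0) / max(n - 2, 1)
        t = slope / np.sqrt(s2 / szz)
    t = np.where(slope > 0, np.nan_to_num(t), 0.0)
    if np.ndim(z) == 1:
        return slope[0], intercept[0], t[0]
    return slope, intercept, t


def boundary_p(slope: np.ndarray, t: np.ndarray) -> np.ndarray:
    """p-value under the boundary mixture null 1/2 delta_0 + 1/2 chi2(1).

    One-sided for A > 0: p = 0.5 * P(chi2_1 >= t^2) when the slope is
    positive, and p = 1 at or below the boundary (slope <= 0).
    """
    p = np.where(np.asarray(slope) > 0, 0.5 * sstats.chi2.sf(np.asarray(t) ** 2, df=1), 1.0)
    return p


def h2_from_sq_diffs(
    d: np.ndarray, z: np.ndarray, var_p: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constrained (A, C, E) -> h2 plus test stat and p, vectorized.

    Accepts a permutation matrix for ``z`` exactly like :func:`_slope_t`;
    used by the permutation machinery to recompute h2 maps cheaply.
    """
    slope, intercept, t = _slope_t(d, z)
    raw_e = intercept / 2.0
    a, c, e = _constrain(slope, raw_e, var_p)
    tot = a + c + e
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(tot > 0, a / np.where(tot > 0, tot, 1.0), np.nan)
    return h2, t, boundary_p(slope, t)


def lrsd_ace(pheno, cohort: TwinCohort, covariates=None) -> pd.DataFrame:
    """Per-element ACE estimates by the squared-differences regression.

    ``pheno`` is a subjects x elements DataFrame (indexed by subject_id) or
    array aligned with the cohort. Optional ``covariates`` (subjects x k)
    are residualized out first. Returns one row per element with columns
    raw_A, raw_C, raw_E, A, C, E, h2, stat_A, p_A; elements with zero
    phenotypic variance get NaN h2.
    """
    if cohort.n_mz_pairs < 2 or cohort.n_dz_pairs < 2:
        raise ValueError("need at least 2 MZ and 2 DZ pairs")
    arr = _as_array(pheno, cohort)
    if covariates is not None:
        arr = residualize_covariates(arr, covariates)
    arr = arr - arr.mean(axis=0)
    d, is_dz, var_p = pair_sq_diffs(arr, cohort)
    slope, intercept, t = _slope_t(d, is_dz)
    raw_e = intercept / 2.0
    raw_c = var_p - slope - raw_e
    a, c, e = _constrain(slope, raw_e, var_p)
    tot = a + c + e
    degenerate = var_p <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where((tot > 0) & ~degenerate, a / np.where(tot > 0, tot, 1.0), np.nan)
    p = boundary_p(slope, t)
    cols = (
        pheno.columns
        if isinstance(pheno, pd.DataFrame)
        else [f"e{k:04d}" for k in range(arr.shape[1])]
    )
    return pd.DataFrame(
        {
            "raw_A": slope,
            "raw_C": raw_c,
            "raw_E": raw_e,
            "A": a,
            "C": c,
            "E": e,
            "var_p": var_p,
            "h2": h2,
            "stat_A": np.where(degenerate, np.nan, t),
            "p_A": np.where(degenerate, np.nan, p),
        },
        index=pd.Index(cols, name="element"),
    )


def a_test_statistic(y, cohort: TwinCohort) -> tuple[float, float]:
    """One-sided test for additive-genetic variance on a single element."""
    res = lrsd_ace(np.asarray(y, float).reshape(-1, 1), cohort)
    return float(res["stat_A"].iloc[0]), float(res["p_A"].iloc[0])
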