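import numpy as np
import pandas as pd
import pytest

from twinconn import ACEParams, simulate_ace_phenotypes, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(6, 8, seed=42)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for moment-convergence checks."""
    return simulate_cohort(2000, 2000, seed=7)


@pytest.fixture(scope="session")
def big_pheno(big_cohort):
    """One phenotype with (A, C, E) = (0.5, 0.2, 0.3) on the large cohort."""
    return simulate_ace_phenotypes(big_cohort, ACEParams(0.5, 0.2, 0.3), seed=11)


@pytest.fixture(scope="session")
def huge_cohort():
    """Asymptotic-scale cohort for estimator-agreement checks."""
    return simulate_cohort(5000, 5000, seed=13)


@pytest.fixture(scope="session")
def huge_pheno(huge_cohort):
    return simulate_ace_phenotypes(huge_cohort, ACEParams(0.5, 0.2, 0.3), seed=17)


def pair_correlations(cohort, values: np.ndarray) -> tuple[float, float]:
    """Empirical MZ and DZ within-pair Pearson correlations."""
    first, second, is_dz = cohort.pair_index()
    r_mz = np.corrcoef(values[first[~is_dz]], values[second[~is_dz]])[0, 1]
    r_dz = np.corrcoef(values[first[is_dz]], values[second[is_dz]])[0, 1]
    return float(r_mz), float(r_dz)


@pytest.fixture(scope="session")
def roster_305():
    """Recruitment roster reproducing the published exclusion arithmetic.

    305 scanned subjects: 152 complete pairs plus one twin whose co-twin
    was never scanned. QC flags: 8 full pairs high motion (16), 4 seed
    outliers whose co-twin removal makes 8, and 35 subjects with missing
    data (17 full pairs plus the lone twin).
    """
    from twinconn import TwinCohort

    rows, pairs, sid = [], [], 0
    for p in range(152):
        ids = []
        for _ in range(2):
            sid += 1
            ids.append(f"s{sid:04d}")
            rows.append((ids[-1], f"p{p:04d}", "MZ" if p < 70 else "DZ", "F", 30))
        pairs.append(ids)
    sid += 1
    lone = f"s{sid:04d}"
    rows.append((lone, "p9999", "DZ", "F", 30))
    cohort = TwinCohort(
        pd.DataFrame(rows, columns=["subject_id", "pair_id", "zygosity", "sex", "age"]),
        require_complete_pairs=False,
    )
    motion = {s for pr in pairs[:8] for s in pr}
    outlier_seeds = {pr[0] for pr in pairs[8:12]}
    missing = {s for pr in pairs[12:29] for s in pr} | {lone}
    qc = pd.DataFrame(
        {
            "subject_id": cohort.subject_ids,
            "high_motion": [s in motion for s in cohort.subject_ids],
            "outlier_summary": [50.0 if s in outlier_seeds else 0.0 for s in cohort.subject_ids],
            "missing": [s in missing for s in cohort.subject_ids],
        }
    )
    return cohort, qc
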