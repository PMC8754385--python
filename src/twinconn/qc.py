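"""Subject-level quality control and exclusion.

Three screening rules are applied before any heritability analysis: head
motion (more than half of the volumes with framewise displacement above
0.5 mm), robust amplitude outliers (scaled-MAD rule, removed together with
the co-twin), and missing data. Because all inference is pair-based, the
final roster is always restricted to intact twin pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import TwinCohort
from .containers import MOTION_COLUMNS

MAD_SCALE = 1.4826  # scaled MAD estimates the SD under normality


def framewise_displacement(motion) -> np.ndarray:
    """Per-volume framewise displacement in mm.

    FD(t) = sum of absolute backward differences of the 3 translations (mm)
    plus 50 mm times those of the 3 rotations (radians), i.e. rotations are
    converted to arc length on a 50 mm sphere. FD of the first volume is 0.
    """
    if isinstance(motion, pd.DataFrame):
        cols = [c for c in MOTION_COLUMNS if c in motion.columns]
        m = motion[cols].to_numpy(float) if len(cols) == 6 else motion.to_numpy(float)
    else:
        m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion table must have 6 columns (3 translations, 3 rotations)")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + 50.0 * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def high_motion_flag(fd: np.ndarray, fd_thresh: float = 0.5, prop_thresh: float = 0.5) -> bool:
    """True iff the fraction of volumes with FD strictly above ``fd_thresh``
    strictly exceeds ``prop_thresh``."""
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    return bool((fd > fd_thresh).sum() / fd.size > prop_thresh)


def mad_outlier_flags(values, k: float = 3.0) -> np.ndarray:
    """Robust outlier flags: |x - median| > k * 1.4826 * MAD.

    With the 1.4826 scaling the rule approximates "more than k robust
    standard deviations from the center". When MAD is zero (all values
    equal up to the median) only strictly deviating values are flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for a robust scale")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return np.abs(x - med) > k * MAD_SCALE * mad


@dataclass
class ExclusionReport:
    """Per-stage exclusion bookkeeping for one cohort."""

    excluded_motion: list = field(default_factory=list)
    excluded_outlier: list = field(default_factory=list)
    excluded_missing: list = field(default_factory=list)
    excluded_unpaired: list = field(default_factory=list)
    n_recruited: int = 0
    n_final: int = 0

    @property
    def n_excluded(self) -> int:
        return len(
            set(self.excluded_motion)
            | set(self.excluded_outlier)
            | set(self.excluded_missing)
            | set(self.excluded_unpaired)
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def apply_exclusions(
    cohort: TwinCohort,
    qc: pd.DataFrame,
    mad_k: float = 3.0,
    remove_cotwin_motion: bool = True,
) -> tuple[TwinCohort, ExclusionReport]:
    """Apply the motion -> outlier -> missing exclusion cascade.

    ``qc`` must cover every subject, with columns ``subject_id``,
    ``high_motion`` (bool), ``outlier_summary`` (scalar fed to the MAD
    rule, NaN to skip) and ``missing`` (bool). Outliers are removed
    together with their co-twin; the MAD rule is evaluated on subjects
    surviving the motion stage. Finally any subject left without a co-twin
    is dropped so only intact pairs remain. Each exclusion is counted at
    the first stage that triggers it.
    """
    needed = {"subject_id", "high_motion", "outlier_summary", "missing"}
    if not needed <= set(qc.columns):
        raise ValueError(f"qc table needs columns {sorted(needed)}")
    qc = qc.set_index("subject_id", drop=False)
    roster = list(cohort.subject_ids)
    unknown = set(roster) - set(qc.index)
    if unknown:
        raise ValueError(f"qc table does not cover subjects: {sorted(unknown)[:5]}")
    cotwin = cohort.co_twin_map()
    removed: set = set()

    # stage 1: head motion
    motion_out = [s for s in roster if bool(qc.loc[s, "high_motion"])]
    if remove_cotwin_motion:
        motion_out = sorted(set(motion_out) | {cotwin[s] for s in motion_out if s in cotwin})
    removed |= set(motion_out)

    # stage 2: robust amplitude outliers (+ co-twins), on survivors
    survivors = [s for s in roster if s not in removed]
    vals = qc.loc[survivors, "outlier_summary"].to_numpy(float)
    ok = ~np.isnan(vals)
    outlier_out: list = []
    if ok.sum() >= 3:
        flags = np.zeros(len(survivors), dtype=bool)
        flags[ok] = mad_outlier_flags(vals[ok], k=mad_k)
        hit = [s for s, f in zip(survivors, flags) if f]
        outlier_out = sorted((set(hit) | {cotwin[s] for s in hit if s in cotwin}) - removed)
    removed |= set(outlier_out)

    # stage 3: missing / incomplete data
    missing_out = [
        s for s in roster if s not in removed and bool(qc.loc[s, "missing"])
    ]
    removed |= set(missing_out)

    # final sweep: intact pairs only
    left = [s for s in roster if s not in removed]
    left_set = set(left)
    unpaired = [s for s in left if cotwin.get(s) not in left_set]
    removed |= set(unpaired)

    final = cohort.subset([s for s in roster if s not in removed])
    report = ExclusionReport(
        excluded_motion=sorted(motion_out),
        excluded_outlier=sorted(outlier_out),
        excluded_missing=sorted(missing_out),
        excluded_unpaired=sorted(unpaired),
        n_recruited=len(roster),
        n_final=final.n_subjects,
    )
    return final, report
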