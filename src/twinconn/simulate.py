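"""Synthetic twin-cohort data generation.

Every downstream stage of the package (QC, task FC, ACE mapping, permutation
inference, network statistics) is exercised on data produced here. The
generator plants known ground truth:

* phenotypes with an exact ACE covariance structure, built from latent
  additive-genetic, shared-environment and unique-environment factors, so
  MZ pairs correlate at A + C and DZ pairs at A/2 + C;
* an aversive-conditioning event schedule (16 six-second cues, 8 of them
  reinforced by a 3-s electrical stimulus, 8-12 s jittered inter-stimulus
  intervals, total run under 9 min 47 s);
* ROI time series whose designated node pairs gain extra shared signal
  during reinforced-cue frames, with the gain itself ACE-structured across
  twins; and
* motion-parameter traces with optional injected displacement spikes for
  exclusion testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import TwinCohort
from .containers import (
    CS_PLUS_NOUS,
    CS_PLUS_US,
    MOTION_COLUMNS,
    US,
    FCMatrixStack,
    RoiTimeSeries,
    stack_from_edges,
    validate_events,
)


@dataclass(frozen=True)
class ACEParams:
    """Variance fractions of the ACE decomposition (generator convention A+C+E=1).

    A is additive-genetic variance, C shared-environment variance, E unique
    environment (including measurement error); heritability is h2 = A/(A+C+E).
    """

    A: float
    C: float
    E: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.C < 0 or self.E <= 0:
            raise ValueError("require A >= 0, C >= 0, E > 0")
        if abs(self.A + self.C + self.E - 1.0) > 1e-8:
            raise ValueError("A + C + E must equal 1")


def simulate_ace_phenotypes(
    cohort: TwinCohort,
    params_per_element: Sequence[ACEParams] | ACEParams,
    seed: int,
) -> pd.DataFrame:
    """Draw unit-variance phenotypes with exact twin ACE structure.

    For each element, y = sqrt(A) a + sqrt(C) c + sqrt(E) e. The additive
    factor a is identical within MZ pairs; within DZ pairs each twin gets
    a = sqrt(1/2) a_pair + sqrt(1/2) a_own, giving the 0.5 genetic
    correlation of full siblings. c is shared within every pair, e is
    individual. Twin-pair correlations are therefore rMZ = A + C and
    rDZ = A/2 + C exactly in expectation.

    Returns a subjects x elements DataFrame indexed by subject_id.
    """
    if isinstance(params_per_element, ACEParams):
        params_per_element = [params_per_element]
    params = list(params_per_element)
    if not params:
        raise ValueError("need at least one element")
    A = np.array([p.A for p in params])
    C = np.array([p.C for p in params])
    E = np.array([p.E for p in params])

    first, second, is_dz = cohort.pair_index()
    n_pairs, n_elem = len(first), len(params)
    rng = np.random.default_rng(seed)

    a_pair = rng.standard_normal((n_pairs, 1, n_elem))
    a_own = rng.standard_normal((n_pairs, 2, n_elem))
    c_pair = rng.standard_normal((n_pairs, 1, n_elem))
    e_own = rng.standard_normal((n_pairs, 2, n_elem))

    a = np.where(is_dz[:, None, None], np.sqrt(0.5) * a_pair + np.sqrt(0.5) * a_own, a_pair)
    y = np.sqrt(A) * a + np.sqrt(C) * c_pair + np.sqrt(E) * e_own

    out = np.empty((cohort.n_subjects, n_elem))
    out[first] = y[:, 0, :]
    out[second] = y[:, 1, :]
    cols = [f"e{k:04d}" for k in range(n_elem)]
    return pd.DataFrame(out, index=pd.Index(cohort.subject_ids, name="subject_id"), columns=cols)


def simulate_task_events(
    seed: int,
    n_cues: int = 16,
    n_reinforced: int = 8,
    cue_duration: float = 6.0,
    us_duration: float = 3.0,
    isi_range: tuple[float, float] = (8.0, 12.0),
    max_total: float = 587.0,
) -> pd.DataFrame:
    """Generate one conditioning-run event table.

    Defaults mirror the paradigm the package targets: 16 aversive cues of
    6 s, half co-terminating with a brief electrical stimulus (modelled as
    a 3-s US regressor starting at cue offset), inter-stimulus intervals
    jittered uniformly on 8-12 s, run length capped at 9 min 47 s.
    """
    if n_reinforced > n_cues:
        raise ValueError("cannot reinforce more cues than exist")
    rng = np.random.default_rng(seed)
    reinforced = np.zeros(n_cues, dtype=bool)
    reinforced[rng.permutation(n_cues)[:n_reinforced]] = True

    rows = []
    t = float(rng.uniform(*isi_range))
    for k in range(n_cues):
        if reinforced[k]:
            rows.append((t, cue_duration, CS_PLUS_US))
            rows.append((t + cue_duration, us_duration, US))
            t += cue_duration + us_duration
        else:
            rows.append((t, cue_duration, CS_PLUS_NOUS))
            t += cue_duration
        t += float(rng.uniform(*isi_range))
    if t > max_total:
        raise RuntimeError("generated schedule exceeds the run length cap")
    ev = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    return validate_events(ev)


def _edge_params(
    n_edges: int,
    planted: Iterable[int],
    planted_params: ACEParams,
    background_params: ACEParams,
) -> list[ACEParams]:
    planted = set(planted)
    return [planted_params if k in planted else background_params for k in range(n_edges)]


def planted_edge_indices(n_nodes: int, edges: Iterable[tuple[int, int]]) -> np.ndarray:
    """Map (i, j) node pairs to positions in the upper-triangle edge order."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    lookup = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(iu, ju))}
    out = []
    for i, j in edges:
        i, j = int(i), int(j)
        if i == j or not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ValueError(f"edge ({i},{j}) outside the upper triangle of {n_nodes} nodes")
        out.append(lookup[(min(i, j), max(i, j))])
    return np.asarray(out, dtype=int)


def simulate_fc_phenotypes(
    cohort: TwinCohort,
    n_nodes: int,
    planted_edges: Iterable[tuple[int, int]],
    planted_params: ACEParams,
    background_params: ACEParams,
    seed: int,
    node_meta: pd.DataFrame = None,
) -> FCMatrixStack:
    """Generate per-subject symmetric FC matrices edge-by-edge.

    Each upper-triangle edge is an independent ACE phenotype: edges in
    ``planted_edges`` use ``planted_params`` (the heritable component),
    every other edge uses ``background_params``.
    """
    n_edges = n_nodes * (n_nodes - 1) // 2
    planted_idx = planted_edge_indices(n_nodes, planted_edges)
    params = _edge_params(n_edges, planted_idx, planted_params, background_params)
    pheno = simulate_ace_phenotypes(cohort, params, seed=seed)
    return stack_from_edges(pheno.to_numpy(), n_nodes, list(pheno.index), node_meta=node_meta)


def simulate_roi_timeseries(
    cohort: TwinCohort,
    events: pd.DataFrame,
    n_nodes: int,
    tr: float,
    condition_edge_boost: float,
    pair_share: ACEParams,
    seed: int,
    boosted_edges: Sequence[tuple[int, int]] = ((0, 1),),
    n_volumes: int = None,
    spikes: Mapping[str, Sequence[int]] = None,
    spike_mm: float = 3.0,
) -> tuple[dict, dict]:
    """Simulate per-subject ROI time series plus motion traces.

    Node signals are unit-variance white noise; during reinforced-cue
    frames (CS+US weight series convolved with the canonical HRF,
    normalized to peak 1) the nodes of each boosted edge additionally load
    on a common latent factor. The per-subject loading gain is
    ``condition_edge_boost`` scaled by a positive, ACE-structured factor
    drawn under ``pair_share``, so the planted connectivity contrast is
    itself heritable. Connectivity is modulated through correlations, not
    mean shifts, so removing task-mean confounds leaves the signal intact.

    Returns ``(timeseries, motion)``: two dicts keyed by subject_id with
    :class:`RoiTimeSeries` values and volumes x 6 motion DataFrames
    (translations in mm, rotations in radians).
    """
    from .taskfc import condition_weight_series

    if tr <= 0:
        raise ValueError("tr must be positive")
    if condition_edge_boost < 0:
        raise ValueError("condition_edge_boost must be >= 0")
    events = validate_events(events)
    if n_volumes is None:
        end = float((events["onset"] + events["duration"]).max())
        n_volumes = int(np.ceil((end + 20.0) / tr))

    w = condition_weight_series(events, [CS_PLUS_US, US], n_volumes, tr).weights
    if w.max() > 0:
        w = w / w.max()

    # heritable positive gain per subject, mean 1
    z = simulate_ace_phenotypes(cohort, pair_share, seed=seed + 1).iloc[:, 0]
    gain = np.clip(1.0 + 0.5 * z, 0.0, None)

    rng = np.random.default_rng(seed)
    spikes = spikes or {}
    timeseries, motion = {}, {}
    for s_idx, sid in enumerate(cohort.subject_ids):
        x = rng.standard_normal((n_volumes, n_nodes))
        lam = condition_edge_boost * float(gain.loc[sid]) * w  # per-volume factor variance
        for i, j in boosted_edges:
            f = rng.standard_normal(n_volumes) * np.sqrt(lam)
            x[:, i] += f
            x[:, j] += f
        timeseries[sid] = RoiTimeSeries(x, tr=tr, subject_id=sid)

        steps = np.concatenate(
            [
                rng.standard_normal((n_volumes, 3)) * 0.02,  # mm
                rng.standard_normal((n_volumes, 3)) * 2e-4,  # rad
            ],
            axis=1,
        )
        m = np.cumsum(steps, axis=0)
        for vol in spikes.get(sid, ()):
            m[int(vol), 0] += spike_mm
        motion[sid] = pd.DataFrame(m, columns=MOTION_COLUMNS)
    return timeseries, motion
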