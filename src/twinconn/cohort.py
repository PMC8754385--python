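"""Twin cohort container: pairing and zygosity structure.

The cohort table is the exchangeability backbone of every permutation
scheme in the package: subjects come in pairs, each pair is monozygotic
(MZ, genetically identical) or dizygotic (DZ, sharing on average half of
their co-segregating alleles), and all inference on additive genetics
rests on contrasting those two pair types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MZ = "MZ"
DZ = "DZ"

_COLUMNS = ["subject_id", "pair_id", "zygosity", "sex", "age"]


@dataclass
class TwinCohort:
    """Roster of twin subjects with pair and zygosity structure.

    Parameters
    ----------
    table:
        DataFrame with columns ``subject_id``, ``pair_id``, ``zygosity``
        (``"MZ"`` or ``"DZ"``) and optional covariates ``sex``, ``age``.
    require_complete_pairs:
        When True (default) every ``pair_id`` must map to exactly two
        subjects. Recruitment rosters may legitimately contain a twin
        whose co-twin was never scanned; pass False for those and let
        :func:`twinconn.qc.apply_exclusions` restore the invariant.
    """

    table: pd.DataFrame
    require_complete_pairs: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("subject_id", "pair_id", "zygosity") if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table lacks required columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        for col in ("sex", "age"):
            if col not in t.columns:
                t[col] = pd.NA
        t = t[_COLUMNS]
        bad = set(t["zygosity"].unique()) - {MZ, DZ}
        if bad:
            raise ValueError(f"unknown zygosity labels: {sorted(bad)}")
        if t["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in cohort")
        sizes = t.groupby("pair_id", sort=False)["subject_id"].size()
        if self.require_complete_pairs and not (sizes == 2).all():
            bad_pairs = sizes.index[sizes != 2].tolist()
            raise ValueError(f"pairs without exactly 2 subjects: {bad_pairs[:5]}")
        if (sizes > 2).any():
            raise ValueError("a pair_id maps to more than 2 subjects")
        nzyg = t.groupby("pair_id", sort=False)["zygosity"].nunique()
        if (nzyg > 1).any():
            raise ValueError("both members of a pair must share zygosity")
        self.table = t

    # -- basic accessors -------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def _pair_zygosity(self) -> pd.Series:
        return self.table.groupby("pair_id", sort=False)["zygosity"].first()

    @property
    def n_pairs(self) -> int:
        return self.table["pair_id"].nunique()

    @property
    def n_mz_pairs(self) -> int:
        return int((self._pair_zygosity() == MZ).sum())

    @property
    def n_dz_pairs(self) -> int:
        return int((self._pair_zygosity() == DZ).sum())

    def pair_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row indices of the two members of each complete pair.

        Returns ``(first, second, is_dz)``: integer row positions into
        :attr:`table` for each pair's members, and a boolean array that is
        True for DZ pairs. Pairs are ordered by first appearance.
        """
        t = self.table
        first, second, is_dz = [], [], []
        for pid, grp in t.groupby("pair_id", sort=False):
            if len(grp) != 2:
                raise ValueError(f"pair {pid!r} is incomplete; cannot build pair index")
            i, j = grp.index
            first.append(i)
            second.append(j)
            is_dz.append(grp["zygosity"].iloc[0] == DZ)
        return np.asarray(first), np.asarray(second), np.asarray(is_dz)

    def co_twin_map(self) -> dict:
        """subject_id -> co-twin subject_id (absent for lone subjects)."""
        out = {}
        for _, grp in self.table.groupby("pair_id", sort=False):
            ids = grp["subject_id"].tolist()
            if len(ids) == 2:
                out[ids[0]], out[ids[1]] = ids[1], ids[0]
        return out

    def subset(self, subject_ids) -> "TwinCohort":
        keep = self.table["subject_id"].isin(set(subject_ids))
        return TwinCohort(self.table[keep], require_complete_pairs=False)

    def with_zygosity(self, pair_zygosity: dict) -> "TwinCohort":
        """Return a copy with zygosity relabelled per pair (for permutation)."""
        t = self.table.copy()
        t["zygosity"] = t["pair_id"].map(pair_zygosity)
        return TwinCohort(t, require_complete_pairs=self.require_complete_pairs)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, require_complete_pairs: bool = True) -> "TwinCohort":
        return cls(pd.read_csv(path, sep="\t"), require_complete_pairs=require_complete_pairs)


def simulate_cohort(n_mz: int, n_dz: int, seed: int) -> TwinCohort:
    """Simulate a twin cohort of ``n_mz`` MZ and ``n_dz`` DZ complete pairs.

    Subjects get ids ``s0001``..., pairs ``p0001``...; sex is shared within
    a pair (same-sex pairs only, as in registry-based twin designs) and age
    is drawn uniformly on 20-60 years, shared within a pair.
    """
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be non-negative")
    if n_mz + n_dz < 1:
        raise ValueError("need at least one pair")
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for p in range(n_mz + n_dz):
        zyg = MZ if p < n_mz else DZ
        sex = rng.choice(["F", "M"])
        age = int(rng.integers(20, 61))
        for _ in range(2):
            sid += 1
            rows.append((f"s{sid:04d}", f"p{p + 1:04d}", zyg, sex, age))
    return TwinCohort(pd.DataFrame(rows, columns=_COLUMNS))
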