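"""Subject-by-condition cohort container.

A cohort is one row per participant carrying a unique subject identifier, a
stratum label (here: sex), a strictly positive survey weight, and K binary
disease indicators. All downstream estimators (prevalence, rule mining,
networks) consume this container.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("subject_id", "stratum", "weight")

#: sentinel accepted wherever a stratum label is expected, meaning "all subjects"
ALL_STRATA = None


@dataclass
class CohortTable:
    """Validated subject × condition table.

    Parameters
    ----------
    data
        DataFrame with columns ``subject_id``, ``stratum``, ``weight`` followed
        by one 0/1 column per condition, in the order of ``condition_names``.
    condition_names
        The K condition labels; must be unique and match the data columns.
    """

    data: pd.DataFrame
    condition_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.condition_names = list(self.condition_names)
        if len(set(self.condition_names)) != len(self.condition_names):
            raise ValueError("condition names must be unique")
        for col in RESERVED_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"cohort data missing required column {col!r}")
        missing = [c for c in self.condition_names if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort data missing indicator columns: {missing}")
        # canonical column order
        cols = list(RESERVED_COLUMNS) + self.condition_names
        self.data = self.data.loc[:, cols].reset_index(drop=True)

        if self.data["subject_id"].duplicated().any():
            n_dup = int(self.data["subject_id"].duplicated().sum())
            raise ValueError(f"{n_dup} duplicate subject_id value(s)")
        w = self.data["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            bad = int(np.sum(~(np.isfinite(w) & (w > 0))))
            raise ValueError(f"{bad} non-positive or non-finite weight(s)")
        ind = self.data[self.condition_names].to_numpy()
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("indicators must be exactly 0 or 1")
        self.data[self.condition_names] = ind.astype(np.int8)

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_names)

    @property
    def strata(self) -> list:
        """Stratum labels in sorted order."""
        return sorted(self.data["stratum"].unique().tolist())

    def _mask(self, stratum) -> np.ndarray:
        if stratum is ALL_STRATA:
            return np.ones(self.n_subjects, dtype=bool)
        mask = (self.data["stratum"] == stratum).to_numpy()
        if not mask.any():
            raise ValueError(f"stratum {stratum!r} is empty or unknown")
        return mask

    def indicators(self, stratum=ALL_STRATA) -> np.ndarray:
        """(n, K) float array of 0/1 indicators for one stratum (or all)."""
        m = self._mask(stratum)
        return self.data.loc[m, self.condition_names].to_numpy(dtype=float)

    def weights(self, stratum=ALL_STRATA) -> np.ndarray:
        m = self._mask(stratum)
        return self.data.loc[m, "weight"].to_numpy(dtype=float)

    def subset(self, stratum) -> "CohortTable":
        m = self._mask(stratum)
        return CohortTable(self.data.loc[m].reset_index(drop=True),
                           self.condition_names)

    def stratum_size(self, stratum) -> int:
        """Unweighted respondent count in a stratum."""
        return int(self._mask(stratum).sum())

    def condition_index(self, name: str) -> int:
        try:
            return self.condition_names.index(name)
        except ValueError:
            raise ValueError(f"unknown condition {name!r}") from None


def make_cohort(indicators, condition_names, strata=None, weights=None,
                subject_ids=None) -> CohortTable:
    """Assemble a :class:`CohortTable` from raw arrays (test/analysis helper)."""
    ind = np.asarray(indicators)
    n = ind.shape[0]
    if strata is None:
        strata = ["all"] * n
    if weights is None:
        weights = np.ones(n)
    if subject_ids is None:
        subject_ids = [f"S{i:06d}" for i in range(n)]
    df = pd.DataFrame({"subject_id": subject_ids, "stratum": list(strata),
                       "weight": np.asarray(weights, dtype=float)})
    for j, name in enumerate(condition_names):
        df[name] = ind[:, j]
    return CohortTable(df, list(condition_names))
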