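"""Survey-weighted prevalence, morbidity-count distribution and sex tests.

Prevalences are weighted proportions Σ(wᵢ·xᵢ)/Σwᵢ so that the sample
represents the target population. Sex association is tested per condition
with a 2×2 chi-square test on unweighted counts (1 df, no continuity
correction) and corrected across conditions with the Benjamini–Hochberg
false-discovery-rate procedure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .cohort import ALL_STRATA, CohortTable


def weighted_prevalence(cohort: CohortTable, condition: str,
                        stratum=ALL_STRATA) -> float:
    """Weighted proportion of subjects with ``condition`` in a stratum."""
    j = cohort.condition_index(condition)
    x = cohort.indicators(stratum)[:, j]
    w = cohort.weights(stratum)
    return float(np.dot(w, x) / w.sum())


@dataclass
class MorbidityCountDistribution:
    """Weighted distribution of per-subject condition counts (0..K)."""

    proportions: np.ndarray          # index = number of conditions
    multimorbid_proportion: float    # weighted P(count >= 2)
    proportion_zero: float
    median_count: int                # weighted 50th percentile (lowest count
                                     # with cumulative proportion >= 0.5)
    max_count: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_conditions": np.arange(self.proportions.size),
                             "weighted_proportion": self.proportions})


def morbidity_distribution(cohort: CohortTable) -> MorbidityCountDistribution:
    """Weighted breakdown of the population by number of morbidities.

    Multimorbidity is the co-existence of two or more chronic conditions, so
    the multimorbid proportion is the weighted mass at counts >= 2.
    """
    counts = cohort.indicators().sum(axis=1).astype(int)
    w = cohort.weights()
    total = w.sum()
    k = cohort.n_conditions
    props = np.bincount(counts, weights=w, minlength=k + 1) / total
    cum = np.cumsum(props)
    median = int(np.searchsorted(cum, 0.5 - 1e-12))
    return MorbidityCountDistribution(
        proportions=props,
        multimorbid_proportion=float(props[2:].sum()),
        proportion_zero=float(props[0]),
        median_count=median,
        max_count=int(counts.max()) if counts.size else 0)


def sex_association_tests(cohort: CohortTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-condition prevalence by stratum with chi-square sex association.

    Requires exactly two strata. For each condition a 2×2 contingency table of
    unweighted counts (condition × stratum) is tested with the chi-square
    statistic (no continuity correction); p-values are adjusted across the K
    conditions with Benjamini–Hochberg and flagged significant at q < alpha.
    Conditions with zero variance (all subjects 0 or all 1) are recorded as
    not tested rather than failing the run.

    Returns a table with one row per condition: total and per-stratum weighted
    prevalences, per-stratum positive counts, chi2, p_value, q_value,
    significant and tested flags.
    """
    strata = cohort.strata
    if len(strata) != 2:
        raise ValueError(f"expected exactly two strata, found {len(strata)}")
    s1, s2 = strata
    x1, x2 = cohort.indicators(s1), cohort.indicators(s2)
    n1, n2 = x1.shape[0], x2.shape[0]
    rows = []
    for j, name in enumerate(cohort.condition_names):
        pos1, pos2 = int(x1[:, j].sum()), int(x2[:, j].sum())
        total_pos = pos1 + pos2
        tested = 0 < total_pos < n1 + n2
        if tested:
            table = np.array([[pos1, n1 - pos1], [pos2, n2 - pos2]])
            chi2, p, _, _ = chi2_contingency(table, correction=False)
        else:
            chi2, p = np.nan, np.nan
        rows.append({"condition": name,
                     "prevalence_total": weighted_prevalence(cohort, name),
                     f"prevalence_{s1}": weighted_prevalence(cohort, name, s1),
                     f"prevalence_{s2}": weighted_prevalence(cohort, name, s2),
                     f"count_{s1}": pos1, f"count_{s2}": pos2,
                     "chi2": float(chi2), "p_value": float(p),
                     "tested": tested})
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    out["significant"] = False
    mask = out["tested"].to_numpy()
    if mask.any():
        rej, q, _, _ = multipletests(out.loc[mask, "p_value"], alpha=alpha,
                                     method="fdr_bh")
        out.loc[mask, "q_value"] = q
        out.loc[mask, "significant"] = rej
    return out
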