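"""Association-rule mining of disease co-occurrence with the standardised lift.

For a rule A ⇒ B the classical interest measures are

    support    = P(A, B)
    confidence = P(B | A)
    lift       = P(A, B) / (P(A) P(B))      (the observed/expected ratio)

The attainable range of the lift depends on the margins: given P(A), P(B), a
sample of size n, a support floor s and a confidence floor c, the lift of any
mineable rule is bounded by

    λ = max{ P(A)+P(B)−1, 1/n, s, c·P(A) } / (P(A) P(B))
    υ = 1 / max{ P(A), P(B) }

so a raw-lift threshold favours low-prevalence conditions. The standardised
lift rescales onto [0, 1]:

    std_lift = (lift − λ) / (υ − λ)

allowing a fair ranking of rules across prevalence regimes. A widely printed
variant of this formula uses υ = 1/(P(A)P(B)) as the upper bound; that bound
is not attainable (lift ≤ 1/max{P(A),P(B)} always) and is kept behind the
``as_printed`` flag for auditability only — the attainable (``corrected``)
bound is the default.

A rule is *defined* only when it is mineable: non-degenerate margins, observed
support at least 1/n (the pair co-occurs in at least one subject) and above
the configured floors, and a non-degenerate bound interval υ − λ.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .cohort import CohortTable

_EPS = 1e-12
_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and conventions for rule mining.

    ``std_lift_threshold`` prunes rules at std_lift > threshold (default 0.2);
    ``support_floor``/``confidence_floor`` default to 0 (no lower limit on
    support or confidence — low-prevalence interactions are of interest);
    ``weighting`` selects survey-weighted or unweighted proportions (the 1/n
    term always uses the unweighted respondent count).
    """

    std_lift_threshold: float = 0.2
    support_floor: float = 0.0
    confidence_floor: float = 0.0
    upper_bound_variant: str = "corrected"   # or "as_printed"
    weighting: str = "weighted"              # or "unweighted"
    triad_min_prevalence: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.std_lift_threshold <= 1.0:
            raise ValueError("std_lift_threshold must lie in [0, 1]")
        for name in ("support_floor", "confidence_floor", "triad_min_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.upper_bound_variant not in ("corrected", "as_printed"):
            raise ValueError(f"unknown upper_bound_variant {self.upper_bound_variant!r}")
        if self.weighting not in ("weighted", "unweighted"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


DEFAULT_CONFIG = MiningConfig()


@dataclass(frozen=True)
class RuleMetrics:
    """Interest measures of one rule antecedent ⇒ consequent."""

    antecedent: tuple
    consequent: tuple
    stratum: object
    n: int
    p_a: float
    p_b: float
    support: float
    confidence: float
    lift: float
    lift_lower: float
    lift_upper: float
    std_lift: float
    defined: bool


@dataclass
class RuleSet:
    """Rules surviving a mining configuration for one stratum."""

    rules: list[RuleMetrics]
    config: MiningConfig
    stratum: object

    def __len__(self) -> int:
        return len(self.rules)

    def pairs(self) -> set:
        """Unordered condition pairs with at least one retained direction."""
        return {frozenset(r.antecedent + r.consequent) for r in self.rules}

    def as_frame(self) -> pd.DataFrame:
        rows = [{"stratum": r.stratum,
                 "antecedent": "+".join(map(str, r.antecedent)),
                 "consequent": "+".join(map(str, r.consequent)),
                 "n": r.n, "p_a": r.p_a, "p_b": r.p_b, "support": r.support,
                 "confidence": r.confidence, "lift": r.lift,
                 "lift_lower": r.lift_lower, "lift_upper": r.lift_upper,
                 "std_lift": r.std_lift,
                 "variant": self.config.upper_bound_variant}
                for r in self.rules]
        return pd.DataFrame(rows, columns=[
            "stratum", "antecedent", "consequent", "n", "p_a", "p_b",
            "support", "confidence", "lift", "lift_lower", "lift_upper",
            "std_lift", "variant"])


@dataclass(frozen=True)
class TriadRecord:
    """An unordered set of three conditions co-occurring in the cohort."""

    conditions: tuple
    stratum: object
    prevalence: float        # weighted P(all three)
    std_lift_max: float      # max std lift over the six bipartition rules
    qualifying: bool         # std_lift_max > threshold
    cooccurrence_count: int  # unweighted subjects with all three


def rule_metrics(p_a: float, p_b: float, joint: float, n: int,
                 config: MiningConfig = DEFAULT_CONFIG, *,
                 antecedent: tuple = ("A",), consequent: tuple = ("B",),
                 stratum=None) -> RuleMetrics:
    """Score one rule from its margins, joint probability and sample size."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    degenerate = not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0)
    if degenerate:
        support = joint
        confidence = joint / p_a if p_a > 0 else np.nan
        lift = np.nan
        return RuleMetrics(antecedent, consequent, stratum, n, p_a, p_b,
                           support, confidence, lift, np.nan, np.nan,
                           np.nan, False)

    frechet_lo = max(p_a + p_b - 1.0, 0.0)
    frechet_hi = min(p_a, p_b)
    if joint < frechet_lo - _EPS or joint > frechet_hi + _EPS:
        raise ValueError(
            f"joint probability {joint} outside the Fréchet bounds "
            f"[{frechet_lo}, {frechet_hi}] for margins ({p_a}, {p_b})")
    joint = min(max(joint, frechet_lo), frechet_hi)

    denom = p_a * p_b
    support = joint
    confidence = joint / p_a
    lift = joint / denom
    lam_num = max(p_a + p_b - 1.0, 1.0 / n,
                  config.support_floor, config.confidence_floor * p_a)
    lam = lam_num / denom
    if config.upper_bound_variant == "corrected":
        ups = 1.0 / max(p_a, p_b)
    else:
        ups = 1.0 / denom

    defined = (joint >= lam_num - _EPS) and (ups - lam >= _EPS)
    if defined:
        std = (lift - lam) / (ups - lam)
        if -_BOUND_TOL < std < 0.0:
            std = 0.0
        elif 1.0 < std < 1.0 + _BOUND_TOL:
            std = 1.0
    else:
        std = np.nan
    return RuleMetrics(antecedent, consequent, stratum, n, p_a, p_b,
                       support, confidence, lift, lam, ups, std, defined)


# ---------------------------------------------------------------------------
# cohort-level mining
# ---------------------------------------------------------------------------

def _stratum_arrays(cohort: CohortTable, stratum, config: MiningConfig):
    """Indicators, mining weights, margins and pairwise joint matrix."""
    x = cohort.indicators(stratum)
    if config.weighting == "weighted":
        w = cohort.weights(stratum)
    else:
        w = np.ones(x.shape[0])
    total = w.sum()
    margins = (w @ x) / total
    joint = (x.T * w) @ x / total
    return x, w, margins, joint, x.shape[0]


def _all_pair_metrics(cohort: CohortTable, stratum,
                      config: MiningConfig) -> Iterator[RuleMetrics]:
    names = cohort.condition_names
    _, _, margins, joint, n = _stratum_arrays(cohort, stratum, config)
    for i, j in itertools.permutations(range(len(names)), 2):
        yield rule_metrics(margins[i], margins[j], joint[i, j], n, config,
                           antecedent=(names[i],), consequent=(names[j],),
                           stratum=stratum)


def mine_pairwise(cohort: CohortTable, stratum,
                  config: MiningConfig = DEFAULT_CONFIG) -> RuleSet:
    """All ordered single-condition rules with std_lift above the threshold."""
    if cohort.n_conditions < 2:
        raise ValueError("pairwise mining needs at least two conditions")
    rules = [r for r in _all_pair_metrics(cohort, stratum, config)
             if r.defined and r.std_lift > config.std_lift_threshold]
    return RuleSet(rules, config, stratum)


def confidence_matrix(cohort: CohortTable, stratum,
                      config: MiningConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """K×K matrix of P(column condition | row condition).

    Entry (y, x) is the probability of having disease x given disease y is
    already present; the diagonal is 1 for any condition with nonzero
    prevalence. Rows for zero-prevalence conditions are undefined (NaN).
    """
    names = cohort.condition_names
    _, _, margins, joint, _ = _stratum_arrays(cohort, stratum, config)
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = joint / margins[:, None]
    mat[margins == 0, :] = np.nan
    diag = np.where(margins > 0, 1.0, np.nan)
    np.fill_diagonal(mat, diag)
    return pd.DataFrame(mat, index=names, columns=names)


def mine_triads(cohort: CohortTable, stratum,
                config: MiningConfig = DEFAULT_CONFIG) -> list[TriadRecord]:
    """Score every condition triple with nonzero observed co-occurrence.

    A triple's prevalence is the weighted proportion having all three
    conditions. Its standardised lift is taken as the maximum over the six
    bipartition rules {X} ⇒ {Y,Z} and {Y,Z} ⇒ {X} (margins being set-event
    probabilities), which is symmetric in the triple and reduces to the
    pairwise definition when two conditions coincide.
    """
    if cohort.n_conditions < 3:
        raise ValueError("triad mining needs at least three conditions")
    names = cohort.condition_names
    x, w, margins, joint, n = _stratum_arrays(cohort, stratum, config)
    total = w.sum()
    records = []
    for i, j, k in itertools.combinations(range(len(names)), 3):
        together = x[:, i] * x[:, j] * x[:, k]
        count = int(together.sum())
        if count == 0:
            continue
        prevalence = float(w @ together / total)
        std_max = -np.inf
        for single, pair in (((i,), (j, k)), ((j,), (i, k)), ((k,), (i, j))):
            p_single = margins[single[0]]
            p_pair = joint[pair[0], pair[1]]
            for ante, cons, pa, pb in ((single, pair, p_single, p_pair),
                                       (pair, single, p_pair, p_single)):
                r = rule_metrics(pa, pb, prevalence, n, config,
                                 antecedent=tuple(names[t] for t in ante),
                                 consequent=tuple(names[t] for t in cons),
                                 stratum=stratum)
                if r.defined and r.std_lift > std_max:
                    std_max = r.std_lift
        std_max = std_max if np.isfinite(std_max) else np.nan
        qualifying = bool(np.isfinite(std_max)
                          and std_max > config.std_lift_threshold)
        records.append(TriadRecord(
            conditions=tuple(sorted((names[i], names[j], names[k]))),
            stratum=stratum, prevalence=prevalence, std_lift_max=std_max,
            qualifying=qualifying, cooccurrence_count=count))
    return records


def prevalent_triads(records: list[TriadRecord],
                     config: MiningConfig = DEFAULT_CONFIG) -> list[TriadRecord]:
    """Qualifying triads above the reporting prevalence floor."""
    return [t for t in records
            if t.qualifying and t.prevalence > config.triad_min_prevalence]


def triads_frame(records: list[TriadRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"stratum": t.stratum, "conditions": "+".join(t.conditions),
          "prevalence": t.prevalence, "std_lift_max": t.std_lift_max,
          "qualifying": t.qualifying,
          "cooccurrence_count": t.cooccurrence_count} for t in records],
        columns=["stratum", "conditions", "prevalence", "std_lift_max",
                 "qualifying", "cooccurrence_count"])


def threshold_sensitivity(cohort: CohortTable, stratum, thresholds,
                          config: MiningConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Retained-rule counts over a grid of std-lift thresholds.

    The retained set is nested, so counts are non-increasing in the
    threshold; the count at 0 equals the number of defined ordered rules
    with positive standardised lift.
    """
    thresholds = list(thresholds)
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    stds = np.array([r.std_lift for r in
                     _all_pair_metrics(cohort, stratum, config) if r.defined])
    counts = [int((stds > t).sum()) for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "retained_rules": counts})


def enumerate_two_by_two_metrics(n: int,
                                 config: MiningConfig = DEFAULT_CONFIG
                                 ) -> Iterator[RuleMetrics]:
    """Rule metrics for every 2×2 contingency table of total count ``n``.

    Iterates over all non-negative integer tables (n11, n10, n01, n00)
    summing to n whose two margins are non-degenerate. Used to verify the
    standardised-lift bound properties exhaustively at small n.
    """
    for n11 in range(n + 1):
        for n10 in range(n - n11 + 1):
            for n01 in range(n - n11 - n10 + 1):
                pa = (n11 + n10) / n
                pb = (n11 + n01) / n
                if not (0.0 < pa < 1.0 and 0.0 < pb < 1.0):
                    continue
                yield rule_metrics(pa, pb, n11 / n, n, config)
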