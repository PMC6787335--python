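"""CSV readers and writers binding the analysis stages together.

Everything is plain CSV with explicit headers; floats are written at full
precision so every file parses back into its domain object without loss.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .cohort import CohortTable
from .rules import MiningConfig, RuleMetrics, RuleSet, TriadRecord

_TRUE = {"1", "true"}
_FALSE = {"0", "false"}


def read_cohort(path, id_col: str = "subject_id", stratum_col: str = "stratum",
                weight_col: str = "weight",
                condition_cols: list[str] | None = None) -> CohortTable:
    """Read a cohort CSV, validating identifiers, weights and indicators.

    Indicator columns accept 0/1 and true/false (case-insensitive). Rows with
    missing or unparseable indicators are rejected with row-numbered
    diagnostics (1-based data rows, excluding the header).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (id_col, stratum_col, weight_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if condition_cols is None:
        condition_cols = [c for c in df.columns
                          if c not in (id_col, stratum_col, weight_col)]
    if not condition_cols:
        raise ValueError("no indicator columns found")

    dup = df[id_col].duplicated()
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate subject id(s), "
                         f"e.g. {df.loc[dup, id_col].iloc[0]!r}")
    w = pd.to_numeric(df[weight_col], errors="coerce")
    bad_w = ~(w > 0)
    if bad_w.any():
        rows = (np.flatnonzero(bad_w) + 1).tolist()
        raise ValueError(
            f"{len(rows)} non-positive weight(s) at row(s) {rows}")

    parsed = {}
    bad_rows: set[int] = set()
    for col in condition_cols:
        vals = df[col].astype(str).str.strip().str.lower()
        is_one = vals.isin(_TRUE)
        is_zero = vals.isin(_FALSE)
        unknown = ~(is_one | is_zero)
        if unknown.any():
            bad_rows.update((np.flatnonzero(unknown) + 1).tolist())
        parsed[col] = is_one.astype(np.int8)
    if bad_rows:
        rows = sorted(bad_rows)
        raise ValueError(
            f"{len(rows)} row(s) with missing or unparseable indicators "
            f"at row(s) {rows}")

    out = pd.DataFrame({"subject_id": df[id_col],
                        "stratum": df[stratum_col],
                        "weight": w})
    for col in condition_cols:
        out[col] = parsed[col]
    return CohortTable(out, list(condition_cols))


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis outputs
# ---------------------------------------------------------------------------

def write_rules(ruleset: RuleSet, path) -> None:
    ruleset.as_frame().to_csv(path, index=False)


def read_rules(path) -> RuleSet:
    """Rebuild a RuleSet from a rules CSV (all stored rules are defined)."""
    df = pd.read_csv(path, float_precision="round_trip")
    variants = df["variant"].unique().tolist() if len(df) else ["corrected"]
    if len(variants) > 1:
        raise ValueError(f"mixed upper-bound variants in file: {variants}")
    config = MiningConfig(std_lift_threshold=0.0, upper_bound_variant=variants[0])
    rules = [RuleMetrics(antecedent=tuple(str(r.antecedent).split("+")),
                         consequent=tuple(str(r.consequent).split("+")),
                         stratum=r.stratum, n=int(r.n), p_a=r.p_a, p_b=r.p_b,
                         support=r.support, confidence=r.confidence,
                         lift=r.lift, lift_lower=r.lift_lower,
                         lift_upper=r.lift_upper, std_lift=r.std_lift,
                         defined=True)
             for r in df.itertuples()]
    stratum = df["stratum"].iloc[0] if len(df) else None
    return RuleSet(rules, config, stratum)


def write_confidence_matrix(matrix: pd.DataFrame, path) -> None:
    """Row label = conditioning (already-present) disease."""
    matrix.to_csv(path, index_label="given")


def read_confidence_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="given", float_precision="round_trip")


def write_prevalence_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_triads(records: list[TriadRecord], path) -> None:
    from .rules import triads_frame
    triads_frame(records).to_csv(path, index=False)


def write_edgelist(network: nx.Graph, path) -> None:
    rows = [{"condition_a": a, "condition_b": b,
             "cooccurrence_count": d["cooccurrence_count"]}
            for a, b, d in sorted(network.edges(data=True))]
    pd.DataFrame(rows, columns=["condition_a", "condition_b",
                                "cooccurrence_count"]).to_csv(path, index=False)


def write_graphml(network: nx.Graph, path, membership: dict | None = None) -> None:
    g = network.copy()
    if membership is not None:
        nx.set_node_attributes(g, membership, "community")
    nx.write_graphml(g, path)


def write_partition(membership: dict, path) -> None:
    pd.DataFrame(sorted(membership.items()),
                 columns=["condition", "community"]).to_csv(path, index=False)


def read_partition(path) -> dict:
    df = pd.read_csv(path, float_precision="round_trip")
    return dict(zip(df["condition"], df["community"]))
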