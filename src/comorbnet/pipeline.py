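"""End-to-end analysis pipeline: prevalence → mining → networks → communities.

``run_pipeline`` executes every stage for every stratum and writes all tables
plus a JSON manifest (seed, configuration, library versions, retained-rule
counts, and — when the input is a synthetic spec — whether each planted pair
was recovered). With a fixed configuration and seed the output files are
byte-identical across runs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx
import numpy
import pandas
import scipy
import statsmodels

from . import io as cio
from .cohort import CohortTable
from .network import build_network, detect_communities
from .prevalence import morbidity_distribution, sex_association_tests
from .rules import (MiningConfig, confidence_matrix, mine_pairwise,
                    mine_triads, threshold_sensitivity)
from .simulate import CohortSpec, generate_cohort, truth_table


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name and error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Exactly one of ``input_path`` / ``spec`` selects the cohort source."""

    input_path: str | None = None
    spec: CohortSpec | None = None
    mining: MiningConfig = field(default_factory=MiningConfig)
    thresholds: list[float] = field(
        default_factory=lambda: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
    output_dir: str = "results"
    seed: int | None = None
    id_col: str = "subject_id"
    stratum_col: str = "stratum"
    weight_col: str = "weight"

    def __post_init__(self):
        if (self.input_path is None) == (self.spec is None):
            raise ValueError("exactly one of input_path / spec must be set")


def _stage(name: str, code: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, code, str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = config.spec
    if spec is not None and config.seed is not None:
        spec = dataclasses.replace(spec, seed=config.seed)

    if spec is not None:
        cohort: CohortTable = _stage("load", "generate", generate_cohort, spec)
    else:
        cohort = _stage("load", "read", cio.read_cohort, config.input_path,
                        config.id_col, config.stratum_col, config.weight_col)
    _stage("load", "write", cio.write_cohort, cohort, out / "cohort.csv")

    dist = _stage("prevalence", "distribution", morbidity_distribution, cohort)
    dist.as_frame().to_csv(out / "morbidity_distribution.csv", index=False)
    if len(cohort.strata) == 2:
        prev = _stage("prevalence", "sex_tests", sex_association_tests, cohort)
        _stage("prevalence", "write", cio.write_prevalence_table,
               prev, out / "prevalence.csv")

    manifest: dict = {
        "seed": spec.seed if spec is not None else config.seed,
        "mining_config": dataclasses.asdict(config.mining),
        "thresholds": list(config.thresholds),
        "strata": cohort.strata,
        "n_subjects": cohort.n_subjects,
        "n_conditions": cohort.n_conditions,
        "multimorbid_proportion": dist.multimorbid_proportion,
        "median_morbidity_count": dist.median_count,
        "rules_retained": {},
        "versions": {
            "comorbnet": _version(),
            "numpy": numpy.__version__, "pandas": pandas.__version__,
            "scipy": scipy.__version__, "networkx": networkx.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }

    truth = truth_table(spec) if spec is not None else None

    for stratum in cohort.strata:
        tag = str(stratum)
        ruleset = _stage("mine", "pairwise", mine_pairwise, cohort, stratum,
                         config.mining)
        cio.write_rules(ruleset, out / f"rules_{tag}.csv")
        manifest["rules_retained"][tag] = len(ruleset)

        conf = _stage("mine", "confidence", confidence_matrix, cohort,
                      stratum, config.mining)
        cio.write_confidence_matrix(conf, out / f"confidence_{tag}.csv")

        triads = _stage("triads", "mine", mine_triads, cohort, stratum,
                        config.mining)
        cio.write_triads(triads, out / f"triads_{tag}.csv")

        net = _stage("network", "build", build_network, ruleset, cohort)
        cio.write_edgelist(net, out / f"network_{tag}_edges.csv")
        if net.number_of_nodes() > 0:
            part = _stage("network", "communities", detect_communities, net)
            cio.write_partition(part.membership, out / f"communities_{tag}.csv")
            cio.write_graphml(net, out / f"network_{tag}.graphml",
                              part.membership)
            manifest.setdefault("modularity", {})[tag] = part.modularity
        else:
            cio.write_partition({}, out / f"communities_{tag}.csv")

        sens = _stage("sensitivity", "thresholds", threshold_sensitivity,
                      cohort, stratum, config.thresholds, config.mining)
        sens.to_csv(out / f"sensitivity_{tag}.csv", index=False)

        if truth is not None:
            retained = {tuple(sorted(p)) for p in ruleset.pairs()}
            planted = truth[(truth["stratum"] == stratum) & truth["planted"]]
            seen = set()
            report = []
            for row in planted.itertuples():
                pair = tuple(sorted((row.condition_a, row.condition_b)))
                if pair in seen:
                    continue
                seen.add(pair)
                report.append({"pair": list(pair),
                               "expected_lift": row.lift,
                               "retained": pair in retained})
            manifest.setdefault("planted_pairs", {})[tag] = report

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _version() -> str:
    from . import __version__
    return __version__
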