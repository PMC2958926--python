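"""Iterative analysis loop: run an engine under the current knowledge base,
write artifacts and an inconsistency report, and repeat with updated KB files
until the KB is stable and no inconsistencies remain (or the iteration cap)."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (ConfusionTable, align_partitions, cohen_kappa,
                        diagnostic_metrics, icc_consistency)
from .clbr import MixedDissimilarityParams, clbr_cluster
from .data import MixedTable, StochasticSpec
from .dea import (ConvergenceSettings, DEAModelConfig, Scenario,
                  classify_tiers, run_monte_carlo)
from .interpret import build_cpg, detect_inconsistencies, mark_cells, test_variables
from .rules import IOAnnotation, KnowledgeBase, diff_kb

__all__ = ["EbcaConfig", "IterationRecord", "run_iteration", "run_loop",
           "compare_with_expert"]


@dataclass
class EbcaConfig:
    engine: str  # "dea" | "clbr"
    table: MixedTable
    seed: int
    out_dir: Union[str, Path]
    # dea engine
    stochastic_spec: Optional[StochasticSpec] = None
    annotations: Optional[Mapping[str, IOAnnotation]] = None
    scenario: Optional[Scenario] = None
    dea_config: DEAModelConfig = field(default_factory=DEAModelConfig)
    convergence: ConvergenceSettings = field(default_factory=ConvergenceSettings)
    # clbr engine
    params: Optional[MixedDissimilarityParams] = None
    kmax: Optional[int] = None

    def __post_init__(self):
        if self.engine not in ("dea", "clbr"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.engine == "dea":
            if self.stochastic_spec is None or self.scenario is None \
                    or self.annotations is None:
                raise ValueError("dea engine needs spec, scenario and annotations")


@dataclass
class IterationRecord:
    index: int
    kb_version: int
    engine: str
    digest: str
    inconsistency_count: int
    summary: dict
    timestamp: float


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_iteration(config: EbcaConfig, kb: KnowledgeBase,
                  index: int = 1) -> IterationRecord:
    """Execute one engine pass and write all artifacts into the output dir."""
    out = Path(config.out_dir) / f"iteration_{index:02d}"
    out.mkdir(parents=True, exist_ok=True)

    if config.engine == "dea":
        pool = run_monte_carlo(
            config.stochastic_spec, config.annotations, config.dea_config,
            config.scenario, config.table.unit_ids, config.seed,
            config.convergence,
        )
        tiers = classify_tiers(pool)
        pool.scores_frame().to_csv(out / "scores.csv", index_label="run")
        pool.summary().to_csv(out / "pool_summary.csv")
        tiers.to_frame().to_csv(out / "tiers.csv")
        pool.convergence_frame().to_csv(out / "convergence.csv", index_label="block")
        digest = _digest(pool.summary().round(12).to_dict())
        summary = {
            "converged": pool.converged,
            "n_runs": pool.n_runs,
            "tiers": tiers.binary,
        }
        inconsistencies = 0
    else:
        dendro, partition, curve, rule_partition = clbr_cluster(
            config.table, kb, params=config.params, kmax=config.kmax)
        report = detect_inconsistencies(config.table, partition.labels)
        part_rows = pd.DataFrame(
            [{"id": rid, "class": lab,
              "provenance": partition.provenance.get(lab, "data-driven")}
             for rid, lab in partition.labels.items()]
        )
        part_rows.to_csv(out / "partition.csv", index=False)
        if dendro is not None and dendro.merges:
            (out / "dendrogram.json").write_text(json.dumps(dendro.to_dict(), indent=2))
            (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        pd.DataFrame(curve.to_rows()).to_csv(out / "ch_curve.csv", index=False)
        significance = test_variables(config.table, partition.labels) \
            if partition.k >= 2 else []
        pd.DataFrame([vars(s) for s in significance]).to_csv(
            out / "significance.csv", index=False)
        cpg = mark_cells(build_cpg(config.table, partition.labels))
        cpg.to_frame().to_csv(out / "cpg.csv", index=False)
        (out / "inconsistencies.json").write_text(
            json.dumps(report.to_rows(), indent=2))
        digest = _digest(sorted(partition.labels.items(), key=lambda x: str(x[0])))
        summary = {"k": partition.k, "rule_groups": rule_partition.counts,
                   "unknown_records": rule_partition.unknown_count}
        inconsistencies = len(report)

    record = IterationRecord(
        index=index, kb_version=kb.version, engine=config.engine,
        digest=digest, inconsistency_count=inconsistencies,
        summary=summary, timestamp=time.time(),
    )
    manifest = {
        "software_version": __version__,
        "engine": config.engine,
        "seed": config.seed,
        "iteration": index,
        "kb_version": kb.version,
        "kb_rules": [r.to_text() for r in kb.rules],
        "digest": digest,
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return record


def run_loop(config: EbcaConfig, kb_sequence: Sequence[KnowledgeBase],
             max_iterations: int = 5) -> list[IterationRecord]:
    """Non-interactive loop over a pre-supplied KB sequence.

    Stops at the iteration cap, when the KB sequence is exhausted with no
    change and no inconsistencies were flagged, or raises if a KB regresses
    its version number.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if not kb_sequence:
        raise ValueError("need at least one knowledge base")
    records: list[IterationRecord] = []
    previous: Optional[KnowledgeBase] = None
    for index in range(1, max_iterations + 1):
        kb = kb_sequence[min(index - 1, len(kb_sequence) - 1)]
        if previous is not None and kb.version < previous.version:
            raise ValueError(
                f"KB version regressed: {previous.version} -> {kb.version}")
        unchanged = False
        if previous is not None and kb is not previous:
            changes = diff_kb(previous, kb)
            unchanged = changes.is_empty()
        elif previous is not None:
            unchanged = True
        record = run_iteration(config, kb, index=index)
        records.append(record)
        if previous is not None and unchanged and record.inconsistency_count == 0:
            break
        if record.inconsistency_count == 0 and index >= len(kb_sequence):
            break
        previous = kb
    return records


def compare_with_expert(predicted: Mapping, reference: Mapping) -> dict:
    """Agreement bundle between model output and expert labels keyed by id.

    Binary efficient/inefficient labelings get diagnostic metrics + kappa;
    multi-class partitions get kappa after optimal class alignment.
    """
    pred_ids = set(predicted)
    ref_ids = set(reference)
    if pred_ids != ref_ids:
        unmatched = sorted(map(str, pred_ids ^ ref_ids))
        raise ValueError(f"unit id mismatch: {unmatched}")
    ids = sorted(predicted, key=str)
    pred = [predicted[i] for i in ids]
    ref = [reference[i] for i in ids]
    result: dict = {}
    levels = set(pred) | set(ref)
    if levels <= {"efficient-group", "inefficient-group"}:
        # positive = efficient-group, reference = expert gold standard
        tp = sum(1 for r, p in zip(ref, pred)
                 if r == "efficient-group" and p == "efficient-group")
        fn = sum(1 for r, p in zip(ref, pred)
                 if r == "efficient-group" and p == "inefficient-group")
        fp = sum(1 for r, p in zip(ref, pred)
                 if r == "inefficient-group" and p == "efficient-group")
        tn = sum(1 for r, p in zip(ref, pred)
                 if r == "inefficient-group" and p == "inefficient-group")
        table = ConfusionTable.binary(tp, fn, fp, tn)
        result["diagnostics"] = diagnostic_metrics(table)
        result["kappa"] = cohen_kappa(table)
        result["confusion"] = table
    else:
        table = align_partitions(ref, pred)
        result["kappa"] = cohen_kappa(table)
        result["confusion"] = table
    return result


def compare_scores_with_expert(model_scores: Sequence[float],
                               ratings: np.ndarray) -> dict:
    """Consistency ICC between model scores and each expert rating column."""
    matrix = np.column_stack([np.asarray(model_scores, dtype=float),
                              np.asarray(ratings, dtype=float)])
    return {"icc": icc_consistency(matrix)}
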