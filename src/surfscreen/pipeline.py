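"""End-to-end orchestration of the screen and the reference-list report.

``screen_cohort`` is the in-memory pipeline: score every comparator panel,
restrict to membrane transcripts, and rank. ``run_screen`` wraps it with
file I/O, overlap/consensus reporting and a manifest; ``reference_report``
recomputes the cross-list overlap, consensus and gene-family statistics from
the bundled published target lists, with no expression data involved.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import io as sio
from .containers import CohortDesign, ExpressionMatrix, PipelineError, ProbeAnnotation
from .differential import DEFAULT_FC_FLOOR, score_all
from .preprocess import collapse_probes
from .ranking import (
    OverlapReport,
    RankedTargetList,
    consensus,
    family_breakdown,
    filter_membrane,
    rank_targets,
    shared_fraction,
)

logger = logging.getLogger(__name__)

DEFAULT_METRICS = ("fold_change", "t_score")


def screen_cohort(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    ann: ProbeAnnotation,
    top_n: int = 40,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    fc_floor: float = DEFAULT_FC_FLOOR,
    t_variant: str = "welch",
) -> tuple[dict[str, pd.DataFrame], list[RankedTargetList]]:
    """Score, membrane-filter and rank the disease cohort vs every comparator.

    Returns the per-comparator score tables (all probes) and the ranked
    membrane target lists (one per comparator x metric).
    """
    scores: dict[str, pd.DataFrame] = {}
    lists: list[RankedTargetList] = []
    for comp in design.comparator_groups:
        t0 = time.perf_counter()
        table = score_all(matrix, design, comp, ann, fc_floor=fc_floor,
                          t_variant=t_variant)
        scores[comp] = table
        membrane = filter_membrane(table, ann)
        for metric in metrics:
            lists.append(
                rank_targets(membrane, metric, top_n, comparator=comp,
                             absolute=(metric == "pearson_r"))
            )
        logger.info("scored %s (%d probes) in %.2fs", comp, len(table),
                    time.perf_counter() - t0)
    return scores, lists


def pairwise_overlaps(lists: list[RankedTargetList],
                      metric: str = "fold_change",
                      denominator: str = "len_a") -> list[OverlapReport]:
    """One overlap report per comparator pair, on the given metric's lists."""
    chosen = [l for l in lists if l.metric == metric]
    reports = []
    for i, a in enumerate(chosen):
        for b in chosen[i + 1:]:
            reports.append(shared_fraction(a, b, denominator=denominator))
    return reports


def run_screen(config) -> dict[str, Path]:
    """Run the full screen described by a RunConfig; returns written paths.

    Any stage error aborts with a stage-named message and removes files
    written so far.
    """
    from .config import RunConfig  # local import to avoid a cycle

    assert isinstance(config, RunConfig)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(key: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        written[key] = path

    stage = "read-inputs"
    try:
        matrix = sio.read_expression_table(config.matrix, scale=config.scale,
                                           sep=config.sep)
        design = sio.read_design(config.design, config.disease_group,
                                 list(config.comparators), sep=config.sep)
        ann = sio.read_annotation(config.annotation, alias_path=config.aliases,
                                  sep=config.sep)
        if config.collapse_method != "none":
            stage = "collapse-probes"
            matrix = collapse_probes(matrix, ann, method=config.collapse_method)

        stage = "score"
        scores, lists = screen_cohort(
            matrix, design, ann, top_n=config.top_n,
            metrics=tuple(config.metrics), fc_floor=config.fc_floor,
            t_variant=config.t_variant,
        )
        for comp, table in scores.items():
            emit(f"scores_{comp}", f"scores_{comp}.tsv",
                 lambda p, t=table: t.to_csv(p, sep="\t", index=False,
                                             float_format="%.10g"))
        for lst in lists:
            emit(f"ranked_{lst.comparator}_{lst.metric}",
                 f"ranked_{lst.comparator}_{lst.metric}.tsv",
                 lambda p, l=lst: sio.write_ranked_list(l, p))

        stage = "overlap"
        reports = pairwise_overlaps(lists, metric=config.metrics[0])
        emit("overlaps", "overlaps.tsv",
             lambda p: sio.write_overlap_reports(reports, p))

        stage = "consensus"
        cons = consensus(lists)
        emit("consensus", "consensus.tsv", lambda p: sio.write_consensus(cons, p))

        stage = "manifest"
        emit("manifest", "manifest.txt",
             lambda p: p.write_text(config.to_manifest()))
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return written


def reference_report() -> dict:
    """Overlap, consensus and family statistics of the bundled target lists.

    Recomputes, from the shipped reference tables, the comparator-sensitivity
    statistics: how much of each restricted-comparator top list is shared
    with the broad-normal list, which genes reach full cross-comparator
    consensus, and how much of the disease list is clonotypic (TCR chains +
    CD3 complex members).
    """
    tall = sio.load_reference_list("tall_vs_normal")
    ball = sio.load_reference_list("ball_vs_normal")
    hsc_t = sio.load_reference_list("tall_vs_hsc_tscore")
    hsc_fc = sio.load_reference_list("tall_vs_hsc_fc")
    pbmc_t = sio.load_reference_list("tall_vs_pbmc_tscore")
    pbmc_fc = sio.load_reference_list("tall_vs_pbmc_fc")
    families = sio.reference_families()

    overlaps = {
        "hsc_tscore_vs_broad": shared_fraction(hsc_t, tall),
        "hsc_fc_vs_broad": shared_fraction(hsc_fc, tall),
        "pbmc_tscore_vs_broad": shared_fraction(pbmc_t, tall),
        "pbmc_fc_vs_broad": shared_fraction(pbmc_fc, tall),
        "tall_vs_ball": shared_fraction(tall, ball),
    }
    cons = consensus([tall, hsc_t, hsc_fc, pbmc_t, pbmc_fc])
    return {
        "overlaps": overlaps,
        "consensus": cons,
        "family_breakdown": family_breakdown(tall, families),
        "n_tall": len(tall),
        "n_ball": len(ball),
    }
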