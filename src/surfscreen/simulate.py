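"""Synthetic expression cohorts with the structure the screen assumes.

The generator emulates a leukemia screening setting with three normal
comparator panels: a *broad* multi-tissue panel, a *stemlike* panel (the
HSC-like tissue of origin), and a *maturelike* panel (PBMC-like mature
lymphocytes that share the disease's lineage program). Three planted gene
sets encode the mechanism under study:

* ``lineage`` genes — elevated in the disease AND in the maturelike panel
  (the shared T-cell program); they surface against the broad and stemlike
  panels but drop out against mature lymphocytes;
* ``tumor`` genes — elevated in the disease only; they surface against
  every panel and are the consensus targets;
* ``stem`` genes — elevated in the stemlike panel only.

Intensities are log-normal: log2 value = per-gene baseline + effect-size
shift where planted + Gaussian noise, independently per cell. Everything is
driven by one seeded generator, so a cohort is a pure function of its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CohortDesign,
    ExpressionMatrix,
    PipelineError,
    ProbeAnnotation,
)
from .ranking import RankedTargetList

COMPARATORS = ("broad", "stemlike", "maturelike")

MEMBERSHIPS = ("lineage", "tumor", "stem", "null")


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic screening cohort.

    Defaults model a desk-scale version of the study design: a 15-sample
    disease cohort against broad (n=15), stemlike (n=14, the HSC panel
    size) and maturelike (n=15, the PBMC panel size) comparators, 2000
    probes, a 30-gene lineage signature, 5 tumor-specific membrane targets,
    a 3 log2-unit planted shift and unit log2 noise.
    """

    n_genes: int = 2000
    fraction_membrane: float = 0.3
    n_disease: int = 15
    comparator_sizes: dict[str, int] = field(
        default_factory=lambda: {"broad": 15, "stemlike": 14, "maturelike": 15}
    )
    n_lineage: int = 30
    n_tumor: int = 5
    n_stem: int = 10
    effect_size: float = 3.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    baseline_floor: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise PipelineError("n_genes must be >= 1")
        if not 0 <= self.fraction_membrane <= 1:
            raise PipelineError("fraction_membrane must be in [0, 1]")
        if self.n_lineage + self.n_tumor + self.n_stem > self.n_genes:
            raise PipelineError("planted sets exceed n_genes")
        if self.n_disease < 2:
            raise PipelineError("disease cohort needs >= 2 samples")
        if set(self.comparator_sizes) != set(COMPARATORS):
            raise PipelineError(f"comparator_sizes must name {COMPARATORS}")
        if any(n < 2 for n in self.comparator_sizes.values()):
            raise PipelineError("every comparator needs >= 2 samples")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise PipelineError("spread parameters must be non-negative")


@dataclass
class GroundTruth:
    """Planted memberships and realized log2 group means, per gene."""

    table: pd.DataFrame  # index probe_id; membership + mean_<group> columns

    def genes_of(self, membership: str) -> list[str]:
        if membership not in MEMBERSHIPS:
            raise PipelineError(f"membership must be one of {MEMBERSHIPS}")
        return list(self.table.index[self.table["membership"] == membership])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float, size: int) -> np.ndarray:
    """Rejection-sample a normal truncated from below."""
    out = rng.normal(mean, sd, size)
    while True:
        bad = out < floor
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())


def generate_cohort(spec: SyntheticCohortSpec
                    ) -> tuple[ExpressionMatrix, CohortDesign,
                               ProbeAnnotation, GroundTruth]:
    """Sample one cohort; identical spec (incl. seed) -> identical bytes."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = spec.n_genes
    width = len(str(g))
    probes = [f"P{i:0{width}d}_at" for i in range(1, g + 1)]
    symbols = [f"G{i:0{width}d}" for i in range(1, g + 1)]

    membership = np.array(["null"] * g, dtype=object)
    planted = rng.permutation(g)[: spec.n_lineage + spec.n_tumor + spec.n_stem]
    membership[planted[: spec.n_lineage]] = "lineage"
    membership[planted[spec.n_lineage: spec.n_lineage + spec.n_tumor]] = "tumor"
    membership[planted[spec.n_lineage + spec.n_tumor:]] = "stem"

    membrane = rng.random(g) < spec.fraction_membrane
    membrane[planted] = True  # planted genes are surface candidates

    baseline = _truncated_normal(rng, spec.baseline_mean, spec.baseline_sd,
                                 spec.baseline_floor, g)

    groups = {"disease": spec.n_disease, **spec.comparator_sizes}
    prefixes = {"disease": "D", "broad": "B", "stemlike": "H", "maturelike": "M"}
    delta = spec.effect_size
    shifts = {
        "disease": np.where(np.isin(membership, ("lineage", "tumor")), delta, 0.0),
        "broad": np.zeros(g),
        "stemlike": np.where(membership == "stem", delta, 0.0),
        # the maturelike panel carries the lineage program at the same level
        "maturelike": np.where(membership == "lineage", delta, 0.0),
    }

    blocks, sample_ids, design_groups = [], [], {}
    for group, n in groups.items():
        ids = [f"{prefixes[group]}{j:02d}" for j in range(1, n + 1)]
        mean = baseline + shifts[group]
        noise = rng.normal(0.0, spec.noise_sd, size=(g, n))
        blocks.append(mean[:, None] + noise)
        sample_ids.extend(ids)
        design_groups[group] = tuple(ids)

    values = pd.DataFrame(np.concatenate(blocks, axis=1), index=probes,
                          columns=sample_ids)
    matrix = ExpressionMatrix(values, "log2")
    design = CohortDesign(groups=design_groups, disease_group="disease",
                          comparator_groups=COMPARATORS)
    ann = ProbeAnnotation(
        table=pd.DataFrame(
            {"symbol": symbols, "membrane": membrane, "family": "other"},
            index=pd.Index(probes, name="probe_id"),
        ),
        aliases={},
    )
    truth = pd.DataFrame(
        {"symbol": symbols, "membership": membership},
        index=pd.Index(probes, name="probe_id"),
    )
    for group in groups:
        truth[f"mean_{group}"] = baseline + shifts[group]
    return matrix, design, ann, GroundTruth(truth)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.table.reset_index().to_csv(path, sep="\t", index=False)


def recovery_report(truth: GroundTruth,
                    lists: Sequence[RankedTargetList],
                    consensus_table: pd.DataFrame) -> dict[str, float]:
    """How well ranked lists recover the planted structure.

    Symbols are matched at the gene level. Reports:

    * ``tumor_in_broad`` — fraction of tumor genes present in the broad-
      comparator list(s);
    * ``lineage_broad_only`` — fraction of lineage genes present against the
      broad comparator but absent against the maturelike comparator (the
      lineage-dropout signature);
    * ``tumor_full_consensus`` — fraction of tumor genes whose consensus
      count equals the number of comparators screened.
    """
    per_comp: dict[str, set[str]] = {}
    for lst in lists:
        per_comp.setdefault(lst.comparator, set()).update(lst.canonical_symbols)
    for needed in ("broad", "maturelike"):
        if needed not in per_comp:
            raise PipelineError(f"recovery_report needs a {needed!r} list")
    symbol_of = truth.table["symbol"]
    tumor = {symbol_of[p] for p in truth.genes_of("tumor")}
    lineage = {symbol_of[p] for p in truth.genes_of("lineage")}
    k = len(per_comp)
    counts = dict(zip(consensus_table["symbol"], consensus_table["n_comparators"]))
    report = {
        "tumor_in_broad":
            len(tumor & per_comp["broad"]) / len(tumor) if tumor else float("nan"),
        "lineage_broad_only":
            (len((lineage & per_comp["broad"]) - per_comp["maturelike"])
             / len(lineage)) if lineage else float("nan"),
        "tumor_full_consensus":
            (sum(counts.get(s, 0) == k for s in tumor) / len(tumor))
            if tumor else float("nan"),
    }
    return report
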