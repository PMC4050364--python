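"""Per-probe disease-vs-comparator scoring.

Three scores rank candidate targets, mirroring how array screens report
over-expression:

* **fold-change** — ratio of linear-scale group mean intensities (arrays are
  un-logged before averaging), with a configurable floor on the comparator
  mean so near-zero denominators cannot inflate the ratio without bound;
* **T score** — two-sample t statistic on log2 intensities, Welch by default
  (comparator panels have unequal variances by construction; a pooled
  variant is available);
* **gene-vs-outcome Pearson r** — point-biserial correlation between a
  probe's log2 values and 0/1 disease membership, disease coded 1 so a
  positive r means disease-high.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CohortDesign, ExpressionMatrix, PipelineError, ProbeAnnotation
from .preprocess import as_scale

DEFAULT_FC_FLOOR = 1.0


def group_mean(m: ExpressionMatrix, design: CohortDesign, group: str) -> pd.Series:
    """Per-probe mean of *linear*-scale intensities over a group's samples."""
    samples = design.samples_of(group)
    linear = as_scale(m, "linear")
    return linear.values[list(samples)].mean(axis=1)


def fold_change(disease_mean, comparator_mean,
                floor: float = DEFAULT_FC_FLOOR):
    """disease_mean / max(comparator_mean, floor), elementwise.

    The floor bounds ratio inflation when the comparator barely expresses a
    transcript; with both means above the floor, swapping the arguments
    yields the reciprocal.
    """
    if floor <= 0:
        raise PipelineError("fold-change floor must be > 0")
    comp = np.maximum(np.asarray(comparator_mean, dtype=float), floor)
    return np.asarray(disease_mean, dtype=float) / comp


def _group_arrays(m: ExpressionMatrix, design: CohortDesign,
                  g1: str, g2: str) -> tuple[np.ndarray, np.ndarray]:
    log2 = as_scale(m, "log2")
    a = log2.values[list(design.samples_of(g1))].to_numpy()
    b = log2.values[list(design.samples_of(g2))].to_numpy()
    return a, b


def t_score(m: ExpressionMatrix, design: CohortDesign, g1: str, g2: str,
            variant: str = "welch") -> pd.Series:
    """Per-probe two-sample t on log2 values; positive when g1 mean is higher.

    Degenerate probes: zero variance in both groups with equal means gives
    t = 0; zero variance with unequal means gives a signed infinity.
    """
    if variant not in ("welch", "pooled"):
        raise PipelineError(f"unknown t variant {variant!r}")
    a, b = _group_arrays(m, design, g1, g2)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise PipelineError("t_score requires >= 2 samples per group")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if variant == "welch":
        denom = np.sqrt(v1 / n1 + v2 / n2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t = np.where((denom == 0) & (diff == 0), 0.0, t)
    t = np.where((denom == 0) & (diff != 0), np.copysign(np.inf, diff), t)
    return pd.Series(t, index=m.values.index, name="t_score")


def welch_df(m: ExpressionMatrix, design: CohortDesign, g1: str, g2: str
             ) -> pd.Series:
    """Per-probe Welch-Satterthwaite degrees of freedom."""
    a, b = _group_arrays(m, design, g1, g2)
    n1, n2 = a.shape[1], b.shape[1]
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    u1, u2 = v1 / n1, v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (u1 + u2) ** 2 / (u1 ** 2 / (n1 - 1) + u2 ** 2 / (n2 - 1))
    return pd.Series(df, index=m.values.index, name="welch_df")


def pearson_outcome(m: ExpressionMatrix, labels: dict[str, int] | pd.Series
                    ) -> pd.Series:
    """Point-biserial correlation of each probe with a 0/1 sample labeling.

    ``labels`` must cover every sample of ``m`` and contain both classes.
    Constant probes get NaN (the undefined flag). Computed on log2 values.
    """
    labels = pd.Series(labels)
    missing = [s for s in m.sample_ids if s not in labels.index]
    if missing:
        raise PipelineError(f"labels missing for samples {missing[:5]}")
    y = labels[m.sample_ids].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise PipelineError("pearson_outcome: labels contain a single class")
    x = as_scale(m, "log2").values.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = xc @ yc
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / denom
    r = np.where((xc ** 2).sum(axis=1) == 0, np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    return pd.Series(r, index=m.values.index, name="pearson_r")


def score_all(m: ExpressionMatrix, design: CohortDesign, comparator: str,
              ann: ProbeAnnotation, fc_floor: float = DEFAULT_FC_FLOOR,
              t_variant: str = "welch") -> pd.DataFrame:
    """Full differential score table for disease vs one comparator panel.

    One row per probe (input order), columns: probe_id, symbol, canonical,
    disease_mean, comparator_mean, fold_change, t_score, pearson_r,
    n_disease, n_comparator. Fold-change uses linear means; t and r use
    log2 values; r is computed over disease+comparator samples with disease
    coded 1.
    """
    disease = design.disease_group
    if comparator not in design.comparator_groups:
        raise PipelineError(f"{comparator!r} is not a comparator group")
    d_mean = group_mean(m, design, disease)
    c_mean = group_mean(m, design, comparator)
    fc = fold_change(d_mean, c_mean, floor=fc_floor)
    t = t_score(m, design, disease, comparator, variant=t_variant)
    d_samples = list(design.samples_of(disease))
    c_samples = list(design.samples_of(comparator))
    sub = m.subset_samples(d_samples + c_samples)
    labels = {s: 1 for s in d_samples} | {s: 0 for s in c_samples}
    r = pearson_outcome(sub, labels)
    probes = m.probe_ids
    symbols, canon = [], []
    for p in probes:
        if not ann.has_probe(p):
            raise PipelineError(f"probe {p!r} has no annotation row")
        symbols.append(ann.symbol_of(p))
        canon.append(ann.canonical_of(p))
    return pd.DataFrame(
        {
            "probe_id": probes,
            "symbol": symbols,
            "canonical": canon,
            "disease_mean": d_mean.to_numpy(),
            "comparator_mean": c_mean.to_numpy(),
            "fold_change": np.asarray(fc),
            "t_score": t.to_numpy(),
            "pearson_r": r.to_numpy(),
            "n_disease": len(d_samples),
            "n_comparator": len(c_samples),
        }
    )
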