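"""Scale conversion, per-gene z-scoring, and optional probe collapsing.

Fold-changes are ratios of *linear*-scale group means while t statistics and
correlations are computed on *log2* intensities, so matrices move between the
two scales explicitly. Z-scoring is per probe row, using the mean and sample
standard deviation over a named sample subset (typically all leukemia
samples); other samples are transformed with the subset's statistics.

The default pipeline stays probe-level — distinct probes for one gene rank
separately, matching how array screens report hits — and collapsing to gene
symbols is a reporting convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PipelineError, ProbeAnnotation


@dataclass
class ZScoredMatrix:
    """Row-standardized expression with the applied statistics retained.

    ``degenerate`` flags constant rows, which are mapped to all-zero rather
    than erroring so clustering tolerates uninformative probes.
    """

    values: pd.DataFrame
    row_mean: pd.Series
    row_sd: pd.Series
    degenerate: pd.Series  # boolean per probe
    normalized_over: tuple[str, ...]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def to_linear(m: ExpressionMatrix) -> ExpressionMatrix:
    """2**x per cell; requires a log2-scale matrix."""
    if m.scale != "log2":
        raise PipelineError(f"to_linear requires log2 scale, got {m.scale}")
    return ExpressionMatrix(np.exp2(m.values), "linear")


def to_log2(m: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """log2(x + pseudocount) per cell; requires strictly positive arguments."""
    if m.scale != "linear":
        raise PipelineError(f"to_log2 requires linear scale, got {m.scale}")
    shifted = m.values + pseudocount
    if (shifted.to_numpy() <= 0).any():
        raise PipelineError(
            "to_log2: non-positive value after pseudocount "
            f"{pseudocount}; increase the pseudocount"
        )
    return ExpressionMatrix(np.log2(shifted), "log2")


def as_scale(m: ExpressionMatrix, scale: str, pseudocount: float = 0.0
             ) -> ExpressionMatrix:
    """Return ``m`` on the requested scale, converting if needed."""
    if m.scale == scale:
        return m
    return to_linear(m) if scale == "linear" else to_log2(m, pseudocount)


def zscore_rows(m: ExpressionMatrix, samples: list[str] | None = None,
                ddof: int = 1) -> ZScoredMatrix:
    """Standardize each probe row to mean 0, SD 1 over a sample subset.

    ``samples`` names the subset whose mean/SD define the transform (default:
    all samples); columns outside the subset are transformed with the
    subset's statistics. SD uses the n-1 (sample) denominator by default.
    """
    if samples is None:
        samples = m.sample_ids
    if not samples:
        raise PipelineError("zscore_rows: empty sample subset")
    missing = [s for s in samples if s not in m.values.columns]
    if missing:
        raise PipelineError(f"zscore_rows: unknown samples {missing}")
    sub = m.values[samples]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=ddof)
    degenerate = (sd == 0) | sd.isna()
    safe_sd = sd.mask(degenerate, 1.0)
    z = m.values.sub(mean, axis=0).div(safe_sd, axis=0)
    z = z.mask(pd.DataFrame(
        np.broadcast_to(degenerate.to_numpy()[:, None], z.shape),
        index=z.index, columns=z.columns), 0.0)
    return ZScoredMatrix(
        values=z,
        row_mean=mean,
        row_sd=sd.mask(degenerate, 0.0),
        degenerate=degenerate,
        normalized_over=tuple(samples),
    )


def collapse_probes(m: ExpressionMatrix, ann: ProbeAnnotation,
                    method: str = "max_mean") -> ExpressionMatrix:
    """Collapse probe rows to canonical gene symbols.

    ``max_mean`` keeps, per symbol, the probe row with the highest mean over
    all samples (output rows are bit-identical to input rows); ``mean``
    averages the probes of each symbol. Row order follows first appearance
    of each symbol.
    """
    if method not in ("max_mean", "mean"):
        raise PipelineError(f"unknown collapse method {method!r}")
    unannotated = [p for p in m.probe_ids if not ann.has_probe(p)]
    if unannotated:
        raise PipelineError(f"collapse_probes: unannotated probes {unannotated[:5]}")
    symbols = [ann.canonical_of(p) for p in m.probe_ids]
    order = list(dict.fromkeys(symbols))
    grouped = m.values.groupby(pd.Index(symbols, name="symbol"), sort=False)
    if method == "mean":
        out = grouped.mean()
    else:
        means = m.values.mean(axis=1)
        keep = []
        by_symbol: dict[str, list[str]] = {}
        for p, s in zip(m.probe_ids, symbols):
            by_symbol.setdefault(s, []).append(p)
        for s in order:
            probes = by_symbol[s]
            keep.append(max(probes, key=lambda p: (means[p], p)))
        out = m.values.loc[keep]
        out.index = pd.Index(order)
    return ExpressionMatrix(out.loc[order], m.scale)
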