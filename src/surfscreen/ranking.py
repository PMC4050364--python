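"""Membrane filtering, top-N target lists, list overlap and consensus.

This is the deliverable end of the screen: differential scores are restricted
to transcripts encoding plasma-membrane proteins (the candidate space for
antibody or CAR-T targeting), ranked per comparator panel, and the resulting
lists are compared across panels. Overlap between lists quantifies how much
of a target list is lineage signature shared with a comparator; the consensus
table counts, per gene, in how many comparator analyses it surfaces — genes
found against every panel (the HHIP pattern) are the highest-priority
candidates.

All cross-list matching is done on canonical gene symbols obtained by one
application of the alias map; probe ids are deliberately not used because
published lists do not always print them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .containers import FAMILIES, PipelineError, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)

METRICS = ("fold_change", "t_score", "pearson_r")

DENOMINATOR_RULES = ("len_a", "len_b", "union")


@dataclass(frozen=True)
class RankedEntry:
    """One row of a ranked target list."""

    rank: str
    probe_id: str  # empty string when the source list prints none
    symbol: str
    canonical: str
    score: float


@dataclass
class RankedTargetList:
    """Top-N membrane targets for one comparator panel under one metric.

    ``absolute`` records whether ranking was by |score| (used for the
    gene-vs-outcome correlation, where sign encodes the class direction).
    """

    comparator: str
    metric: str
    entries: tuple[RankedEntry, ...]
    absolute: bool = False

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        key = (lambda e: abs(e.score)) if self.absolute else (lambda e: e.score)
        scores = [key(e) for e in self.entries]
        if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValidationError(
                f"ranked list {self.comparator}/{self.metric}: scores increase "
                "with rank"
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def canonical_symbols(self) -> frozenset[str]:
        return frozenset(e.canonical for e in self.entries)

    @property
    def name(self) -> str:
        return f"{self.comparator}:{self.metric}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [e.rank for e in self.entries],
                "probe_id": [e.probe_id for e in self.entries],
                "symbol": [e.symbol for e in self.entries],
                "canonical": [e.canonical for e in self.entries],
                "score": [e.score for e in self.entries],
            }
        )


@dataclass(frozen=True)
class OverlapReport:
    """Shared canonical symbols between two ranked lists."""

    list_a: str
    list_b: str
    shared_symbols: tuple[str, ...]
    denominator_rule: str
    denominator: int
    percent_shared: float

    @property
    def shared_count(self) -> int:
        return len(self.shared_symbols)


def filter_membrane(scores: pd.DataFrame, ann: ProbeAnnotation) -> pd.DataFrame:
    """Keep only probes whose annotation carries the plasma-membrane flag.

    Input row order is preserved. Every probe in ``scores`` must be
    annotated; an unannotated probe is an error naming it.
    """
    keep = []
    for probe in scores["probe_id"]:
        if not ann.has_probe(probe):
            raise ValidationError(f"probe {probe!r} has no annotation row")
        keep.append(ann.is_membrane(probe))
    return scores.loc[keep].reset_index(drop=True)


def rank_targets(
    scores: pd.DataFrame,
    metric: str,
    n: int,
    comparator: str = "",
    absolute: bool = False,
) -> RankedTargetList:
    """Top-``n`` probes by ``metric``, descending.

    Ties are broken by canonical symbol ascending, then probe id ascending,
    so re-running on the same score table yields byte-identical output. If
    ``n`` exceeds the table size the full table is returned with a warning.
    """
    if metric not in scores.columns:
        raise PipelineError(f"metric {metric!r} not in score table")
    if n < 1:
        raise PipelineError("n must be >= 1")
    if n > len(scores):
        logger.warning(
            "requested top-%d but table has %d rows; returning all", n, len(scores)
        )
        n = len(scores)
    df = scores.copy()
    key = df[metric].abs() if absolute else df[metric]
    df = df.assign(_key=key.to_numpy())
    df = df.sort_values(
        ["_key", "canonical", "probe_id"], ascending=[False, True, True],
        kind="mergesort",
    ).head(n)
    entries = tuple(
        RankedEntry(
            rank=str(i + 1),
            probe_id=str(row.probe_id),
            symbol=str(row.symbol),
            canonical=str(row.canonical),
            score=float(getattr(row, metric)),
        )
        for i, row in enumerate(df.itertuples(index=False))
    )
    return RankedTargetList(
        comparator=comparator, metric=metric, entries=entries, absolute=absolute
    )


def canonicalize(symbol: str, aliases: Mapping[str, str]) -> str:
    """One alias-map application; unknown symbols map to themselves."""
    return aliases.get(symbol, symbol)


def classify_family(canonical: str, families: Mapping[str, str]) -> str:
    """Family tag (TCR_chain, CD3_complex, other) for a canonical symbol."""
    fam = families.get(canonical, "other")
    if fam not in FAMILIES:
        logger.warning("unknown family %r for %s; using 'other'", fam, canonical)
        return "other"
    return fam


def shared_fraction(
    list_a: RankedTargetList,
    list_b: RankedTargetList,
    denominator: str = "len_a",
) -> OverlapReport:
    """Strict canonical-symbol intersection of two ranked lists.

    ``percent_shared`` is the shared count relative to the chosen
    denominator rule; the default ``len_a`` treats A as the query list being
    checked against reference list B.
    """
    if denominator not in DENOMINATOR_RULES:
        raise PipelineError(f"denominator must be one of {DENOMINATOR_RULES}")
    if not list_a.entries or not list_b.entries:
        raise PipelineError("overlap requires non-empty lists")
    shared = sorted(list_a.canonical_symbols & list_b.canonical_symbols)
    denom = {
        "len_a": len(list_a.canonical_symbols),
        "len_b": len(list_b.canonical_symbols),
        "union": len(list_a.canonical_symbols | list_b.canonical_symbols),
    }[denominator]
    return OverlapReport(
        list_a=list_a.name,
        list_b=list_b.name,
        shared_symbols=tuple(shared),
        denominator_rule=denominator,
        denominator=denom,
        percent_shared=100.0 * len(shared) / denom,
    )


def consensus(lists: Sequence[RankedTargetList]) -> pd.DataFrame:
    """Per-gene count of comparator panels whose top lists contain it.

    Lists are pooled per comparator: a gene counts once per comparator if it
    appears in any of that comparator's lists (any metric). Returns a frame
    with columns symbol, n_comparators, comparators, sorted by descending
    count then symbol.
    """
    if len({l.comparator for l in lists}) < 2:
        raise PipelineError("consensus requires lists from >= 2 comparators")
    per_comp: dict[str, set[str]] = {}
    for lst in lists:
        per_comp.setdefault(lst.comparator, set()).update(lst.canonical_symbols)
    rows: dict[str, list[str]] = {}
    for comp in sorted(per_comp):
        for sym in per_comp[comp]:
            rows.setdefault(sym, []).append(comp)
    frame = pd.DataFrame(
        {
            "symbol": list(rows),
            "n_comparators": [len(v) for v in rows.values()],
            "comparators": [";".join(v) for v in rows.values()],
        }
    )
    return frame.sort_values(
        ["n_comparators", "symbol"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def consensus_count(table: pd.DataFrame, symbol: str) -> int:
    """Consensus count for one canonical symbol (0 when absent everywhere)."""
    hit = table.loc[table["symbol"] == symbol, "n_comparators"]
    return int(hit.iloc[0]) if len(hit) else 0


def family_breakdown(
    lst: RankedTargetList, families: Mapping[str, str]
) -> dict[str, int]:
    """Counts per gene family in a ranked list; counts sum to the list length.

    Each entry counts once, so distinct TCR variable/constant chain entries
    each contribute to the TCR_chain tally.
    """
    counts = Counter(classify_family(e.canonical, families) for e in lst.entries)
    return {fam: counts.get(fam, 0) for fam in FAMILIES}
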