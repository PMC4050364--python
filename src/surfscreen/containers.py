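"""Core data containers: expression matrices, cohort designs, probe annotation.

The screen operates on three objects throughout: an :class:`ExpressionMatrix`
(probes x samples, with an explicit intensity scale), a :class:`CohortDesign`
assigning every sample to exactly one group (the disease cohort or one of the
named normal comparator panels), and a :class:`ProbeAnnotation` mapping probes
to gene symbols, a plasma-membrane flag, and a gene-family tag (TCR chain /
CD3 complex / other) plus a symbol-alias table used for gene-level matching
across differently formatted target lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCALES = ("log2", "linear")

FAMILIES = ("TCR_chain", "CD3_complex", "other")


class PipelineError(Exception):
    """Base class for errors raised by the screening pipeline."""


class FormatError(PipelineError):
    """A file or table does not conform to the expected format."""


class ValidationError(PipelineError):
    """An in-memory object violates one of its invariants."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


class ExpressionMatrix:
    """Probe x sample intensity grid with an explicit scale tag.

    Parameters
    ----------
    values
        DataFrame with probe ids as index and sample ids as columns. Every
        cell must be a finite number; on the linear scale all values must be
        non-negative. Row and column order is preserved.
    scale
        ``"log2"`` or ``"linear"``. The scale is always declared explicitly
        and never inferred from value ranges.
    """

    def __init__(self, values: pd.DataFrame, scale: str):
        if scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {scale!r}")
        _check_unique(values.index, "probe")
        _check_unique(values.columns, "sample")
        arr = values.to_numpy(dtype=float, copy=False)
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at probe {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
        if scale == "linear" and arr.size and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative linear-scale value at probe {values.index[bad[0]]!r}"
            )
        self.values = values.astype(float)
        self.scale = scale

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(self.values[samples], self.scale)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.scale == other.scale and self.values.equals(other.values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n, m = self.shape
        return f"ExpressionMatrix({n} probes x {m} samples, scale={self.scale})"


@dataclass
class CohortDesign:
    """Assignment of samples to exactly one group.

    ``disease_group`` names the leukemia cohort; ``comparator_groups`` are
    the normal panels it is scored against (broad multi-tissue, HSC-like,
    PBMC-like, ...). Each comparator needs at least two samples so a group
    variance is computable.
    """

    groups: dict[str, tuple[str, ...]]
    disease_group: str
    comparator_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        self.groups = {g: tuple(s) for g, s in self.groups.items()}
        self.comparator_groups = tuple(self.comparator_groups)
        if self.disease_group not in self.groups:
            raise ValidationError(f"disease group {self.disease_group!r} not in groups")
        if self.disease_group in self.comparator_groups:
            raise ValidationError("disease group cannot also be a comparator")
        seen: dict[str, str] = {}
        for g, samples in self.groups.items():
            if not samples:
                raise ValidationError(f"group {g!r} is empty")
            for s in samples:
                if s in seen:
                    raise ValidationError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {g!r}"
                    )
                seen[s] = g
        for g in self.comparator_groups:
            if g not in self.groups:
                raise ValidationError(f"comparator group {g!r} not in groups")
            if len(self.groups[g]) < 2:
                raise ValidationError(
                    f"comparator group {g!r} has fewer than 2 samples"
                )

    @property
    def all_samples(self) -> list[str]:
        return [s for g in self.groups.values() for s in g]

    def samples_of(self, group: str) -> tuple[str, ...]:
        if group not in self.groups:
            raise ValidationError(f"unknown group {group!r}")
        return self.groups[group]


@dataclass
class ProbeAnnotation:
    """Probe -> (gene symbol, membrane flag, family tag) plus an alias map.

    The alias map rewrites printed symbol variants (``CD62L``, ``MHMA1``,
    ``ICAM-3/CD50`` ...) to one canonical symbol per gene and must be
    idempotent: canonical symbols map to themselves.
    """

    table: pd.DataFrame  # index probe_id; columns symbol, membrane, family
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"symbol", "membrane", "family"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation table missing columns {sorted(missing)}")
        _check_unique(self.table.index, "probe")
        bad_fam = set(self.table["family"]) - set(FAMILIES)
        if bad_fam:
            raise ValidationError(f"unknown family tags {sorted(bad_fam)}")
        for alias, canon in self.aliases.items():
            if self.aliases.get(canon, canon) != canon:
                raise ValidationError(
                    f"alias map not idempotent: {alias!r} -> {canon!r} -> "
                    f"{self.aliases[canon]!r}"
                )

    def has_probe(self, probe: str) -> bool:
        return probe in self.table.index

    def symbol_of(self, probe: str) -> str:
        return str(self.table.at[probe, "symbol"])

    def canonical_of(self, probe: str) -> str:
        return self.canonicalize(self.symbol_of(probe))

    def canonicalize(self, symbol: str) -> str:
        """One alias-map application; unknown symbols map to themselves."""
        return self.aliases.get(symbol, symbol)

    def is_membrane(self, probe: str) -> bool:
        return bool(self.table.at[probe, "membrane"])

    def family_of(self, probe: str) -> str:
        return str(self.table.at[probe, "family"])

    def family_of_symbol(self, symbol: str) -> str:
        """Family tag for a canonical symbol (majority over probes; 'other' if unseen)."""
        canon = self.canonicalize(symbol)
        canon_col = self.table["symbol"].map(self.canonicalize)
        fams = self.table.loc[canon_col == canon, "family"]
        if fams.empty:
            return "other"
        return str(fams.mode().iloc[0])


def design_from_frame(frame: pd.DataFrame, disease_group: str,
                      comparator_groups: Iterable[str]) -> CohortDesign:
    """Build a CohortDesign from a two-column (sample_id, group) table."""
    groups: dict[str, list[str]] = {}
    for sample, group in zip(frame["sample_id"], frame["group"]):
        groups.setdefault(str(group), []).append(str(sample))
    return CohortDesign(
        groups={g: tuple(s) for g, s in groups.items()},
        disease_group=disease_group,
        comparator_groups=tuple(comparator_groups),
    )
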