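"""Readers and writers for every table the screen touches.

Canonical on-disk formats are plain TSV (comma accepted via ``sep``):

* expression matrix — header ``probe_id<TAB>sample...``, one probe per row;
* GEO Series Matrix text dialect (read-only) — ``!``-prefixed metadata, data
  between the standard table sentinels;
* annotation — columns ``probe_id, symbol, membrane, family``; alias table
  with columns ``alias, canonical``;
* design — columns ``sample_id, group``;
* ranked target lists, overlap reports and consensus tables with stable,
  documented column orders.

The package also bundles curated reference target lists for pediatric
T-ALL/B-ALL transcribed from a published microarray screen (top cell-surface
transcripts versus a 117-tissue broad normal panel, CD34+ HSC, and normal
PBMC comparators), used as fixtures for overlap and consensus analysis.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    CohortDesign,
    ExpressionMatrix,
    FAMILIES,
    FormatError,
    ProbeAnnotation,
    ValidationError,
)
from .ranking import OverlapReport, RankedEntry, RankedTargetList

logger = logging.getLogger(__name__)

SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
SERIES_MATRIX_END = "!series_matrix_table_end"

#: fixture id -> (comparator name, ranking metric)
REFERENCE_LISTS: dict[str, tuple[str, str]] = {
    "tall_vs_normal": ("broad_normal", "fold_change"),
    "ball_vs_normal": ("broad_normal_ball", "fold_change"),
    "tall_vs_hsc_tscore": ("hsc", "t_score"),
    "tall_vs_hsc_fc": ("hsc", "fold_change"),
    "tall_vs_pbmc_tscore": ("pbmc", "t_score"),
    "tall_vs_pbmc_fc": ("pbmc", "fold_change"),
}


def _strip_quotes(token: str) -> str:
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "\"'":
        return token[1:-1]
    return token


def _parse_matrix_lines(
    lines: list[str], scale: str, sep: str, where: str
) -> ExpressionMatrix:
    if not lines:
        raise FormatError(f"{where}: empty table")
    header = [_strip_quotes(t) for t in lines[0].rstrip("\n").split(sep)]
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{where}: header row has no sample columns")
    probes: list[str] = []
    rows: list[list[float]] = []
    width = len(header)
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.rstrip("\n").split(sep)
        if len(parts) != width:
            raise FormatError(
                f"{where}: ragged row at line {lineno} "
                f"({len(parts)} fields, expected {width})"
            )
        probe = _strip_quotes(parts[0])
        values = []
        for j, cell in enumerate(parts[1:]):
            cell = _strip_quotes(cell).strip()
            if cell == "":
                raise FormatError(
                    f"{where}: empty cell at probe {probe!r}, "
                    f"sample {sample_ids[j]!r} (missing values unsupported)"
                )
            try:
                values.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{where}: non-numeric cell {cell!r} at probe {probe!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
        probes.append(probe)
        rows.append(values)
    frame = pd.DataFrame(np.asarray(rows, dtype=float), index=probes,
                         columns=sample_ids)
    return ExpressionMatrix(frame, scale)


def read_expression_table(path: str | Path, scale: str,
                          sep: str = "\t") -> ExpressionMatrix:
    """Read a probe x sample matrix from a delimited text table.

    Row and column order are preserved from the file. Duplicate ids,
    non-numeric cells, empty cells and ragged rows are rejected with the
    offending coordinates.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [l for l in lines if l.strip() != ""]
    return _parse_matrix_lines(lines, scale, sep, str(path))


def write_expression_table(m: ExpressionMatrix, path: str | Path,
                           sep: str = "\t") -> None:
    """Write a matrix as TSV; values keep up to 12 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join(["probe_id", *m.sample_ids]) + "\n")
        for probe, row in zip(m.probe_ids, m.values.to_numpy()):
            cells = (f"{v:.12g}" for v in row)
            fh.write(sep.join([probe, *cells]) + "\n")


def read_series_matrix(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    """Read the data block of a GEO Series Matrix text file.

    Only lines between the table-begin and table-end sentinels are parsed;
    all ``!``-prefixed metadata is ignored. Quoted sample headers and probe
    ids are unquoted. The scale is recorded as log2 unless overridden —
    series matrices customarily hold log-transformed intensities.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        begin = next(
            i for i, l in enumerate(lines)
            if l.strip().lower() == SERIES_MATRIX_BEGIN
        )
    except StopIteration:
        raise FormatError(f"{path}: missing {SERIES_MATRIX_BEGIN} sentinel") from None
    try:
        end = next(
            i for i, l in enumerate(lines[begin + 1:], start=begin + 1)
            if l.strip().lower() == SERIES_MATRIX_END
        )
    except StopIteration:
        raise FormatError(f"{path}: missing {SERIES_MATRIX_END} sentinel") from None
    block = [l for l in lines[begin + 1:end] if l.strip() != ""]
    if not block or len(block) < 2:
        raise FormatError(f"{path}: empty series-matrix data block")
    return _parse_matrix_lines(block, scale, "\t", str(path))


def read_design(path: str | Path, disease_group: str,
                comparator_groups: list[str], sep: str = "\t") -> CohortDesign:
    """Read a sample_id/group table into a CohortDesign."""
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"sample_id", "group"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: design table missing columns {sorted(missing)}")
    groups: dict[str, list[str]] = {}
    for sample, group in zip(frame["sample_id"], frame["group"]):
        groups.setdefault(group, []).append(sample)
    return CohortDesign(
        groups={g: tuple(s) for g, s in groups.items()},
        disease_group=disease_group,
        comparator_groups=tuple(comparator_groups),
    )


def write_design(design: CohortDesign, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for group, samples in design.groups.items():
            for s in samples:
                fh.write(f"{s}\t{group}\n")


def read_annotation(path: str | Path, alias_path: str | Path | None = None,
                    sep: str = "\t") -> ProbeAnnotation:
    """Read a probe annotation table and optional alias table.

    Unknown family strings map to ``other`` with a logged warning. A probe
    annotated twice with conflicting symbols is rejected; exact duplicate
    rows are tolerated and collapsed.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"probe_id", "symbol", "membrane", "family"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns {sorted(missing)}")
    dup = frame[frame.duplicated("probe_id", keep=False)]
    for probe, sub in dup.groupby("probe_id"):
        if sub["symbol"].nunique() > 1:
            raise FormatError(
                f"{path}: probe {probe!r} annotated with conflicting symbols "
                f"{sorted(sub['symbol'].unique())}"
            )
    frame = frame.drop_duplicates("probe_id")
    family = frame["family"].where(frame["family"].isin(FAMILIES), None)
    n_bad = family.isna().sum()
    if n_bad:
        logger.warning("%d unknown family tags mapped to 'other'", n_bad)
    table = pd.DataFrame(
        {
            "symbol": frame["symbol"].to_numpy(),
            "membrane": frame["membrane"]
            .str.lower()
            .isin(("true", "1", "yes", "t"))
            .to_numpy(),
            "family": family.fillna("other").to_numpy(),
        },
        index=pd.Index(frame["probe_id"], name="probe_id"),
    )
    aliases = read_aliases(alias_path, sep=sep) if alias_path is not None else {}
    return ProbeAnnotation(table=table, aliases=aliases)


def read_aliases(path: str | Path, sep: str = "\t") -> dict[str, str]:
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"alias", "canonical"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: alias table missing columns {sorted(missing)}")
    return dict(zip(frame["alias"], frame["canonical"]))


def write_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    frame = ann.table.reset_index()
    frame["membrane"] = frame["membrane"].map({True: "true", False: "false"})
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables

RANKED_COLUMNS = ["rank", "probe_id", "symbol", "canonical", "score"]
OVERLAP_COLUMNS = [
    "list_a", "list_b", "shared_count", "denominator", "percent_shared",
    "shared_symbols",
]
CONSENSUS_COLUMNS = ["symbol", "n_comparators", "comparators"]


def write_ranked_list(lst: RankedTargetList, path: str | Path) -> None:
    lst.to_frame()[RANKED_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ranked_list(path: str | Path, comparator: str, metric: str,
                     absolute: bool = False) -> RankedTargetList:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(RANKED_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: ranked list missing columns {sorted(missing)}")
    entries = tuple(
        RankedEntry(
            rank=row["rank"],
            probe_id=row["probe_id"],
            symbol=row["symbol"],
            canonical=row["canonical"],
            score=float(row["score"]),
        )
        for _, row in frame.iterrows()
    )
    return RankedTargetList(comparator=comparator, metric=metric,
                            entries=entries, absolute=absolute)


def write_overlap_reports(reports: list[OverlapReport], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "list_a": [r.list_a for r in reports],
            "list_b": [r.list_b for r in reports],
            "shared_count": [r.shared_count for r in reports],
            "denominator": [r.denominator for r in reports],
            "percent_shared": [round(r.percent_shared, 6) for r in reports],
            "shared_symbols": [";".join(r.shared_symbols) for r in reports],
        }
    )
    frame[OVERLAP_COLUMNS].to_csv(path, sep="\t", index=False)


def write_consensus(table: pd.DataFrame, path: str | Path) -> None:
    table[CONSENSUS_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bundled reference lists

def _fixture_path(name: str):
    return resources.files("surfscreen.fixtures").joinpath(name)


def load_reference_list(name: str) -> RankedTargetList:
    """Load one of the bundled published reference target lists.

    Valid names: ``tall_vs_normal``, ``ball_vs_normal``,
    ``tall_vs_hsc_tscore``, ``tall_vs_hsc_fc``, ``tall_vs_pbmc_tscore``,
    ``tall_vs_pbmc_fc``. Entries keep the symbols exactly as printed plus a
    curated canonical symbol, in printed order.
    """
    if name not in REFERENCE_LISTS:
        raise FormatError(
            f"unknown reference list {name!r}; valid names: "
            f"{sorted(REFERENCE_LISTS)}"
        )
    comparator, metric = REFERENCE_LISTS[name]
    frame = pd.read_csv(_fixture_path(f"{name}.tsv"), sep="\t", dtype=str,
                        keep_default_na=False)
    entries = tuple(
        RankedEntry(
            rank=row["rank"],
            probe_id=row["probe_id"],
            symbol=row["symbol"],
            canonical=row["canonical"],
            score=float(row["score"]),
        )
        for _, row in frame.iterrows()
    )
    return RankedTargetList(comparator=comparator, metric=metric, entries=entries)


def reference_aliases() -> dict[str, str]:
    """Curated symbol-alias map shipped with the reference lists."""
    frame = pd.read_csv(_fixture_path("aliases.tsv"), sep="\t", dtype=str,
                        keep_default_na=False)
    return dict(zip(frame["alias"], frame["canonical"]))


def reference_families() -> dict[str, str]:
    """Curated gene-family tags (TCR_chain / CD3_complex) for list symbols."""
    frame = pd.read_csv(_fixture_path("families.tsv"), sep="\t", dtype=str,
                        keep_default_na=False)
    return dict(zip(frame["canonical"], frame["family"]))
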