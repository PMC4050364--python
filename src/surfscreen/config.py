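"""Run configuration: a flat key=value text file, validated all at once.

Unknown keys are rejected, and validation collects every problem before
reporting, so a bad config is fixed in one pass. CLI flags override config
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .containers import PipelineError

_LIST_KEYS = {"comparators", "metrics"}
_INT_KEYS = {"top_n", "seed"}
_FLOAT_KEYS = {"fc_floor"}
_VALID_METRICS = ("fold_change", "t_score", "pearson_r")


class ConfigError(PipelineError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    matrix: str = ""
    design: str = ""
    annotation: str = ""
    aliases: str | None = None
    disease_group: str = "disease"
    comparators: tuple[str, ...] = ()
    metrics: tuple[str, ...] = ("fold_change", "t_score")
    top_n: int = 40
    fc_floor: float = 1.0
    t_variant: str = "welch"
    collapse_method: str = "none"
    scale: str = "log2"
    sep: str = "\t"
    distance: str = "euclidean"
    linkage: str = "average"
    out_dir: str = "screen_out"
    seed: int = 0

    def to_manifest(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(v)
            if v is None:
                v = ""
            if f.name == "sep":
                v = "tab" if v == "\t" else v
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"


def parse_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` file; '#' starts a comment line."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError([f"line {lineno}: expected key=value, got {line!r}"])
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()
    return raw


def validate_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig, collecting *all* errors before raising."""
    raw = parse_config(path)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    errors: list[str] = []
    known = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    kwargs: dict = {}
    for key, value in raw.items():
        if key not in known:
            continue
        if key in _LIST_KEYS:
            kwargs[key] = tuple(
                t.strip() for t in str(value).split(",") if t.strip()
            )
        elif key in _INT_KEYS:
            try:
                kwargs[key] = int(value)
            except (TypeError, ValueError):
                errors.append(f"{key}: not an integer: {value!r}")
        elif key in _FLOAT_KEYS:
            try:
                kwargs[key] = float(value)
            except (TypeError, ValueError):
                errors.append(f"{key}: not a number: {value!r}")
        elif key == "sep":
            kwargs[key] = "\t" if value in ("tab", "\\t") else str(value)
        else:
            kwargs[key] = str(value)
    cfg = RunConfig(**kwargs)

    for key in ("matrix", "design", "annotation"):
        p = getattr(cfg, key)
        if not p:
            errors.append(f"missing required path {key!r}")
        elif not Path(p).exists():
            errors.append(f"{key}: no such file {p!r}")
    if cfg.aliases and not Path(cfg.aliases).exists():
        errors.append(f"aliases: no such file {cfg.aliases!r}")
    if not cfg.comparators:
        errors.append("comparators: at least one comparator group required")
    if cfg.top_n < 1:
        errors.append("top_n: must be >= 1")
    if cfg.fc_floor <= 0:
        errors.append("fc_floor: must be > 0")
    if cfg.scale not in ("log2", "linear"):
        errors.append(f"scale: must be log2 or linear, got {cfg.scale!r}")
    if cfg.t_variant not in ("welch", "pooled"):
        errors.append(f"t_variant: must be welch or pooled, got {cfg.t_variant!r}")
    if cfg.collapse_method not in ("none", "max_mean", "mean"):
        errors.append("collapse_method: must be none, max_mean or mean")
    bad_metrics = [m for m in cfg.metrics if m not in _VALID_METRICS]
    if bad_metrics:
        errors.append(f"metrics: unknown {bad_metrics}")
    if errors:
        raise ConfigError(errors)
    return cfg
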