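"""Table readers/writers, run configuration and provenance headers.

All tables are tab-separated with explicit column names; report files
carry ``#``-prefixed provenance header lines (tool version, seed,
configuration hash) that readers skip transparently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "RunConfig",
    "read_table",
    "read_band_matrix",
    "write_table",
    "write_json",
    "config_hash",
]


def _binary(value: Any) -> int:
    v = int(value)
    if v not in (0, 1):
        raise ValueError(f"expected 0 or 1, got {value!r}")
    return v


SCHEMAS: dict[str, dict[str, Callable[[Any], Any]]] = {
    "loci": {"locus": str, "chromosome": str, "allele": str, "carriers": str},
    "progeny": {"progeny_id": str, "locus": str, "allele": str, "present": _binary},
    "samples": {"sample": str, "genotype": str, "group": str},
    "annotation": {"gene": str, "term": str},
    "ct": {"sample": str, "gene": str, "ct": float},
}


@dataclass
class RunConfig:
    """Plain-text key=value run configuration.

    Thresholds default to the study conventions: significance stars at
    p <= 0.05 / 0.01, differential expression at |log2FC| > 1 with
    BH-adjusted p < 0.05.
    """

    out_dir: Path = Path("polyploidkit_out")
    seed: int = 0
    alpha: float = 0.05
    alpha_strict: float = 0.01
    log2fc_cutoff: float = 1.0
    fdr: float = 0.05
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_strict", "log2fc_cutoff", "fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        known = {"out_dir", "seed", "alpha", "alpha_strict", "log2fc_cutoff", "fdr"}
        kwargs: dict[str, Any] = {}
        extra: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "out_dir":
                kwargs[key] = Path(value)
            elif key == "seed":
                kwargs[key] = int(value)
            elif key in known:
                kwargs[key] = float(value)
            else:
                extra[key] = value
        return cls(extra=extra, **kwargs)

    def as_dict(self) -> dict[str, Any]:
        d = {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "alpha": self.alpha,
            "alpha_strict": self.alpha_strict,
            "log2fc_cutoff": self.log2fc_cutoff,
            "fdr": self.fdr,
        }
        d.update(self.extra)
        return d


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable digest of a configuration mapping."""
    payload = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_table(path: str | Path, schema: str | Mapping[str, Callable[[Any], Any]]) -> pd.DataFrame:
    """Read and validate a tab-separated table against a column schema.

    ``schema`` is a known schema name (see ``SCHEMAS``) or a mapping of
    required column names to converters.  Missing or extra columns and
    invalid cell values raise descriptive errors naming the offending
    row.
    """
    if isinstance(schema, str):
        try:
            schema = SCHEMAS[schema]
        except KeyError:
            raise ValueError(f"unknown schema {schema!r}") from None
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = set(schema) - set(df.columns)
    extra = set(df.columns) - set(schema)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if extra:
        raise ValueError(f"{path}: unexpected columns {sorted(extra)}")
    out = {}
    for col, convert in schema.items():
        values = []
        for row, raw in enumerate(df[col], start=2):  # header is line 1
            try:
                values.append(convert(raw))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: invalid value {raw!r} in column {col!r}, line {row}: {exc}"
                ) from None
        out[col] = values
    return pd.DataFrame(out)


def read_band_matrix(path: str | Path) -> pd.DataFrame:
    """Read an MSAP band matrix: columns individual, lane, site_1..site_n (0/1)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("individual", "lane"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    sites = [c for c in df.columns if c not in ("individual", "lane")]
    if not sites:
        raise ValueError(f"{path}: no site columns")
    for col in sites:
        bad = ~df[col].isin((0, 1))
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2
            raise ValueError(
                f"{path}: non-binary band value {df[col][bad].iloc[0]!r} "
                f"in column {col!r}, line {row}"
            )
    return df.set_index(["individual", "lane"])[sites]


def _provenance(seed: int | None, config: Mapping[str, Any] | None) -> list[str]:
    lines = [f"# polyploidkit version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config hash: {config_hash(config)}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
    index: bool = False,
) -> Path:
    """Write a report table with a provenance header; round-trips exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\n".join(_provenance(seed, config))
    body = df.to_csv(sep="\t", index=index)
    path.write_text(f"{header}\n{body}")
    return path


def write_json(
    obj: Any,
    path: str | Path,
    *,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> Path:
    """Write a JSON report; provenance is embedded under a ``_provenance`` key."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    provenance: dict[str, Any] = {"tool_version": __version__}
    if seed is not None:
        provenance["seed"] = seed
    if config is not None:
        provenance["config_hash"] = config_hash(config)

    def _default(o: Any) -> Any:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    payload = {"_provenance": provenance, "results": obj}
    path.write_text(json.dumps(payload, indent=2, default=_default, sort_keys=True) + "\n")
    return path
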