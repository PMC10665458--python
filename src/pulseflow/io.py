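"""Tidy-CSV readers and writers with provenance headers.

Every output file starts with ``#``-prefixed metadata lines (package
version, parameter-file hash, run parameters) so a number can always be
traced back to the configuration that produced it.  Writes are atomic
(temp file + rename) and reruns with identical inputs are byte-identical —
no timestamps.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import pandas as pd

from . import __version__
from .accounting import EmissionInventory, GrasslandInventory
from .params import InputError


def metadata_lines(meta: dict) -> list[str]:
    lines = [f"# pulseflow={__version__}"]
    lines += [f"# {key}={value}" for key, value in sorted(meta.items())]
    return lines


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a tidy CSV with a commented metadata header, atomically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = df.to_csv(index=False, float_format="%.10g")
    text = "\n".join(metadata_lines(meta or {})) + "\n" + body
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed CSV ({exc})") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(
            f"{path}: header is missing required columns {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def read_emissions(path: str | Path) -> EmissionInventory:
    """Read an emissions CSV (region, species, gas, tonnes_per_year)."""
    df = _read_csv(path, ("region", "species", "gas", "tonnes_per_year"))
    try:
        return EmissionInventory.from_frame(df)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from None


def read_grasslands(path: str | Path) -> GrasslandInventory:
    """Read a grassland CSV (region, area_ha, soc_t_per_ha)."""
    df = _read_csv(path, ("region", "area_ha", "soc_t_per_ha"))
    try:
        return GrasslandInventory.from_frame(df)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from None
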