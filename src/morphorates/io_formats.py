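"""Readers and writers for the standard formats the pipeline touches.

* TPS-dialect outline files (the format emitted by outline digitizers):
  both ``LM=0 / CURVES=1 / POINTS=n`` records and plain ``POINTS=n``
  records are accepted, with an optional ``ID=`` label line.
* Newick trees (read through dendropy via :class:`~morphorates.phylo.Phylogeny`).
* UTF-8 CSV tables ("." decimal separator, no locale dependence) for
  specimen metadata, coefficients and result records, written at full
  double precision so a write/read round trip is bit-exact.

Parsers never silently drop records: any mismatch between a declared
point count and the coordinates found raises a parse error naming the
offending record.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .efa import Outline
from .errors import DataError, TPSParseError
from .phylo import Phylogeny

__all__ = [
    "SpecimenRecord",
    "read_tps_outlines",
    "write_tps_outlines",
    "read_newick",
    "read_specimen_table",
    "write_table",
    "read_table",
    "write_result_tables",
]

SEXES = ("female", "male", "unknown")
FLOAT_FORMAT = "%.17g"  # round-trips IEEE doubles exactly


@dataclasses.dataclass(frozen=True)
class SpecimenRecord:
    """One measured structure of one individual."""

    specimen_id: str
    species: str
    sex: str
    trait: str
    outline_source: str
    trait_size: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataError(
                f"sex must be one of {SEXES}, got {self.sex!r} "
                f"for specimen {self.specimen_id!r}"
            )
        if self.trait_size is not None and self.trait_size < 0:
            raise DataError(f"negative trait_size for specimen {self.specimen_id!r}")


# ---------------------------------------------------------------------------
# TPS outline files

_KEY_RE = re.compile(r"^([A-Za-z]+)\s*=\s*(.*)$")


def read_tps_outlines(path) -> list[tuple[str, Outline]]:
    """Parse a TPS-dialect outline file into (label, Outline) pairs.

    Records start at an ``LM=`` or ``POINTS=`` key; the declared number of
    coordinate lines must follow.  Labels come from ``ID=`` lines when
    present, otherwise the zero-based record index is used.
    """
    path = Path(path)
    records: list[dict] = []
    current: dict | None = None

    def start_record() -> dict:
        nonlocal current
        finish_record()
        current = {"declared": None, "points": [], "label": None}
        records.append(current)
        return current

    def finish_record() -> None:
        if current is None:
            return
        _validate_record(current, len(records) - 1, path)

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _KEY_RE.match(line)
            if m:
                key, value = m.group(1).upper(), m.group(2).strip()
                if key == "LM":
                    rec = start_record()
                    if value not in ("", "0"):
                        raise TPSParseError(
                            f"{path}: record {len(records) - 1}: landmark records "
                            f"(LM={value}) are not supported, only outlines"
                        )
                elif key == "POINTS":
                    if current is None or current["declared"] is not None:
                        rec = start_record()
                    else:
                        rec = current
                    try:
                        rec["declared"] = int(value)
                    except ValueError:
                        raise TPSParseError(
                            f"{path}:{lineno}: bad POINTS declaration {value!r}"
                        ) from None
                elif key == "CURVES":
                    if value not in ("", "1"):
                        raise TPSParseError(
                            f"{path}:{lineno}: only single-curve records are "
                            f"supported (CURVES={value})"
                        )
                elif key == "ID":
                    if current is None:
                        raise TPSParseError(f"{path}:{lineno}: ID= before any record")
                    current["label"] = value
                else:
                    # IMAGE=, SCALE=, COMMENT= ... metadata we do not need
                    continue
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise TPSParseError(
                        f"{path}:{lineno}: expected 'x y' coordinates, got {line!r}"
                    )
                if current is None or current["declared"] is None:
                    raise TPSParseError(
                        f"{path}:{lineno}: coordinates outside a POINTS record"
                    )
                if len(current["points"]) >= current["declared"]:
                    raise TPSParseError(
                        f"{path}: record "
                        f"{current['label'] or len(records) - 1}: more coordinate "
                        f"lines than the declared POINTS={current['declared']}"
                    )
                try:
                    current["points"].append((float(parts[0]), float(parts[1])))
                except ValueError:
                    raise TPSParseError(
                        f"{path}:{lineno}: non-numeric coordinates {line!r}"
                    ) from None
    finish_record()

    out = []
    for idx, rec in enumerate(records):
        label = rec["label"] if rec["label"] is not None else str(idx)
        out.append((label, Outline(np.asarray(rec["points"]))))
    return out


def _validate_record(rec: dict, index: int, path: Path) -> None:
    label = rec["label"] if rec["label"] is not None else str(index)
    if rec["declared"] is None:
        raise TPSParseError(f"{path}: record {label}: missing POINTS declaration")
    if len(rec["points"]) != rec["declared"]:
        raise TPSParseError(
            f"{path}: record {label}: declared {rec['declared']} points but "
            f"found {len(rec['points'])}"
        )


def write_tps_outlines(path, outlines) -> None:
    """Write (label, Outline) pairs as a TPS outline file."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for label, outline in outlines:
            fh.write("LM=0\nCURVES=1\n")
            fh.write(f"POINTS={outline.n_points}\n")
            for x, y in outline.points:
                fh.write(f"{x:.17g} {y:.17g}\n")
            fh.write(f"ID={label}\n")


# ---------------------------------------------------------------------------
# Trees


def read_newick(path) -> Phylogeny:
    """Read a single rooted newick tree with branch lengths."""
    return Phylogeny.from_file(path)


# ---------------------------------------------------------------------------
# Tables


def read_specimen_table(path) -> pd.DataFrame:
    """Read specimens.csv and validate its schema.

    Required columns: specimen_id, species, sex, trait, outline_file;
    optional: trait_size.  Specimen ids must be unique.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "species": str})
    required = ["specimen_id", "species", "sex", "trait", "outline_file"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns: {', '.join(missing)}")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise DataError(f"{path}: duplicate specimen ids: {dupes[:5]}")
    bad_sex = set(df["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise DataError(f"{path}: unknown sex values: {sorted(bad_sex)}")
    if "trait_size" in df.columns and (df["trait_size"].dropna() < 0).any():
        raise DataError(f"{path}: negative trait_size values")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a CSV at full double precision (17 significant digits)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    # round_trip parsing so write_table -> read_table is bit-exact
    return pd.read_csv(path, float_precision="round_trip")


def write_result_tables(results: dict, out_dir) -> list[Path]:
    """Write a mapping name -> DataFrame (or to_frame()-able) to CSV files.

    Returns the paths written, one ``<name>.csv`` per entry, with a
    deterministic column order (as provided by each frame).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        frame = obj.to_frame() if hasattr(obj, "to_frame") else pd.DataFrame(obj)
        target = out_dir / f"{name}.csv"
        write_table(frame, target)
        written.append(target)
    return written
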