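"""File formats: morphometry tables, FreeSurfer aparc stats, result CSVs.

Long-format morphometry tables are UTF-8 CSV with the header
``subject_id,group,session_index,age,image_type,method,roi,thickness_mm``
(plus the ``identical_params`` session flag), optionally preceded by
``#``-prefixed comment lines carrying the master seed and a configuration
hash.  Missing CE rows are absent, never blank.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .synthetic import MORPH_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "write_morph_table",
    "read_morph_table",
    "validate_morph_table",
    "config_hash",
    "AparcStats",
    "read_freesurfer_aparc_stats",
    "read_dldirect_stats",
]


def config_hash(obj) -> str:
    """Stable SHA-256 digest of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def validate_morph_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a morphometry table."""
    missing = [c for c in MORPH_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"morph table missing columns: {missing}")
    if (table["thickness_mm"] <= 0).any():
        raise FormatError("thickness_mm must be > 0 on every row")
    # ages strictly increasing with session index within a subject
    sess = table.drop_duplicates(["subject_id", "session_index"]).sort_values(
        ["subject_id", "session_index"]
    )
    for sid, sub in sess.groupby("subject_id", sort=False):
        ages = sub["age"].to_numpy()
        if not np.all(np.diff(ages) > 0):
            raise FormatError(f"ages not strictly increasing for subject {sid}")


def write_morph_table(
    table: pd.DataFrame,
    path,
    *,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    """Write a morphometry table as CSV at full precision.

    A ``#`` comment header records the seed and configuration hash so any
    output can be traced back to the run that produced it.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash}\n")
        table.to_csv(fh, index=False, float_format="%.17g")


def read_morph_table(path, validate: bool = True) -> pd.DataFrame:
    """Read a morphometry table CSV (skipping ``#`` comment lines)."""
    table = pd.read_csv(
        path,
        comment="#",
        float_precision="round_trip",
        dtype={"subject_id": str, "group": str, "image_type": str, "method": str, "roi": str},
    )
    if "identical_params" in table.columns:
        table["identical_params"] = table["identical_params"].astype(bool)
    if validate:
        validate_morph_table(table)
    return table[MORPH_COLUMNS] if set(MORPH_COLUMNS) <= set(table.columns) else table


# --------------------------------------------------------------------------
# FreeSurfer ?h.aparc.stats


@dataclass(frozen=True)
class AparcStats:
    """Parsed content of a FreeSurfer ``?h.aparc.stats`` file."""

    roi_thickness: dict[str, float]  # StructName -> ThickAvg (mm)
    surf_area: dict[str, float]  # StructName -> SurfArea (mm^2)
    mean_thickness_header: float | None  # "# Measure Cortex, MeanThickness"

    @property
    def global_mean(self) -> float:
        """Header MeanThickness when present, else area-weighted ROI mean."""
        if self.mean_thickness_header is not None:
            return self.mean_thickness_header
        names = list(self.roi_thickness)
        w = np.array([self.surf_area.get(n, 1.0) for n in names])
        t = np.array([self.roi_thickness[n] for n in names])
        return float((w * t).sum() / w.sum())


def read_freesurfer_aparc_stats(path) -> AparcStats:
    """Parse a FreeSurfer surface-statistics file.

    Column positions are taken from the ``# ColHeaders`` line, so permuted
    columns parse identically.  The global mean is read from the
    ``# Measure Cortex, MeanThickness`` header when present.
    """
    mean_header: float | None = None
    col_names: list[str] | None = None
    rois: dict[str, float] = {}
    areas: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("ColHeaders"):
                    col_names = body.split()[1:]
                elif body.startswith("Measure Cortex, MeanThickness"):
                    parts = [p.strip() for p in body.split(",")]
                    try:
                        mean_header = float(parts[3])
                    except (IndexError, ValueError):
                        raise FormatError(
                            f"{path}: malformed MeanThickness line {lineno}"
                        ) from None
                continue
            if col_names is None:
                raise FormatError(
                    f"{path}: data before '# ColHeaders' at line {lineno}"
                )
            fields = line.split()
            if len(fields) != len(col_names):
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {len(col_names)}"
                )
            row = dict(zip(col_names, fields))
            if "StructName" not in row or "ThickAvg" not in row:
                raise FormatError(
                    f"{path}: ColHeaders lacks StructName/ThickAvg (line {lineno})"
                )
            name = row["StructName"]
            try:
                rois[name] = float(row["ThickAvg"])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric ThickAvg at line {lineno}"
                ) from None
            if "SurfArea" in row:
                try:
                    areas[name] = float(row["SurfArea"])
                except ValueError:
                    pass
    if col_names is None:
        raise FormatError(f"{path}: no '# ColHeaders' line found")
    if not rois:
        raise FormatError(f"{path}: no data rows")
    return AparcStats(
        roi_thickness=rois, surf_area=areas, mean_thickness_header=mean_header
    )


# --------------------------------------------------------------------------
# DL+DiReCT per-subject result CSV


def read_dldirect_stats(path) -> dict[str, float]:
    """Read a one-row wide result CSV mapping region columns to thickness.

    Non-numeric metadata columns are ignored with a logged notice; a
    duplicated region column is an error.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        dupes = {h for h in header if header.count(h) > 1}
        if dupes:
            raise FormatError(f"{path}: duplicate ROI columns: {sorted(dupes)}")
        try:
            values = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: header but no data row") from None
    result: dict[str, float] = {}
    skipped = []
    for name, val in zip(header, values):
        try:
            result[name] = float(val)
        except ValueError:
            skipped.append(name)
    if skipped:
        logger.info("%s: ignored non-numeric columns %s", path, skipped)
    if not result:
        raise FormatError(f"{path}: no numeric ROI columns")
    return result
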