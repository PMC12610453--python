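"""Readers, validators and writers for panel Ct tables and tabular artifacts.

File dialect is UTF-8 with a decimal point; the delimiter is chosen from the
extension (``.csv`` -> comma, anything else -> tab). All pipeline outputs are
written as TSV with full float precision so that a write/read round trip is
the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROLE_TARGET = "target"
ROLE_HOUSEKEEPING = "housekeeping"
ROLE_CONTROL = "control"
ROLES = (ROLE_TARGET, ROLE_HOUSEKEEPING, ROLE_CONTROL)

#: Ct ceiling beyond which a well is treated as undetected.
DEFAULT_LOD_CT = 35.0

GROUPS = ("cancer", "healthy")
POLE_STATUSES = ("mutant", "wildtype", "not_applicable")

#: Column order of a serialized differential-expression table.
DE_COLUMNS = (
    "mirna",
    "mean_dct_a",
    "mean_dct_b",
    "ddct",
    "log2_fold_reg",
    "fold_reg",
    "t_stat",
    "welch_df",
    "p",
    "fdr",
    "significant",
    "tested",
)


class PanelFormatError(ValueError):
    """An input table violates the expected panel schema."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def detected_mask(ct: np.ndarray, lod_ct: float) -> np.ndarray:
    """Boolean detection mask: finite Ct strictly below the LOD."""
    ct = np.asarray(ct, dtype=float)
    return np.isfinite(ct) & (ct < lod_ct)


@dataclass(frozen=True)
class PanelLayout:
    """Assay identities and roles for one panel plate.

    Exactly which wells are targets, housekeeping references or vendor
    controls; the LOD in cycles is carried alongside because detection is
    a property of the acquisition, not of any single table.
    """

    assay_ids: tuple[str, ...]
    roles: tuple[str, ...]
    lod_ct: float = DEFAULT_LOD_CT

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay_ids", tuple(self.assay_ids))
        object.__setattr__(self, "roles", tuple(self.roles))
        if len(self.assay_ids) != len(self.roles):
            raise PanelFormatError("assay_ids and roles differ in length")
        if len(set(self.assay_ids)) != len(self.assay_ids):
            raise PanelFormatError("duplicate assay ids in layout")
        bad = sorted(set(self.roles) - set(ROLES))
        if bad:
            raise PanelFormatError(f"unknown assay roles: {bad}")
        if not np.isfinite(self.lod_ct) or self.lod_ct <= 0:
            raise PanelFormatError("lod_ct must be a positive finite cycle count")

    def _ids_with_role(self, role: str) -> tuple[str, ...]:
        return tuple(a for a, r in zip(self.assay_ids, self.roles) if r == role)

    @property
    def target_assays(self) -> tuple[str, ...]:
        return self._ids_with_role(ROLE_TARGET)

    @property
    def housekeeping_assays(self) -> tuple[str, ...]:
        return self._ids_with_role(ROLE_HOUSEKEEPING)

    @property
    def control_assays(self) -> tuple[str, ...]:
        return self._ids_with_role(ROLE_CONTROL)

    def role_of(self, assay_id: str) -> str:
        try:
            return self.roles[self.assay_ids.index(assay_id)]
        except ValueError:
            raise KeyError(f"assay {assay_id!r} not in layout") from None


@dataclass
class CtTable:
    """Raw Ct matrix (samples x assays) with its layout and detection mask."""

    sample_ids: tuple[str, ...]
    layout: PanelLayout
    ct: np.ndarray
    detected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PanelFormatError("duplicate sample ids")
        self.ct = np.asarray(self.ct, dtype=float)
        expected = (len(self.sample_ids), len(self.layout.assay_ids))
        if self.ct.shape != expected:
            raise PanelFormatError(
                f"Ct matrix shape {self.ct.shape} != samples x assays {expected}"
            )
        if self.detected is None:
            self.detected = detected_mask(self.ct, self.layout.lod_ct)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.detected.shape != expected:
            raise PanelFormatError("detected mask shape mismatch")
        if not np.all(np.isfinite(self.ct[self.detected])):
            raise PanelFormatError("non-finite Ct flagged as detected")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ct, index=list(self.sample_ids), columns=list(self.layout.assay_ids)
        )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical annotation accompanying a Ct table."""

    sample_id: str
    group: str
    pole_status: str
    age: float | None = None
    bmi: float | None = None
    grade: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise PanelFormatError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}"
            )
        if self.pole_status not in POLE_STATUSES:
            raise PanelFormatError(
                f"sample {self.sample_id!r}: unknown pole_status {self.pole_status!r}"
            )
        # POLE status is a tumor property: not_applicable iff healthy.
        if self.group == "healthy" and self.pole_status != "not_applicable":
            raise PanelFormatError(
                f"sample {self.sample_id!r}: healthy sample with pole_status "
                f"{self.pole_status!r}"
            )
        if self.group == "cancer" and self.pole_status == "not_applicable":
            raise PanelFormatError(
                f"sample {self.sample_id!r}: cancer sample requires a POLE status"
            )


def read_layout(path: str | Path, lod_ct: float = DEFAULT_LOD_CT) -> PanelLayout:
    """Read a panel layout table with columns ``assay_id`` and ``role``."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in ("assay_id", "role"):
        if col not in df.columns:
            raise PanelFormatError(f"layout file missing column {col!r}")
    return PanelLayout(tuple(df["assay_id"]), tuple(df["role"]), lod_ct=lod_ct)


def read_ct_table(path: str | Path, layout: PanelLayout) -> CtTable:
    """Parse a delimited Ct table (first column: sample id, one column per assay).

    Values at or above ``layout.lod_ct`` are retained but flagged undetected;
    empty cells become undetected NaN. Non-numeric cells raise with the cell
    coordinates.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise PanelFormatError("Ct table needs a sample-id column plus assay columns")
    id_col = df.columns[0]
    sample_ids = tuple(df[id_col].astype(str))
    dupes = df[id_col][df[id_col].duplicated()].unique().tolist()
    if dupes:
        raise PanelFormatError(f"duplicate sample ids: {dupes}")
    missing = [a for a in layout.assay_ids if a not in df.columns]
    if missing:
        raise PanelFormatError(f"assay columns missing from Ct table: {missing}")

    ct = np.full((len(sample_ids), len(layout.assay_ids)), np.nan)
    for j, assay in enumerate(layout.assay_ids):
        col = df[assay]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() & col.notna() & (col.str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelFormatError(
                f"non-numeric Ct at sample {sample_ids[i]!r}, assay {assay!r}: "
                f"{col.iloc[i]!r}"
            )
        ct[:, j] = numeric.to_numpy(dtype=float)
    return CtTable(sample_ids, layout, ct)


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Parse sample metadata (sample_id, group, pole_status, age, bmi, grade)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = ("sample_id", "group", "pole_status")
    for col in required:
        if col not in df.columns:
            raise PanelFormatError(f"metadata missing column {col!r}")

    def _num(row: pd.Series, col: str) -> float | None:
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            return None
        try:
            return float(raw)
        except ValueError:
            raise PanelFormatError(
                f"sample {row['sample_id']!r}: non-numeric {col} {raw!r}"
            ) from None

    records = []
    for _, row in df.iterrows():
        grade = row.get("grade")
        if grade is not None and (pd.isna(grade) or str(grade).strip() == ""):
            grade = None
        records.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]).strip().lower(),
                pole_status=str(row["pole_status"]).strip().lower(),
                age=_num(row, "age"),
                bmi=_num(row, "bmi"),
                grade=grade,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise PanelFormatError("duplicate sample ids in metadata")
    return records


def meta_to_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "group": [m.group for m in meta],
            "pole_status": [m.pole_status for m in meta],
            "age": [m.age for m in meta],
            "bmi": [m.bmi for m in meta],
            "grade": [m.grade for m in meta],
        }
    )


def group_ids(meta: Sequence[SampleMeta], group: str) -> tuple[str, ...]:
    return tuple(m.sample_id for m in meta if m.group == group)


def pole_ids(meta: Sequence[SampleMeta], status: str) -> tuple[str, ...]:
    return tuple(
        m.sample_id for m in meta if m.group == "cancer" and m.pole_status == status
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write one artifact as TSV; floats use repr so reads round-trip exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> dict[str, Path]:
    """Serialize a mapping of named pipeline outputs to ``<name>.tsv`` files."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PanelFormatError(f"cannot create output directory {out_dir}: {exc}")
    if not out_dir.is_dir():
        raise PanelFormatError(f"not a directory: {out_dir}")
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        paths[name] = write_table(df, out_dir / f"{name}.tsv")
    return paths
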