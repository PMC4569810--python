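"""Study-level meta-analytic data: records, datasets, conversions, CSV I/O.

A meta-analytic dataset is one row per study: a standardized mean difference
(Hedges' g), its standard error, optional per-group sample sizes and a subset
tag. All downstream estimators (descriptives, PET-PEESE, Bayesian bias
correction) consume :class:`MetaDataset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "MetaDataset",
    "MetaDataError",
    "CsvFormatError",
    "ValidationError",
    "read_meta_csv",
    "write_meta_csv",
    "hedges_correction",
    "se_from_groups",
]

CSV_COLUMNS = ("study_id", "g", "se", "n1", "n2", "subset")


class MetaDataError(ValueError):
    """Base class for malformed meta-analytic input."""


class CsvFormatError(MetaDataError):
    """The CSV file cannot be interpreted (e.g. a required column is missing)."""


class ValidationError(MetaDataError):
    """Rows violate the study-record invariants (e.g. non-positive SE)."""


@dataclass(frozen=True)
class StudyRecord:
    """One study's observed effect.

    Parameters
    ----------
    study_id : str
        Unique label for the study.
    effect_g : float
        Observed standardized mean difference (Hedges' g), unitless.
    se : float
        Standard error of ``effect_g``; must be strictly positive.
    n1, n2 : int, optional
        Per-group sample sizes (each >= 2 when given).
    subset : str, optional
        Analysis subset tag (e.g. ``"prosocial"``).
    published_flag : bool, optional
        Set by the simulator on accepted (published) studies.
    """

    study_id: str
    effect_g: float
    se: float
    n1: int | None = None
    n2: int | None = None
    subset: str | None = None
    published_flag: bool | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.effect_g):
            raise ValidationError(f"study {self.study_id!r}: effect_g must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"study {self.study_id!r}: se must be > 0, got {self.se!r}")
        for name, n in (("n1", self.n1), ("n2", self.n2)):
            if n is not None and (int(n) != n or n < 2):
                raise ValidationError(
                    f"study {self.study_id!r}: {name} must be an integer >= 2, got {n!r}"
                )


@dataclass(frozen=True)
class MetaDataset:
    """Ordered collection of :class:`StudyRecord` with a label.

    Study ids must be unique. The dataset may be empty at construction time;
    estimation operations require ``k >= 1`` (or more) and say so explicitly.
    """

    records: tuple[StudyRecord, ...] = field(default_factory=tuple)
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.study_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate study_ids: {dupes}")

    @property
    def k(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    @property
    def g(self) -> np.ndarray:
        """Observed effects as a float array, file order."""
        return np.array([r.effect_g for r in self.records], dtype=float)

    @property
    def se(self) -> np.ndarray:
        """Standard errors as a float array, file order."""
        return np.array([r.se for r in self.records], dtype=float)

    def subset(self, tag: str) -> "MetaDataset":
        """Return the studies whose subset tag equals ``tag``."""
        recs = tuple(r for r in self.records if r.subset == tag)
        return MetaDataset(recs, label=f"{self.label}[{tag}]" if self.label else tag)

    def relabel(self, label: str) -> "MetaDataset":
        return replace(self, label=label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "study_id": r.study_id,
                "g": r.effect_g,
                "se": r.se,
                "n1": r.n1,
                "n2": r.n2,
                "subset": r.subset,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def hedges_correction(d: float, df: float) -> float:
    """Small-sample bias correction turning Cohen's d into Hedges' g.

    Applies the multiplicative factor ``J(df) = 1 - 3 / (4 df - 1)``, which
    shrinks d toward zero; ``df`` is the degrees of freedom of the
    standardizer (``n1 + n2 - 2`` for a two-group design).
    """
    if df < 2:
        raise ValueError(f"df must be >= 2, got {df}")
    return (1.0 - 3.0 / (4.0 * df - 1.0)) * d


def se_from_groups(g: float, n1: int, n2: int) -> float:
    """Large-sample standard error of a standardized mean difference.

    Uses the standard SMD variance ``(n1+n2)/(n1*n2) + g^2 / (2 (n1+n2))``.
    Strictly decreasing in each group size for fixed g.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"group sizes must be >= 2, got n1={n1}, n2={n2}")
    n1 = float(n1)
    n2 = float(n2)
    var = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return math.sqrt(var)


_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-"})


def _parse_float(value: object) -> float:
    if isinstance(value, str):
        value = value.strip().translate(_MINUS_VARIANTS)
    return float(value)


def _parse_optional_int(value: object) -> int | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    return int(float(value))


def read_meta_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> MetaDataset:
    """Read a study-level effect-size table from CSV.

    Parameters
    ----------
    path : path-like
        Comma-separated file with a header row; UTF-8; ``.`` decimal
        separator. Unicode minus signs are normalized.
    column_map : mapping, optional
        Maps canonical names (``study_id``, ``g``, ``se``, ``n1``, ``n2``,
        ``subset``) to the file's column names. Only ``g`` and ``se`` are
        required to resolve; absent ``study_id`` columns get ``study_<row>``
        labels.

    Raises
    ------
    CsvFormatError
        If a required column cannot be resolved.
    ValidationError
        If any row violates the record invariants; the message lists the
        offending 1-based data-row numbers and study ids.
    """
    path = Path(path)
    cmap = {c: c for c in CSV_COLUMNS}
    if column_map:
        cmap.update(column_map)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for required in ("g", "se"):
        if cmap[required] not in frame.columns:
            raise CsvFormatError(
                f"{path.name}: required column {cmap[required]!r} (for {required!r}) not found; "
                f"columns present: {list(frame.columns)}"
            )

    records: list[StudyRecord] = []
    problems: list[str] = []
    for row_num, (_, row) in enumerate(frame.iterrows(), start=1):
        sid = row.get(cmap["study_id"], "") if cmap["study_id"] in frame.columns else ""
        sid = str(sid).strip() or f"study_{row_num}"
        try:
            rec = StudyRecord(
                study_id=sid,
                effect_g=_parse_float(row[cmap["g"]]),
                se=_parse_float(row[cmap["se"]]),
                n1=_parse_optional_int(row.get(cmap["n1"])) if cmap["n1"] in frame.columns else None,
                n2=_parse_optional_int(row.get(cmap["n2"])) if cmap["n2"] in frame.columns else None,
                subset=(str(row[cmap["subset"]]).strip() or None)
                if cmap["subset"] in frame.columns
                else None,
            )
        except (MetaDataError, ValueError) as exc:
            problems.append(f"row {row_num} (study_id={sid!r}): {exc}")
            continue
        records.append(rec)
    if problems:
        raise ValidationError(f"{path.name}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    return MetaDataset(tuple(records), label=path.stem)


def write_meta_csv(data: MetaDataset, path: str | Path) -> None:
    """Write the dataset to CSV with the canonical columns.

    Floats are written with Python's shortest round-trip representation, so
    ``read_meta_csv(write_meta_csv(ds))`` reproduces every field exactly.
    """
    frame = data.to_frame()
    frame.to_csv(path, index=False, encoding="utf-8")
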