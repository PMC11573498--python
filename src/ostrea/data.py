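"""Shell-record data model and delimited-text I/O.

An *assemblage* is the basic analysis unit: a collection of individually
measured oyster shells from one or more archaeological sites.  Each shell
carries a hinge size (mm, caliper precision: one decimal), a biological age
(integer years from counting annual growth lines in thin section), a cultural
period, and optionally a stratigraphic position.  Either hinge or age may be
missing — shells missing both carry no information and are rejected.

The canonical on-disk form is a UTF-8 CSV with header
``shell_id,site,period,layer_label,layer_order,hinge_mm,age_years``.
Legacy files with arbitrary headers are read through a column-mapping config.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conversion import hinge_to_length

PERIOD_MESOLITHIC = "Mesolithic"
PERIOD_NEOLITHIC = "Neolithic"
PERIOD_UNASSIGNED = "unassigned"
PERIODS = (PERIOD_MESOLITHIC, PERIOD_NEOLITHIC, PERIOD_UNASSIGNED)

#: canonical column order for assemblage CSV files
CANONICAL_COLUMNS = [
    "shell_id",
    "site",
    "period",
    "layer_label",
    "layer_order",
    "hinge_mm",
    "age_years",
]

_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan"}


class AssemblageValidationError(ValueError):
    """Raised when rows violate shell-record invariants in strict mode."""

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        super().__init__(
            f"{len(self.diagnostics)} invalid row(s): " + "; ".join(self.diagnostics[:5])
        )


def normalize_period(label: object) -> str:
    """Map a free-text period label onto the two studied periods.

    Matching is case-insensitive; anything unrecognized becomes
    ``unassigned`` (kept for site-level work, excluded from period
    comparisons).
    """
    if label is None:
        return PERIOD_UNASSIGNED
    text = str(label).strip().lower()
    if text in {"mesolithic", "meso", "ertebolle", "ertebølle"}:
        return PERIOD_MESOLITHIC
    if text in {"neolithic", "neo", "funnel beaker", "funnelbeaker", "trb"}:
        return PERIOD_NEOLITHIC
    return PERIOD_UNASSIGNED


@dataclass(frozen=True)
class ShellRecord:
    """One measured oyster shell."""

    shell_id: str
    site: str
    period: str = PERIOD_UNASSIGNED
    layer_label: str | None = None
    layer_order: int | None = None
    hinge_mm: float | None = None
    age_years: int | None = None

    def problems(self) -> list[str]:
        """Return invariant violations (empty list = valid record)."""
        out: list[str] = []
        if self.hinge_mm is None and self.age_years is None:
            out.append("both hinge_mm and age_years missing")
        if self.hinge_mm is not None and not self.hinge_mm > 0:
            out.append(f"hinge_mm must be > 0, got {self.hinge_mm}")
        if self.age_years is not None and (
            int(self.age_years) != self.age_years or self.age_years < 1
        ):
            out.append(f"age_years must be an integer >= 1, got {self.age_years}")
        if (self.layer_label is None) != (self.layer_order is None):
            out.append("layer_label and layer_order must be present together")
        return out


@dataclass
class Assemblage:
    """An ordered collection of shell records backed by a DataFrame.

    ``records`` always holds the canonical columns with nullable dtypes
    (``hinge_mm`` float with NaN, ``age_years``/``layer_order`` Int64).
    """

    records: pd.DataFrame
    provenance: str = ""
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[CANONICAL_COLUMNS].reset_index(drop=True)
        df["shell_id"] = df["shell_id"].astype(str)
        df["site"] = df["site"].astype(str)
        df["period"] = df["period"].map(normalize_period)
        df["hinge_mm"] = pd.to_numeric(df["hinge_mm"], errors="raise").astype(float)
        df["age_years"] = pd.array(
            pd.to_numeric(df["age_years"], errors="raise"), dtype="Int64"
        )
        df["layer_order"] = pd.array(
            pd.to_numeric(df["layer_order"], errors="raise"), dtype="Int64"
        )
        if df["shell_id"].duplicated().any():
            dups = df.loc[df["shell_id"].duplicated(), "shell_id"].unique()[:5]
            raise AssemblageValidationError(
                [f"duplicate shell_id {d!r}" for d in dups]
            )
        self.records = df

    # -- missingness bookkeeping -------------------------------------------
    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_both(self) -> int:
        return int(
            (self.records["hinge_mm"].notna() & self.records["age_years"].notna()).sum()
        )

    @property
    def n_hinge_only(self) -> int:
        return int(
            (self.records["hinge_mm"].notna() & self.records["age_years"].isna()).sum()
        )

    @property
    def n_age_only(self) -> int:
        return int(
            (self.records["hinge_mm"].isna() & self.records["age_years"].notna()).sum()
        )

    def complete(self) -> pd.DataFrame:
        """Records with both hinge and age (the growth-model subset)."""
        m = self.records["hinge_mm"].notna() & self.records["age_years"].notna()
        return self.records.loc[m].copy()

    @classmethod
    def from_records(
        cls, records: Iterable[ShellRecord], provenance: str = ""
    ) -> "Assemblage":
        rows = []
        diags = []
        for i, rec in enumerate(records):
            probs = rec.problems()
            if probs:
                diags.append(f"record {i} ({rec.shell_id!r}): " + "; ".join(probs))
                continue
            rows.append(
                {
                    "shell_id": rec.shell_id,
                    "site": rec.site,
                    "period": rec.period,
                    "layer_label": rec.layer_label,
                    "layer_order": rec.layer_order,
                    "hinge_mm": np.nan if rec.hinge_mm is None else rec.hinge_mm,
                    "age_years": rec.age_years,
                }
            )
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return cls(df, provenance=provenance, diagnostics=diags)


def _parse_cell(raw: str | None) -> str | None:
    if raw is None:
        return None
    raw = raw.strip()
    return None if raw in _MISSING_TOKENS else raw


def read_assemblage(
    path: str | Path | io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
    strict: bool = False,
    provenance: str | None = None,
) -> Assemblage:
    """Read a delimited-text assemblage file.

    Parameters
    ----------
    path
        CSV file with a header row.  Empty cells and the literal ``NA``
        parse as missing.
    column_map
        Mapping from canonical column name to the header used in the file,
        e.g. ``{"hinge_mm": "Hinge (mm)"}``.  Unmapped canonical columns
        default to their own name; of these only ``shell_id``, ``site`` and
        one of hinge/age are required in the file.
    strict
        If True, any invalid row raises :class:`AssemblageValidationError`;
        otherwise invalid rows are dropped and row-numbered diagnostics are
        stored on the returned assemblage.

    Rows violating record invariants (both measurements missing,
    non-positive hinge, fractional or sub-1 age, layer label without order)
    are rejected with a diagnostic naming the file row (header = row 1).
    Non-numeric hinge/age cells always raise, with the row number.
    """
    column_map = dict(column_map or {})
    name_for = {c: column_map.get(c, c) for c in CANONICAL_COLUMNS}

    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    header = list(raw.columns)
    for canonical in ("shell_id",):
        if name_for[canonical] not in header:
            raise ValueError(
                f"required column {name_for[canonical]!r} (for {canonical}) "
                f"not found in header {header}"
            )
    if name_for["hinge_mm"] not in header and name_for["age_years"] not in header:
        raise ValueError("file maps neither a hinge nor an age column")

    rows: list[dict] = []
    diagnostics: list[str] = []
    for i, row in raw.iterrows():
        file_row = i + 2  # header is row 1
        cells = {
            c: _parse_cell(row[name_for[c]]) if name_for[c] in header else None
            for c in CANONICAL_COLUMNS
        }
        try:
            hinge = None if cells["hinge_mm"] is None else float(cells["hinge_mm"])
        except ValueError:
            raise ValueError(
                f"row {file_row}: non-numeric hinge cell {cells['hinge_mm']!r}"
            ) from None
        try:
            age_raw = None if cells["age_years"] is None else float(cells["age_years"])
        except ValueError:
            raise ValueError(
                f"row {file_row}: non-numeric age cell {cells['age_years']!r}"
            ) from None
        try:
            order = None if cells["layer_order"] is None else int(float(cells["layer_order"]))
        except ValueError:
            raise ValueError(
                f"row {file_row}: non-numeric layer_order cell {cells['layer_order']!r}"
            ) from None

        age = None
        if age_raw is not None:
            if age_raw != int(age_raw):
                diagnostics.append(f"row {file_row}: age_years {age_raw} not an integer")
                continue
            age = int(age_raw)
        # caliper convention: hinge carries one-decimal precision
        if hinge is not None:
            hinge = round(hinge, 1)

        rec = ShellRecord(
            shell_id=cells["shell_id"] or f"row{file_row}",
            site=cells["site"] or "unknown",
            period=normalize_period(cells["period"]),
            layer_label=cells["layer_label"],
            layer_order=order,
            hinge_mm=hinge,
            age_years=age,
        )
        probs = rec.problems()
        if probs:
            diagnostics.append(f"row {file_row}: " + "; ".join(probs))
            continue
        rows.append(
            {
                "shell_id": rec.shell_id,
                "site": rec.site,
                "period": rec.period,
                "layer_label": rec.layer_label,
                "layer_order": rec.layer_order,
                "hinge_mm": np.nan if rec.hinge_mm is None else rec.hinge_mm,
                "age_years": rec.age_years,
            }
        )

    if strict and diagnostics:
        raise AssemblageValidationError(diagnostics)
    src = provenance if provenance is not None else str(path)
    return Assemblage(
        pd.DataFrame(rows, columns=CANONICAL_COLUMNS),
        provenance=src,
        diagnostics=diagnostics,
    )


def write_assemblage(assemblage: Assemblage, path: str | Path) -> None:
    """Write the canonical CSV (hinge one decimal, ages as integers)."""
    df = assemblage.records
    out = pd.DataFrame(
        {
            "shell_id": df["shell_id"],
            "site": df["site"],
            "period": df["period"],
            "layer_label": df["layer_label"].fillna(""),
            "layer_order": df["layer_order"].map(
                lambda v: "" if pd.isna(v) else str(int(v))
            ),
            "hinge_mm": df["hinge_mm"].map(
                lambda v: "" if pd.isna(v) else f"{v:.1f}"
            ),
            "age_years": df["age_years"].map(
                lambda v: "" if pd.isna(v) else str(int(v))
            ),
        }
    )
    out.to_csv(path, index=False)


_SUMMARY_COLS = ["min", "q1", "median", "mean", "q3", "max"]


def _six_numbers(values: np.ndarray) -> list[float]:
    # linear-interpolation quantiles: the convention mainstream statistical
    # software defaults to, fixed here so summary tables are reproducible
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return [float(values.min()), float(q1), float(med), float(values.mean()),
            float(q3), float(values.max())]


def summarize_metrics(
    assemblage: Assemblage, coefficient: float = 35.4, rounded: bool = False
) -> pd.DataFrame:
    """Six-number summaries (min, Q1, median, mean, Q3, max) of hinge,
    derived length, and age, over present values only.

    ``rounded=True`` applies report precision: hinge/length to one decimal,
    age means/quartiles to one decimal, age min/max to integers.
    """
    if assemblage.n_total == 0:
        raise ValueError("cannot summarize an empty assemblage")
    hinge = assemblage.records["hinge_mm"].dropna().to_numpy(float)
    age = assemblage.records["age_years"].dropna().to_numpy(float)
    rows = {}
    if hinge.size:
        rows["hinge_mm"] = _six_numbers(hinge)
        rows["length_mm"] = _six_numbers(hinge_to_length(hinge, coefficient))
    if age.size:
        rows["age_years"] = _six_numbers(age)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=_SUMMARY_COLS)
    if rounded:
        table = table.round(1)
        if "age_years" in table.index:
            table.loc["age_years", ["min", "max"]] = [
                float(int(table.loc["age_years", "min"])),
                float(int(table.loc["age_years", "max"])),
            ]
    return table
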