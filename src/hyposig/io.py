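"""Expression matrices, design/clinical/annotation tables, and normalization.

The expression container is a thin wrapper around a pandas DataFrame
(probesets as rows, samples as columns) carrying an explicit scale flag,
so that every operation downstream can state whether it expects linear
signal values or log2 values.

The normalization chain reproduces the classic MAS5-style post-processing
of summarized array signals: global scaling of each array to a fixed mean
intensity, per-array division by the 50th percentile, and per-probeset
division by the probeset's median across arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PairedDesign",
    "AnnotationTable",
    "ClinicalTable",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "normalize_chain",
    "log2_transform",
    "read_paired_design",
    "read_clinical_table",
    "read_annotation_table",
]

VALID_INSS = ("1", "2", "3", "4", "4S")
VALID_MYCN = ("amplified", "normal")
VALID_AGE = ("lt1", "ge1")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class ExpressionMatrix:
    """Probesets x samples signal matrix with an explicit scale flag.

    ``scale`` is ``"linear"`` (strictly positive signal values) or
    ``"log2"``.  Validation enforces unique ids, finiteness, and
    positivity on the linear scale; missing values are rejected, never
    imputed.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probeset ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        if self.data.size == 0:
            raise FormatError("empty expression matrix")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if not np.isfinite(values).all():
            raise FormatError("missing or non-finite values in expression matrix")
        if self.scale == "linear" and not (values > 0).all():
            raise FormatError("linear-scale matrix must be strictly positive")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probesets(self, ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"probesets not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(ids)].copy(), self.scale)


@dataclass
class PairedDesign:
    """Cell line -> (normoxic sample, hypoxic sample) mapping."""

    entries: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise FormatError("paired design needs at least 2 cell lines")
        samples = [s for _, n, h in self.entries for s in (n, h)]
        if len(set(samples)) != len(samples):
            raise FormatError("a sample appears twice in the paired design")
        lines = [c for c, _, _ in self.entries]
        if len(set(lines)) != len(lines):
            raise FormatError("duplicate cell line in paired design")

    @property
    def cell_lines(self) -> list[str]:
        return [c for c, _, _ in self.entries]

    @property
    def normoxic_samples(self) -> list[str]:
        return [n for _, n, _ in self.entries]

    @property
    def hypoxic_samples(self) -> list[str]:
        return [h for _, _, h in self.entries]

    def validate_against(self, E: ExpressionMatrix) -> None:
        known = set(E.sample_ids)
        missing = [s for s in self.normoxic_samples + self.hypoxic_samples if s not in known]
        if missing:
            raise FormatError(f"design references unknown samples: {missing[:5]}")


@dataclass
class AnnotationTable:
    """probeset_id -> (gene_symbol, accession)."""

    mapping: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for pid, (sym, _acc) in self.mapping.items():
            if not sym:
                raise FormatError(f"empty gene symbol for probeset {pid}")

    def gene_symbol(self, probeset_id: str) -> str | None:
        entry = self.mapping.get(probeset_id)
        return entry[0] if entry else None


@dataclass
class ClinicalTable:
    """Per-patient survival endpoint and binary/categorical risk factors.

    ``time`` is in years; ``event`` is 1 for an observed event (death for
    OS, relapse/progression/death for EFS) and 0 for censoring.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("time", "event", "mycn", "inss", "age_group")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if t.index.duplicated().any():
            raise FormatError("duplicate patient ids")
        times = t["time"].to_numpy(dtype=float)
        if not np.isfinite(times).all() or (times < 0).any():
            raise FormatError("times must be finite and >= 0")
        if not set(t["event"].unique()) <= {0, 1}:
            raise FormatError("event must be 0/1")
        if not set(t["mycn"].unique()) <= set(VALID_MYCN):
            raise FormatError(f"mycn values must be in {VALID_MYCN}")
        if not set(t["inss"].astype(str).str.upper().unique()) <= set(VALID_INSS):
            raise FormatError(f"inss values must be in {VALID_INSS}")
        if not set(t["age_group"].unique()) <= set(VALID_AGE):
            raise FormatError(f"age_group values must be in {VALID_AGE}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def covariate_matrix(self, include_mycn: bool = True) -> pd.DataFrame:
        """Binary risk-factor codings: 1 means the adverse level.

        stage4 = 1 for INSS stage 4; mycn = 1 for amplified; age_ge1 = 1
        for age >= 1 year at diagnosis.
        """
        t = self.table
        cov = pd.DataFrame(index=t.index)
        cov["stage4"] = (t["inss"].astype(str).str.upper() == "4").astype(float)
        if include_mycn:
            cov["mycn"] = (t["mycn"] == "amplified").astype(float)
        cov["age_ge1"] = (t["age_group"] == "ge1").astype(float)
        return cov

    def subset(self, ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(ids)].copy())


def read_expression_matrix(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read a tab-delimited probesets x samples matrix.

    First row: sample ids (header); first column: probeset ids.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].apply(lambda v: not isinstance(v, (int, float, np.number)))
            row = df.index[bad.to_numpy().nonzero()[0][0]] if bad.any() else "?"
            raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_expression_matrix(E: ExpressionMatrix, path: str | Path) -> None:
    E.data.to_csv(path, sep="\t", index_label="probeset_id")


def normalize_chain(E: ExpressionMatrix, target_mean: float = 500.0) -> ExpressionMatrix:
    """Three-step array normalization on the linear scale.

    1. per sample, rescale so the sample mean equals ``target_mean``;
    2. per sample, divide by that sample's 50th percentile;
    3. per probeset, divide by the probeset's median across samples.

    After step 3 the per-probeset median equals 1.  With a single sample
    step 3 is degenerate (every probeset would map to 1); in that case a
    warning is emitted and the step-2 output is returned.
    """
    if E.scale != "linear":
        raise ValueError("normalize_chain expects a linear-scale matrix")
    values = E.values
    if not (values > 0).all():
        raise ValueError("normalize_chain requires strictly positive values")
    # step 1: global scaling to target mean intensity
    scaled = values * (target_mean / values.mean(axis=0, keepdims=True))
    # step 2: per-array 50th percentile
    med = np.median(scaled, axis=0, keepdims=True)
    scaled = scaled / med
    if E.shape[1] == 1:
        warnings.warn("single-sample matrix: per-probeset median step skipped")
        return ExpressionMatrix(pd.DataFrame(scaled, index=E.data.index, columns=E.data.columns), "linear")
    # step 3: per-probeset median across samples
    row_med = np.median(scaled, axis=1, keepdims=True)
    out = scaled / row_med
    return ExpressionMatrix(pd.DataFrame(out, index=E.data.index, columns=E.data.columns), "linear")


def log2_transform(E: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    if E.scale != "linear":
        raise ValueError("log2_transform expects a linear-scale matrix")
    values = E.values + pseudocount
    if not (values > 0).all():
        raise ValueError("values + pseudocount must be strictly positive")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(values), index=E.data.index, columns=E.data.columns),
        "log2",
    )


def read_paired_design(path: str | Path) -> PairedDesign:
    """CSV with columns cell_line,normoxic_sample,hypoxic_sample."""
    df = pd.read_csv(path)
    required = ("cell_line", "normoxic_sample", "hypoxic_sample")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"design table missing column {col!r}")
    entries = [tuple(str(v) for v in row) for row in df[list(required)].itertuples(index=False)]
    return PairedDesign(entries)  # type: ignore[arg-type]


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """CSV with columns id,time_years,event,mycn,inss,age_group."""
    df = pd.read_csv(path, dtype={"id": str, "inss": str})
    if "id" not in df.columns or "time_years" not in df.columns:
        raise FormatError("clinical table must have columns id,time_years,event,mycn,inss,age_group")
    df = df.set_index("id").rename(columns={"time_years": "time"})
    df["inss"] = df["inss"].astype(str).str.upper()
    return ClinicalTable(df)


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """CSV with columns probeset_id,gene_symbol,accession."""
    df = pd.read_csv(path, dtype=str)
    for col in ("probeset_id", "gene_symbol", "accession"):
        if col not in df.columns:
            raise FormatError(f"annotation table missing column {col!r}")
    if df["probeset_id"].duplicated().any():
        raise FormatError("duplicate probeset_id in annotation table")
    mapping = {
        str(r.probeset_id): (str(r.gene_symbol), str(r.accession))
        for r in df.itertuples(index=False)
    }
    return AnnotationTable(mapping)
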