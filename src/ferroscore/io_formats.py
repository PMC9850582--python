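"""Readers and writers for the on-disk artifacts of the analysis.

Expression matrices travel as tab-separated text (first column header
``gene``) or GCT v1.2; phenotype tables as CSV; ferroptosis gene panels as
two-column TSV (``symbol``, ``category``); fitted scoring models as JSON.
Every reader validates domain invariants on load: unique identifiers,
finite values after the missing-value policy, closed category vocabularies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
#: rows with at least this fraction of missing cells are dropped instead of imputed
MAX_MISSING_FRACTION = 0.2

DIAGNOSES = ("TCMR", "non_rejection", "other")

#: case-insensitive label aliases applied by default when reading phenotypes
DEFAULT_DIAGNOSIS_ALIASES: dict[str, str] = {
    "tcmr": "TCMR",
    "non_rejection": "non_rejection",
    "non-rejection": "non_rejection",
    "nonrejection": "non_rejection",
    "sta": "non_rejection",
    "stable": "non_rejection",
    "other": "other",
}

GENE_SET_CATEGORIES = ("driver", "suppressor", "marker")

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2-scale expression values.

    ``values`` has shape ``(len(gene_ids), len(sample_ids))``; identifiers
    are unique and keep the order of the source file.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids in ExpressionMatrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids in ExpressionMatrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows, :])

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")


def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each repeated gene symbol, the row with maximal variance.

    Standard probe-to-gene collapse; deterministic (first row wins exact
    variance ties because ``idxmax`` returns the first maximal position).
    """
    dup_mask = frame.index.duplicated(keep=False)
    if not dup_mask.any():
        return frame
    dup_symbols = sorted(set(frame.index[dup_mask]))
    logger.warning(
        "collapsing %d duplicated gene symbol(s) by max variance: %s",
        len(dup_symbols), ", ".join(dup_symbols[:10]),
    )
    variances = frame.var(axis=1, ddof=1).fillna(0.0).to_numpy()
    keep = np.ones(len(frame), dtype=bool)
    positions: dict[str, list[int]] = {}
    for pos, symbol in enumerate(frame.index):
        positions.setdefault(symbol, []).append(pos)
    for symbol, rows in positions.items():
        if len(rows) > 1:
            best = rows[int(np.argmax(variances[rows]))]
            for r in rows:
                keep[r] = r == best
    return frame.loc[keep]


def _apply_missing_policy(frame: pd.DataFrame) -> pd.DataFrame:
    """Row-mean impute sparse missingness; drop rows missing >= 20% of cells."""
    missing = frame.isna()
    if not missing.to_numpy().any():
        return frame
    frac = missing.mean(axis=1)
    drop = frac >= MAX_MISSING_FRACTION
    if drop.any():
        logger.warning(
            "dropping %d gene row(s) with >= %.0f%% missing values",
            int(drop.sum()), 100 * MAX_MISSING_FRACTION,
        )
        frame = frame.loc[~drop]
    row_means = frame.mean(axis=1)
    if row_means.isna().any():
        raise ValidationError("gene row with all values missing survived drop policy")
    return frame.apply(lambda row: row.fillna(row_means[row.name]), axis=1)


def _parse_numeric(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    def convert(col: pd.Series) -> pd.Series:
        converted = pd.to_numeric(col, errors="coerce")
        bad = converted.isna() & col.notna() & (col.astype(str).str.strip() != MISSING_TOKEN)
        if bad.any():
            row = col.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric value {col[bad].iloc[0]!r} at gene {row!r}, "
                f"sample {col.name!r}"
            )
        mask = col.notna() & (col.astype(str).str.strip() == MISSING_TOKEN)
        converted[mask] = np.nan
        return converted

    return frame.apply(convert)


def read_expression(
    path: str | Path,
    dialect: str = "tsv",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT v1.2.

    Duplicate gene symbols collapse to the max-variance row; ``NA`` cells
    follow the row-mean-impute / drop policy; ``log2_transform`` applies
    ``log2(x + 1)`` for sources that ship linear-scale values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        # pandas silently mangles duplicate column names; check the raw header
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise ValidationError(f"{path}: duplicate sample IDs {dupes}")
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if frame.empty or frame.columns[0].lower() != "gene":
            raise FormatError(f"{path}: expected first column header 'gene'")
        frame = frame.mask(frame.isin(["", MISSING_TOKEN]))
        frame = frame.set_index(frame.columns[0])
    elif dialect == "gct":
        with open(path) as handle:
            version = handle.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = handle.readline().split()
            if len(dims) < 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
            header = handle.readline().rstrip("\n").split("\t")
            if len(set(header)) != len(header):
                dupes = sorted({h for h in header if header.count(h) > 1})
                raise ValidationError(f"{path}: duplicate sample IDs {dupes}")
            frame = pd.read_csv(handle, sep="\t", dtype=str,
                                keep_default_na=False, names=header)
        frame = frame.mask(frame.isin(["", MISSING_TOKEN]))
        if frame.columns[0].lower() not in ("name", "gene"):
            raise FormatError(f"{path}: expected GCT header starting with 'Name'")
        frame = frame.set_index(frame.columns[0])
        if frame.columns[0].lower() == "description":
            frame = frame.drop(columns=frame.columns[0])
        if frame.shape != (int(dims[0]), int(dims[1])):
            raise FormatError(
                f"{path}: GCT declares {dims[0]}x{dims[1]} but file holds {frame.shape}"
            )
    else:
        raise ValueError(f"unknown expression dialect {dialect!r}")
    if frame.columns.duplicated().any():
        dupes = sorted(set(frame.columns[frame.columns.duplicated()]))
        raise ValidationError(f"{path}: duplicate sample IDs {dupes}")
    frame = _parse_numeric(frame, path)
    frame = _collapse_duplicate_genes(frame)
    frame = _apply_missing_policy(frame)
    if log2_transform:
        if (frame.to_numpy() < 0).any():
            raise ValidationError(f"{path}: negative values under --log2 transform")
        frame = np.log2(frame + 1.0)
    matrix = ExpressionMatrix.from_frame(frame)
    matrix.require_finite()
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-sample diagnosis with optional right-censored follow-up.

    ``time`` is follow-up in days; ``event`` is 1 for graft loss, 0 for
    censoring; both are present or absent together, per sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.data.copy()
        required = {"sample_id", "diagnosis"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"phenotype table missing column(s) {sorted(missing)}")
        if frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in phenotype table")
        bad = ~frame["diagnosis"].isin(DIAGNOSES)
        if bad.any():
            raise ValidationError(
                f"diagnosis outside closed vocabulary {DIAGNOSES}: "
                f"{sorted(frame.loc[bad, 'diagnosis'].unique())}"
            )
        if "time" not in frame.columns:
            frame["time"] = np.nan
        if "event" not in frame.columns:
            frame["event"] = np.nan
        has_time = frame["time"].notna()
        has_event = frame["event"].notna()
        if (has_time != has_event).any():
            raise ValidationError("event must be present exactly when time is present")
        if (frame.loc[has_time, "time"] < 0).any():
            raise ValidationError("negative follow-up time")
        if not frame.loc[has_event, "event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        self.data = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def diagnosis_of(self) -> pd.Series:
        return self.data.set_index("sample_id")["diagnosis"]

    def survival(self) -> pd.DataFrame:
        """Rows carrying follow-up, as (sample_id, time, event)."""
        rows = self.data[self.data["time"].notna()]
        return rows[["sample_id", "time", "event"]].reset_index(drop=True)


def read_phenotypes(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> PhenotypeTable:
    """Read a phenotype CSV, mapping labels case-insensitively to the closed
    vocabulary; unknown labels become ``other``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if "sample_id" not in frame.columns or "diagnosis" not in frame.columns:
        raise ValidationError(f"{path}: required columns sample_id, diagnosis")
    mapping = dict(DEFAULT_DIAGNOSIS_ALIASES)
    if aliases:
        mapping.update({k.lower(): v for k, v in aliases.items()})
    for target in mapping.values():
        if target not in DIAGNOSES:
            raise ValidationError(f"alias target {target!r} outside {DIAGNOSES}")

    def map_label(label: object) -> str:
        mapped = mapping.get(str(label).strip().lower())
        if mapped is None:
            logger.warning("unknown diagnosis label %r mapped to 'other'", label)
            return "other"
        return mapped

    frame["diagnosis"] = frame["diagnosis"].map(map_label)
    frame["sample_id"] = frame["sample_id"].astype(str)
    return PhenotypeTable(frame)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ferroptosis gene panel
# ---------------------------------------------------------------------------

@dataclass
class FerroptosisGeneSet:
    """Panel of ferroptosis-associated genes labelled driver / suppressor /
    marker (the FerrDb trichotomy: promotes, inhibits, or indicates the
    iron-dependent death process)."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        symbols = [s for s, _ in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValidationError("duplicate symbols in gene panel")
        bad = [(s, c) for s, c in self.entries if c not in GENE_SET_CATEGORIES]
        if bad:
            raise ValidationError(f"unknown gene categories: {bad[:5]}")
        if not self.entries:
            raise ValidationError("gene panel is empty")

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in GENE_SET_CATEGORIES}
        for _, c in self.entries:
            counts[c] += 1
        return counts

    def symbols_in(self, category: str) -> list[str]:
        if category not in GENE_SET_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return [s for s, c in self.entries if c == category]

    def __len__(self) -> int:
        return len(self.entries)


def read_gene_set(path: str | Path) -> FerroptosisGeneSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.empty:
        raise ValidationError(f"{path}: empty gene panel")
    if not {"symbol", "category"} <= set(frame.columns):
        raise ValidationError(f"{path}: required columns symbol, category")
    bad = ~frame["category"].isin(GENE_SET_CATEGORIES)
    if bad.any():
        rows = [f"row {i + 2}: {frame.loc[i, 'symbol']}={frame.loc[i, 'category']!r}"
                for i in frame.index[bad][:10]]
        raise ValidationError(f"{path}: unknown category token(s): " + "; ".join(rows))
    panel = FerroptosisGeneSet(list(zip(frame["symbol"], frame["category"])))
    logger.info("gene panel %s: %s", path.name, panel.category_counts())
    return panel


def write_gene_set(panel: FerroptosisGeneSet, path: str | Path) -> None:
    pd.DataFrame(panel.entries, columns=["symbol", "category"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# scoring model serialization
# ---------------------------------------------------------------------------

def save_model(model: "ScoringModel", path: str | Path) -> None:  # noqa: F821
    """Serialize a fitted scoring model to JSON (schema version 1)."""
    payload = model.to_dict()
    payload["schema_version"] = MODEL_SCHEMA_VERSION
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)


def load_model(path: str | Path) -> "ScoringModel":  # noqa: F821
    from .scoring import ScoringModel

    path = Path(path)
    try:
        with open(path) as handle:
            payload = json.load(handle)
    except json.JSONDecodeError as err:
        raise SchemaError(f"{path}: not valid model JSON ({err})") from err
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema_version {version!r} unsupported "
            f"(this build reads version {MODEL_SCHEMA_VERSION})"
        )
    try:
        return ScoringModel.from_dict(payload)
    except (KeyError, TypeError, ValueError) as err:
        raise SchemaError(f"{path}: malformed model payload ({err})") from err
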