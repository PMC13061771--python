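"""Reading, validation and writing of the pipeline's tabular inputs and outputs.

The pipeline consumes four kinds of files:

* an expression matrix (genes x samples, normalized CPM) in the dialect of a
  GREIN gene-level export: first column gene identifier, one numeric column
  per GSM sample, comma- or tab-delimited;
* a per-sample clinical table (seizure frequency, gender, age, epilepsy
  duration, onset age, etiology);
* plain-text gene lists (one identifier per line, ``#`` comments);
* a two-column gene -> cytogenetic-band annotation.

All result tables are written as TSV with at least six significant digits so
that a write/read round trip preserves every number to the precision the
downstream comparisons use.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataValidationError",
    "MissingFileError",
    "NonNumericValueError",
    "NegativeValueError",
    "EmptySampleSetError",
    "MissingColumnError",
    "UnknownGenderError",
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneList",
    "BandAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "read_gene_list",
    "write_gene_list",
    "read_band_annotation",
    "write_result_table",
]


class DataValidationError(ValueError):
    """Base class for input validation failures."""


class MissingFileError(DataValidationError):
    """The requested input file does not exist."""


class NonNumericValueError(DataValidationError):
    """A cell that must be numeric could not be parsed as a number."""


class NegativeValueError(DataValidationError):
    """A negative value appeared where only non-negative expression is valid."""


class EmptySampleSetError(DataValidationError):
    """The table defines no sample columns / rows."""


class MissingColumnError(DataValidationError):
    """A required clinical column is absent."""


class UnknownGenderError(DataValidationError):
    """A gender code outside {F, M} was encountered."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values.

    ``data`` is a DataFrame indexed by gene identifier with one column per
    sample, in input order.  ``log_scale`` records whether the values have
    already been log2-transformed (raw CPM must be non-negative; log values
    may be negative).
    """

    data: pd.DataFrame
    log_scale: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __post_init__(self) -> None:
        self.data = _validate_expression_frame(self.data, self.log_scale)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(self.data[ids].copy(), log_scale=self.log_scale)


def _dedupe_gene_ids(ids: list[str]) -> list[str]:
    """Suffix repeated identifiers with .1, .2, ... keeping the first as-is."""
    seen: dict[str, int] = {}
    out = []
    duplicated = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            duplicated.append(g)
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    if duplicated:
        logger.warning(
            "%d duplicate gene identifier(s) suffixed with .1, .2, ...: %s",
            len(duplicated),
            ", ".join(sorted(set(duplicated))[:10]),
        )
    return out


def _validate_expression_frame(df: pd.DataFrame, log_scale: bool) -> pd.DataFrame:
    if df.shape[1] == 0:
        raise EmptySampleSetError("expression matrix has zero sample columns")
    gene_ids = [str(g).strip() for g in df.index]
    if any(g == "" for g in gene_ids):
        raise DataValidationError("empty gene identifier after whitespace stripping")
    df = df.copy()
    df.index = _dedupe_gene_ids(gene_ids)
    df.index.name = "gene_id"
    df.columns = [str(c).strip() for c in df.columns]
    if len(set(df.columns)) != df.shape[1]:
        raise DataValidationError("duplicate sample identifiers")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric(df)
        raise NonNumericValueError(
            f"non-numeric expression value at gene {bad[0]!r}, sample {bad[1]!r}: {bad[2]!r}"
        ) from exc
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise NonNumericValueError(
            f"non-finite expression value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if not log_scale and (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise NegativeValueError(
            f"negative expression value {values[i, j]} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    df = df.astype(float)
    return df


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str, object]:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            return str(df.index[i]), str(col), df[col].iloc[i]
    return "?", "?", None


CLINICAL_COLUMNS = (
    "sample_id",
    "seizure_frequency",
    "gender",
    "age",
    "duration",
    "onset_age",
    "etiology",
)

_NUMERIC_CLINICAL = ("seizure_frequency", "age", "duration", "onset_age")


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates.

    ``data`` holds one row per sample with the canonical columns
    ``sample_id, seizure_frequency, gender, age, duration, onset_age,
    etiology``.  Gender is coded F/M; etiology labels are kept verbatim.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_clinical_frame(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def values_for(self, variable: str, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        """Numeric values of ``variable``, optionally restricted/ordered by sample ids."""
        if variable not in self.data.columns:
            raise MissingColumnError(f"unknown clinical variable {variable!r}")
        frame = self.data.set_index("sample_id")
        if sample_ids is None:
            return frame[variable].to_numpy()
        return frame.loc[list(sample_ids), variable].to_numpy()


def _validate_clinical_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"clinical table missing column(s): {missing}")
    if len(df) == 0:
        raise EmptySampleSetError("clinical table has no samples")
    df = df.loc[:, list(CLINICAL_COLUMNS)].copy().reset_index(drop=True)
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataValidationError(f"duplicate sample ids: {dups}")
    gender = df["gender"].astype(str).str.strip().str.upper()
    gender = gender.replace({"FEMALE": "F", "MALE": "M"})
    bad = ~gender.isin(["F", "M"])
    if bad.any():
        offender = df.loc[bad, "sample_id"].iloc[0]
        code = df.loc[bad, "gender"].iloc[0]
        raise UnknownGenderError(f"unknown gender code {code!r} for sample {offender!r}")
    df["gender"] = gender
    for col in _NUMERIC_CLINICAL:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            offender = df.loc[bad, "sample_id"].iloc[0]
            raise NonNumericValueError(
                f"non-numeric {col} for sample {offender!r}: {df.loc[bad, col].iloc[0]!r}"
            )
        df[col] = coerced.astype(float)
    if (df["duration"] <= 0).any():
        offender = df.loc[df["duration"] <= 0, "sample_id"].iloc[0]
        raise DataValidationError(f"non-positive epilepsy duration for sample {offender!r}")
    if (df["onset_age"] < 0).any():
        offender = df.loc[df["onset_age"] < 0, "sample_id"].iloc[0]
        raise DataValidationError(f"negative onset age for sample {offender!r}")
    if (df["seizure_frequency"] < 0).any():
        offender = df.loc[df["seizure_frequency"] < 0, "sample_id"].iloc[0]
        raise DataValidationError(f"negative seizure frequency for sample {offender!r}")
    df["etiology"] = df["etiology"].astype(str).str.strip()
    return df


@dataclass(frozen=True)
class GeneList:
    """An unordered set of gene identifiers with a free-text label."""

    identifiers: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if any((not isinstance(g, str)) or g == "" for g in self.identifiers):
            raise DataValidationError("gene list contains empty or non-string identifiers")

    @classmethod
    def from_iterable(cls, genes: Iterable[str], label: str = "") -> "GeneList":
        return cls(frozenset(str(g).strip() for g in genes), label)

    @property
    def sorted(self) -> list[str]:
        return sorted(self.identifiers)

    def __len__(self) -> int:
        return len(self.identifiers)

    def __contains__(self, gene: str) -> bool:
        return gene in self.identifiers


@dataclass
class BandAnnotation:
    """Gene identifier -> cytogenetic band (one band per gene)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, band in self.mapping.items():
            if not band:
                raise DataValidationError(f"empty band label for gene {gene!r}")

    def band_of(self, gene: str) -> str | None:
        return self.mapping.get(gene)

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _check_exists(path: str | Path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise MissingFileError(f"input file not found: {p}")
    return p


def _sniff_delimiter(path: Path) -> str:
    """Choose between comma and tab from the header line."""
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_expression_matrix(
    path: str | Path, delimiter: str | None = None, log_scale: bool = False
) -> ExpressionMatrix:
    """Read a GREIN-style gene-level matrix (first column = gene identifier).

    The delimiter is auto-detected between comma and tab unless given.
    Duplicate gene identifiers are retained with ``.1``, ``.2``... suffixes
    and a warning, so row counts are never silently changed.
    """
    p = _check_exists(path)
    sep = delimiter or _sniff_delimiter(p)
    df = pd.read_csv(p, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise EmptySampleSetError(f"no sample columns parsed from {p} (delimiter {sep!r})")
    return ExpressionMatrix(df, log_scale=log_scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV in the same dialect ``read_expression_matrix`` accepts."""
    matrix.data.to_csv(path, sep="\t", float_format="%.10g")


_HEADER_PATTERNS: list[tuple[str, str]] = [
    # checked in order; first regex match on the normalized header wins
    ("sample_id", r"(sample|geo.?accession|gsm)"),
    ("seizure_frequency", r"(seizure.?frequency|frequency|seizure.?month)"),
    ("gender", r"(gender|sex)"),
    ("onset_age", r"(onset)"),
    ("duration", r"(duration)"),
    ("etiology", r"(etiolog|aetiolog|cause)"),
    ("age", r"(^age$|age.?at.?sampling|^age\b)"),
]


def _map_clinical_headers(columns: Iterable[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        norm = re.sub(r"\(.*?\)", "", str(col)).strip().lower()
        norm = re.sub(r"[^a-z0-9]+", " ", norm).strip()
        for canonical, pattern in _HEADER_PATTERNS:
            if canonical in mapping:
                continue
            if re.search(pattern, norm.replace(" ", " ")):
                mapping[canonical] = col
                break
    return mapping


def read_clinical_table(path: str | Path, delimiter: str | None = None) -> ClinicalTable:
    """Read a per-sample clinical table with case-insensitive header matching."""
    p = _check_exists(path)
    sep = delimiter or _sniff_delimiter(p)
    raw = pd.read_csv(p, sep=sep, dtype=str)
    mapping = _map_clinical_headers(raw.columns)
    missing = [c for c in CLINICAL_COLUMNS if c not in mapping]
    if missing:
        raise MissingColumnError(
            f"clinical table {p} missing column(s) {missing}; headers were {list(raw.columns)}"
        )
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_list(path: str | Path, label: str | None = None) -> GeneList:
    """Read a plain-text gene list: one identifier per line, ``#`` comments."""
    p = _check_exists(path)
    genes = []
    for line in p.read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            genes.append(entry)
    return GeneList.from_iterable(genes, label if label is not None else p.stem)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        if genes.label:
            fh.write(f"# {genes.label}\n")
        for g in genes.sorted:
            fh.write(g + "\n")


def read_band_annotation(path: str | Path, delimiter: str | None = None) -> BandAnnotation:
    """Read a two-column (gene, band) TSV/CSV; later duplicates overwrite earlier."""
    p = _check_exists(path)
    sep = delimiter or _sniff_delimiter(p)
    df = pd.read_csv(p, sep=sep, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataValidationError(f"band annotation {p} needs two columns (gene, band)")
    mapping = {
        str(g).strip(): str(b).strip()
        for g, b in zip(df.iloc[:, 0], df.iloc[:, 1])
        if str(g).strip()
    }
    return BandAnnotation(mapping)


def write_result_table(records, path: str | Path) -> None:
    """Write a homogeneous record table as TSV with >= 6 significant digits.

    ``records`` may be a DataFrame or a sequence of dataclass instances
    sharing one schema; row order is preserved.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows and not isinstance(rows[0], Mapping):
            import dataclasses

            rows = [dataclasses.asdict(r) for r in rows]
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
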