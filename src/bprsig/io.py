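"""Tabular I/O and cohort summary statistics.

The package operates on already-summarized log2 expression matrices
(features x samples, e.g. RMA output) plus per-sample phenotype tables.
All file formats are UTF-8 tab-separated text with '.' decimal separator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypeTable",
    "CohortSummary",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_phenotype_table",
    "write_phenotype_table",
    "summarize_cohort",
]

LOBES = ("upper", "lower", "unknown")
SAMPLE_TYPES = ("biopsy", "explant", "control")

#: accepted spellings for the binary phenotype, extendable by callers
DEFAULT_PHENOTYPE_SYNONYMS = {
    "0": 0, "1": 1,
    "control": 0, "normal": 0, "healthy": 0,
    "case": 1, "ipf": 1, "disease": 1,
}

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class FormatError(ValueError):
    """Raised when an input file violates the package's tabular contracts."""


@dataclass
class ExpressionMatrix:
    """log2 expression values, features x samples, with feature annotation.

    Parameters
    ----------
    feature_ids : ordered unique feature identifiers (rows).
    sample_ids : ordered unique sample identifiers (columns).
    values : float matrix, shape (n_features, n_samples), log2 intensity.
    annotation : feature_id -> set of gene identifiers (may be empty).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotation: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise FormatError(f"duplicate feature ID {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample ID {dup!r}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at ({self.feature_ids[g]}, {self.sample_ids[s]})"
            )
        self.annotation = {
            f: set(self.annotation.get(f, set())) for f in self.feature_ids
        }

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise KeyError(f"unknown feature IDs: {missing[:5]}")
        rows = [idx[f] for f in feature_ids]
        return ExpressionMatrix(
            list(feature_ids), list(self.sample_ids), self.values[rows],
            {f: self.annotation.get(f, set()) for f in feature_ids},
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.feature_ids), list(sample_ids), self.values[:, cols],
            dict(self.annotation),
        )


@dataclass
class PhenotypeTable:
    """Per-sample metadata: binary phenotype, patient, lobe, sample type.

    ``table`` holds one row per sample with columns ``sample_id``,
    ``phenotype`` (0 = control, 1 = case), ``patient_id``, ``lobe``,
    ``sample_type`` plus free covariate columns (numeric or categorical).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "phenotype", "patient_id", "lobe", "sample_type")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"phenotype table missing column {col!r}")
        if df["sample_id"].isna().any():
            raise FormatError("missing sample_id")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        bad = ~df["phenotype"].isin([0, 1])
        if bad.any():
            raise FormatError(
                f"phenotype must be 0/1; offending sample "
                f"{df.loc[bad, 'sample_id'].iloc[0]!r}"
            )
        df["phenotype"] = df["phenotype"].astype(int)
        df["lobe"] = [
            l if l in LOBES else "unknown"
            for l in df["lobe"].astype(str).str.lower()
        ]
        st = df["sample_type"].astype(str).str.lower()
        bad_st = ~st.isin(SAMPLE_TYPES)
        if bad_st.any():
            raise FormatError(
                f"unknown sample_type {st[bad_st].iloc[0]!r} "
                f"(expected one of {SAMPLE_TYPES})"
            )
        df["sample_type"] = st
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]

    def y(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Binary labels aligned to ``sample_ids`` (table order by default)."""
        df = self.table.set_index("sample_id")
        if sample_ids is None:
            sample_ids = self.sample_ids
        return df.loc[list(sample_ids), "phenotype"].to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        df = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return PhenotypeTable(df)


@dataclass
class CohortSummary:
    """Per-group descriptive statistics (the study-population table layer).

    ``numeric``: (group, covariate) -> {n, mean, se}; ``se`` is None when
    n < 2 (sample sd undefined).  ``categorical``: (group, covariate, level)
    -> {n, proportion, percent} with percent rounded half-up to an integer.
    """

    numeric: dict[tuple[str, str], dict]
    categorical: dict[tuple[str, str, str], dict]
    group_sizes: dict[str, int]


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate present")


def read_expression_matrix(path, annotation_path=None) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample IDs, first col = feature IDs)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty expression file: {path}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise FormatError(f"expression file has no data: {path}")
    feature_ids = [str(f) for f in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"non-numeric value {raw[i, j]!r} at "
                    f"({feature_ids[i]}, {sample_ids[j]})"
                ) from exc
    annotation = read_annotation(annotation_path) if annotation_path else {}
    return ExpressionMatrix(feature_ids, sample_ids, values, annotation)


def write_expression_matrix(X: ExpressionMatrix, path,
                            annotation_path=None) -> None:
    X.to_dataframe().to_csv(path, sep="\t", index_label="feature_id",
                            float_format="%.17g")
    if annotation_path is not None:
        write_annotation(X.annotation, annotation_path)


def read_annotation(path) -> dict[str, set[str]]:
    """Read (feature_id, gene_id) pairs, one per line; repeats allowed."""
    ann: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("annotation file needs feature_id and gene_id columns")
    fcol, gcol = df.columns[:2]
    for f, g in zip(df[fcol], df[gcol]):
        if pd.isna(f):
            continue
        s = ann.setdefault(str(f), set())
        if not pd.isna(g) and str(g) not in MISSING_TOKENS:
            s.add(str(g))
    return ann


def write_annotation(annotation: Mapping[str, set[str]], path) -> None:
    rows = []
    for f in annotation:
        genes = sorted(annotation[f])
        if genes:
            rows.extend((f, g) for g in genes)
        else:
            rows.append((f, ""))
    pd.DataFrame(rows, columns=["feature_id", "gene_id"]).to_csv(
        path, sep="\t", index=False)


def read_phenotype_table(path, phenotype_synonyms: Mapping[str, int] | None = None
                         ) -> PhenotypeTable:
    """Read a TSV phenotype table; phenotype labels may use configured synonyms."""
    synonyms = dict(DEFAULT_PHENOTYPE_SYNONYMS)
    if phenotype_synonyms:
        synonyms.update({k.lower(): v for k, v in phenotype_synonyms.items()})
    df = pd.read_csv(path, sep="\t", header=0, dtype=str,
                     keep_default_na=False)
    if "phenotype" not in df.columns:
        raise FormatError("phenotype table missing 'phenotype' column")
    coded = []
    for v in df["phenotype"]:
        key = str(v).strip().lower()
        if key not in synonyms:
            raise FormatError(f"unrecognized phenotype label {v!r}")
        coded.append(synonyms[key])
    df["phenotype"] = coded
    if "sample_id" in df.columns and (df["sample_id"].str.strip() == "").any():
        raise FormatError("missing sample_id")
    # covariates: numeric where possible, missing tokens -> NaN
    for col in df.columns:
        if col in PhenotypeTable.REQUIRED:
            continue
        cleaned = df[col].replace(list(MISSING_TOKENS), np.nan)
        as_num = pd.to_numeric(cleaned, errors="coerce")
        non_missing = cleaned.notna()
        if non_missing.any() and as_num[non_missing].notna().all():
            df[col] = as_num
        else:
            df[col] = cleaned
    return PhenotypeTable(df)


def write_phenotype_table(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_cohort(pheno: PhenotypeTable, group_field: str,
                     fields: Sequence[str]) -> CohortSummary:
    """Per-group mean +/- SE (numeric) and rounded percentages (categorical).

    Each patient is counted once (deduplicated by ``patient_id``; the first
    sample row of a patient carries the clinical covariates).  SE uses the
    sample standard deviation (n-1 denominator) and is reported missing
    when fewer than two non-missing values exist.
    """
    df = pheno.table
    if group_field not in df.columns:
        raise KeyError(f"unknown group field {group_field!r}")
    for f in fields:
        if f not in df.columns:
            raise KeyError(f"unknown covariate {f!r}")
    # one row per patient: keep the first non-missing covariate row
    dedup = df.drop_duplicates(subset="patient_id", keep="first")
    numeric: dict[tuple[str, str], dict] = {}
    categorical: dict[tuple[str, str, str], dict] = {}
    group_sizes: dict[str, int] = {}
    for group, sub in dedup.groupby(group_field, sort=True):
        group = str(group)
        group_sizes[group] = len(sub)
        for f in fields:
            col = sub[f]
            if pd.api.types.is_numeric_dtype(col):
                vals = col.dropna().to_numpy(dtype=float)
                n = len(vals)
                if n == 0:
                    numeric[(group, f)] = {"n": 0, "mean": None, "se": None}
                    continue
                mean = float(np.mean(vals))
                se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else None
                numeric[(group, f)] = {"n": n, "mean": mean, "se": se}
            else:
                vals = col.dropna()
                vals = vals[vals.astype(str) != ""]
                n = len(vals)
                for level, cnt in vals.value_counts().items():
                    prop = cnt / n
                    categorical[(group, f, str(level))] = {
                        "n": int(cnt),
                        "proportion": float(prop),
                        "percent": _round_half_up(100.0 * prop),
                    }
    return CohortSummary(numeric, categorical, group_sizes)
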