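"""Data model and readers/writers for expression, clinical, gene-set and signature tables.

The substrate of every statistic in this package is a probe-by-sample matrix of
log2 expression ratios with probe-level gene-symbol annotation, joined to a
per-sample clinical table carrying hormone-receptor status, histopathological
covariates and a right-censored survival endpoint.  Probes are identified by
their array feature number (an integer-like token, e.g. ``16670``); the gene
symbol is annotation only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "CohortSet",
    "SignatureTable",
    "GeneSetCollection",
    "TableDialect",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "define_cohorts",
    "load_packaged_signature",
    "read_gene_sets",
    "load_packaged_gene_sets",
    "DEFAULT_CLINICAL_PANEL",
    "PACKAGED_SIGNATURES",
]

#: Default clinical-relevance panel: the 10 clinicopathological parameters
#: screened by ANOVA against each probe.  Age and tumor size are binned into
#: the conventional clinical categories so every panel member is a factor.
DEFAULT_CLINICAL_PANEL: tuple[str, ...] = (
    "pr_status",
    "her_status",
    "lvi",
    "lym",
    "lnm_category",
    "age_group",
    "size_group",
    "grade",
    "nuclear_pleomorphism",
    "mitotic_count",
)


@dataclass
class TableDialect:
    """File dialect for the tab-separated tables (UTF-8, '.' decimal)."""

    sep: str = "\t"
    na_tokens: tuple[str, ...] = ("", "NA", "NaN")
    encoding: str = "utf-8"
    gene_symbol_column: str = "gene_symbol"


@dataclass
class ExpressionMatrix:
    """Probe x sample matrix of log2 expression ratios.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by probe id (string token), columns by sample id.
        Missing measurements are NaN, never silently zero.
    gene_symbols : Series
        probe id -> gene symbol; empty string where unknown.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        # canonical in-memory form: unnamed axes (write_* adds header names)
        self.values.index.name = None
        self.values.columns.name = None
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series("", index=self.values.index)
        self.gene_symbols = self.gene_symbols.reindex(self.values.index).fillna("").astype(str)
        self._validate()

    def _validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        for name, labels in (("probe_ids", idx), ("sample_ids", cols)):
            dup = labels[labels.duplicated()].unique()
            if len(dup):
                raise ValueError(f"duplicate {name}: {sorted(map(str, dup))}")
        if self.values.shape[1] < 2 or self.values.shape[0] < 1:
            raise ValueError(
                f"expression matrix needs >=1 probe and >=2 samples, got {self.values.shape}"
            )
        arr = self.values.to_numpy(dtype=float)
        bad = np.isinf(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"non-finite value at probe {idx[i]!r}, sample {cols[j]!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [str(s) for s in sample_ids]
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return ExpressionMatrix(self.values[ids].copy(), self.gene_symbols.copy())


# ordinal clinical columns and their level order (low -> high)
ORDINAL_LEVELS: Mapping[str, tuple] = {
    "grade": (1, 2, 3),
    "nuclear_pleomorphism": (1, 2, 3),
    "mitotic_count": (1, 2, 3),
    "tubule_formation": (1, 2, 3),
    "stage": (1, 2, 3, 4),
}

_CLINICAL_COLUMNS = [
    "er_status", "pr_status", "her_status", "grade", "nuclear_pleomorphism",
    "mitotic_count", "tubule_formation", "lvi", "lym", "lnm", "age",
    "tumor_size", "stage", "surv_time", "event",
]


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and a right-censored (time, event) pair.

    ``er_status``/``pr_status``/``her_status`` are tri-state strings
    ``"+"``/``"-"``/``"?"``.  ``surv_time`` is in the months of follow-up,
    ``event`` is 1 for an observed death/relapse event, 0 for censoring.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str)
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate sample_ids: {sorted(map(str, dup))}")
        if "surv_time" in self.data and (self.data["surv_time"].dropna() < 0).any():
            raise ValueError("surv_time must be >= 0")
        if "event" in self.data:
            ev = self.data["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise ValueError("event must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def derived_factors(self) -> pd.DataFrame:
        """Clinical panel with age/size/LNM binned into clinical categories."""
        d = self.data
        out = d.copy()
        if "age" in d:
            out["age_group"] = np.where(d["age"] >= 50, ">=50", "<50")
        if "tumor_size" in d:
            out["size_group"] = np.where(d["tumor_size"] > 2.0, ">2cm", "<=2cm")
        if "lnm" in d:
            out["lnm_category"] = pd.cut(
                d["lnm"], bins=[-0.5, 0.5, 3.5, np.inf], labels=["0", "1-3", ">3"]
            ).astype(str)
        return out


@dataclass
class CohortSet:
    """Named sample subsets (e.g. ``"90A"``, ``"91A"``, ``"181A"``)."""

    cohorts: dict[str, list[str]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, ids in self.cohorts.items():
            if len(set(ids)) != len(ids):
                raise ValueError(f"cohort {name!r} has duplicate sample ids")
            if uni and not set(ids) <= uni:
                raise ValueError(f"cohort {name!r} not a subset of the sample universe")
        if {"90A", "91A", "181A"} <= set(self.cohorts):
            a, b, c = (set(self.cohorts[k]) for k in ("90A", "91A", "181A"))
            if a & b:
                raise ValueError("90A and 91A overlap")
            if not (a | b) <= c:
                raise ValueError("181A must contain 90A and 91A")

    def __getitem__(self, name: str) -> list[str]:
        return self.cohorts[name]

    def __contains__(self, name: str) -> bool:
        return name in self.cohorts

    def names(self) -> list[str]:
        return list(self.cohorts)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.cohorts.items()}


@dataclass
class SignatureTable:
    """Rows of (feature_number, gene_symbol, direction, literature, regulation)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"feature_number", "gene_symbol", "direction", "literature_annotation",
               "regulation_by_tf"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"signature table missing columns: {sorted(missing)}")
        self.data["feature_number"] = self.data["feature_number"].astype(str)
        if self.data["feature_number"].duplicated().any():
            raise ValueError("duplicate feature_numbers in signature table")
        bad = ~self.data["direction"].isin(["poor", "good"])
        if bad.any():
            raise ValueError(f"direction must be poor/good, got {self.data.loc[bad, 'direction'].tolist()}")

    @property
    def feature_numbers(self) -> list[str]:
        return self.data["feature_number"].tolist()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets (pathways), e.g. read from a GMT file."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, dialect: TableDialect) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=dialect.sep, index_col=0, dtype={0: str},
        na_values=list(dialect.na_tokens), keep_default_na=False,
        encoding=dialect.encoding,
    )


def read_expression_matrix(path: str | Path, dialect: TableDialect | None = None) -> ExpressionMatrix:
    """Read a probe-by-sample expression TSV.

    First column is the probe id, header row the sample ids; an optional
    ``gene_symbol`` column carries annotation.  Missing cells (NA tokens)
    become NaN.  Duplicate ids and non-numeric cells are hard errors naming
    the offending coordinates.
    """
    dialect = dialect or TableDialect()
    raw = _read_table(path, dialect)
    raw.index = raw.index.astype(str)
    symbols = None
    if dialect.gene_symbol_column in raw.columns:
        symbols = raw.pop(dialect.gene_symbol_column).astype(str)
    converted_cols = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            probe = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric expression value at probe {probe!r}, sample {col!r}: "
                f"{raw.loc[probe, col]!r}"
            )
        converted_cols[col] = converted
    values = pd.DataFrame(converted_cols, index=raw.index)
    return ExpressionMatrix(values, symbols)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            dialect: TableDialect | None = None) -> None:
    dialect = dialect or TableDialect()
    out = expr.values.copy()
    if (expr.gene_symbols != "").any():
        out.insert(0, dialect.gene_symbol_column, expr.gene_symbols)
    out.index.name = "probe_id"
    out.to_csv(path, sep=dialect.sep, encoding=dialect.encoding, na_rep="NA",
               float_format="%.17g")


def read_clinical_table(path: str | Path, dialect: TableDialect | None = None) -> ClinicalTable:
    dialect = dialect or TableDialect()
    raw = _read_table(path, dialect)
    for col in ("surv_time", "age", "tumor_size"):
        if col in raw:
            raw[col] = pd.to_numeric(raw[col])
    for col in ("event", "lvi", "lym", "lnm", "grade", "nuclear_pleomorphism",
                "mitotic_count", "tubule_formation", "stage"):
        if col in raw:
            raw[col] = pd.to_numeric(raw[col], errors="coerce").astype("Int64")
    return ClinicalTable(raw)


def write_clinical_table(clin: ClinicalTable, path: str | Path,
                         dialect: TableDialect | None = None) -> None:
    dialect = dialect or TableDialect()
    out = clin.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=dialect.sep, encoding=dialect.encoding, na_rep="NA",
               float_format="%.17g")


# ---------------------------------------------------------------------------
# cohorts


def define_cohorts(clinical: ClinicalTable) -> CohortSet:
    """Partition samples into the ER-status cohorts and molecular subtype subsets.

    ``"90A"`` = ER(+), ``"91A"`` = ER(−), ``"181A"`` = every sample (the
    names follow the array-dataset convention regardless of actual counts).
    Subtype subsets: IE (ER+PR+), IIE (ER+PR−), TN (ER−PR−HER−),
    ERBB2 (ER−PR−HER+) and the remaining ER(−) subgroups.  A sample with
    unknown ER status is placed in 181A only, with a warning.
    """
    d = clinical.data
    er = d["er_status"].astype(str)
    pr = d["pr_status"].astype(str) if "pr_status" in d else pd.Series("?", index=d.index)
    her = d["her_status"].astype(str) if "her_status" in d else pd.Series("?", index=d.index)
    ids = d.index

    unknown = ids[~er.isin(["+", "-"])]
    if len(unknown):
        warnings.warn(
            f"{len(unknown)} sample(s) with unknown ER status placed in 181A only",
            stacklevel=2,
        )
    pos, neg = ids[er == "+"], ids[er == "-"]
    cohorts = {
        "181A": list(ids),
        "90A": list(pos),
        "91A": list(neg),
        "IE": list(ids[(er == "+") & (pr == "+")]),
        "IIE": list(ids[(er == "+") & (pr == "-")]),
        "TN": list(ids[(er == "-") & (pr == "-") & (her == "-")]),
        "ERBB2": list(ids[(er == "-") & (pr == "-") & (her == "+")]),
        "ERneg_PRpos_HERneg": list(ids[(er == "-") & (pr == "+") & (her == "-")]),
        "ERneg_PRpos_HERpos": list(ids[(er == "-") & (pr == "+") & (her == "+")]),
        "ERneg_HERunknown": list(ids[(er == "-") & ~her.isin(["+", "-"])]),
    }
    if not cohorts["91A"]:
        warnings.warn("91A cohort is empty (no ER(−) samples)", stacklevel=2)
    if not cohorts["90A"]:
        warnings.warn("90A cohort is empty (no ER(+) samples)", stacklevel=2)
    return CohortSet(cohorts, universe=list(ids))


# ---------------------------------------------------------------------------
# packaged fixtures

PACKAGED_SIGNATURES = {
    "type2_nr5a2": "table_type2_nr5a2.tsv",
    "type4_nr5a1": "table_type4_nr5a1.tsv",
}


def _data_path(filename: str):
    return resources.files("cidnet.data").joinpath(filename)


def load_packaged_signature(name: str) -> SignatureTable:
    """Load a packaged signature table.

    ``"type2_nr5a2"`` — the 16-probe poor-prognosis predictor table of the
    NR5A2 network (feature type II); ``"type4_nr5a1"`` — the 8-TF favorable
    signature regulated by NR5A1 (feature type IV).
    """
    if name not in PACKAGED_SIGNATURES:
        raise KeyError(
            f"unknown signature {name!r}; available: {sorted(PACKAGED_SIGNATURES)}"
        )
    with resources.as_file(_data_path(PACKAGED_SIGNATURES[name])) as p:
        df = pd.read_csv(p, sep="\t", dtype={"feature_number": str})
    return SignatureTable(df)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, tab-separated members."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: need name, description, >=1 member")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = members
    return GeneSetCollection(sets, source=str(path))


def load_packaged_gene_sets() -> GeneSetCollection:
    """The packaged 13-pathway signal-transduction collection (KEGG-derived)."""
    with resources.as_file(_data_path("pathways13.gmt")) as p:
        return read_gene_sets(p)
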