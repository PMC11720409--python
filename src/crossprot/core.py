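"""Domain types, file IO and harmonization for two-platform proteomics data.

The package compares an aptamer platform (two independent runs, raw linear
RFU readout) against an antibody/PEA platform (log2 NPX readout) on the same
cerebrospinal-fluid cohort.  This module defines the shared containers:

* :class:`ExpressionMatrix` — a reagent-by-sample abundance matrix with an
  explicit scale tag, so that log2/z-score harmonization can refuse to run
  twice and CV formulas can pick the right identity for the readout scale.
* :class:`ReagentAnnotation` / :class:`ReagentPair` — reagent→UniProt-ID-set
  mapping and cross-platform matches.  Two reagents match when their UniProt
  ID *sets* are equal (protein complexes carry several IDs; partial overlap
  is not a match).
* :class:`PlateMap` and :class:`PhenotypeTable` — plate/calibrator structure
  for CV computation and per-sample clinical covariates.

Readers accept two delimited dialects: a wide table (reagents as rows,
samples as columns) standing in for an ADAT export, and a long NPX table
with one row per (sample, reagent) measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("crossprot")

# ---------------------------------------------------------------------------
# Enums
# ---------------------------------------------------------------------------


class Platform(str, Enum):
    """Assay run identity: two aptamer runs and one antibody run."""

    SOMA_A = "SOMA_A"
    SOMA_B = "SOMA_B"
    OLINK = "OLINK"


class Scale(str, Enum):
    """Readout scale of an :class:`ExpressionMatrix`."""

    LINEAR_RFU = "LINEAR_RFU"
    NPX_LOG2 = "NPX_LOG2"
    LOG2 = "LOG2"
    ZSCORED = "ZSCORED"


class Dialect(str, Enum):
    """Input file layout."""

    ADAT_WIDE = "ADAT_WIDE"
    NPX_LONG = "NPX_LONG"


class SampleRole(str, Enum):
    STUDY = "STUDY"
    CALIBRATOR = "CALIBRATOR"


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReagentAnnotation:
    """A single capture reagent and the UniProt accession(s) of its target.

    ``uniprot_ids`` is a frozenset because protein complexes (e.g. IgG
    heavy+light chain) are annotated with several accessions and matching
    across platforms is defined on the *complete* ID set.
    """

    reagent_id: str
    platform: Platform
    uniprot_ids: frozenset[str]
    gene_symbol: str | None = None
    panel: str | None = None

    def __post_init__(self) -> None:
        if not self.uniprot_ids:
            raise ValueError(
                f"reagent {self.reagent_id!r}: uniprot_ids must be non-empty"
            )
        object.__setattr__(self, "uniprot_ids", frozenset(self.uniprot_ids))
        object.__setattr__(self, "platform", Platform(self.platform))


@dataclass(frozen=True)
class ReagentPair:
    """A cross-dataset reagent match justified by a shared UniProt ID set."""

    reagent_a: ReagentAnnotation
    reagent_b: ReagentAnnotation
    match_basis: frozenset[str]

    def __post_init__(self) -> None:
        if self.reagent_a.uniprot_ids != self.reagent_b.uniprot_ids:
            raise ValueError("paired reagents must have set-equal uniprot_ids")


@dataclass
class ExpressionMatrix:
    """Reagent-by-sample abundance matrix with an explicit scale tag.

    ``values`` is a DataFrame indexed by reagent_id with sample_id columns.
    LINEAR_RFU matrices must be strictly positive (they are log2-transformed
    during harmonization).
    """

    values: pd.DataFrame
    scale: Scale
    platform: Platform

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        self.platform = Platform(self.platform)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate reagent ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.scale is Scale.LINEAR_RFU:
            arr = self.values.to_numpy()
            if np.any(~np.isnan(arr) & (arr <= 0)):
                raise ValueError("LINEAR_RFU values must be strictly positive")

    @property
    def reagent_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_reagents(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy(),
                                self.scale, self.platform)

    def subset_reagents(self, reagent_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(reagent_ids), :].copy(),
                                self.scale, self.platform)


@dataclass
class PlateMap:
    """sample_id → (plate_id, role) assignment.

    Calibrator entries drive the intra-/inter-assay CV computation; intra CV
    needs at least two calibrators per plate.
    """

    table: pd.DataFrame  # columns: sample_id, plate_id, role

    def __post_init__(self) -> None:
        required = {"sample_id", "plate_id", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"plate map missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("plate map assigns a sample to more than one plate")
        self.table = self.table.copy()
        self.table["role"] = self.table["role"].map(lambda r: SampleRole(r))

    @property
    def plates(self) -> list[str]:
        return sorted(self.table["plate_id"].unique())

    def calibrators(self, plate_id: str | None = None) -> list[str]:
        t = self.table[self.table["role"] == SampleRole.CALIBRATOR]
        if plate_id is not None:
            t = t[t["plate_id"] == plate_id]
        return t["sample_id"].tolist()

    def study_samples(self) -> list[str]:
        t = self.table[self.table["role"] == SampleRole.STUDY]
        return t["sample_id"].tolist()


#: phenotype columns treated as CSF biomarkers; the assay-technique covariate
#: applies only to these (they were quantified by either ELISA or CLEIA).
CSF_BIOMARKERS = ("csf_ab42", "csf_ptau")

PHENOTYPE_COLUMNS = (
    "age", "sex", "diagnosis", "csf_ab42", "csf_ptau", "csf_albumin",
    "csf_globulins", "csf_total_protein", "csf_rbc", "qalb", "mmse",
    "technique", "apoe_e4", "storage_years",
)


@dataclass
class PhenotypeTable:
    """Per-sample clinical covariates, indexed by sample_id.

    sex and apoe_e4 are 0/1; diagnosis is "HC"/"MCI"; technique is
    "ELISA"/"CLEIA" and must be present whenever a CSF biomarker value is.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in phenotype table")
        if "mmse" in df.columns:
            mmse = df["mmse"].dropna()
            if ((mmse < 0) | (mmse > 30)).any():
                raise ValueError("mmse values must lie in [0, 30]")
        if "age" in df.columns and (df["age"].dropna() <= 0).any():
            raise ValueError("age must be positive")
        for bm in CSF_BIOMARKERS:
            if bm in df.columns and "technique" in df.columns:
                bad = df[bm].notna() & df["technique"].isna()
                if bad.any():
                    raise ValueError(
                        f"technique missing for samples with {bm}: "
                        f"{df.index[bad].tolist()[:5]}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def numeric_frame(self) -> pd.DataFrame:
        """Encode categorical columns (sex, diagnosis, technique, apoe_e4)
        as 0/1 numerics for regression/correlation use."""
        df = self.data.copy()
        if "diagnosis" in df.columns and df["diagnosis"].dtype == object:
            df["diagnosis"] = (df["diagnosis"] == "MCI").astype(float)
        if "technique" in df.columns and df["technique"].dtype == object:
            df["technique"] = (df["technique"] == "CLEIA").astype(float)
        return df.astype(float)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression(path: str | Path, dialect: Dialect | str,
                    platform: Platform | str) -> ExpressionMatrix:
    """Read an expression matrix from one of the two supported dialects.

    ADAT_WIDE: first column reagent_id, remaining columns one per sample,
    linear RFU values.  NPX_LONG: columns sample_id, reagent_id, npx
    (optionally panel), one row per measurement; duplicate (sample, reagent)
    rows are an error.
    """
    path = Path(path)
    dialect = Dialect(dialect)
    platform = Platform(platform)
    sep = _detect_sep(path)
    if dialect is Dialect.ADAT_WIDE:
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # malformed header / ragged rows
            raise ParseError(f"{path}: cannot parse wide table: {exc}") from exc
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ParseError(f"{path}: duplicate reagent ids {dups[:5]}")
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ParseError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                )
            df[col] = coerced
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix(df, Scale.LINEAR_RFU, platform)
    # NPX_LONG
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "reagent_id", "npx"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: NPX_LONG missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["sample_id", "reagent_id"])
    if dup.any():
        first = df.loc[dup, ["sample_id", "reagent_id"]].iloc[0]
        raise ParseError(
            f"{path}: duplicate measurement for sample {first['sample_id']!r}, "
            f"reagent {first['reagent_id']!r}"
        )
    npx = pd.to_numeric(df["npx"], errors="coerce")
    bad = npx.isna() & df["npx"].notna()
    if bad.any():
        i = df.index[bad][0]
        raise ParseError(f"{path}: non-numeric npx value at input row {i}")
    df = df.assign(npx=npx)
    wide = df.pivot(index="reagent_id", columns="sample_id", values="npx")
    wide.index = wide.index.astype(str)
    wide.columns = wide.columns.astype(str)
    return ExpressionMatrix(wide, Scale.NPX_LOG2, platform)


def write_expression(m: ExpressionMatrix, path: str | Path,
                     dialect: Dialect | str = Dialect.ADAT_WIDE,
                     sep: str = "\t") -> None:
    path = Path(path)
    dialect = Dialect(dialect)
    if dialect is Dialect.ADAT_WIDE:
        out = m.values.copy()
        out.index.name = "reagent_id"
        out.to_csv(path, sep=sep)
    else:
        long = (m.values.rename_axis("reagent_id")
                .reset_index()
                .melt(id_vars="reagent_id", var_name="sample_id",
                      value_name="npx"))
        long[["sample_id", "reagent_id", "npx"]].to_csv(path, sep=sep,
                                                        index=False)


def read_annotations(path: str | Path) -> list[ReagentAnnotation]:
    """Annotation TSV: reagent_id, platform, uniprot_ids (pipe-separated),
    optional gene_symbol and panel columns."""
    df = pd.read_csv(path, sep=_detect_sep(Path(path)), dtype=str)
    anns = []
    for _, row in df.iterrows():
        ids = frozenset(s for s in str(row["uniprot_ids"]).split("|") if s)
        anns.append(ReagentAnnotation(
            reagent_id=str(row["reagent_id"]),
            platform=Platform(row["platform"]),
            uniprot_ids=ids,
            gene_symbol=row.get("gene_symbol") if isinstance(
                row.get("gene_symbol"), str) else None,
            panel=row.get("panel") if isinstance(row.get("panel"), str) else None,
        ))
    return anns


def write_annotations(anns: Iterable[ReagentAnnotation],
                      path: str | Path) -> None:
    rows = [{
        "reagent_id": a.reagent_id,
        "platform": a.platform.value,
        "uniprot_ids": "|".join(sorted(a.uniprot_ids)),
        "gene_symbol": a.gene_symbol or "",
        "panel": a.panel or "",
    } for a in anns]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_plate_map(path: str | Path) -> PlateMap:
    df = pd.read_csv(path, sep=_detect_sep(Path(path)), dtype=str)
    return PlateMap(df)


def write_plate_map(pm: PlateMap, path: str | Path) -> None:
    out = pm.table.copy()
    out["role"] = out["role"].map(lambda r: r.value)
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep=_detect_sep(Path(path)), index_col="sample_id")
    return PhenotypeTable(df)


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    out = pt.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def log2_zscale(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform (linear input only) then z-score each reagent row.

    Each dataset is harmonized independently: per reagent, subtract the mean
    and divide by the SD (n−1 denominator) across samples.  Constant rows
    have no defined z-score and are dropped with a logged reason; non-positive
    linear values are a domain error.  Refuses already z-scored input so the
    transform cannot be applied twice.
    """
    if m.scale is Scale.ZSCORED:
        raise ValueError("matrix is already z-scored")
    vals = m.values
    if m.scale is Scale.LINEAR_RFU:
        arr = vals.to_numpy(dtype=float)
        if np.any(~np.isnan(arr) & (arr <= 0)):
            raise ValueError("non-positive value under LINEAR_RFU; cannot log2")
        vals = pd.DataFrame(np.log2(arr), index=vals.index, columns=vals.columns)
    sd = vals.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        logger.warning(
            "log2_zscale: dropping %d constant reagent row(s) "
            "(z-score undefined): %s%s", len(constant), constant[:5],
            "..." if len(constant) > 5 else "")
        vals = vals.drop(index=constant)
        sd = sd.drop(index=constant)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, Scale.ZSCORED, m.platform)


# ---------------------------------------------------------------------------
# Reagent pairing and sample alignment
# ---------------------------------------------------------------------------


def pair_reagents(a: Sequence[ReagentAnnotation],
                  b: Sequence[ReagentAnnotation]) -> list[ReagentPair]:
    """Match reagents across two datasets by set-equal UniProt ID sets.

    Many-to-many: every (a, b) combination with identical ID sets yields a
    pair (several aptamers per protein × several subpanel assays per protein).
    Symmetric in its arguments up to the a/b slot labels.
    """
    index: dict[frozenset[str], list[ReagentAnnotation]] = {}
    for ann in b:
        index.setdefault(ann.uniprot_ids, []).append(ann)
    pairs = []
    for ann in a:
        for other in index.get(ann.uniprot_ids, ()):
            pairs.append(ReagentPair(ann, other, ann.uniprot_ids))
    return pairs


class AlignedSamples(NamedTuple):
    a: ExpressionMatrix
    b: ExpressionMatrix
    n_overlap: int


def align_overlap(a: ExpressionMatrix, b: ExpressionMatrix) -> AlignedSamples:
    """Restrict two matrices to their shared samples, identical order."""
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not shared:
        raise ValueError("no overlapping samples between the two matrices")
    return AlignedSamples(a.subset_samples(shared), b.subset_samples(shared),
                          len(shared))
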