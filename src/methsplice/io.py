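"""Validated containers and TSV readers/writers for every on-disk artifact.

The pipeline exchanges five kinds of delimited-text files:

* feature x sample matrices — methylation beta values in [0, 1], or
  gene/exon/isoform expression on the log2(x+1) scale; tab-separated,
  features in rows, samples in columns, ``NA`` for missing cells;
* a gene-centric feature map linking CpG probes, exon loci
  (``chrom:start-end:strand`` identifiers) and isoforms with their member
  exons, in long format;
* a sample table assigning each sample to one cancer type;
* a clinical table with right-censored survival outcomes (time, event).

Containers are thin wrappers around :class:`pandas.DataFrame` that check
their invariants on construction, so downstream stages can assume clean
inputs. Missing methylation values are kept as ``NaN`` and handled
pairwise downstream; they are never imputed to zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NA_REP",
    "EXPRESSION_KINDS",
    "FormatError",
    "MethylationMatrix",
    "ExpressionMatrix",
    "ExonLocus",
    "FeatureMap",
    "SampleTable",
    "ClinicalTable",
    "read_matrix",
    "parse_exon_id",
    "format_exon_id",
    "log_transform",
]

NA_REP = "NA"
EXPRESSION_KINDS = ("gene", "exon", "isoform")


class FormatError(ValueError):
    """An on-disk artifact (or in-memory construction) violates the format contract."""


def _require_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    dup = idx[idx.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate {what}: {dup[0]!r}")


def _read_matrix_df(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df.astype(float)


@dataclass
class MethylationMatrix:
    """Beta values (CpG x sample); all non-missing entries must lie in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _require_unique(self.values.index, "CpG id")
        _require_unique(self.values.columns, "sample id")
        self.values = self.values.astype(float)
        vals = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | (vals > 1.0)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"beta value {vals[i, j]} outside [0, 1] at CpG "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path) -> "MethylationMatrix":
        return cls(_read_matrix_df(path))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep=NA_REP, index_label="cpg_id")


@dataclass
class ExpressionMatrix:
    """log2(x+1)-scale expression (feature x sample) for one feature kind."""

    values: pd.DataFrame
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.kind not in EXPRESSION_KINDS:
            raise FormatError(f"unknown feature kind {self.kind!r}; expected one of {EXPRESSION_KINDS}")
        _require_unique(self.values.index, f"{self.kind} id")
        _require_unique(self.values.columns, "sample id")
        self.values = self.values.astype(float)
        vals = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | np.isinf(vals)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"expression value {vals[i, j]} negative or non-finite at "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path, kind: str = "gene") -> "ExpressionMatrix":
        return cls(_read_matrix_df(path), kind=kind)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep=NA_REP, index_label=f"{self.kind}_id")


def read_matrix(path, kind: str):
    """Read a matrix file; ``kind='methylation'`` yields a MethylationMatrix."""
    if kind == "methylation":
        return MethylationMatrix.from_tsv(path)
    return ExpressionMatrix.from_tsv(path, kind=kind)


# -- exon loci ---------------------------------------------------------------

_EXON_ID_RE = re.compile(
    r"^(?P<chrom>[A-Za-z0-9_.]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$"
)


@dataclass(frozen=True)
class ExonLocus:
    """A 1-based, fully-closed exon interval keyed as ``chrom:start-end:strand``."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise FormatError(f"exon start {self.start} > end {self.end}")
        if self.start < 0:
            raise FormatError(f"negative exon start {self.start}")

    @property
    def exon_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


def parse_exon_id(exon_id: str) -> ExonLocus:
    m = _EXON_ID_RE.match(exon_id)
    if m is None:
        raise FormatError(f"malformed exon id {exon_id!r}; expected chrom:start-end:strand")
    return ExonLocus(m["chrom"], int(m["start"]), int(m["end"]), m["strand"])


def format_exon_id(locus: ExonLocus) -> str:
    return locus.exon_id


# -- feature map -------------------------------------------------------------


@dataclass
class FeatureMap:
    """Gene-centric index: CpGs, exon loci and isoforms per gene, plus
    isoform -> ordered member exons.

    Membership is declarative (it comes from the map file, not from
    coordinate overlap); exon ids are parsed only to validate their syntax
    and interval ordering.
    """

    gene_cpgs: dict = field(default_factory=dict)
    gene_exons: dict = field(default_factory=dict)
    gene_isoforms: dict = field(default_factory=dict)
    isoform_exons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        iso_owner: dict[str, str] = {}
        for gene, isos in self.gene_isoforms.items():
            for iso in isos:
                if iso in iso_owner:
                    raise FormatError(f"isoform {iso!r} assigned to two genes")
                iso_owner[iso] = gene
        for iso in self.isoform_exons:
            if iso not in iso_owner:
                raise FormatError(f"isoform {iso!r} has members but no gene")
        for gene, exons in self.gene_exons.items():
            for ex in exons:
                parse_exon_id(ex)
        for iso, gene in iso_owner.items():
            members = self.isoform_exons.get(iso, [])
            if not members:
                raise FormatError(f"isoform {iso!r} declares no member exons")
            missing = [e for e in members if e not in set(self.gene_exons.get(gene, []))]
            if missing:
                raise FormatError(
                    f"isoform {iso!r} member exon {missing[0]!r} absent from gene {gene!r}"
                )

    @property
    def genes(self) -> list[str]:
        seen = dict.fromkeys(self.gene_cpgs) | dict.fromkeys(self.gene_exons)
        seen |= dict.fromkeys(self.gene_isoforms)
        return list(seen)

    def cpg_genes(self) -> dict:
        """Invert the CpG assignment; a probe may map to several genes."""
        out: dict[str, list[str]] = {}
        for gene, cpgs in self.gene_cpgs.items():
            for cpg in cpgs:
                out.setdefault(cpg, []).append(gene)
        return out

    def isoforms_containing(self, gene: str, exon_id: str) -> list[str]:
        return [
            iso
            for iso in self.gene_isoforms.get(gene, [])
            if exon_id in self.isoform_exons.get(iso, [])
        ]

    @classmethod
    def from_tsv(cls, path) -> "FeatureMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        expected = ["gene_id", "feature_kind", "feature_id", "parent_isoform_id"]
        if list(df.columns) != expected:
            raise FormatError(f"feature map columns {list(df.columns)} != {expected}")
        gene_cpgs: dict = {}
        gene_exons: dict = {}
        gene_isoforms: dict = {}
        isoform_exons: dict = {}
        for row in df.itertuples(index=False):
            gene, kind, feat, parent = row
            if kind == "cpg":
                gene_cpgs.setdefault(gene, []).append(feat)
            elif kind == "isoform":
                gene_isoforms.setdefault(gene, []).append(feat)
            elif kind == "exon":
                if parent:
                    isoform_exons.setdefault(parent, []).append(feat)
                else:
                    gene_exons.setdefault(gene, []).append(feat)
            else:
                raise FormatError(f"unknown feature_kind {kind!r} in feature map")
        return cls(gene_cpgs, gene_exons, gene_isoforms, isoform_exons)

    def to_tsv(self, path) -> None:
        rows = []
        iso_gene = {
            iso: gene for gene, isos in self.gene_isoforms.items() for iso in isos
        }
        for gene, cpgs in self.gene_cpgs.items():
            rows += [(gene, "cpg", c, "") for c in cpgs]
        for gene, exons in self.gene_exons.items():
            rows += [(gene, "exon", e, "") for e in exons]
        for gene, isos in self.gene_isoforms.items():
            rows += [(gene, "isoform", i, "") for i in isos]
        for iso, members in self.isoform_exons.items():
            rows += [(iso_gene[iso], "exon", e, iso) for e in members]
        pd.DataFrame(
            rows, columns=["gene_id", "feature_kind", "feature_id", "parent_isoform_id"]
        ).to_csv(path, sep="\t", index=False)


# -- sample & clinical tables ------------------------------------------------


@dataclass
class SampleTable:
    """sample_id -> cancer_type assignment; one cancer per sample."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["sample_id", "cancer_type"]
        if list(self.table.columns)[:2] != need:
            raise FormatError(f"sample table columns must start with {need}")
        _require_unique(self.table["sample_id"], "sample id")
        if self.table[need].isna().any().any():
            raise FormatError("sample table contains missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def cancer_types(self) -> list[str]:
        return sorted(self.table["cancer_type"].unique())

    def samples_of(self, cancer: str) -> list[str]:
        return list(self.table.loc[self.table["cancer_type"] == cancer, "sample_id"])

    @classmethod
    def from_tsv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ClinicalTable:
    """Right-censored survival outcomes: time >= 0, event in {0, 1}."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["sample_id", "time", "event"]
        if list(self.table.columns)[:3] != need:
            raise FormatError(f"clinical table columns must start with {need}")
        _require_unique(self.table["sample_id"], "sample id")
        self.table = self.table.assign(
            time=self.table["time"].astype(float), event=self.table["event"].astype(int)
        )
        if (self.table["time"] < 0).any():
            raise FormatError("negative survival time")
        if not self.table["event"].isin([0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")

    def lookup(self, sample_ids) -> pd.DataFrame:
        """Rows for the requested samples, dropping those without clinical data."""
        idx = self.table.set_index("sample_id")
        present = [s for s in sample_ids if s in idx.index]
        return idx.loc[present, ["time", "event"]]

    @classmethod
    def from_tsv(cls, path) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t")
        df["sample_id"] = df["sample_id"].astype(str)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def log_transform(x):
    """log2(x + 1) on non-negative expression values (0 maps to 0)."""
    arr = np.asarray(x, dtype=float)
    finite = np.isfinite(arr)
    if np.any(arr[finite] < 0):
        raise ValueError("expression values must be non-negative before log transform")
    return np.log2(arr + 1.0)
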