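"""Shared in-memory containers.

The pipeline moves data between stages as thin, validated wrappers around
pandas objects.  Coordinates are 0-based half-open everywhere inside the
package; readers that accept 1-based inclusive input convert at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CN_CODES = (-2, -1, 0, 1, 2)

_ARM_RE = re.compile(r"^(?P<chrom>\w+?)(?P<arm>[pq])")


def arm_of_band(band_name: str) -> str:
    """Chromosome arm of a cytoband name, e.g. ``"13q14.2" -> "13q"``."""
    m = _ARM_RE.match(band_name)
    if m is None:
        raise ValidationError(f"cannot parse chromosome arm from {band_name!r}")
    return m.group("chrom") + m.group("arm")


@dataclass(frozen=True)
class GeneCNMatrix:
    """Gene x sample matrix of GISTIC-thresholded copy-number codes.

    ``values`` is float64 with entries in {-2, -1, 0, 1, 2} or NaN for
    missing cells.  Rows are gene symbols, columns sample identifiers.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene rows: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample columns: {dups}")
        arr = df.to_numpy(dtype=float)
        ok = np.isnan(arr) | np.isin(arr, CN_CODES)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"CN value {arr[i, j]!r} outside {{-2..2}} at "
                f"(gene {df.index[i]!r}, sample {df.columns[j]!r})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_samples(self, samples: list[str]) -> "GeneCNMatrix":
        return GeneCNMatrix(self.values.loc[:, samples])


@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene intervals and cytoband intervals, both 0-based half-open.

    ``genes``: columns gene_id, chrom, start, end.
    ``bands``: columns chrom, start, end, band_name, stain — sorted and
    non-overlapping within each chromosome.
    """

    genes: pd.DataFrame
    bands: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        if len(g) and not (g["start"] < g["end"]).all():
            bad = g.loc[~(g["start"] < g["end"]), "gene_id"].tolist()
            raise ValidationError(f"gene intervals with start >= end: {bad}")
        if g["gene_id"].duplicated().any():
            dups = g.loc[g["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        b = self.bands
        for chrom, grp in b.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            overlap = grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]
            if overlap.any():
                k = int(np.argwhere(overlap)[0][0])
                pair = grp.iloc[[k, k + 1]]["band_name"].tolist()
                raise ValidationError(
                    f"overlapping bands on {chrom}: {pair[0]} and {pair[1]}"
                )

    @property
    def band_names(self) -> list[str]:
        """Band names in genomic order (chromosome, then start)."""
        b = self.bands.sort_values(["chrom", "start"], kind="stable")
        return list(b["band_name"])

    def band_arm(self, band_name: str) -> str:
        return arm_of_band(band_name)


@dataclass(frozen=True)
class MutationTable:
    """Long-format mutation records.

    Columns: sample_id, gene_id, mutation_class, pathogenic (bool).
    The (sample_id, gene_id, mutation_class) triple is unique; an
    unannotated pathogenicity flag defaults to False at read time.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        key = ["sample_id", "gene_id", "mutation_class"]
        if df.duplicated(subset=key).any():
            dup = df.loc[df.duplicated(subset=key), key].iloc[0].tolist()
            raise ValidationError(f"duplicate mutation record: {dup}")

    def select_samples(self, samples: list[str]) -> "MutationTable":
        keep = self.records["sample_id"].isin(samples)
        return MutationTable(self.records.loc[keep].reset_index(drop=True))

    def binary_matrix(self, samples: list[str]) -> pd.DataFrame:
        """Sample x gene 0/1 indicator of any mutation."""
        sub = self.records[self.records["sample_id"].isin(samples)]
        mat = pd.crosstab(sub["sample_id"], sub["gene_id"]).clip(upper=1)
        return mat.reindex(index=samples, fill_value=0).astype(int)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene (or protein) x sample real-valued matrix with a scale tag."""

    values: pd.DataFrame
    scale_tag: str = "raw"  # raw | log2 | zscore

    def __post_init__(self) -> None:
        if self.scale_tag not in ("raw", "log2", "zscore"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def select_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, samples], self.scale_tag)


@dataclass(frozen=True)
class CohortTable:
    """Per-sample clinical covariates and overall survival.

    Columns: sample_id, pam50, er, her2, os_months, os_event.  Missing
    covariates are allowed (NaN); os_time must be non-negative and os_event
    in {0, 1} wherever present.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate clinical sample ids: {dups}")
        t = df["os_months"].dropna()
        if (t < 0).any():
            raise ValidationError("negative os_months in clinical table")
        e = df["os_event"].dropna()
        if not e.isin([0, 1]).all():
            raise ValidationError("os_event values outside {0,1}")

    def select_samples(self, samples: list[str]) -> "CohortTable":
        keep = self.rows["sample_id"].isin(samples)
        return CohortTable(self.rows.loc[keep].reset_index(drop=True))


@dataclass(frozen=True)
class SignatureMatrix:
    """Gene x cell-type matrix of non-negative mean expression profiles."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise ValidationError("duplicate genes in signature matrix")
        if (df.to_numpy() < 0).any():
            raise ValidationError("negative entries in signature matrix")
        zero = df.columns[(df == 0).all(axis=0)].tolist()
        if zero:
            raise ValidationError(f"all-zero cell-type columns: {zero}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class CellFractions:
    """Cell-type x sample fractions on the probability simplex.

    ``fractions`` columns are samples, rows cell types; each column is
    non-negative and sums to one (up to 1e-9).  ``residual_norm`` holds the
    per-sample reconstruction residual ||P_j - SM beta_j||; ``flagged``
    lists samples whose raw solution was all-zero before renormalisation.
    """

    fractions: pd.DataFrame
    residual_norm: pd.Series | None = None
    flagged: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValidationError("negative cell fractions")
        sums = arr.sum(axis=0)
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("cell fractions do not sum to one")

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.columns)


@dataclass(frozen=True)
class DrugResponseTable:
    """Long-format drug response: one log10 IC50 per (cell line, drug, screen).

    An optional ``auc`` column carries PDX-style area-under-curve responses
    through the identical two-group machinery.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        key = ["cell_line", "drug", "screen_id"]
        if df.duplicated(subset=key).any():
            dup = df.loc[df.duplicated(subset=key), key].iloc[0].tolist()
            raise ValidationError(f"duplicate drug-response record: {dup}")
        if not np.isfinite(df["log10_ic50"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite log10_ic50 values")


@dataclass(frozen=True)
class FeatureMatrix:
    """Cell line x binary genomic feature matrix (mutations, band CNAs)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("feature matrix must be binary 0/1")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CohortBundle:
    """A coherent cohort: CN + mutations + clinical (+ expression), plus a
    provenance log recording every filter applied to it."""

    cn: GeneCNMatrix
    mutations: MutationTable
    clinical: CohortTable
    annotation: GenomeAnnotation
    expression: ExpressionMatrix | None = None
    provenance: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.cn.sample_ids

    def log(self, message: str) -> None:
        self.provenance.append(message)
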