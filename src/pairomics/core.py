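"""Core domain containers for paired multi-omics analysis.

The pipeline operates on three abundance layers (miRNA, mRNA, protein)
measured on the same matched tumor/control cohort. These containers wrap
pandas structures and enforce the invariants every downstream stage relies
on: nonnegative finite abundances, unique identifiers, and a strict
one-tumor/one-control pairing per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "OmicsKind",
    "Condition",
    "CHROMOSOMES",
    "ExpressionMatrix",
    "SampleDesign",
    "FeatureAnnotation",
    "InteractionTable",
    "ProteinGeneMap",
]


class OmicsKind(str, Enum):
    """The three molecular layers measured on the cohort."""

    MIRNA = "miRNA"
    MRNA = "mRNA"
    PROTEIN = "protein"


class Condition(str, Enum):
    TUMOR = "tumor"
    CONTROL = "control"


#: Canonical chromosome order used for genome linearization.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """One omics layer's abundance values, features x samples, linear scale.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample id.
        All values must be finite and >= 0.
    omics_kind
        Which layer this matrix belongs to.
    """

    data: pd.DataFrame
    omics_kind: OmicsKind

    def __post_init__(self) -> None:
        self.omics_kind = OmicsKind(self.omics_kind)
        self.data = self.data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                "non-finite value at feature "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                "negative value at feature "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.omics_kind)


@dataclass
class SampleDesign:
    """Matched-pairs sample design: one tumor and one control per patient."""

    table: pd.DataFrame  # columns: sample_id, patient_id, condition

    def __post_init__(self) -> None:
        required = {"sample_id", "patient_id", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        self.table = self.table[["sample_id", "patient_id", "condition"]].astype(str)
        _check_unique(self.table["sample_id"], "sample ids")
        bad = set(self.table["condition"]) - {c.value for c in Condition}
        if bad:
            raise ValueError(
                f"unknown condition labels {sorted(bad)}; expected 'tumor' or 'control'"
            )
        counts = self.table.groupby(["patient_id", "condition"]).size()
        for (patient, cond), n in counts.items():
            if n != 1:
                raise ValueError(
                    f"patient {patient!r} has {n} {cond} samples; exactly one required"
                )
        per_patient = self.table.groupby("patient_id")["condition"].nunique()
        incomplete = per_patient[per_patient != 2]
        if len(incomplete):
            raise ValueError(
                f"patients without a complete tumor/control pair: "
                f"{sorted(incomplete.index.tolist())}"
            )

    @property
    def patients(self) -> list[str]:
        return sorted(self.table["patient_id"].unique())

    @property
    def n_pairs(self) -> int:
        return len(self.patients)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_of(self, condition: Condition | str) -> list[str]:
        """Sample ids for one condition, ordered by patient id.

        The shared patient ordering is what makes tumor/control vectors from
        the two calls align pairwise.
        """
        cond = Condition(condition).value
        sub = self.table[self.table["condition"] == cond]
        return list(sub.sort_values("patient_id")["sample_id"])

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        extra = set(matrix.sample_ids) - set(self.table["sample_id"])
        if extra:
            raise ValueError(f"samples absent from design: {sorted(extra)}")


@dataclass
class FeatureAnnotation:
    """Genomic coordinates per feature, 1-based inclusive."""

    table: pd.DataFrame  # columns: feature_id, omics_kind, chromosome, start, end

    def __post_init__(self) -> None:
        required = {"feature_id", "omics_kind", "chromosome", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        self.table = self.table[
            ["feature_id", "omics_kind", "chromosome", "start", "end"]
        ].copy()
        self.table["chromosome"] = self.table["chromosome"].astype(str)
        self.table["start"] = self.table["start"].astype(int)
        self.table["end"] = self.table["end"].astype(int)
        _check_unique(self.table["feature_id"], "feature ids")
        bad_chrom = set(self.table["chromosome"]) - set(CHROMOSOMES)
        if bad_chrom:
            raise ValueError(f"chromosomes outside 1..22/X/Y: {sorted(bad_chrom)}")
        bad = self.table[self.table["start"] > self.table["end"]]
        if len(bad):
            raise ValueError(
                f"start > end for features: {bad['feature_id'].tolist()[:10]}"
            )
        if (self.table["start"] < 1).any():
            raise ValueError("1-based coordinates must be >= 1")


@dataclass
class InteractionTable:
    """miRNA -> target gene edges with curation support level."""

    table: pd.DataFrame  # columns: mirna_id, gene_id, support
    SUPPORT_LEVELS = ("functional_strong", "other")

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id", "support"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"interaction table missing columns: {sorted(missing)}")
        self.table = self.table[["mirna_id", "gene_id", "support"]].astype(str)
        bad = set(self.table["support"]) - set(self.SUPPORT_LEVELS)
        if bad:
            raise ValueError(f"unknown support levels: {sorted(bad)}")
        if self.table.duplicated(["mirna_id", "gene_id"]).any():
            dups = self.table[self.table.duplicated(["mirna_id", "gene_id"])]
            raise ValueError(
                "duplicate interaction pairs: "
                f"{list(map(tuple, dups[['mirna_id', 'gene_id']].values[:5]))}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.table["mirna_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene_id"].unique())


@dataclass
class ProteinGeneMap:
    """Many-to-many mapping between protein identifiers and gene names."""

    table: pd.DataFrame  # columns: protein_id, gene_id

    def __post_init__(self) -> None:
        required = {"protein_id", "gene_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"protein-gene map missing columns: {sorted(missing)}")
        self.table = self.table[["protein_id", "gene_id"]].astype(str)
        if self.table.duplicated().any():
            raise ValueError("duplicate protein-gene pairs")
        if len(self.table) == 0:
            raise ValueError("protein-gene map is empty")
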