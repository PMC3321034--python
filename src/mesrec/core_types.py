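"""Core data model: expression matrices, clinical tables, gene signatures, centroids.

All expression values are log2-scale normalized intensities (RMA-style); the
matrix is genes x samples.  Clinical tables carry a nullable
days-to-tumor-recurrence phenotype: a null entry means the patient never
improved after therapy (non-responder), so ``responder`` is true exactly when
the field is non-null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four transcriptional glioblastoma subtypes; anything else is UNKNOWN.
SUBTYPES = ("Mesenchymal", "Classical", "Neural", "Proneural")
UNKNOWN_SUBTYPE = "UNKNOWN"

_NULL_TOKENS = {"", "null", "na", "nan"}


def normalize_gene_id(gene_id: str) -> str:
    """Canonical form used for gene matching: trimmed, upper-cased."""
    return str(gene_id).strip().upper()


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log2 normalized expression.

    ``data`` is a float DataFrame indexed by gene IDs with sample-ID columns.
    IDs must be unique along both axes and every value finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        frame = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index(gene_ids, name="gene_id"),
            columns=pd.Index(sample_ids, name="sample_id"),
        )
        return cls(frame)

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def find_genes(self, gene_ids: Iterable[str]) -> tuple[list[str], list[str]]:
        """Split ``gene_ids`` into (present, missing) by case-insensitive match.

        Present genes are returned as the matrix's own row labels, preserving
        the query order.
        """
        lookup = {normalize_gene_id(g): g for g in self.data.index}
        present, missing = [], []
        for g in gene_ids:
            row = lookup.get(normalize_gene_id(g))
            (present if row is not None else missing).append(row if row is not None else g)
        return present, missing


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample clinical annotations.

    ``data`` is indexed by sample ID with columns ``days_to_recurrence``
    (float, NaN = null), ``responder`` (bool) and ``subtype`` (one of
    :data:`SUBTYPES` or ``UNKNOWN``).  An optional ``event`` bool column is
    accepted for generality (censoring); absent means every non-null
    recurrence time is an observed event.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample IDs in clinical table")
        required = {"days_to_recurrence", "responder", "subtype"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        days = self.data["days_to_recurrence"]
        responder = self.data["responder"].astype(bool)
        if not (responder == days.notna()).all():
            raise ValueError("responder flag must be true exactly when days_to_recurrence is non-null")
        if (days.dropna() < 0).any():
            raise ValueError("days_to_recurrence must be nonnegative")
        allowed = set(SUBTYPES) | {UNKNOWN_SUBTYPE}
        bad = set(self.data["subtype"]) - allowed
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")

    @classmethod
    def from_records(
        cls,
        sample_ids: Sequence[str],
        days_to_recurrence: Sequence[float],
        subtype: Sequence[str] | None = None,
    ) -> "ClinicalTable":
        days = pd.array(days_to_recurrence, dtype=float)
        frame = pd.DataFrame(
            {
                "days_to_recurrence": days,
                "responder": pd.notna(days),
                "subtype": list(subtype) if subtype is not None else UNKNOWN_SUBTYPE,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return cls(frame)

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def responders(self) -> pd.DataFrame:
        return self.data[self.data["responder"]]


@dataclass(frozen=True)
class GeneSignature:
    """Ordered, duplicate-free list of gene symbols defining a metagene."""

    name: str
    gene_ids: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValueError("signature must contain at least one gene")
        normalized = [normalize_gene_id(g) for g in self.gene_ids]
        if len(set(normalized)) != len(normalized):
            raise ValueError("duplicate genes in signature")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class SubtypeCentroids:
    """Classifier centroids: genes x exactly four subtype columns."""

    gene_ids: tuple[str, ...]
    subtype_names: tuple[str, ...]
    centroid_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.subtype_names) != 4:
            raise ValueError("exactly four subtype centroids are required")
        normalized = [normalize_gene_id(g) for g in self.gene_ids]
        if len(set(normalized)) != len(normalized):
            raise ValueError("duplicate genes in centroids")
        values = np.asarray(self.centroid_values, dtype=float)
        if values.shape != (len(self.gene_ids), 4):
            raise ValueError(f"centroid matrix must be genes x 4, got {values.shape}")
        if not np.isfinite(values).all():
            raise ValueError("centroid values must be finite")
        object.__setattr__(self, "centroid_values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.centroid_values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.subtype_names),
        )


# ---------------------------------------------------------------------------
# readers / writers


def _check_numeric(frame: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric expression value {frame.iat[gi, si]!r} "
            f"at gene {frame.index[gi]!r}, sample {frame.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing expression value at gene {frame.index[gi]!r}, "
            f"sample {frame.columns[si]!r}"
        )
    return numeric.astype(float)


def _assert_unique_samples(samples: list[str], path: str | Path) -> None:
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}: duplicated sample IDs {dups}")


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    TSV: header ``gene_id<TAB>sample...``, one row per gene.  GCT: ``#1.2``
    line, a dimensions line, then NAME/Description columns before the samples.
    Format is inferred from the extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format not in {"tsv", "gct"}:
        raise ValueError(f"unknown expression format {format!r}")

    if format == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            fh.readline()  # dimensions line; trusted but unused
            header_pos = fh.tell()
            samples = fh.readline().rstrip("\n").split("\t")[2:]
            _assert_unique_samples(samples, path)
            fh.seek(header_pos)
            frame = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        frame = frame.drop(columns=frame.columns[0])  # Description
        frame.columns = samples  # undo any pandas dedup-mangling
    else:
        with open(path, encoding="utf-8") as fh:
            samples = fh.readline().rstrip("\n").split("\t")[1:]
        _assert_unique_samples(samples, path)
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        frame.columns = samples
    frame.index = frame.index.astype(str)
    frame.index.name = "gene_id"
    frame.columns.name = "sample_id"
    return ExpressionMatrix(_check_numeric(frame, path))


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        matrix.data.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        n_genes, n_samples = matrix.shape
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            fh.write("NAME\tDescription\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
            for gene, row in zip(matrix.gene_ids, matrix.values):
                fh.write(str(gene) + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV (sample_id, days_to_tumor_recurrence[, subtype]).

    A days entry that is empty or the literal ``null`` (case-insensitive) is
    treated as a non-responder.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    raw_days = frame["days_to_tumor_recurrence"]
    is_null = raw_days.isna() | raw_days.str.strip().str.lower().isin(_NULL_TOKENS)
    days = pd.to_numeric(raw_days.where(~is_null), errors="raise").astype(float)
    subtype = (
        frame["subtype"].fillna(UNKNOWN_SUBTYPE)
        if "subtype" in frame.columns
        else pd.Series(UNKNOWN_SUBTYPE, index=frame.index)
    )
    return ClinicalTable.from_records(frame.index.tolist(), days.tolist(), subtype.tolist())


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    days = clinical.data["days_to_recurrence"]
    out = pd.DataFrame(
        {
            "sample_id": clinical.sample_ids,
            "days_to_tumor_recurrence": [
                "null" if pd.isna(d) else str(int(d)) for d in days
            ],
            "subtype": clinical.data["subtype"].tolist(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a plain-text gene list (one symbol per line, '#' comments)."""
    path = Path(path)
    genes = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return GeneSignature(name=name or path.stem, gene_ids=tuple(genes), provenance=str(path))


def emt_signature() -> GeneSignature:
    """The 64-gene Slug-based EMT (mesenchymal transition) signature."""
    text = resources.files("mesrec.data").joinpath("emt_signature_64.txt").read_text("utf-8")
    genes = tuple(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )
    return GeneSignature(
        name="mesenchymal_transition_64",
        gene_ids=genes,
        provenance="64 genes of the multi-cancer Slug-based EMT signature",
    )


def read_centroids(path: str | Path) -> SubtypeCentroids:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SubtypeCentroids(
        gene_ids=tuple(frame.index.astype(str)),
        subtype_names=tuple(frame.columns.astype(str)),
        centroid_values=frame.to_numpy(dtype=float),
    )


def write_centroids(centroids: SubtypeCentroids, path: str | Path) -> None:
    centroids.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# matrix-level operations


def collapse_probes(matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to gene-level rows by per-sample mean.

    Probes absent from the mapping are dropped (count logged).  Gene order
    follows first occurrence of each gene among the kept probes.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    lookup = {normalize_gene_id(p): g for p, g in probe_to_gene.items()}
    genes_in_order: list[str] = []
    groups: dict[str, list[int]] = {}
    n_dropped = 0
    for i, probe in enumerate(matrix.gene_ids):
        gene = lookup.get(normalize_gene_id(probe))
        if gene is None:
            n_dropped += 1
            continue
        key = normalize_gene_id(gene)
        if key not in groups:
            groups[key] = []
            genes_in_order.append(gene)
        groups[key].append(i)
    if n_dropped:
        logger.warning("collapse_probes: dropped %d probes absent from mapping", n_dropped)
    if not groups:
        raise ValueError("no probes left after applying mapping")
    values = matrix.values
    collapsed = np.vstack(
        [values[groups[normalize_gene_id(g)]].mean(axis=0) for g in genes_in_order]
    )
    return ExpressionMatrix.from_arrays(genes_in_order, matrix.sample_ids, collapsed)


def align(matrix: ExpressionMatrix, clinical: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both containers to their shared samples, in matrix order."""
    clinical_ids = set(clinical.sample_ids)
    shared = [s for s in matrix.sample_ids if s in clinical_ids]
    if not shared:
        raise ValueError("expression matrix and clinical table share no samples")
    dropped_expr = len(matrix.sample_ids) - len(shared)
    dropped_clin = len(clinical.sample_ids) - len(shared)
    if dropped_expr or dropped_clin:
        logger.info(
            "align: dropped %d expression-only and %d clinical-only samples",
            dropped_expr,
            dropped_clin,
        )
    return (
        ExpressionMatrix(matrix.data.loc[:, shared]),
        ClinicalTable(clinical.data.loc[shared]),
    )
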