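"""Signature and expression I/O, gene re-annotation, and the signature registry.

Gene signatures travel as GMT files (one tab-separated line per signature:
name, description, genes...).  Expression matrices are read either from a
dense TSV/CSV (genes in rows, header row of sample ids) or from a
matrix-market triplet file accompanied by plain-text gene and sample index
files.  The packaged registry carries the metadata of the 70 published
hypoxia signatures surveyed in the field (name, derivation class, reported
sizes, tissue of origin); the gene lists themselves are supplied by the user
via GMT.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "SignatureSet",
    "ExpressionMatrix",
    "AliasMap",
    "ReannotationReport",
    "RegistryStats",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "read_metadata",
    "reannotate_signature",
    "tpm_normalize",
    "load_registry",
    "registry_stats",
    "signature_overlap",
    "gene_frequency",
]


@dataclass
class GeneSignature:
    """A named set of up-regulated gene identifiers with provenance metadata.

    ``genes`` preserves first-occurrence order; duplicates and empty
    identifiers are rejected at construction.
    """

    name: str
    genes: tuple[str, ...]
    source_class: str = "in_vitro"  # clinical | in_vitro | both
    clinical_derived: bool = False
    reported_size_original: int | None = None
    reported_size_final: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if any(not g for g in genes):
            raise DataError(f"signature {self.name!r}: empty gene identifier")
        if len(set(genes)) != len(genes):
            raise DataError(f"signature {self.name!r}: duplicate gene identifiers")
        self.genes = genes
        if (
            self.reported_size_original is not None
            and self.reported_size_final is not None
            and self.reported_size_final > self.reported_size_original
        ):
            raise DataError(
                f"signature {self.name!r}: final size exceeds original size"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureSet:
    """A list of signatures keyed by unique name."""

    signatures: list[GeneSignature] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.signatures]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise DataError(f"duplicate signature names: {dup}")

    def __iter__(self):
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    def __getitem__(self, name: str) -> GeneSignature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with identifiers and a scale flag."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"  # linear | log

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite expression values")
        if self.scale not in ("linear", "log"):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and np.any(self.values < 0):
            raise DataError("negative values in a linear-scale matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the given genes, silently dropping absent ones."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise DataError(f"sample {sample_id!r} not in matrix") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids),
            self.values[idx], self.scale,
        )


@dataclass
class AliasMap:
    """Mapping from outdated gene identifiers to current approved symbols."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if any(not v for v in self.entries.values()):
            raise DataError("alias map entry maps to an empty identifier")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["old", "new"], dtype=str)
        return cls(dict(zip(df["old"], df["new"])))


@dataclass
class ReannotationReport:
    renamed: list[tuple[str, str]]
    collapsed: list[str]
    untouched: list[str]


@dataclass
class RegistryStats:
    n_signatures: int
    mean_size: float
    median_size: float
    min_size: int
    max_size: int
    n_clinical_derived: int
    n_in_vitro_only: int


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> SignatureSet:
    """Parse a GMT file into a :class:`SignatureSet`.

    Each line needs at least three tab-separated fields (name, description,
    one or more genes).  Duplicate genes within a line are collapsed with a
    warning; duplicate signature names are an error.
    """
    sigs: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate gene {g!r} in signature "
                        f"{name!r} collapsed",
                        stacklevel=2,
                    )
                seen[g] = None
            sigs.append(GeneSignature(name=name, genes=tuple(seen), notes=desc))
    return SignatureSet(sigs)


def write_gmt(sig_set: SignatureSet, path: str | Path) -> None:
    """Write a signature set as GMT; round-trips names and gene sets."""
    if len(sig_set) == 0:
        raise DataError("refusing to write an empty signature set")
    with open(path, "w") as fh:
        for sig in sig_set:
            desc = sig.notes.replace("\t", " ") or "na"
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices and metadata


def read_expression(
    path: str | Path,
    layout: str = "dense_tsv",
    *,
    gene_index: str | Path | None = None,
    sample_index: str | Path | None = None,
    scale: str = "linear",
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``dense_tsv``: header row of sample ids, first column gene ids (TSV or
    CSV, sniffed from the extension).  ``matrix_market``: a coordinate .mtx
    file plus one-id-per-line gene and sample index files; entries absent
    from the triplets materialize as zero.
    """
    if layout == "dense_tsv":
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise DataError(f"{path}: duplicated gene id {dup!r}")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError:
            bad = df.map(lambda v: isinstance(v, str))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ParseError(
                f"{path}: non-numeric value at gene {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            ) from None
        return ExpressionMatrix(
            [str(g) for g in df.index], [str(s) for s in df.columns], values, scale
        )
    if layout == "matrix_market":
        if gene_index is None or sample_index is None:
            raise DataError("matrix_market layout needs gene_index and sample_index")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(gene_index).read_text().split()
        samples = Path(sample_index).read_text().split()
        if len(set(genes)) != len(genes):
            raise DataError(f"{gene_index}: duplicated gene id")
        return ExpressionMatrix(genes, samples, np.asarray(mat, dtype=float), scale)
    raise DataError(f"unknown layout {layout!r}")


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as dense TSV (genes in rows)."""
    pd.DataFrame(
        matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids
    ).to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table (TSV) with mandatory sample_id, condition."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise DataError(f"{path}: missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        raise DataError(f"{path}: duplicated sample_id")
    bad = set(df["condition"]) - {"hypoxia", "normoxia", "tumor", "nat"}
    if bad:
        raise DataError(f"{path}: unknown condition labels {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Re-annotation and normalization


def reannotate_signature(
    sig: GeneSignature, alias_map: AliasMap
) -> tuple[GeneSignature, ReannotationReport]:
    """Map each gene through the alias table; collapse resulting duplicates.

    Gene symbols drift as nomenclature evolves (VEGF became VEGFA, for
    example), so signatures must be lifted to current approved symbols before
    they are intersected with a measured gene universe.  Unmapped genes are
    kept as-is; first-occurrence order is preserved.
    """
    renamed: list[tuple[str, str]] = []
    collapsed: list[str] = []
    untouched: list[str] = []
    out: dict[str, None] = {}
    for g in sig.genes:
        new = alias_map.entries.get(g, g)
        if new != g:
            renamed.append((g, new))
        else:
            untouched.append(g)
        if new in out:
            collapsed.append(new)
        else:
            out[new] = None
    new_sig = GeneSignature(
        name=sig.name,
        genes=tuple(out),
        source_class=sig.source_class,
        clinical_derived=sig.clinical_derived,
        reported_size_original=sig.reported_size_original,
        reported_size_final=sig.reported_size_final,
        notes=sig.notes,
    )
    return new_sig, ReannotationReport(renamed, collapsed, untouched)


def tpm_normalize(
    counts: ExpressionMatrix, gene_lengths_kb: Mapping[str, float]
) -> ExpressionMatrix:
    """Convert raw counts to Transcripts Per Million.

    Per sample: rate_g = count_g / length_g (length in kilobases), then
    TPM_g = rate_g / sum(rate) * 1e6, so each non-degenerate column sums to
    one million.  All-zero columns stay all-zero with a warning.
    """
    if counts.scale != "linear":
        raise DataError("tpm_normalize expects a linear-scale count matrix")
    lengths = np.empty(len(counts.gene_ids))
    for i, g in enumerate(counts.gene_ids):
        if g not in gene_lengths_kb:
            raise DataError(f"missing gene length for {g!r}")
        L = float(gene_lengths_kb[g])
        if not L > 0:
            raise DataError(f"non-positive gene length for {g!r}")
        lengths[i] = L
    rates = counts.values / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero sample column(s) left as zero",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    tpm = rates / safe[None, :] * 1e6
    tpm[:, zero] = 0.0
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), tpm, "linear"
    )


# ---------------------------------------------------------------------------
# Registry


def load_registry() -> SignatureSet:
    """The packaged metadata registry of the 70 surveyed hypoxia signatures.

    Gene lists are not part of the registry (published counts only); the
    ``genes`` tuple of each entry is empty.
    """
    with importlib.resources.files("sigeval.data").joinpath(
        "table1_registry.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    sigs = [
        GeneSignature(
            name=row["name"],
            genes=(),
            source_class=row["source_class"],
            clinical_derived=bool(row["clinical_derived"]),
            reported_size_original=int(row["n_genes_original"]),
            reported_size_final=int(row["n_genes_final"]),
            notes=f"PMID:{row['pubmed_id']}; tissue: {row['tissue']}",
        )
        for row in df.to_dict("records")
    ]
    return SignatureSet(sigs)


def registry_stats(
    registry: SignatureSet, subset: str = "all", basis: str = "original"
) -> RegistryStats:
    """Size statistics over a signature registry.

    ``subset`` keeps all signatures, the clinically derived ones, or the
    in-vitro-only ones.  ``basis`` selects the originally published gene
    counts or the post-reannotation counts; the two differ for signatures
    whose symbols were collapsed or dropped during re-annotation.  Mean and
    median are rounded half-up when reported as integers elsewhere; here the
    raw values are returned (median uses the midpoint convention for even n).
    """
    if subset == "all":
        sigs = list(registry)
    elif subset == "clinical":
        sigs = [s for s in registry if s.clinical_derived]
    elif subset == "in_vitro":
        sigs = [s for s in registry if not s.clinical_derived]
    else:
        raise DataError(f"unknown subset {subset!r}")
    if not sigs:
        raise DataError(f"subset {subset!r} is empty")
    if basis == "original":
        sizes = np.array([s.reported_size_original for s in sigs], dtype=float)
    elif basis == "final":
        sizes = np.array([s.reported_size_final for s in sigs], dtype=float)
    else:
        raise DataError(f"unknown basis {basis!r}")
    if np.any(np.isnan(sizes)):
        raise DataError("registry entries lack size metadata")
    return RegistryStats(
        n_signatures=len(sigs),
        mean_size=float(sizes.mean()),
        median_size=float(np.median(sizes)),
        min_size=int(sizes.min()),
        max_size=int(sizes.max()),
        n_clinical_derived=sum(s.clinical_derived for s in sigs),
        n_in_vitro_only=sum(not s.clinical_derived for s in sigs),
    )


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (0.5 -> 1)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# Set descriptives


def signature_overlap(sig_set: SignatureSet) -> pd.DataFrame:
    """Pairwise shared-gene counts; diagonal holds signature sizes."""
    if len(sig_set) < 2:
        raise DataError("signature_overlap needs at least two signatures")
    names = sig_set.names
    sets = [set(s.genes) for s in sig_set]
    n = len(sets)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            mat[i, j] = mat[j, i] = len(sets[i] & sets[j])
    return pd.DataFrame(mat, index=names, columns=names)


def gene_frequency(sig_set: SignatureSet) -> dict[str, int]:
    """How many signatures contain each gene (absent genes are absent)."""
    if len(sig_set) == 0:
        raise DataError("gene_frequency needs at least one signature")
    freq: dict[str, int] = {}
    for sig in sig_set:
        for g in set(sig.genes):
            freq[g] = freq.get(g, 0) + 1
    return freq
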