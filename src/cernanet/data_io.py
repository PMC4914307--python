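"""Domain containers and plain-text readers/writers for the pipeline.

All expression data travel as molecules x samples matrices of log-scale
values; interaction catalogs are two-column miRNA -> target edge lists;
disease/annotation gene sets use the GMT convention (one set per line:
name, description, members...); clinical annotations are a TSV with named
columns (sample, os_months, event, age, stage, grade, residual).

Identifiers are opaque, case-sensitive strings throughout: no gene-symbol
normalization is attempted.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MOLECULE_CLASSES = ("miRNA", "lncRNA", "mRNA")

CLINICAL_COLUMNS = ("os_months", "event", "age", "stage", "grade", "residual")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class AlignmentError(ValueError):
    """Raised when expression layers cannot be matched on enough samples."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """A molecules x samples matrix of finite, log-scale expression values.

    ``data`` is a pandas DataFrame indexed by molecule id with sample ids as
    columns; ``molecule_class`` is one of :data:`MOLECULE_CLASSES`.
    """

    data: pd.DataFrame
    molecule_class: str

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(
                f"molecule_class must be one of {MOLECULE_CLASSES}, "
                f"got {self.molecule_class!r}"
            )
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate molecule ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)  # raises on non-numeric
        if values.size and not np.isfinite(values).all():
            bad = self.data.index[~np.isfinite(values).all(axis=1)].tolist()
            raise ParseError(f"non-finite expression values in rows: {bad}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def molecule_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_molecules(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def restrict_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not present: {missing}")
        return ExpressionMatrix(self.data[list(sample_ids)].copy(), self.molecule_class)

    def restrict_molecules(self, molecule_ids: list[str]) -> "ExpressionMatrix":
        missing = [m for m in molecule_ids if m not in self.data.index]
        if missing:
            raise KeyError(
                f"{self.molecule_class} ids not present: {missing}"
            )
        return ExpressionMatrix(self.data.loc[list(molecule_ids)].copy(), self.molecule_class)

    def drop_constant_rows(self) -> tuple["ExpressionMatrix", int]:
        """Remove rows with zero variance; returns (matrix, n_dropped)."""
        sd = self.data.std(axis=1, ddof=1)
        keep = sd > 0
        n_dropped = int((~keep).sum())
        if n_dropped == 0:
            return self, 0
        return ExpressionMatrix(self.data.loc[keep].copy(), self.molecule_class), n_dropped

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.molecule_class == other.molecule_class
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.values, other.values)
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    Required: unique sample ids, overall-survival time in months (>= 0) and a
    death indicator in {0, 1}. Age (years), stage, grade and residual-disease
    status may be missing (NaN / empty field).
    """

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids in clinical table: {dups}")
        for col in ("os_months", "event"):
            if col not in df.columns:
                raise ParseError(f"clinical table missing required column {col!r}")
        for col in CLINICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        os_months = pd.to_numeric(df["os_months"])
        if os_months.isna().any() or (os_months < 0).any():
            raise ParseError("os_months must be present and non-negative")
        event = pd.to_numeric(df["event"])
        if not event.isin([0, 1]).all():
            raise ParseError("event must be 0 (censored) or 1 (death)")
        df["os_months"] = os_months.astype(float)
        df["event"] = event.astype(int)
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        self.data = df[list(CLINICAL_COLUMNS)]

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def restrict_samples(self, sample_ids: list[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in clinical table: {missing}")
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class MatchedExpressionSet:
    """Three expression layers plus clinical data over one shared sample set."""

    mirna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mrna: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        ref = self.mirna.sample_ids
        for layer in (self.lncrna, self.mrna):
            if layer.sample_ids != ref:
                raise AlignmentError(
                    "expression layers do not share an identical ordered sample set; "
                    "use align_matched_set()"
                )
        missing = [s for s in ref if s not in self.clinical.data.index]
        if missing:
            raise AlignmentError(f"samples absent from clinical table: {missing}")
        if len(ref) < 3:
            raise AlignmentError(f"need >= 3 shared samples, got {len(ref)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.mirna.sample_ids

    @property
    def n(self) -> int:
        return self.mirna.n_samples

    def restrict_samples(self, sample_ids: list[str]) -> "MatchedExpressionSet":
        return MatchedExpressionSet(
            self.mirna.restrict_samples(sample_ids),
            self.lncrna.restrict_samples(sample_ids),
            self.mrna.restrict_samples(sample_ids),
            self.clinical.restrict_samples(sample_ids),
        )


@dataclass(frozen=True)
class InteractionCatalog:
    """Validated miRNA -> target pairs for one target class (mRNA or lncRNA)."""

    pairs: frozenset  # of (mirna_id, target_id)
    target_class: str

    def __post_init__(self) -> None:
        if self.target_class not in ("mRNA", "lncRNA"):
            raise ValueError(f"target_class must be mRNA or lncRNA, got {self.target_class!r}")
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def mirnas_of(self, target_id: str) -> frozenset:
        return frozenset(m for m, t in self.pairs if t == target_id)

    def targets_of(self, mirna_id: str) -> frozenset:
        return frozenset(t for m, t in self.pairs if m == mirna_id)

    def mirna_index(self) -> dict:
        """target_id -> set of interacting miRNAs (precomputed lookup)."""
        index: dict[str, set] = {}
        for m, t in self.pairs:
            index.setdefault(t, set()).add(m)
        return index

    def merge(self, other: "InteractionCatalog") -> "InteractionCatalog":
        if other.target_class != self.target_class:
            raise ValueError("cannot merge catalogs of different target classes")
        return InteractionCatalog(self.pairs | other.pairs, self.target_class)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path, molecule_class: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column molecule id, header samples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.index.isna().any() or df.columns.isna().any():
        raise ParseError(f"{path}: malformed header or missing ids")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        for row_pos, (mol, row) in enumerate(df.iterrows(), start=2):
            if pd.to_numeric(row, errors="coerce").isna().any():
                raise ParseError(
                    f"{path}: non-numeric expression value on line {row_pos} "
                    f"(molecule {mol!r})"
                ) from exc
        raise ParseError(f"{path}: non-numeric expression value: {exc}") from exc
    if df.isna().to_numpy().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: missing expression values in rows {bad}")
    return ExpressionMatrix(df, molecule_class)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="id")


def read_clinical(path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise ParseError(f"{path}: clinical table must have a 'sample' column")
    df = df.set_index("sample")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample")


def read_interactions(path, target_class: str) -> InteractionCatalog:
    """Read a two-column (miRNA<TAB>target) edge list; duplicates collapsed."""
    path = Path(path)
    pairs = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}: line {lineno} is not a two-column miRNA-target pair: {line!r}"
                )
            pairs.add((fields[0].strip(), fields[1].strip()))
    if not pairs:
        warnings.warn(f"{path}: empty interaction file", stacklevel=2)
    return InteractionCatalog(frozenset(pairs), target_class)


def write_interactions(catalog: InteractionCatalog, path) -> None:
    with open(path, "w") as handle:
        for mirna, target in sorted(catalog.pairs):
            handle.write(f"{mirna}\t{target}\n")


def read_gene_sets(path) -> list[GeneSet]:
    """Read GMT-like gene sets: name<TAB>description<TAB>member..."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT needs name, description and >= 1 member"
                )
            sets.append(GeneSet(fields[0], frozenset(f for f in fields[2:] if f), fields[1]))
    return sets


def write_gene_sets(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w") as handle:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            handle.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# alignment


def align_matched_set(
    mirna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    clinical: ClinicalTable,
    verbose: bool = False,
) -> MatchedExpressionSet:
    """Restrict all layers to their shared samples, in lexicographic order.

    The intersection of the four sample sets is taken and sorted so that the
    result is independent of input column order; dropped samples are reported
    (stderr) when ``verbose``.
    """
    for layer in (mirna, lncrna, mrna):
        if layer.n_molecules == 0:
            raise AlignmentError("empty expression matrix")
    shared = (
        set(mirna.sample_ids)
        & set(lncrna.sample_ids)
        & set(mrna.sample_ids)
        & set(clinical.sample_ids)
    )
    if len(shared) < 3:
        raise AlignmentError(
            f"only {len(shared)} samples shared across layers; need >= 3"
        )
    order = sorted(shared)
    if verbose:
        for name, layer_samples in (
            ("miRNA", mirna.sample_ids),
            ("lncRNA", lncrna.sample_ids),
            ("mRNA", mrna.sample_ids),
            ("clinical", clinical.sample_ids),
        ):
            dropped = sorted(set(layer_samples) - shared)
            if dropped:
                print(f"align: dropped {len(dropped)} {name} samples: {dropped}", file=sys.stderr)
    return MatchedExpressionSet(
        mirna.restrict_samples(order),
        lncrna.restrict_samples(order),
        mrna.restrict_samples(order),
        clinical.restrict_samples(order),
    )
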