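"""Flat-file input/output and the annotated DNA-repair gene catalog.

All tabular data travel as UTF-8, tab-separated text with LF line endings
and the literal string ``NA`` for missing values — the dialect of
cBioPortal's gene-by-sample flat-file exports.  Matrices are stored with
genes as rows; samples-as-rows input is rejected rather than auto-detected,
because silent transposition is the classic failure mode of this layout.

Every result writer also emits a small JSON "run summary" sidecar recording
the parameters, seed and counts that produced the file, so that any number
in a TSV can be traced back to the knobs that generated it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PATHWAY_VOCABULARY",
    "GeneCatalog",
    "OmicsMatrix",
    "MutationTable",
    "Cohort",
    "read_matrix",
    "write_matrix",
    "read_catalog",
    "default_catalog",
    "read_mutations",
    "write_mutations",
    "write_results",
    "write_run_summary",
]

#: Closed vocabulary of DNA-repair mechanistic group labels.
PATHWAY_VOCABULARY = frozenset(
    {
        "homologous recombination",
        "mismatch excision repair",
        "nucleotide excision repair",
        "base excision repair",
        "fanconi anemia",
        "ubiquitination and modification",
        "other",
    }
)

MISSING = "NA"


class FormatError(ValueError):
    """A flat file violates the expected dialect."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCatalog:
    """DNA-repair gene symbols annotated with repair-pathway groups.

    ``groups`` maps each gene symbol to a frozenset of mechanistic group
    labels drawn from :data:`PATHWAY_VOCABULARY`; a gene may sit in more
    than one group (e.g. BRCA2 is both a homologous-recombination and a
    Fanconi-anemia gene).
    """

    groups: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for gene, labels in self.groups.items():
            if not gene:
                raise ValueError("empty gene symbol in catalog")
            if not labels:
                raise ValueError(f"gene {gene!r} has no pathway group")
            unknown = set(labels) - PATHWAY_VOCABULARY
            if unknown:
                raise ValueError(
                    f"gene {gene!r}: unknown pathway label(s) {sorted(unknown)}; "
                    f"allowed: {sorted(PATHWAY_VOCABULARY)}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.groups.keys())

    def __len__(self) -> int:
        return len(self.groups)

    def __contains__(self, gene: str) -> bool:
        return gene in self.groups

    def genes_in_group(self, label: str) -> list[str]:
        if label not in PATHWAY_VOCABULARY:
            raise ValueError(f"unknown pathway label {label!r}")
        return [g for g, labs in self.groups.items() if label in labs]

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for labs in self.groups.values():
            for lab in sorted(labs):
                seen.setdefault(lab, None)
        return list(seen)

    def subset(self, genes: Iterable[str]) -> "GeneCatalog":
        genes = [g for g in genes if g in self.groups]
        return GeneCatalog({g: self.groups[g] for g in genes})

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene\tpathway_group\n")
            for gene, labels in self.groups.items():
                fh.write(f"{gene}\t{';'.join(sorted(labels))}\n")


@dataclass(frozen=True)
class OmicsMatrix:
    """A gene × sample matrix of methylation beta values or expression.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample IDs
    as columns.  Methylation values lie in [0, 1]; expression values are
    non-negative (RSEM-style).  NaN marks missing entries; downstream
    pairwise operations drop the affected sample for that gene only.
    """

    kind: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("methylation", "expression"):
            raise ValueError(f"kind must be methylation|expression, got {self.kind!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if self.kind == "methylation":
            bad = (arr < 0) | (arr > 1)
        else:
            bad = arr < 0
        bad &= ~np.isnan(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"{self.kind} value {arr[i, j]!r} out of range at "
                f"gene {self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def row(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in {self.kind} matrix")
        return self.values.loc[gene]


@dataclass(frozen=True)
class MutationTable:
    """Long-format somatic mutation records: (sample, gene, variant_class)."""

    records: pd.DataFrame

    COLUMNS = ("sample", "gene", "variant_class")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"mutation table missing column(s) {sorted(missing)}")

    @property
    def samples(self) -> set[str]:
        return set(self.records["sample"])

    def mutated_genes(self, sample: str) -> set[str]:
        sub = self.records[self.records["sample"] == sample]
        return set(sub["gene"])


@dataclass
class Cohort:
    """One cancer type's bundle of methylation, expression and mutations.

    Paired analyses use the intersection of the methylation and expression
    sample universes, which must be non-empty.
    """

    name: str
    methylation: OmicsMatrix
    expression: OmicsMatrix
    mutations: MutationTable | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.methylation.kind != "methylation":
            raise ValueError("methylation matrix has wrong kind")
        if self.expression.kind != "expression":
            raise ValueError("expression matrix has wrong kind")
        if not self.shared_samples():
            raise ValueError(
                f"cohort {self.name!r}: methylation and expression share no samples"
            )

    def shared_samples(self) -> list[str]:
        expr = set(self.expression.samples)
        return [s for s in self.methylation.samples if s in expr]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} ID {x!r}")
        if x == "" or x is None:
            raise FormatError(f"empty {what} ID")
        seen.add(str(x))


def read_matrix(path: str | Path, kind: str) -> OmicsMatrix:
    """Read a gene × sample TSV into an :class:`OmicsMatrix`.

    The header row is ``gene<TAB>sample1<TAB>…``; cells are numeric or the
    literal ``NA``.  Row and column order are preserved.  Any duplicate ID,
    non-numeric cell, or methylation value outside [0, 1] is a hard error
    naming the offending coordinates — rows are never silently dropped.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample")  # pandas would silently mangle dupes
    raw = pd.read_csv(
        path, sep="\t", dtype=str, index_col=0, keep_default_na=False, na_values=[]
    )
    _check_unique(raw.index, "gene")
    _check_unique(raw.columns, "sample")
    values = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            cell = arr[i, j]
            if cell == MISSING:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path.name}: non-numeric cell {cell!r} at gene "
                    f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
                ) from None
    frame = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))
    try:
        return OmicsMatrix(kind=kind, values=frame)
    except ValueError as exc:
        raise FormatError(f"{path.name}: {exc}") from None


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    _write_frame(matrix.values, Path(path), index_label="gene")


def read_catalog(path: str | Path) -> GeneCatalog:
    """Read a two-column catalog TSV (gene, semicolon-separated groups)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    if list(frame.columns[:2]) != ["gene", "pathway_group"]:
        raise FormatError(
            f"{path.name}: expected header 'gene<TAB>pathway_group', "
            f"got {list(frame.columns)!r}"
        )
    groups: dict[str, frozenset] = {}
    for _, row in frame.iterrows():
        gene = row["gene"]
        if gene in groups:
            raise FormatError(f"{path.name}: duplicate gene {gene!r}")
        labels = frozenset(x.strip() for x in str(row["pathway_group"]).split(";") if x.strip())
        groups[gene] = labels
    try:
        return GeneCatalog(groups)
    except ValueError as exc:
        raise FormatError(f"{path.name}: {exc}") from None


def default_catalog() -> GeneCatalog:
    """The bundled 179-gene DNA-repair catalog.

    Built from the literature-derived classification of human DNA-repair
    genes into mechanistic groups; it is a replaceable input, not a fixed
    constant of the method.  The homologous-recombination group holds 19
    genes, including RAD51B, XRCC3, RAD54B, BRCA1, SHFM1 and GEN1.
    """
    ref = resources.files("methscreen.data").joinpath("dna_repair_catalog.tsv")
    with resources.as_file(ref) as path:
        return read_catalog(path)


def read_mutations(path: str | Path) -> MutationTable:
    """Read a long-format mutation TSV with header sample/gene/variant_class."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    if list(frame.columns[:3]) != list(MutationTable.COLUMNS):
        raise FormatError(
            f"{path.name}: expected header 'sample<TAB>gene<TAB>variant_class', "
            f"got {list(frame.columns)!r}"
        )
    return MutationTable(records=frame)


def write_mutations(table: MutationTable, path: str | Path) -> None:
    _write_frame(table.records, Path(path), index=False)


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------


def _write_frame(frame: pd.DataFrame, path: Path, index_label: str | None = None,
                 index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(
        path,
        sep="\t",
        na_rep=MISSING,
        index=index,
        index_label=index_label,
        lineterminator="\n",
    )


def write_run_summary(path: str | Path, summary: Mapping) -> None:
    """Write a JSON sidecar with sorted keys (byte-stable across reruns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        return [_jsonable(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Path):
        return str(obj)
    return obj


def read_cohort(directory: str | Path, name: str | None = None) -> Cohort:
    """Read a cohort directory written by the simulator or assembled by hand.

    Expects ``methylation.tsv`` and ``expression.tsv``; ``mutations.tsv``
    and ``metadata.tsv`` are optional.
    """
    directory = Path(directory)
    meth = read_matrix(directory / "methylation.tsv", "methylation")
    expr = read_matrix(directory / "expression.tsv", "expression")
    mutations = None
    if (directory / "mutations.tsv").exists():
        mutations = read_mutations(directory / "mutations.tsv")
    metadata = None
    if (directory / "metadata.tsv").exists():
        metadata = pd.read_csv(directory / "metadata.tsv", sep="\t",
                               index_col="sample", na_values=[MISSING],
                               keep_default_na=False)
    return Cohort(name=name or directory.name, methylation=meth,
                  expression=expr, mutations=mutations, metadata=metadata)


def write_results(obj, path: str | Path) -> None:
    """Write a screen / enrichment / signature result as TSV + JSON sidecar.

    The TSV holds the tabular payload with a stable column order; the
    ``<stem>.summary.json`` sidecar records parameters and counts.
    Re-reading the TSV reproduces the numeric fields bit-exactly (floats
    are serialised with full repr precision).
    """
    path = Path(path)
    frame = obj.to_frame()
    _write_frame(frame, path, index=False)
    write_run_summary(path.with_suffix(".summary.json"), obj.summary())
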