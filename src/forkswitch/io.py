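"""Reading and writing the tabular formats the pipeline touches.

Expression matrices are plain TSV/CSV with genes in rows (first column gene
identifiers, header row sample identifiers); an orientation flag transposes.
Gene sets use the GMT format (``name <TAB> description <TAB> member...``).
Values are assumed already log-transformed and normalized: this package
performs no preprocessing of its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("forkswitch")

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_results_table",
]


class FormatError(ValueError):
    """An input file violates the expected format."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for ident in ids:
        if ident in seen:
            raise FormatError(f"duplicate {kind} identifier: {ident!r}")
        seen.add(ident)


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log-scale expression values.

    Rows correspond to ``gene_ids`` and columns to ``sample_ids``, both of
    which must be unique.  All values must be finite.  Internally everything
    is indexed by identifier, never by position, and the stored order is the
    file order: reading never reorders genes or samples.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n_g, n_s = self.values.shape
        if n_g != len(self.gene_ids) or n_s != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if n_g == 0 or n_s == 0:
            raise FormatError("empty expression matrix")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    # -- identifier lookup ------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_rows(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices for ``genes``; raises ``KeyError`` naming any absent id."""
        try:
            return np.asarray([self._gene_index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene not in matrix: {exc.args[0]!r}") from None

    def sample_cols(self, samples: Iterable[str]) -> np.ndarray:
        try:
            return np.asarray([self._sample_index[s] for s in samples], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample not in matrix: {exc.args[0]!r}") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def submatrix(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Dense sub-array for the given identifiers (all, when ``None``)."""
        out = self.values
        if genes is not None:
            out = out[self.gene_rows(genes), :]
        if samples is not None:
            out = out[:, self.sample_cols(samples)]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways, curated inventories) with optional descriptions."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            deduped = list(dict.fromkeys(members))
            if not deduped:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict_to(self, genes: Iterable[str], min_size: int = 1) -> "GeneSetCollection":
        """Drop members absent from ``genes`` and sets that fall below ``min_size``.

        Unmapped members are discarded silently with a logged count; gene-set
        catalogues never fully overlap a given platform's gene universe.
        """
        universe = set(genes)
        kept: dict[str, list[str]] = {}
        dropped_members = 0
        for name, members in self.sets.items():
            mapped = [g for g in members if g in universe]
            dropped_members += len(members) - len(mapped)
            if len(mapped) >= min_size:
                kept[name] = mapped
        if dropped_members:
            logger.info(
                "dropped %d gene-set members absent from the matrix", dropped_members
            )
        return GeneSetCollection(
            kept, {n: self.descriptions.get(n, "") for n in kept}
        )


# -- file readers ---------------------------------------------------------


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    samples_in_rows: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The first column holds gene identifiers and the header row sample
    identifiers; with ``samples_in_rows`` the roles are swapped and the
    matrix is transposed after reading.  Rows containing any non-numeric
    entry are rejected with a logged count.  Duplicate identifiers raise
    :class:`FormatError` naming the duplicate.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty expression matrix in {path}")
    # pandas silently mangles duplicate column names, so take them from the
    # raw header (with or without a corner label).
    if len(header) == df.shape[1] + 1:
        col_ids = header[1:]
    elif len(header) == df.shape[1]:
        col_ids = header
    else:
        raise FormatError(f"header of {path} does not match its data columns")
    _check_unique(col_ids, "sample" if not samples_in_rows else "gene")
    df.columns = col_ids
    _check_unique(list(df.index), "gene" if not samples_in_rows else "sample")
    if samples_in_rows:
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    vals = numeric.to_numpy(dtype=float)
    bad = ~np.isfinite(vals).all(axis=1)
    if bad.any():
        logger.warning(
            "rejected %d rows with non-numeric entries (e.g. %r)",
            int(bad.sum()),
            str(numeric.index[bad][0]),
        )
        numeric = numeric.loc[~bad]
    if numeric.shape[0] == 0:
        raise FormatError(f"no numeric rows left in {path}")
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    delimiter: str | None = None,
    samples_in_rows: bool = False,
) -> None:
    """Write a matrix back to disk in the same layout ``read_expression_matrix`` expects."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = matrix.to_dataframe()
    if samples_in_rows:
        df = df.T
    df.to_csv(path, sep=sep, float_format="%.10g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, tab-separated.

    Repeated members within a line are kept once (first occurrence); a line
    with fewer than three fields is a format error reported with its line
    number.  An empty file yields an empty collection with a warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one member, got {len(fields)} fields"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = [g for g in fields[2:] if g]
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = description
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, descriptions)


def write_results_table(records, path: str | Path) -> None:
    """Write tabular results as TSV with a header and 6-significant-digit floats.

    ``records`` may be a DataFrame or a list of dicts sharing one schema.
    An empty DataFrame produces a header-only file.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
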