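"""Reading and writing gene expression matrices (GEMs) and sample annotations.

A GEM is a tab-delimited text file with a header row of sample identifiers
and one gene per row (gene id in the first column). Expression values are
assumed to be already preprocessed (log-transformed, normalised); batch
correction, low-count filtering and sample-outlier removal are deliberately
out of scope and expected to have been done upstream.

Missing expression is a first-class state: selected tokens (by default
``NA``, ``nan`` and the empty string) are parsed into missing cells and are
re-written as ``NA``. Internally missingness is represented as ``numpy.nan``
inside a float matrix, but the public contract is "a cell is either a real
value or missing" — no sentinel number in the value domain.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MISSING_TOKENS = frozenset({"NA", "nan", ""})

__all__ = [
    "GEM",
    "AnnotationTable",
    "GEMParseError",
    "load_gem",
    "write_gem",
    "load_annotations",
    "write_annotations",
    "DEFAULT_MISSING_TOKENS",
]


class GEMParseError(ValueError):
    """Raised for malformed GEM or annotation files."""


@dataclass
class GEM:
    """A genes x samples expression matrix with explicit per-cell missingness.

    Attributes
    ----------
    gene_ids : list of str
        Ordered, unique gene identifiers (row labels).
    sample_ids : list of str
        Ordered, unique sample identifiers (column labels).
    values : ndarray of float, shape (n_genes, n_samples)
        Expression values on log scale; missing cells are ``nan``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise GEMParseError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GEMParseError("duplicate sample ids")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across samples (nan = missing)."""
        return self.values[self._gene_index[gene_id]]

    def missing_mask(self, gene_id: str) -> np.ndarray:
        """Boolean missingness indicator for one gene across samples."""
        return np.isnan(self.row(gene_id))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GEM):
            return NotImplemented
        if self.gene_ids != other.gene_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values, other.values
        return bool(np.array_equal(np.isnan(a), np.isnan(b)) and np.array_equal(
            np.nan_to_num(a), np.nan_to_num(b)
        ))


@dataclass
class AnnotationTable:
    """Per-sample experimental variables aligned to a GEM's sample order.

    A variable is either categorical (string labels) or quantitative (real
    values, possibly missing); never both.
    """

    sample_ids: list[str]
    categorical: dict[str, np.ndarray] = field(default_factory=dict)
    quantitative: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GEMParseError("duplicate sample ids in annotations")
        overlap = set(self.categorical) & set(self.quantitative)
        if overlap:
            raise GEMParseError(
                f"variables declared both categorical and quantitative: {sorted(overlap)}"
            )
        n = len(self.sample_ids)
        for name, arr in self.categorical.items():
            arr = np.asarray(arr, dtype=object)
            if arr.shape != (n,):
                raise GEMParseError(f"categorical variable {name!r} has wrong length")
            self.categorical[name] = arr
        for name, arr in self.quantitative.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise GEMParseError(f"quantitative variable {name!r} has wrong length")
            self.quantitative[name] = arr

    @property
    def variables(self) -> list[str]:
        return list(self.categorical) + list(self.quantitative)


def _validate_rectangular(text: str, n_fields: int, path: str) -> None:
    # pandas pads short rows with NaN silently; the file contract requires an
    # error naming the offending line, so field counts are checked up front.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if lineno == 1 or not line.strip():
            continue
        found = line.count("\t") + 1
        if found != n_fields:
            raise GEMParseError(
                f"{path}: line {lineno} has {found} fields, expected {n_fields}"
            )


def load_gem(path, missing_tokens=DEFAULT_MISSING_TOKENS) -> GEM:
    """Load a tab-delimited GEM (header = sample ids, first column = gene id).

    Cells equal to one of ``missing_tokens`` become missing. Ragged rows and
    duplicate identifiers raise :class:`GEMParseError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise GEMParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    _validate_rectangular(text, len(header), str(path))
    df = pd.read_csv(
        io.StringIO(text),
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    values = df.to_numpy(dtype=object)
    out = np.empty(values.shape, dtype=float)
    tokens = set(missing_tokens)
    for idx, cell in np.ndenumerate(values):
        s = str(cell).strip()
        if s in tokens:
            out[idx] = np.nan
        else:
            try:
                out[idx] = float(s)
            except ValueError as exc:
                raise GEMParseError(
                    f"{path}: unparseable expression value {s!r} "
                    f"for gene {df.index[idx[0]]!r}"
                ) from exc
    return GEM(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=out,
    )


def write_gem(gem: GEM, path, missing_token: str = "NA") -> None:
    """Write a GEM as tab-delimited text; missing cells become ``missing_token``.

    Values are written with shortest round-trip float formatting, so a
    write/read cycle reproduces the matrix exactly.
    """
    gem.to_frame().to_csv(
        path, sep="\t", na_rep=missing_token, index_label="gene_id",
    )


def load_annotations(path, declared_types: dict[str, str] | None = None,
                     gem: GEM | None = None) -> AnnotationTable:
    """Load a per-sample annotation table (first column = sample id).

    Parameters
    ----------
    declared_types
        Map of variable name to ``"categorical"`` or ``"quantitative"``.
        Undeclared columns default to categorical.
    gem
        Companion GEM. When given, every GEM sample must appear exactly once
        and rows are reordered to the GEM's (canonical) sample order.
    """
    declared_types = dict(declared_types or {})
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise GEMParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    _validate_rectangular(text, len(header), str(path))
    df = pd.read_csv(
        io.StringIO(text), sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise GEMParseError(f"{path}: duplicate sample ids")
    unknown = set(declared_types) - set(df.columns)
    if unknown:
        raise GEMParseError(f"{path}: declared variables not in file: {sorted(unknown)}")
    bad_kinds = {k: v for k, v in declared_types.items()
                 if v not in ("categorical", "quantitative")}
    if bad_kinds:
        raise GEMParseError(f"invalid declared kinds: {bad_kinds}")
    if gem is not None:
        extra = set(df.index) - set(gem.sample_ids)
        if extra:
            raise GEMParseError(
                f"{path}: samples not present in GEM: {sorted(extra)[:5]}"
            )
        missing = set(gem.sample_ids) - set(df.index)
        if missing:
            raise GEMParseError(
                f"{path}: GEM samples missing from annotations: {sorted(missing)[:5]}"
            )
        df = df.loc[gem.sample_ids]

    categorical: dict[str, np.ndarray] = {}
    quantitative: dict[str, np.ndarray] = {}
    for col in df.columns:
        kind = declared_types.get(col, "categorical")
        raw = df[col].to_numpy(dtype=object)
        if kind == "quantitative":
            vals = np.empty(len(raw), dtype=float)
            for i, cell in enumerate(raw):
                s = str(cell).strip()
                if s in DEFAULT_MISSING_TOKENS:
                    vals[i] = np.nan
                    continue
                try:
                    vals[i] = float(s)
                except ValueError as exc:
                    raise GEMParseError(
                        f"{path}: non-numeric value {s!r} in quantitative "
                        f"variable {col!r} (sample {df.index[i]!r})"
                    ) from exc
            quantitative[col] = vals
        else:
            categorical[col] = np.array([str(c) for c in raw], dtype=object)
    return AnnotationTable(
        sample_ids=[str(s) for s in df.index],
        categorical=categorical,
        quantitative=quantitative,
    )


def write_annotations(table: AnnotationTable, path) -> None:
    """Write an annotation table as tab-delimited text."""
    data: dict[str, object] = {}
    for name, arr in table.categorical.items():
        data[name] = arr
    for name, arr in table.quantitative.items():
        data[name] = arr
    df = pd.DataFrame(data, index=table.sample_ids)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")
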