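"""Input/output and core data containers.

The package works on three objects throughout: an expression matrix in a
canonical genes x samples orientation, a clinical survival table, and a
gene-set collection assembled from pathway lists (e.g. the pyroptosis /
apoptosis / necroptosis programmed-cell-death lists).

Loading is strict by design: duplicated identifiers, non-numeric cells and
missing values are errors, never silent fills, because each of those is a
classic source of quietly corrupted downstream results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class DataValidationError(ValueError):
    """Raised when an input file violates the container invariants."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers (rows). Symbols are preserved verbatim and
        matched case-sensitively everywhere in the package.
    sample_ids : sequence of str
        Unique sample identifiers (columns).
    values : ndarray, shape (n_genes, n_samples)
        Finite real values (e.g. log-normalised counts).
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dups = _duplicates(ids)
            if dups:
                raise DataValidationError(f"duplicate {name} identifiers: {sorted(dups)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order preserved); missing genes are an error."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not present in matrix: {missing}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])

    def samples_matrix(self) -> np.ndarray:
        """Samples x genes view used by the clustering and learning stages."""
        return self.values.T.copy()


@dataclass
class GeneSetCollection:
    """Named gene sets plus per-gene provenance (which pathways name it)."""

    sets: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.provenance:
            prov: dict = {}
            for name, genes in self.sets.items():
                for g in genes:
                    prov.setdefault(g, set()).add(name)
            self.provenance = prov
        for g, paths in self.provenance.items():
            if not any(g in self.sets.get(p, ()) for p in paths):
                raise DataValidationError(f"provenance of {g!r} names no pathway containing it")

    def all_genes(self) -> list:
        """Union of all member genes, lexicographically sorted."""
        out = set()
        for genes in self.sets.values():
            out.update(genes)
        return sorted(out)


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time on a single unit (e.g. days) and event flag."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        dups = _duplicates(self.sample_ids)
        if dups:
            raise DataValidationError(f"duplicate sample identifiers: {sorted(dups)}")
        if len(self.sample_ids) != self.time.size or self.time.size != self.event.size:
            raise DataValidationError("sample_ids, time and event lengths differ")
        bad_t = np.where(~(self.time > 0) | ~np.isfinite(self.time))[0]
        if bad_t.size:
            raise DataValidationError(
                f"non-positive follow-up time for sample {self.sample_ids[bad_t[0]]!r}"
            )
        if not np.all(np.isin(self.event, [0, 1])):
            bad = int(np.where(~np.isin(self.event, [0, 1]))[0][0])
            raise DataValidationError(
                f"event must be 0 or 1; sample {self.sample_ids[bad]!r} has {self.event[bad]!r}"
            )
        self.event = self.event.astype(int)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not present in survival table: {missing}")
        rows = [index[s] for s in samples]
        return SurvivalTable(list(samples), self.time[rows], self.event[rows])


def _duplicates(ids: Sequence[str]) -> set:
    seen, dups = set(), set()
    for x in ids:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# expression matrix load / save
# ---------------------------------------------------------------------------


def load_expression(path, orientation: str = "genes_by_samples") -> ExpressionMatrix:
    """Load an expression matrix from delimited text (TSV/CSV).

    The file must carry a header row and an identifier first column. The
    on-disk orientation is declared explicitly via ``orientation`` — it is
    never guessed from shape — and the returned matrix is always canonical
    genes x samples.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".mtx":
        return _load_expression_mtx(path, orientation)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    row_dups = _duplicates(list(df.index.astype(str)))
    col_dups = _duplicates(list(df.columns.astype(str)))
    if row_dups or col_dups:
        raise DataValidationError(
            f"duplicate identifiers in {path.name}: {sorted(row_dups | col_dups)}"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            i = int(np.where(coerced.isna())[0][0])
            raise DataValidationError(
                f"non-numeric cell at row {df.index[i]!r}, column {col!r}: {df[col].iloc[i]!r}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise DataValidationError(
            f"missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "samples_by_genes":
        return ExpressionMatrix(list(df.columns), list(df.index), values.T)
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def _load_expression_mtx(path: Path, orientation: str) -> ExpressionMatrix:
    """MatrixMarket triplet plus one-column sidecar name files.

    Row and column identifiers are read from ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` next to the ``.mtx`` file, one name per line.
    """
    from scipy.io import mmread
    from scipy.sparse import issparse

    rows_path = path.with_suffix(".rows.txt")
    cols_path = path.with_suffix(".cols.txt")
    for side in (rows_path, cols_path):
        if not side.exists():
            raise FileNotFoundError(f"missing MTX sidecar name file {side}")
    values = mmread(path)
    if issparse(values):
        values = values.toarray()
    values = np.asarray(values, dtype=float)
    row_names = [l.strip() for l in rows_path.read_text().splitlines() if l.strip()]
    col_names = [l.strip() for l in cols_path.read_text().splitlines() if l.strip()]
    if values.shape != (len(row_names), len(col_names)):
        raise DataValidationError(
            f"MTX shape {values.shape} does not match sidecars "
            f"({len(row_names)} rows, {len(col_names)} cols)"
        )
    if np.isnan(values).any():
        raise DataValidationError("missing value in MTX matrix")
    if orientation == "samples_by_genes":
        return ExpressionMatrix(col_names, row_names, values.T)
    return ExpressionMatrix(row_names, col_names, values)


def save_expression(matrix: ExpressionMatrix, path) -> None:
    """Write genes x samples TSV/CSV (header = sample ids, first column = gene ids)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format="%.12g")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def load_gmt(path) -> dict:
    """Parse a GMT file into ``{set_name: [genes...]}`` (description dropped)."""
    sets: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataValidationError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
        name = fields[0]
        if name in sets:
            raise DataValidationError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def save_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def build_composite_geneset(
    lists: Mapping[str, Sequence[str]], overlap_mode: str = "keep_annotated"
) -> GeneSetCollection:
    """Assemble a composite set from pathway lists with explicit overlap handling.

    ``drop_shared`` removes every symbol named by two or more pathways,
    yielding a strictly non-overlapping signature; ``keep_annotated`` (default)
    keeps the full union and records multi-pathway membership in the
    provenance map. Output gene order is lexicographic, hence deterministic.
    """
    if overlap_mode not in ("drop_shared", "keep_annotated"):
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    if not lists or all(len(v) == 0 for v in lists.values()):
        raise DataValidationError("all pathway lists are empty")
    names = list(lists)
    if len(set(names)) != len(names):
        raise DataValidationError("pathway names must be unique")

    membership: dict = {}
    for name, genes in lists.items():
        for g in genes:
            membership.setdefault(str(g), set()).add(name)

    if overlap_mode == "drop_shared":
        kept = {g for g, paths in membership.items() if len(paths) == 1}
    else:
        kept = set(membership)

    sets = {
        name: sorted(g for g in {str(x) for x in genes} if g in kept)
        for name, genes in lists.items()
    }
    provenance = {g: set(paths) for g, paths in membership.items() if g in kept}
    return GeneSetCollection(sets=sets, provenance=provenance)


# ---------------------------------------------------------------------------
# survival + labels
# ---------------------------------------------------------------------------

_SURV_COLUMNS = ("sample_id", "time", "event")


def load_survival(path) -> SurvivalTable:
    """Load a TSV with columns sample_id, time, event and validate it."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SURV_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"survival table missing column(s): {missing}")
    return SurvivalTable(
        list(df["sample_id"].astype(str)),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(),
    )


def save_survival(table: SurvivalTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_labels(path) -> pd.DataFrame:
    """Load a labels TSV with at least sample_id and label columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise DataValidationError(f"labels table missing column {col!r}")
    return df


def save_labels(sample_ids: Sequence[str], labels: Sequence[int], path, **extra_columns) -> None:
    df = pd.DataFrame({"sample_id": list(sample_ids), "label": list(labels)})
    for name, col in extra_columns.items():
        df[name] = list(col)
    df.to_csv(path, sep="\t", index=False)
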