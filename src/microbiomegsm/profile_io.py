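"""Reading and assembling labeled species-level relative-abundance matrices.

Consumes MetaPhlAn-style merged abundance tables (rows are pipe-joined,
rank-prefixed clade strings such as ``k__Bacteria|...|s__alistipes_shahii``;
columns are samples), keeps only species-level rows, attaches binary class
labels by sample id, optionally filters samples by sequencing depth, and
renormalizes each sample's species fractions to sum to one (compositional
closure).

Values may arrive as fractions in [0, 1] or as percentages; closure is
scale-invariant, so both dialects normalize to the same matrix without any
dialect guessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger("microbiomegsm")

#: Rank prefixes in descending taxonomic order, as used by MetaPhlAn clade strings.
RANK_PREFIXES: tuple[str, ...] = ("k", "p", "c", "o", "f", "g", "s", "t")
_PREFIX_DEPTH = {p: i for i, p in enumerate(RANK_PREFIXES)}

#: Row-sum tolerance for a normalized compositional matrix.
CLOSURE_TOL = 1e-6


@dataclass
class AbundanceMatrix:
    """Samples x species relative abundances with aligned binary labels.

    ``values[i, j]`` is the relative abundance of ``species_ids[j]`` in
    ``sample_ids[i]``; after :func:`normalize_abundances` every row sums to 1.
    ``labels`` holds 1 for the disease class and 0 for the healthy class, or is
    ``None`` while the matrix is still being assembled.
    """

    sample_ids: list[str]
    species_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.species_ids = [str(s) for s in self.species_ids]
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.species_ids):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.species_ids)} species"
            )
        if len(set(self.sample_ids)) != n:
            raise InputError("duplicate sample ids")
        if len(set(self.species_ids)) != p:
            raise InputError("duplicate species ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise InputError("labels are not aligned to samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.species_ids)

    def select_samples(self, indices: Sequence[int]) -> "AbundanceMatrix":
        idx = np.asarray(indices, dtype=int)
        return AbundanceMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            species_ids=list(self.species_ids),
            values=self.values[idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    def species_values(self, species: Sequence[str]) -> np.ndarray:
        """Column-slice the value matrix for the given species, in the given order."""
        col = {s: j for j, s in enumerate(self.species_ids)}
        missing = [s for s in species if s not in col]
        if missing:
            raise InputError(f"unknown species: {missing[:5]}")
        return self.values[:, [col[s] for s in species]]


def deepest_prefix(clade: str) -> str:
    """Return the rank prefix letter of the deepest segment of a clade string."""
    last = clade.strip().split("|")[-1]
    if len(last) >= 3 and last[1:3] == "__" and last[0] in _PREFIX_DEPTH:
        return last[0]
    raise InputError(f"malformed clade segment {last!r} in {clade!r}")


def parse_merged_table(source) -> pd.DataFrame:
    """Parse a merged abundance table into a clades x samples numeric DataFrame.

    ``source`` is a path or an open text stream. The first column holds clade
    strings, the remaining columns one numeric column per sample; lines starting
    with ``#`` are comments. Values are returned exactly as written (percent
    tables are not rescaled here). Empty cells and NA markers become NaN and are
    resolved later by :func:`attach_labels_and_clean`.
    """
    try:
        raw = pd.read_csv(
            source, sep="\t", comment="#", header=0, index_col=0, dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise InputError("no data rows") from None
    if raw.shape[0] == 0:
        raise InputError("no data rows")
    if raw.shape[1] == 0:
        raise InputError("no sample columns")
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = [str(c).strip() for c in raw.columns]
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise InputError(f"duplicate clade string {dup[0]!r}")

    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        cells = raw[col].str.strip()
        numeric = pd.to_numeric(cells.replace({"": None, "NA": None, "NaN": None, "nan": None}),
                                errors="coerce")
        bad = numeric.isna() & cells.notna() & ~cells.str.lower().isin(["", "na", "nan"])
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise InputError(f"non-numeric value {raw.at[row, col]!r} at row {row!r}, column {col!r}")
        out[col] = numeric.to_numpy(dtype=float)
    return out


def select_species_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows whose deepest clade prefix is species-level (``s__``).

    Higher-rank aggregate rows (kingdom..genus) and strain rows (``t__``) are
    dropped; input row order is preserved.
    """
    keep = [clade for clade in table.index if deepest_prefix(clade) == "s"]
    if not keep:
        raise InputError("no species-level (s__) rows in table")
    return table.loc[keep]


def normalize_abundances(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Closure-normalize each sample so its species fractions sum to 1.

    Division by the per-sample total makes the operation scale-invariant: a
    percent-dialect table and its fraction-dialect twin normalize identically.
    """
    values = matrix.values
    if np.any(values < 0):
        raise InputError("negative abundance values")
    sums = values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(zero)]
        raise InputError(f"samples with all-zero abundances: {bad}")
    return replace(matrix, values=values / sums[:, None])


def filter_samples_by_reads(
    matrix: AbundanceMatrix,
    read_counts: Mapping[str, int] | None,
    min_reads: int = 1_000_000,
    strict: bool = True,
) -> AbundanceMatrix:
    """Drop samples with fewer than ``min_reads`` total sequencing reads.

    Merged abundance tables do not carry read counts, so ``read_counts`` is
    optional; when absent the filter is a logged no-op. In strict mode a sample
    missing from ``read_counts`` is an error; in lenient mode it is kept with a
    warning.
    """
    if read_counts is None:
        logger.warning("no read-count table supplied; read-depth filter skipped")
        return matrix
    keep: list[int] = []
    for i, sid in enumerate(matrix.sample_ids):
        if sid not in read_counts:
            if strict:
                raise InputError(f"sample {sid!r} missing from read-count table")
            logger.warning("sample %s missing from read-count table; kept", sid)
            keep.append(i)
            continue
        total = int(read_counts[sid])
        if total < 0:
            raise InputError(f"negative read count for sample {sid!r}")
        if total >= min_reads:
            keep.append(i)
        else:
            logger.info("sample %s removed: %d reads < %d", sid, total, min_reads)
    if len(keep) == matrix.n_samples:
        return matrix
    return matrix.select_samples(keep)


def attach_labels_and_clean(
    values: pd.DataFrame,
    label_table: Mapping[str, object] | pd.Series,
    positive_label: str | None = None,
) -> AbundanceMatrix:
    """Attach binary labels by sample id and drop unusable samples.

    ``values`` is samples x species. Samples without a label and samples with
    any missing abundance cell are removed (logged with counts). Non-numeric
    label values are mapped via ``positive_label`` (that value becomes 1,
    everything else 0). Errors if fewer than two classes survive cleaning.
    """
    labels = pd.Series(dict(label_table) if not isinstance(label_table, pd.Series) else label_table)
    labels.index = labels.index.astype(str).str.strip()

    sample_ids = [str(s).strip() for s in values.index]
    unlabeled = [s for s in sample_ids if s not in labels.index]
    if unlabeled:
        logger.info("dropping %d unlabeled samples: %s%s", len(unlabeled), unlabeled[:5],
                    "..." if len(unlabeled) > 5 else "")
    kept = [s for s in sample_ids if s in labels.index]

    sub = values.loc[[s for s in values.index if str(s).strip() in set(kept)]]
    incomplete = sub.isna().any(axis=1)
    if incomplete.any():
        dropped = [str(s).strip() for s in sub.index[incomplete]]
        logger.info("dropping %d samples with missing abundance values: %s%s",
                    len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
        sub = sub.loc[~incomplete]
    if sub.shape[0] == 0:
        raise InputError("no samples left after cleaning")

    kept_ids = [str(s).strip() for s in sub.index]
    y = np.array([_encode_label(labels.loc[s], positive_label) for s in kept_ids], dtype=int)
    if len(np.unique(y)) < 2:
        raise InputError("only one class present after cleaning; need both disease and control")
    return AbundanceMatrix(
        sample_ids=kept_ids,
        species_ids=[str(c) for c in sub.columns],
        values=sub.to_numpy(dtype=float),
        labels=y,
    )


def _encode_label(value, positive_label: str | None) -> int:
    if isinstance(value, (int, np.integer)) or (
        isinstance(value, (float, np.floating)) and float(value).is_integer()
    ):
        iv = int(value)
        if iv in (0, 1):
            return iv
        raise InputError(f"numeric label {value!r} is not 0/1")
    text = str(value).strip()
    if text in ("0", "1"):
        return int(text)
    if positive_label is None:
        raise InputError(
            f"non-binary label {value!r}; supply positive_label to map text labels"
        )
    return int(text.strip().lower() == positive_label.strip().lower())


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample_id,label table (TSV or CSV; delimiter sniffed)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputError("label table needs at least two columns (sample_id, label)")
    series = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str).str.strip())
    if series.index.duplicated().any():
        raise InputError("duplicate sample ids in label table")
    return series


def read_read_counts(path: str | Path) -> dict[str, int]:
    """Read a two-column sample_id,total_reads table."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise InputError("read-count table needs two columns (sample_id, total_reads)")
    out: dict[str, int] = {}
    for sid, n in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out[str(sid).strip()] = int(n)
    return out


def read_sample_matrix_csv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a pre-built samples x species CSV (first column sample_id, last column label).

    Species column headers must be full clade strings, or bare species names to
    be resolved against a separate lineage sidecar at grouping time.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] < 2:
        raise InputError("sample matrix needs at least one feature column and a label column")
    labels = df.iloc[:, -1]
    values = df.iloc[:, :-1].astype(float)
    return values, pd.Series(labels.to_numpy(), index=df.index.astype(str).str.strip())


def load_abundance_matrix(
    abundance_path: str | Path,
    labels_path: str | Path,
    read_counts_path: str | Path | None = None,
    positive_label: str | None = None,
    min_reads: int = 1_000_000,
    strict_read_counts: bool = True,
) -> AbundanceMatrix:
    """End-to-end loader: parse, select species, label, depth-filter, normalize."""
    table = parse_merged_table(abundance_path)
    species = select_species_rows(table)
    labels = read_labels(labels_path)
    matrix = attach_labels_and_clean(species.T, labels, positive_label=positive_label)
    counts = read_read_counts(read_counts_path) if read_counts_path is not None else None
    matrix = filter_samples_by_reads(matrix, counts, min_reads=min_reads,
                                     strict=strict_read_counts)
    if matrix.labels is None or len(np.unique(matrix.labels)) < 2:
        raise InputError("only one class present after read-depth filtering")
    return normalize_abundances(matrix)
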