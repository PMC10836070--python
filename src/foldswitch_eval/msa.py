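"""Multiple sequence alignments: parsing, clustering, random subsampling.

Shallow, randomly subsampled MSAs are one way to coax AlphaFold2-family
predictors into sampling alternative conformations of fold-switching
proteins; clustering the MSA by sequence similarity and predicting per
cluster is the competing strategy.  This module provides both substrates:
A3M/FASTA parsing into a query-anchored :class:`Alignment`, DBSCAN
clustering on sequence Hamming distance, uniform random subsampling to a
requested depth, and pairwise sequence identity.

A3M convention: lowercase letters are insertions relative to the query and
are deleted during normalization, so every row has exactly the query's
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from sklearn.cluster import DBSCAN

from .errors import FormatError, ParameterError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: 22-letter alphabet: 20 amino acids, X (unknown), and the gap symbol.
ALPHABET = AMINO_ACIDS + "X" + GAP
_CHAR_TO_INDEX = {c: i for i, c in enumerate(ALPHABET)}


@dataclass
class Alignment:
    """A query-anchored multiple sequence alignment in matrix form.

    The row at ``query_index`` defines the column space: after A3M
    normalization it contains no insertion-derived gaps, and every row has
    exactly its length.
    """

    ids: list[str]
    rows: list[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or len(self.rows) < 1:
            raise ValidationError("alignment needs equal, non-zero ids and rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("alignment ids must be unique")
        if not 0 <= self.query_index < len(self.rows):
            raise ValidationError("query_index out of range")
        length = len(self.rows[self.query_index])
        for name, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise ValidationError(
                    f"row {name!r} has length {len(row)}, query has {length}"
                )
            bad = set(row) - set(ALPHABET)
            if bad:
                raise FormatError(
                    f"record {name!r} contains characters outside the "
                    f"alphabet: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[self.query_index])

    @property
    def query(self) -> str:
        return self.rows[self.query_index]


@dataclass
class SubsampleSpec:
    """Depth specification for random subsampling.

    ``max_seq`` / ``max_extra_seq`` mirror the ColabFold parameters capping
    cluster and extra sequences; by default ``max_extra_seq = 2 * max_seq``.
    The total depth drawn is ``max_seq + max_extra_seq`` rows including the
    query.
    """

    max_seq: int
    max_extra_seq: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_seq < 1:
            raise ParameterError("max_seq must be a positive integer")
        if self.max_extra_seq is None:
            self.max_extra_seq = 2 * self.max_seq
        if self.max_extra_seq < 0:
            raise ParameterError("max_extra_seq must be >= 0")


@dataclass
class ClusterResult:
    """DBSCAN labels per alignment row; -1 marks noise."""

    labels: np.ndarray
    eps: float
    min_samples: int

    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or A3M alignment into a normalized :class:`Alignment`.

    For A3M, lowercase characters (insertions relative to the query) and
    ``.`` padding are removed so every row has query length.  For FASTA all
    rows must already be equal length.  The first record is taken as the
    query.
    """
    if format not in ("fasta", "a3m"):
        raise ParameterError(f"unknown alignment format {format!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no sequence records found")
    ids, rows = [], []
    for rec in records:
        seq = str(rec.seq)
        if format == "a3m":
            seq = "".join(c for c in seq if not (c.islower() or c == "."))
        ids.append(rec.id)
        rows.append(seq)
    length = len(rows[0])
    for name, row in zip(ids, rows):
        if len(row) != length:
            raise FormatError(
                f"{path}: record {name!r} has length {len(row)}, "
                f"expected {length}"
            )
    return Alignment(ids=ids, rows=rows, query_index=0)


def write_a3m(aln: Alignment, path: str | Path) -> None:
    """Write an alignment with the query first; round-trips with
    :func:`read_alignment` (normalized rows contain no lowercase)."""
    order = [aln.query_index] + [
        i for i in range(len(aln)) if i != aln.query_index
    ]
    with open(path, "w") as fh:
        for i in order:
            fh.write(f">{aln.ids[i]}\n{aln.rows[i]}\n")


def encode_rows(aln: Alignment) -> np.ndarray:
    """Integer-encode rows over the 22-letter alphabet, shape (n, L)."""
    return np.array(
        [[_CHAR_TO_INDEX[c] for c in row] for row in aln.rows], dtype=np.int8
    )


def one_hot_encode(aln: Alignment) -> np.ndarray:
    """One-hot encode rows: shape (n_rows, L * 22), one channel per alphabet
    letter; every per-position block sums to exactly 1."""
    codes = encode_rows(aln)
    n, length = codes.shape
    out = np.zeros((n, length, len(ALPHABET)), dtype=np.float64)
    rows_idx = np.arange(n)[:, None]
    cols_idx = np.arange(length)[None, :]
    out[rows_idx, cols_idx, codes] = 1.0
    return out.reshape(n, length * len(ALPHABET))


def cluster_sequences(
    aln: Alignment, eps: float, min_samples: int = 3
) -> ClusterResult:
    """Density-based clustering of alignment rows (the AF-cluster stage).

    DBSCAN on Hamming distance, expressed as the fraction of alignment
    columns at which two rows differ (gap counts as a 22nd symbol); this is
    the one-hot Hamming distance up to a constant factor.  ``eps`` is in
    those units: rows within ``eps`` column-fraction of a core point join
    its cluster, and rows reachable from no core point are labelled -1.
    Deterministic for fixed inputs.
    """
    if eps <= 0:
        raise ParameterError("eps must be > 0")
    if min_samples < 1:
        raise ParameterError("min_samples must be >= 1")
    if len(aln) < min_samples:
        raise ParameterError(
            f"alignment has {len(aln)} rows, fewer than min_samples={min_samples}"
        )
    codes = encode_rows(aln)
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="hamming").fit(
        codes
    ).labels_
    return ClusterResult(labels=labels, eps=eps, min_samples=min_samples)


def scan_eps(
    aln: Alignment,
    lo: float,
    hi: float,
    step: float,
    min_samples: int = 3,
) -> ClusterResult:
    """Scan eps over [lo, hi] and keep the value maximizing the number of
    clusters of size >= min_samples; ties prefer fewer noise rows, then the
    smaller eps."""
    if not (0 < lo <= hi) or step <= 0:
        raise ParameterError("need 0 < lo <= hi and step > 0")
    best: ClusterResult | None = None
    best_key = None
    for eps in np.arange(lo, hi + 0.5 * step, step):
        result = cluster_sequences(aln, float(eps), min_samples)
        key = (result.n_clusters(), -int((result.labels < 0).sum()))
        if best_key is None or key > best_key:
            best, best_key = result, key
    assert best is not None
    return best


def random_subsample(aln: Alignment, spec: SubsampleSpec) -> Alignment:
    """Uniformly subsample the alignment to max_seq + max_extra_seq rows.

    The query row is always retained and placed first; the remaining
    ``max_seq + max_extra_seq - 1`` rows are drawn uniformly without
    replacement (input order preserved).  Identical seeds give identical
    outputs; an alignment shallower than the requested depth is returned
    whole.
    """
    rng = np.random.default_rng(spec.seed)
    non_query = [i for i in range(len(aln)) if i != aln.query_index]
    k = min(spec.max_seq + spec.max_extra_seq - 1, len(non_query))
    chosen = sorted(rng.choice(len(non_query), size=k, replace=False))
    picked = [non_query[i] for i in chosen]
    order = [aln.query_index] + picked
    return Alignment(
        ids=[aln.ids[i] for i in order],
        rows=[aln.rows[i] for i in order],
        query_index=0,
    )


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity between two aligned sequences.

    Matches divided by the number of columns where neither sequence has a
    gap; symmetric by construction.
    """
    if len(a) != len(b):
        raise ParameterError(
            f"aligned sequences differ in length ({len(a)} vs {len(b)})"
        )
    matches = 0
    denom = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        denom += 1
        if x == y:
            matches += 1
    if denom == 0:
        raise ParameterError("no columns where both sequences are non-gap")
    return matches / denom
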