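"""Readers and writers for the on-disk formats the pipeline touches.

All interval-valued data use the BED convention throughout the package:
0-based, half-open ``[start, end)`` coordinates.  Interval collections are
plain :class:`pandas.DataFrame` objects with at least ``chrom``, ``start``
and ``end`` columns; optional BED columns (``name``, ``score``, ``strand``)
and extra annotation columns (e.g. TE ``class``/``family``) follow.

Contact matrices are stored as a small text COO format with a three-line
header (``#chrom``, ``#bin_size``, ``#n_bins``) followed by
``bin_i<TAB>bin_j<TAB>count`` records with ``i <= j``; the in-memory
representation is a dense symmetric :class:`ContactMatrix`.

Coordinate maps between genome assemblies are read from UCSC chain files
and represented as block tables (:class:`CoordinateMap`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "CoordinateMap",
    "BedFormatError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_matrix_coo",
    "write_matrix_coo",
    "read_chain",
    "write_chain",
    "identity_map",
    "validate_intervals",
]

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


class BedFormatError(ValueError):
    """Malformed interval file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def validate_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Check interval invariants: nonempty chrom, 0 <= start < end."""
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise BedFormatError(f"missing required column {col!r}")
    if len(df):
        if (df["chrom"].astype(str) == "").any():
            raise BedFormatError("empty chrom name")
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        bad = np.flatnonzero((starts < 0) | (starts >= ends))
        if bad.size:
            raise BedFormatError(
                f"invalid interval (need 0 <= start < end)", line=int(bad[0]) + 1
            )
    return df


def read_bed(path, expected_columns: int = 3) -> pd.DataFrame:
    """Read a BED file into a DataFrame.

    Columns beyond the canonical six are kept as ``extra1``, ``extra2``, ...
    (the TE dialect stores repeat class and family there).  Every record is
    validated; a malformed line raises :class:`BedFormatError` naming it.
    """
    if expected_columns < 3:
        raise ValueError("BED requires at least 3 columns")
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < expected_columns:
                raise BedFormatError(
                    f"expected >= {expected_columns} columns, got {len(fields)}",
                    line=lineno,
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"non-integer coordinate: {exc}", line=lineno)
            if not fields[0]:
                raise BedFormatError("empty chrom name", line=lineno)
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"invalid interval [{start}, {end})", line=lineno
                )
            rows.append([fields[0], start, end] + fields[3:])
    ncol = max((len(r) for r in rows), default=expected_columns)
    names = list(BED_COLUMNS[:ncol])
    names += [f"extra{i}" for i in range(1, ncol - len(names) + 1)]
    df = pd.DataFrame(rows, columns=names[:ncol])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write an interval DataFrame as (extended) BED."""
    validate_intervals(df)
    cols = [c for c in BED_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    out = df[cols].copy()
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph track into chrom/start/end/value."""
    df = read_bed(path, expected_columns=4)
    df = df.rename(columns={"name": "value"})
    df["value"] = pd.to_numeric(df["value"])
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    validate_intervals(df)
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C contact matrix for one chromosome.

    ``counts`` is dense ``(n_bins, n_bins)``; symmetry and non-negativity
    are enforced at construction.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContactMatrix)
            and self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and self.counts.shape == other.counts.shape
            and np.array_equal(self.counts, other.counts)
        )


def read_matrix_coo(path) -> ContactMatrix:
    """Read the text COO matrix format.

    Header: ``#chrom <name>``, ``#bin_size <bp>``, ``#n_bins <n>``.
    Body: ``i<TAB>j<TAB>count`` with ``i <= j``.  Duplicate ``(i, j)``
    entries are an error rather than being summed, so generator bugs
    surface instead of silently aggregating.
    """
    header: dict[str, str] = {}
    seen: set[tuple[int, int]] = set()
    mat = None
    n_bins = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, val = line[1:].split(None, 1)
                except ValueError:
                    raise BedFormatError("malformed header", line=lineno)
                header[key] = val
                continue
            if mat is None:
                for key in ("chrom", "bin_size", "n_bins"):
                    if key not in header:
                        raise BedFormatError(f"missing header field #{key}")
                n_bins = int(header["n_bins"])
                mat = np.zeros((n_bins, n_bins))
            fields = line.split("\t")
            if len(fields) != 3:
                raise BedFormatError("expected 3 columns", line=lineno)
            i, j, c = int(fields[0]), int(fields[1]), float(fields[2])
            if i > j:
                raise BedFormatError(f"i > j ({i} > {j})", line=lineno)
            if c < 0:
                raise BedFormatError(f"negative count {c}", line=lineno)
            if j >= n_bins:
                raise BedFormatError(f"bin {j} >= n_bins {n_bins}", line=lineno)
            if (i, j) in seen:
                raise BedFormatError(f"duplicate entry ({i}, {j})", line=lineno)
            seen.add((i, j))
            mat[i, j] = mat[j, i] = c
    if mat is None:
        for key in ("chrom", "bin_size", "n_bins"):
            if key not in header:
                raise BedFormatError(f"missing header field #{key}")
        mat = np.zeros((int(header["n_bins"]),) * 2)
    return ContactMatrix(header["chrom"], int(header["bin_size"]), mat)


def write_matrix_coo(matrix: ContactMatrix, path) -> None:
    """Write upper-triangle nonzero entries in the COO text format."""
    with open(path, "w") as fh:
        fh.write(f"#chrom {matrix.chrom}\n")
        fh.write(f"#bin_size {matrix.bin_size}\n")
        fh.write(f"#n_bins {matrix.n_bins}\n")
        iu, ju = np.nonzero(np.triu(matrix.counts))
        for i, j in zip(iu, ju):
            c = matrix.counts[i, j]
            c_repr = int(c) if float(c).is_integer() else c
            fh.write(f"{i}\t{j}\t{c_repr}\n")


# ---------------------------------------------------------------------------
# Coordinate maps (chain format)
# ---------------------------------------------------------------------------

MAP_COLUMNS = (
    "src_chrom",
    "src_start",
    "src_end",
    "dst_chrom",
    "dst_start",
    "dst_end",
    "strand",
    "score",
    "chain_id",
)


@dataclass
class CoordinateMap:
    """Ordered, src-disjoint alignment blocks between two genomes.

    ``blocks`` holds one row per ungapped block with forward-strand,
    0-based half-open coordinates on both genomes; ``strand`` is the dst
    orientation and ``chain_id`` groups blocks belonging to one collinear
    run (one chain record in chain files).
    """

    blocks: pd.DataFrame

    def __post_init__(self):
        df = self.blocks
        for col in MAP_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"CoordinateMap missing column {col!r}")
        if len(df):
            src_len = df["src_end"] - df["src_start"]
            dst_len = df["dst_end"] - df["dst_start"]
            if not (src_len == dst_len).all():
                raise ValueError("src and dst block lengths differ")
            if (df["score"] < 0).any():
                raise ValueError("block scores must be >= 0")
            by = df.sort_values(["src_chrom", "src_start"])
            same = by["src_chrom"].to_numpy()[1:] == by["src_chrom"].to_numpy()[:-1]
            overlap = by["src_start"].to_numpy()[1:] < by["src_end"].to_numpy()[:-1]
            if (same & overlap).any():
                raise ValueError("blocks overlap on src")
        self.blocks = df.sort_values(["src_chrom", "src_start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.blocks)


def identity_map(chrom: str, length: int, dst_chrom: str | None = None) -> CoordinateMap:
    """One block mapping ``[0, length)`` to itself (or to ``dst_chrom``)."""
    return CoordinateMap(
        pd.DataFrame(
            [
                {
                    "src_chrom": chrom,
                    "src_start": 0,
                    "src_end": length,
                    "dst_chrom": dst_chrom or chrom,
                    "dst_start": 0,
                    "dst_end": length,
                    "strand": "+",
                    "score": float(length),
                    "chain_id": 0,
                }
            ]
        )
    )


def read_chain(path) -> CoordinateMap:
    """Parse a UCSC chain file into a CoordinateMap.

    Chain block lists run on the *target* (first) genome coordinates; we
    treat chain target as ``src`` and chain query as ``dst``.  Negative
    query strands are converted to forward-strand 0-based half-open
    coordinates.  Inconsistent block sums are rejected.
    """
    rows = []
    with open(path) as fh:
        text = fh.read()
    for rec_id, rec in enumerate(_chain_records(text)):
        head, body = rec
        (
            _chain,
            score,
            t_name,
            t_size,
            t_strand,
            t_start,
            t_end,
            q_name,
            q_size,
            q_strand,
            q_start,
            q_end,
            chain_id,
        ) = head
        if t_strand != "+":
            raise BedFormatError("chain target strand must be '+'")
        t_pos, q_pos = int(t_start), int(q_start)
        for size, dt, dq in body:
            t0, t1 = t_pos, t_pos + size
            q0, q1 = q_pos, q_pos + size
            if q_strand == "-":
                # chain minus-strand query coords count from the far end
                f0 = int(q_size) - q1
                f1 = int(q_size) - q0
            else:
                f0, f1 = q0, q1
            rows.append(
                {
                    "src_chrom": t_name,
                    "src_start": t0,
                    "src_end": t1,
                    "dst_chrom": q_name,
                    "dst_start": f0,
                    "dst_end": f1,
                    "strand": q_strand,
                    "score": float(score),
                    "chain_id": int(chain_id) if chain_id else rec_id,
                }
            )
            t_pos = t1 + dt
            q_pos = q1 + dq
        if t_pos != int(t_end) or q_pos != int(q_end):
            raise BedFormatError(
                f"chain {chain_id or rec_id}: block sums inconsistent with header"
            )
    return CoordinateMap(pd.DataFrame(rows, columns=list(MAP_COLUMNS)))


def _chain_records(text: str):
    head = None
    body: list[tuple[int, int, int]] = []
    for raw in io.StringIO(text):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("chain"):
            if head is not None:
                yield head, body
            fields = line.split()
            if len(fields) == 12:
                fields.append("")
            if len(fields) != 13:
                raise BedFormatError(f"malformed chain header: {line!r}")
            head, body = fields, []
        else:
            parts = [int(x) for x in line.split()]
            if len(parts) == 1:
                body.append((parts[0], 0, 0))
            elif len(parts) == 3:
                body.append((parts[0], parts[1], parts[2]))
            else:
                raise BedFormatError(f"malformed chain block line: {line!r}")
    if head is not None:
        yield head, body


def write_chain(cmap: CoordinateMap, path, chrom_sizes: dict[str, int] | None = None) -> None:
    """Write a CoordinateMap as a UCSC chain file, one chain per chain_id."""
    chrom_sizes = chrom_sizes or {}

    def size_of(chrom, end):
        return chrom_sizes.get(chrom, int(end))

    with open(path, "w") as fh:
        for chain_id, grp in cmap.blocks.groupby("chain_id", sort=True):
            grp = grp.sort_values("src_start")
            strand = grp["strand"].iloc[0]
            t_name = grp["src_chrom"].iloc[0]
            q_name = grp["dst_chrom"].iloc[0]
            t_start, t_end = int(grp["src_start"].min()), int(grp["src_end"].max())
            q_size = size_of(q_name, grp["dst_end"].max())
            if strand == "-":
                # forward coords -> chain minus coords, reversing block order
                grp = grp.sort_values("src_start")
                q_lo = int(q_size - grp["dst_end"].max())
                q_hi = int(q_size - grp["dst_start"].min())
            else:
                q_lo, q_hi = int(grp["dst_start"].min()), int(grp["dst_end"].max())
            score = float(grp["score"].sum())
            t_size = size_of(t_name, t_end)
            fh.write(
                f"chain {score:g} {t_name} {t_size} + {t_start} {t_end} "
                f"{q_name} {q_size} {strand} {q_lo} {q_hi} {chain_id}\n"
            )
            starts = grp["src_start"].to_numpy()
            ends = grp["src_end"].to_numpy()
            if strand == "-":
                qs = (q_size - grp["dst_end"].to_numpy())
                qe = (q_size - grp["dst_start"].to_numpy())
            else:
                qs = grp["dst_start"].to_numpy()
                qe = grp["dst_end"].to_numpy()
            for k in range(len(grp)):
                size = int(ends[k] - starts[k])
                if k + 1 < len(grp):
                    dt = int(starts[k + 1] - ends[k])
                    dq = int(qs[k + 1] - qe[k])
                    fh.write(f"{size}\t{dt}\t{dq}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")
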