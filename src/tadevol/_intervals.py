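"""Interval-overlap helpers shared across modules.

All functions operate on DataFrames with chrom/start/end columns (BED
convention, 0-based half-open). Overlap means >= 1 bp of intersection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def build_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        tree = IntervalTree()
        for row, (s, e) in zip(grp.index, zip(grp["start"], grp["end"])):
            tree.addi(int(s), int(e), row)
        trees[chrom] = tree
    return trees


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap >= 1 bp of any subject interval."""
    trees = build_trees(subject)
    out = np.zeros(len(query), dtype=bool)
    for k, (chrom, s, e) in enumerate(
        zip(query["chrom"], query["start"], query["end"])
    ):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(int(s), int(e)):
            out[k] = True
    return out


def count_overlaps(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Number of subject intervals overlapping each query interval."""
    trees = build_trees(subject)
    out = np.zeros(len(query), dtype=int)
    for k, (chrom, s, e) in enumerate(
        zip(query["chrom"], query["start"], query["end"])
    ):
        tree = trees.get(chrom)
        if tree is not None:
            out[k] = len(tree.overlap(int(s), int(e)))
    return out


def overlap_bp(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Total subject bp intersecting each query interval (summed over hits)."""
    trees = build_trees(subject)
    out = np.zeros(len(query), dtype=np.int64)
    for k, (chrom, s, e) in enumerate(
        zip(query["chrom"], query["start"], query["end"])
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        total = 0
        for iv in tree.overlap(int(s), int(e)):
            total += min(iv.end, int(e)) - max(iv.begin, int(s))
        out[k] = total
    return out


def largest_overlap_label(
    query: pd.DataFrame, subject: pd.DataFrame, label_cols: list[str]
) -> pd.DataFrame:
    """Label each query interval by the subject interval with the largest
    overlap; ties broken by the earliest subject interval (smallest start,
    then original order). Rows without any overlap get NA labels."""
    subj = subject.reset_index(drop=True)
    trees = build_trees(subj)
    rows = []
    for chrom, s, e in zip(query["chrom"], query["start"], query["end"]):
        tree = trees.get(chrom)
        best = None
        if tree is not None:
            hits = []
            for iv in tree.overlap(int(s), int(e)):
                ov = min(iv.end, int(e)) - max(iv.begin, int(s))
                hits.append((-ov, iv.begin, iv.data))
            if hits:
                hits.sort()
                best = hits[0][2]
        if best is None:
            rows.append({c: pd.NA for c in label_cols})
        else:
            rows.append({c: subj.at[best, c] for c in label_cols})
    return pd.DataFrame(rows, columns=label_cols)


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """bedtools-merge style single-linkage merge: intervals whose end-to-start
    gap is <= ``gap`` on the same chrom are chained into one interval."""
    if not len(df):
        return df[["chrom", "start", "end"]].copy()
    out = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif int(s) - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def total_coverage(df: pd.DataFrame) -> int:
    """Union bp covered by a set of intervals."""
    merged = merge_intervals(df)
    if not len(merged):
        return 0
    return int((merged["end"] - merged["start"]).sum())
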