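"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities with the most naive
possible implementation (double loops, per-base maps, full enumeration)
so the vectorised production code is checked against something that
cannot share its bugs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from tadevol.synthetic_data import PhylogenySpec


@pytest.fixture(scope="session")
def tree() -> PhylogenySpec:
    return PhylogenySpec.default()


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def diamond_oracle(counts: np.ndarray, w: int) -> np.ndarray:
    """Diamond means by explicit double loop."""
    n = counts.shape[0]
    out = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        vals = [counts[a, b] for a in range(i - w, i) for b in range(i, i + w)]
        out[i] = float(np.mean(vals))
    return out


def expected_matrix_oracle(bbins, strengths, n, alpha, base) -> np.ndarray:
    """Expected contact counts by explicit per-cell loop."""
    E = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                E[i, j] = base
                continue
            lo, hi = min(i, j), max(i, j)
            e = base * (hi - lo) ** (-alpha)
            for k, sv in zip(bbins, strengths):
                if lo < k <= hi:
                    e *= sv
            E[i, j] = e
    return E


def per_base_map_oracle(cmap) -> dict[tuple[str, int], tuple[str, int, str]]:
    """src base -> (dst_chrom, dst_base, strand) by walking every block."""
    out = {}
    for _, b in cmap.blocks.iterrows():
        for off in range(int(b["src_end"] - b["src_start"])):
            src = (b["src_chrom"], int(b["src_start"]) + off)
            if b["strand"] == "+":
                dst = int(b["dst_start"]) + off
            else:
                dst = int(b["dst_end"]) - 1 - off
            out[src] = (b["dst_chrom"], dst, b["strand"])
    return out


def union_components_oracle(df: pd.DataFrame, gap: int) -> list[set[int]]:
    """Connected components of the pairwise gap<=d graph (transitive
    closure), ignoring insertion order entirely."""
    n = len(df)
    adj = [[] for _ in range(n)]
    rows = df.reset_index(drop=True)
    for i in range(n):
        for j in range(i + 1, n):
            if rows.at[i, "chrom"] != rows.at[j, "chrom"]:
                continue
            g = max(
                0,
                max(rows.at[i, "start"], rows.at[j, "start"])
                - min(rows.at[i, "end"], rows.at[j, "end"]),
            )
            if g <= gap:
                adj[i].append(j)
                adj[j].append(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.add(k)
            stack.extend(adj[k])
        comps.append(comp)
    return comps


def chain_runs_oracle(blocks_df: pd.DataFrame, max_gap: int):
    """All maximal contiguous windows of src-sorted blocks whose every
    consecutive pair is collinear; enumerated exhaustively."""

    def pair_ok(a, b):
        if (
            a["src_chrom"] != b["src_chrom"]
            or a["dst_chrom"] != b["dst_chrom"]
            or a["strand"] != b["strand"]
        ):
            return False
        if not (0 <= b["src_start"] - a["src_end"] <= max_gap):
            return False
        if a["strand"] == "+":
            return 0 <= b["dst_start"] - a["dst_end"] <= max_gap
        return 0 <= a["dst_start"] - b["dst_end"] <= max_gap

    runs = []
    for chrom, grp in blocks_df.groupby("src_chrom"):
        idx = list(grp.sort_values("src_start").index)
        m = len(idx)
        for i in range(m):
            for j in range(i, m):
                window = idx[i : j + 1]
                ok = all(
                    pair_ok(blocks_df.loc[a], blocks_df.loc[b])
                    for a, b in zip(window, window[1:])
                )
                if not ok:
                    continue
                left_ext = i > 0 and pair_ok(
                    blocks_df.loc[idx[i - 1]], blocks_df.loc[idx[i]]
                )
                right_ext = j < m - 1 and pair_ok(
                    blocks_df.loc[idx[j]], blocks_df.loc[idx[j + 1]]
                )
                if not left_ext and not right_ext:
                    runs.append(window)
    return runs


def fisher_oracle(table: np.ndarray) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x)
            * math.comb(r2, c1 - x)
            / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def binom_two_sided_oracle(k: int, n: int, p: float) -> float:
    """Tail-doubled exact binomial p by direct summation."""
    def pmf(x):
        return math.comb(n, x) * p**x * (1 - p) ** (n - x)

    lower = sum(pmf(x) for x in range(0, k + 1))
    upper = sum(pmf(x) for x in range(k, n + 1))
    return min(1.0, 2 * min(lower, upper))
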