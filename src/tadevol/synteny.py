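"""Synteny block elongation, break-of-synteny (BOS) detection and the
statistics tying breakpoints to TAD boundary conservation.

Pairwise alignment blocks are chained into elongated synteny blocks:
blocks passing a length and score filter seed chains that absorb
neighbouring collinear blocks (same chromosomes, same strand, consistent
order, bounded gaps).  The 1 Kb flanks of each elongated block on the
rearranged (source) genome are the BOS candidates; candidates whose
re-mapping hits are ambiguous (second-best score within 10% of the best)
are removed as putative duplications.  Enrichment of TAD boundaries at
BOS is assessed against GC-matched random interval sets with Fisher's
exact test, and the conservation-group composition of BOS-overlapping
boundaries is assessed with a label permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import overlaps_any
from .io_formats import CoordinateMap

__all__ = [
    "SyntenyBlock",
    "elongate_blocks",
    "define_bos",
    "duplication_filter",
    "gc_stratified_sample",
    "bos_boundary_overlap_test",
    "bos_conservation_permutation",
    "EnrichmentResult",
]


@dataclass
class SyntenyBlock:
    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int
    dst_end: int
    strand: str
    score: float
    members: list = field(default_factory=list)


@dataclass
class EnrichmentResult:
    """Observed/expected/odds-ratio/p record shared by the overlap tests."""

    unit: str
    observed: float
    expected: float
    ratio: float
    test: str
    p: float
    extra: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        for thr, mark in ((0.0005, "***"), (0.005, "**"), (0.05, "*")):
            if self.p < thr:
                return mark
        return ""


def _collinear(a: pd.Series, b: pd.Series, max_gap: int) -> bool:
    """Can block b (next in src order) extend a chain ending in block a?"""
    if (
        a["src_chrom"] != b["src_chrom"]
        or a["dst_chrom"] != b["dst_chrom"]
        or a["strand"] != b["strand"]
    ):
        return False
    if b["src_start"] - a["src_end"] > max_gap or b["src_start"] < a["src_end"]:
        return False
    if a["strand"] == "+":
        gap = b["dst_start"] - a["dst_end"]
    else:
        gap = a["dst_start"] - b["dst_end"]
    return 0 <= gap <= max_gap


def elongate_blocks(
    blocks: CoordinateMap,
    min_len: int = 1000,
    min_score: float = 100_000,
    max_gap: int = 1_000_000,
) -> list[SyntenyBlock]:
    """Chain collinear alignment blocks into elongated synteny blocks.

    Seed blocks must be longer than ``min_len`` and score at least
    ``min_score``; a seed's chain is the maximal run of consecutive
    (in src order) collinear blocks containing it, absorbing neighbours
    of any size.  Runs without a seed emit nothing.  Output blocks are
    maximal and non-overlapping on src.
    """
    df = blocks.blocks.reset_index(drop=True)
    if not len(df):
        return []
    out: list[SyntenyBlock] = []
    # partition into maximal collinear runs of consecutive blocks
    runs: list[list[int]] = []
    for chrom, grp in df.groupby("src_chrom", sort=True):
        idx = list(grp.sort_values("src_start").index)
        run = [idx[0]]
        for prev, cur in zip(idx, idx[1:]):
            if _collinear(df.loc[prev], df.loc[cur], max_gap):
                run.append(cur)
            else:
                runs.append(run)
                run = [cur]
        runs.append(run)
    for run in runs:
        sub = df.loc[run]
        seeds = sub[(sub["src_end"] - sub["src_start"] > min_len) & (sub["score"] >= min_score)]
        if not len(seeds):
            continue
        out.append(
            SyntenyBlock(
                src_chrom=sub["src_chrom"].iloc[0],
                src_start=int(sub["src_start"].min()),
                src_end=int(sub["src_end"].max()),
                dst_chrom=sub["dst_chrom"].iloc[0],
                dst_start=int(sub["dst_start"].min()),
                dst_end=int(sub["dst_end"].max()),
                strand=sub["strand"].iloc[0],
                score=float(sub["score"].sum()),
                members=list(run),
            )
        )
    out.sort(key=lambda b: (b.src_chrom, b.src_start))
    return out


def define_bos(
    blocks: list[SyntenyBlock],
    flank_width: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """1 Kb regions flanking each elongated synteny block on the source
    (rearranged) genome.  Flanks are clipped at position 0 and, when
    chromosome lengths are given, at the chromosome end; empty flanks are
    dropped.  Columns: chrom/start/end/name/flank_side/block and a
    curation ``status`` initialised to "kept".
    """
    chrom_lengths = chrom_lengths or {}
    rows = []
    for k, b in enumerate(blocks):
        up_s = max(b.src_start - flank_width, 0)
        pairs = [("5prime", up_s, b.src_start)]
        dn_e = b.src_end + flank_width
        limit = chrom_lengths.get(b.src_chrom)
        if limit is not None:
            dn_e = min(dn_e, limit)
        pairs.append(("3prime", b.src_end, dn_e))
        for side, s, e in pairs:
            if e > s:
                rows.append(
                    {
                        "chrom": b.src_chrom,
                        "start": int(s),
                        "end": int(e),
                        "name": f"bos{len(rows)}",
                        "flank_side": side,
                        "block": k,
                        "status": "kept",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "flank_side", "block", "status"],
    )


def duplication_filter(
    bos: pd.DataFrame,
    hits: dict[str, list[float]],
    ratio: float = 0.10,
    repeat_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Curate BOS using re-mapping hit scores.

    A BOS is removed as ``duplicated`` when its second-best hit scores
    within ``ratio`` of the best (inclusive: ``second >= (1-ratio)*top``),
    and as ``unmappable`` with zero hits.  An optional repeat mask removes
    BOS overlapping masked intervals by >= 1 bp (``repeat_overlap``).
    Returns the full table with ``status`` updated; kept rows have
    status == "kept".
    """
    out = bos.copy()
    status = []
    for name in out["name"]:
        scores = sorted(hits.get(name, []), reverse=True)
        if len(scores) == 0:
            status.append("unmappable")
        elif len(scores) >= 2 and scores[1] >= (1 - ratio) * scores[0]:
            status.append("duplicated")
        else:
            status.append("kept")
    out["status"] = status
    if repeat_mask is not None and len(repeat_mask):
        masked = overlaps_any(out, repeat_mask)
        out.loc[masked & (out["status"] == "kept"), "status"] = "repeat_overlap"
    return out


def _mean_gc(intervals: pd.DataFrame, gc_track: pd.DataFrame) -> np.ndarray:
    """Coverage-weighted mean GC over each interval from a bedGraph track."""
    vals = np.full(len(intervals), np.nan)
    for chrom, grp in gc_track.groupby("chrom"):
        ws = grp["start"].to_numpy()
        we = grp["end"].to_numpy()
        wv = grp["value"].to_numpy()
        sel = intervals["chrom"] == chrom
        for k in np.flatnonzero(sel.to_numpy()):
            s = int(intervals["start"].iloc[k])
            e = int(intervals["end"].iloc[k])
            lo = np.searchsorted(we, s, side="right")
            hi = np.searchsorted(ws, e, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(we[lo:hi], e) - np.maximum(ws[lo:hi], s)
            vals[k] = float((wv[lo:hi] * ov).sum() / ov.sum())
    return vals


def gc_stratified_sample(
    bos: pd.DataFrame,
    gc_track: pd.DataFrame,
    n_sets: int,
    n_strata: int = 10,
    seed: int = 0,
    width: int | None = None,
) -> list[pd.DataFrame]:
    """Random interval sets matching the BOS GC composition.

    Observed BOS are binned into ``n_strata`` GC quantile strata; each
    random set draws the same per-stratum counts uniformly (without
    replacement) from the eligible fixed-width windows of the GC track in
    that stratum.  Deterministic per seed.
    """
    if not len(bos):
        raise ValueError("no BOS to match")
    obs_gc = _mean_gc(bos, gc_track)
    if np.isnan(obs_gc).any():
        raise ValueError("BOS outside the GC track extent")
    width = width or int((bos["end"] - bos["start"]).median())
    # round away float jitter from weighted means, and merge duplicate
    # quantile edges (a uniform-GC genome collapses to one stratum)
    obs_gc = np.round(obs_gc, 9)
    qs = np.quantile(obs_gc, np.linspace(0, 1, n_strata + 1))
    edges = np.concatenate([[-np.inf], np.unique(qs[1:-1]), [np.inf]])
    n_strata = len(edges) - 1
    strata_of_obs = np.clip(np.searchsorted(edges, obs_gc, side="right") - 1, 0, n_strata - 1)
    # eligible windows: GC-track windows, one candidate start per window
    win = gc_track.copy()
    win_gc = np.round(win["value"].to_numpy(), 9)
    win_strat = np.clip(np.searchsorted(edges, win_gc, side="right") - 1, 0, n_strata - 1)
    rng = np.random.default_rng(seed)
    counts = np.bincount(strata_of_obs, minlength=n_strata)
    sets = []
    for _ in range(n_sets):
        rows = []
        for st in range(n_strata):
            need = int(counts[st])
            if need == 0:
                continue
            elig = np.flatnonzero(win_strat == st)
            if elig.size == 0:
                raise ValueError(f"stratum {st} has no eligible windows")
            pick = rng.choice(elig, size=need, replace=elig.size < need)
            for w in pick:
                s = int(win["start"].iloc[w])
                rows.append(
                    {
                        "chrom": win["chrom"].iloc[w],
                        "start": s,
                        "end": s + width,
                        "stratum": st,
                    }
                )
        sets.append(pd.DataFrame(rows, columns=["chrom", "start", "end", "stratum"]))
    return sets


def _log2_or_ci(table: np.ndarray) -> tuple[float, float, float]:
    """Woolf log2 odds ratio and 95% CI with Haldane 0.5 correction when
    any cell is zero."""
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    lo = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ln2 = np.log(2)
    return lo / ln2, (lo - 1.96 * se) / ln2, (lo + 1.96 * se) / ln2


def bos_boundary_overlap_test(
    bos: pd.DataFrame,
    boundaries: pd.DataFrame,
    random_sets: list[pd.DataFrame],
) -> EnrichmentResult:
    """Fisher's exact test of BOS/TAD-boundary overlap against pooled
    GC-matched random intervals (>= 1 bp overlap)."""
    if not random_sets:
        raise ValueError("need at least one random set")
    kept = bos[bos["status"] == "kept"] if "status" in bos.columns else bos
    obs_hit = int(overlaps_any(kept, boundaries).sum())
    obs_miss = len(kept) - obs_hit
    pooled = pd.concat(random_sets, ignore_index=True)
    rnd_hit = int(overlaps_any(pooled, boundaries).sum())
    rnd_miss = len(pooled) - rnd_hit
    table = np.array([[obs_hit, obs_miss], [rnd_hit, rnd_miss]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    l2or, lo, hi = _log2_or_ci(table)
    expected = len(kept) * rnd_hit / max(len(pooled), 1)
    return EnrichmentResult(
        unit="bos_boundary_overlap",
        observed=obs_hit,
        expected=expected,
        ratio=obs_hit / expected if expected > 0 else np.nan,
        test="fisher_exact",
        p=float(p),
        extra={
            "table": table,
            "log2_or": l2or,
            "ci_low": lo,
            "ci_high": hi,
            "n_bos": len(kept),
            "n_random": len(pooled),
        },
    )


def bos_conservation_permutation(
    observed_labels: pd.Series,
    pool_labels: pd.Series,
    n_perm: int = 100,
    seed: int = 0,
    plus_one: bool = False,
) -> pd.DataFrame:
    """Per-category one-tailed permutation p-values for the conservation
    composition of BOS-overlapping boundaries.

    Each permutation draws ``len(observed)`` boundaries without
    replacement from the labelled pool and tallies category counts.
    ``p_over`` is the proportion of permutations with count >= observed,
    ``p_under`` with count <= observed (so ``p_over + p_under >= 1``).
    With ``plus_one`` the (k+1)/(n+1) estimator is used instead of the
    plain proportion; a ``resolution`` note marks zero counts.
    """
    if len(observed_labels) == 0:
        raise ValueError("observed set is empty")
    if len(observed_labels) > len(pool_labels):
        raise ValueError("observed set larger than the pool")
    cats = sorted(set(pool_labels) | set(observed_labels))
    obs_counts = observed_labels.value_counts().reindex(cats, fill_value=0)
    rng = np.random.default_rng(seed)
    pool = np.asarray(pool_labels)
    perm = np.zeros((n_perm, len(cats)), dtype=int)
    cat_index = {c: k for k, c in enumerate(cats)}
    for t in range(n_perm):
        draw = rng.choice(pool, size=len(observed_labels), replace=False)
        for lab, cnt in zip(*np.unique(draw, return_counts=True)):
            perm[t, cat_index[lab]] = cnt
    rows = []
    denom = n_perm + 1 if plus_one else n_perm
    add = 1 if plus_one else 0
    for k, c in enumerate(cats):
        over = int((perm[:, k] >= obs_counts[c]).sum())
        under = int((perm[:, k] <= obs_counts[c]).sum())
        rows.append(
            {
                "category": c,
                "observed": int(obs_counts[c]),
                "expected": float(perm[:, k].mean()),
                "p_over": (over + add) / denom,
                "p_under": (under + add) / denom,
                "resolution": f"p < 1/{n_perm}" if over == 0 or under == 0 else "",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["perm_counts"] = perm
    out.attrs["categories"] = cats
    return out
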