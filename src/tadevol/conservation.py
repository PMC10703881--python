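"""Cross-species TAD boundary conservation.

Boundaries called in each species are lifted to a reference genome through
a chain-style coordinate map, merged into a union boundary table (single-
linkage chaining within a merge distance, bedtools-merge semantics), and
each union boundary is classified by its presence/absence pattern across
species: ultraconserved (present in every species), order-conserved
(present in all members of one clade and absent from the other), species-
specific (present only in a clade's reference species, optionally after
filtering against outgroup exclusion sets), or other.

Group-level comparisons (insulation strength, gene and CTCF overlap) use
two-sided Wilcoxon rank-sum tests, plus a gene-overlap-matched permutation
test for insulation extremity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import overlaps_any, count_overlaps
from .io_formats import CoordinateMap

__all__ = [
    "liftover",
    "build_union",
    "classify_conservation",
    "label_from_presence",
    "nway_histogram",
    "group_summary",
    "GroupSummary",
    "matched_insulation_permutation",
]

ULTRACONSERVED = "ultraconserved"
OTHER = "other"


# ---------------------------------------------------------------------------
# Liftover
# ---------------------------------------------------------------------------


def liftover(
    intervals: pd.DataFrame, cmap: CoordinateMap, min_match: float = 0.95
) -> tuple[pd.DataFrame, list]:
    """Map intervals through a coordinate map.

    An interval lifts iff at least ``min_match`` of its bases map within a
    single collinear run (one ``chain_id``) of the map; the lifted
    interval is the span of the mapped bases on the destination genome.
    Returns ``(lifted, failed_ids)``; failures are data, not errors.
    """
    if not 0 < min_match <= 1:
        raise ValueError("min_match must be in (0, 1]")
    blocks = cmap.blocks
    lifted_rows, failed = [], []
    by_chrom = {c: g.sort_values("src_start") for c, g in blocks.groupby("src_chrom")}
    for idx, row in intervals.iterrows():
        iv_id = row.get("name", idx)
        grp = by_chrom.get(row["chrom"])
        if grp is None:
            failed.append(iv_id)
            continue
        pos = np.arange(int(row["start"]), int(row["end"]))
        starts = grp["src_start"].to_numpy()
        ends = grp["src_end"].to_numpy()
        bi = np.searchsorted(starts, pos, side="right") - 1
        ok = (bi >= 0) & (pos < ends[np.clip(bi, 0, None)])
        if not ok.any():
            failed.append(iv_id)
            continue
        bi = bi[ok]
        pos_ok = pos[ok]
        dst_start = grp["dst_start"].to_numpy()[bi]
        dst_end = grp["dst_end"].to_numpy()[bi]
        strand = grp["strand"].to_numpy()[bi]
        src_start = starts[bi]
        off = pos_ok - src_start
        dst_pos = np.where(strand == "+", dst_start + off, dst_end - 1 - off)
        chain = grp["chain_id"].to_numpy()[bi]
        dst_chrom = grp["dst_chrom"].to_numpy()[bi]
        # best single collinear run
        best_chain, best_n = None, 0
        for c in np.unique(chain):
            n = int((chain == c).sum())
            if n > best_n:
                best_chain, best_n = c, n
        need = min_match * (int(row["end"]) - int(row["start"]))
        if best_n < need:
            failed.append(iv_id)
            continue
        sel = chain == best_chain
        out = dict(row)
        out["chrom"] = dst_chrom[sel][0]
        out["start"] = int(dst_pos[sel].min())
        out["end"] = int(dst_pos[sel].max()) + 1
        out["name"] = iv_id
        lifted_rows.append(out)
    lifted = pd.DataFrame(lifted_rows) if lifted_rows else pd.DataFrame(
        columns=list(intervals.columns) + (["name"] if "name" not in intervals.columns else [])
    )
    return lifted, failed


# ---------------------------------------------------------------------------
# Union boundary table
# ---------------------------------------------------------------------------


def build_union(
    boundary_sets: dict[str, pd.DataFrame], merge_distance: int = 10_000
) -> pd.DataFrame:
    """Merge per-species boundaries (reference coordinates) into a union
    boundary table.

    Single-linkage chaining: sorted boundaries are linked whenever the
    end-to-start gap to the running chain is <= ``merge_distance``
    (bedtools-merge semantics; a chain can therefore span more than the
    merge distance end-to-end).  Each source boundary joins exactly one
    chain.  Presence flags record which species contributed at least one
    member; ``members`` keeps per-species source IDs.
    """
    species = list(boundary_sets)
    frames = []
    for sp in species:
        df = boundary_sets[sp]
        if not len(df):
            continue
        sub = df[["chrom", "start", "end"]].copy()
        sub["species"] = sp
        sub["src_id"] = (
            df["name"].astype(str).to_numpy()
            if "name" in df.columns
            else df.index.astype(str).to_numpy()
        )
        frames.append(sub)
    cols = (
        ["chrom", "start", "end"]
        + [f"present_{sp}" for sp in species]
        + ["n_way", "members"]
    )
    if not frames:
        return pd.DataFrame(columns=cols)
    allb = pd.concat(frames).sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    rows = []
    for chrom, grp in allb.groupby("chrom", sort=True):
        chain: list[int] = []
        chain_end = None
        for i in grp.index:
            s, e = int(grp.at[i, "start"]), int(grp.at[i, "end"])
            if chain and s - chain_end > merge_distance:
                rows.append(_union_row(allb, chain, species))
                chain = []
                chain_end = None
            chain.append(i)
            chain_end = e if chain_end is None else max(chain_end, e)
        if chain:
            rows.append(_union_row(allb, chain, species))
    table = pd.DataFrame(rows, columns=cols)
    return table.sort_values(["chrom", "start"]).reset_index(drop=True)


def _union_row(allb: pd.DataFrame, chain: list[int], species: list[str]) -> dict:
    sub = allb.loc[chain]
    present = {sp: False for sp in species}
    members: dict[str, list[str]] = {}
    for sp, sid in zip(sub["species"], sub["src_id"]):
        present[sp] = True
        members.setdefault(sp, []).append(sid)
    row = {
        "chrom": sub["chrom"].iloc[0],
        "start": int(sub["start"].min()),
        "end": int(sub["end"].max()),
    }
    for sp in species:
        row[f"present_{sp}"] = present[sp]
    row["n_way"] = sum(present.values())
    row["members"] = ";".join(
        f"{sp}:{','.join(ids)}" for sp, ids in sorted(members.items())
    )
    return row


def table_species(table: pd.DataFrame) -> list[str]:
    return [c[len("present_") :] for c in table.columns if c.startswith("present_")]


# ---------------------------------------------------------------------------
# Conservation classification
# ---------------------------------------------------------------------------


def label_from_presence(
    present: dict[str, bool],
    clades: dict[str, list[str]],
    reference_species: dict[str, str],
    strict_order_conservation: bool = True,
) -> str:
    """Classify one presence/absence pattern.

    ultraconserved: present in every species.  ``<clade>_conserved``:
    present in all members of that clade (or >= 2 with the loose option)
    and absent from every other clade.  ``<taxon>_specific``: present only
    in a clade's designated reference taxon.  Everything else: other.
    """
    taxa = [t for members in clades.values() for t in members]
    for t in present:
        if t not in taxa:
            raise ValueError(f"species {t!r} not assigned to any clade")
    if all(present.get(t, False) for t in taxa):
        return ULTRACONSERVED
    n_present = sum(bool(v) for v in present.values())
    for clade, members in clades.items():
        others = [t for t in taxa if t not in members]
        if any(present.get(t, False) for t in others):
            continue
        in_clade = sum(present.get(t, False) for t in members)
        if strict_order_conservation:
            if in_clade == len(members):
                return f"{clade}_conserved"
        elif in_clade >= 2:
            return f"{clade}_conserved"
        if in_clade == 1:
            ref = reference_species.get(clade)
            if ref is not None and present.get(ref, False):
                return f"{ref}_specific"
    return OTHER


def classify_conservation(
    table: pd.DataFrame,
    clades: dict[str, list[str]],
    reference_species: dict[str, str],
    exclusion_sets: dict[str, pd.DataFrame] | None = None,
    merge_distance: int = 10_000,
    strict_order_conservation: bool = True,
) -> pd.DataFrame:
    """Attach a conservation label to every union boundary row.

    ``exclusion_sets`` maps a reference taxon to outgroup boundary
    intervals (reference coordinates): a boundary specific to that taxon
    but within ``merge_distance`` of an exclusion interval is demoted to
    ``other`` (the outgroup filter applied to human-specific calls).
    """
    species = table_species(table)
    taxa = [t for members in clades.values() for t in members]
    unknown = [sp for sp in species if sp not in taxa]
    if unknown:
        raise ValueError(f"species not in any clade: {unknown}")
    exclusion_sets = exclusion_sets or {}
    labels = []
    for _, row in table.iterrows():
        present = {sp: bool(row[f"present_{sp}"]) for sp in species}
        labels.append(
            label_from_presence(
                present, clades, reference_species, strict_order_conservation
            )
        )
    out = table.copy()
    out["label"] = labels
    for ref, excl in exclusion_sets.items():
        lab = f"{ref}_specific"
        mask = out["label"] == lab
        if not mask.any() or not len(excl):
            continue
        padded = excl.copy()
        padded["start"] = (padded["start"] - merge_distance).clip(lower=0)
        padded["end"] = padded["end"] + merge_distance
        near = overlaps_any(out.loc[mask], padded)
        out.loc[mask[mask].index[near], "label"] = OTHER
    return out


def nway_histogram(table: pd.DataFrame) -> pd.Series:
    """Count of union boundaries by the number of species sharing them."""
    n_species = len(table_species(table))
    counts = table["n_way"].value_counts().reindex(
        range(1, n_species + 1), fill_value=0
    )
    counts.index.name = "n_way"
    return counts


# ---------------------------------------------------------------------------
# Group summaries and matched permutation
# ---------------------------------------------------------------------------


@dataclass
class GroupSummary:
    per_group: pd.DataFrame
    pairwise: pd.DataFrame


def group_summary(
    table: pd.DataFrame,
    reference_species: str,
    genes: pd.DataFrame | None = None,
    ctcf: pd.DataFrame | None = None,
    score_col: str = "score",
) -> GroupSummary:
    """Per-conservation-group statistics on the reference species'
    boundaries: counts and fractions, median insulation score, gene and
    CTCF overlap, plus two-sided Wilcoxon rank-sum tests between every
    pair of labelled groups and each group against all boundaries.
    Groups with fewer than two members report missing statistics.
    """
    ref = table[table[f"present_{reference_species}"]].copy()
    n_ref = len(ref)
    if genes is not None:
        ref["_gene"] = overlaps_any(ref, genes)
    if ctcf is not None:
        ref["_n_ctcf"] = count_overlaps(ref, ctcf)
    groups: dict[str, pd.DataFrame] = {"all": ref}
    for lab, grp in ref.groupby("label"):
        groups[lab] = grp
    rows = []
    for lab, grp in groups.items():
        row = {
            "label": lab,
            "count": len(grp),
            "fraction_of_reference": len(grp) / n_ref if n_ref else np.nan,
        }
        if score_col in grp.columns and len(grp) >= 2:
            row["median_score"] = float(grp[score_col].median())
        else:
            row["median_score"] = np.nan
        row["gene_overlap_fraction"] = (
            float(grp["_gene"].mean()) if genes is not None and len(grp) else np.nan
        )
        if ctcf is not None and len(grp):
            row["ctcf_fraction"] = float((grp["_n_ctcf"] > 0).mean())
            row["ctcf_per_boundary"] = float(grp["_n_ctcf"].mean())
        else:
            row["ctcf_fraction"] = np.nan
            row["ctcf_per_boundary"] = np.nan
        rows.append(row)
    per_group = pd.DataFrame(rows).set_index("label")
    pairs = []
    labels = [l for l in groups if l != "all"]
    if score_col in ref.columns:
        comparisons = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
        comparisons += [(lab, "all") for lab in labels]
        for a, b in comparisons:
            xa = groups[a][score_col].dropna()
            xb = groups[b][score_col].dropna()
            if len(xa) < 2 or len(xb) < 2:
                pairs.append({"group_a": a, "group_b": b, "W": np.nan, "p": np.nan})
                continue
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            pairs.append(
                {"group_a": a, "group_b": b, "W": float(res.statistic), "p": float(res.pvalue)}
            )
    pairwise = pd.DataFrame(pairs, columns=["group_a", "group_b", "W", "p"])
    return GroupSummary(per_group=per_group, pairwise=pairwise)


def matched_insulation_permutation(
    table: pd.DataFrame,
    group_label: str,
    genes: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    score_col: str = "score",
) -> dict:
    """One-tailed permutation test: is the group's median insulation score
    more extreme (lower) than random boundary sets matched on size and on
    the number of gene-overlapping members?

    p = (1 + #{permutation median <= observed median}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    pool = table.dropna(subset=[score_col]).reset_index(drop=True)
    group = pool[pool["label"] == group_label]
    if not len(group):
        raise ValueError(f"group {group_label!r} is empty")
    gene_flag = overlaps_any(pool, genes)
    grp_flag = gene_flag[group.index.to_numpy()]
    k_gene = int(grp_flag.sum())
    k_non = len(group) - k_gene
    gene_idx = np.flatnonzero(gene_flag)
    non_idx = np.flatnonzero(~gene_flag)
    if k_gene > gene_idx.size or k_non > non_idx.size:
        raise ValueError("cannot match gene-overlap composition from the pool")
    scores = pool[score_col].to_numpy(dtype=float)
    observed = float(np.median(scores[group.index.to_numpy()]))
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for t in range(n_perm):
        pick = np.concatenate(
            [
                rng.choice(gene_idx, size=k_gene, replace=False),
                rng.choice(non_idx, size=k_non, replace=False),
            ]
        )
        perm_stats[t] = np.median(scores[pick])
    p = (1 + int((perm_stats <= observed).sum())) / (n_perm + 1)
    return {
        "observed_median": observed,
        "p": p,
        "n_perm": n_perm,
        "perm_medians": perm_stats,
        "n_group": len(group),
        "n_gene_overlapping": k_gene,
    }
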