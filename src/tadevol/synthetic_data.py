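"""Synthetic multi-species Hi-C study generator with known ground truth.

Everything the analysis pipeline consumes can be generated here: TAD
boundary sets evolving by gain and loss on a fixed eight-species phylogeny
(two clades of four, mirroring a primate and a rodent order), contact
matrices with power-law distance decay and planted boundary insulation,
rearranged genomes with known breakpoints, and annotation layers (CTCF
peaks, transposable elements, genes, GC track, chromatin states, and
case/control deletion CNVs).

Boundary identity is tracked by lineage ID through the simulated
phylogeny, so the true cross-species conservation label of every boundary
is known exactly and downstream liftover/merging/classification errors
are measurable.  All randomness flows from one top-level seed through
named substreams, so identical parameters and seed give byte-identical
outputs.

Default turnover rates are calibrated so that the simulated union table
has a study-like composition (roughly 15% ultraconserved and 15%
species-specific of the reference species' boundaries); conserved
lineages carry stronger planted insulation than recently gained ones,
echoing the empirical pattern that older boundaries insulate more
strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import label_from_presence, ULTRACONSERVED
from .io_formats import ContactMatrix, CoordinateMap, MAP_COLUMNS

__all__ = [
    "PhyloNode",
    "PhylogenySpec",
    "EvolutionParams",
    "SimTruth",
    "simulate_boundary_evolution",
    "simulate_contact_matrix",
    "simulate_rearrangement",
    "AnnotationParams",
    "TEFamily",
    "AnnotationSet",
    "simulate_annotations",
]


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class PhyloNode:
    name: str
    length: float = 0.0  # branch length to parent, arbitrary time units
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["PhyloNode"]:
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]


@dataclass
class PhylogenySpec:
    """Rooted binary tree with clade membership and per-clade reference taxa."""

    root: PhyloNode
    clades: dict[str, list[str]]
    reference_species: dict[str, str]

    def __post_init__(self):
        taxa = self.taxa
        assigned = [t for members in self.clades.values() for t in members]
        if sorted(taxa) != sorted(assigned):
            raise ValueError("every taxon must belong to exactly one clade")
        for node in self._walk(self.root):
            if node is not self.root and node.length <= 0:
                raise ValueError(f"branch length of {node.name!r} must be > 0")
            if node.children and len(node.children) != 2:
                raise ValueError("tree must be binary")
        for clade, ref in self.reference_species.items():
            if ref not in self.clades[clade]:
                raise ValueError(f"reference {ref!r} not in clade {clade!r}")

    @property
    def taxa(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    @staticmethod
    def _walk(node):
        yield node
        for ch in node.children:
            yield from PhylogenySpec._walk(ch)

    def depth(self, taxon: str) -> float:
        """Root-to-tip path length for one taxon."""

        def rec(node, acc):
            acc2 = acc + node.length
            if node.is_leaf:
                return acc2 if node.name == taxon else None
            for ch in node.children:
                r = rec(ch, acc2)
                if r is not None:
                    return r
            return None

        d = rec(self.root, -self.root.length)
        if d is None:
            raise ValueError(f"unknown taxon {taxon!r}")
        return d

    @classmethod
    def default(cls) -> "PhylogenySpec":
        """Eight-taxon two-clade study design:
        (((human,(nomascus,hylobates)),rhesus),((mouse,(caroli,pahari)),rat)),
        ultrametric with root-to-tip depth 1."""

        def leaf(name, ln):
            return PhyloNode(name, ln)

        gib = PhyloNode("gibbon_anc", 0.2, [leaf("nomascus", 0.2), leaf("hylobates", 0.2)])
        hg = PhyloNode("hominoid_anc", 0.3, [leaf("human", 0.4), gib])
        primates = PhyloNode("primate_anc", 0.3, [hg, leaf("rhesus", 0.7)])
        mus = PhyloNode("mus_anc", 0.2, [leaf("caroli", 0.2), leaf("pahari", 0.2)])
        mm = PhyloNode("murinae_anc", 0.3, [leaf("mouse", 0.4), mus])
        rodents = PhyloNode("rodent_anc", 0.3, [mm, leaf("rat", 0.7)])
        root = PhyloNode("root", 0.0, [primates, rodents])
        return cls(
            root=root,
            clades={
                "primate": ["human", "nomascus", "hylobates", "rhesus"],
                "rodent": ["mouse", "caroli", "pahari", "rat"],
            },
            reference_species={"primate": "human", "rodent": "mouse"},
        )


# ---------------------------------------------------------------------------
# Boundary gain/loss evolution
# ---------------------------------------------------------------------------


@dataclass
class EvolutionParams:
    """Controls for boundary turnover on the tree.

    ``gain_rate`` is events per bp of genome per unit branch length;
    ``loss_rate`` is per boundary per unit branch length.  ``min_spacing``
    keeps boundaries apart, reflecting that TADs occupy at least ~100 Kb.
    Strength ranges give the planted cross-boundary attenuation
    multiplier (lower = stronger insulation); ancestral lineages are
    drawn stronger than newly gained ones.
    """

    n_boundaries_root: int = 80
    gain_rate: float = 4.9e-7
    loss_rate: float = 0.42
    genome_length: int = 60_000_000
    boundary_width: int = 10_000
    min_spacing: int = 120_000
    strength_range_root: tuple[float, float] = (0.10, 0.20)
    strength_range_gained: tuple[float, float] = (0.20, 0.35)
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.genome_length < 10 * self.boundary_width:
            raise ValueError("genome_length must be >= 10 x boundary_width")


@dataclass
class SimTruth:
    """Exact ground truth of a boundary-evolution simulation."""

    lineage_positions: dict[str, int]  # lineage id -> start bp on the root genome
    lineage_strength: dict[str, float]
    presence: pd.DataFrame  # lineages x taxa, bool
    labels: pd.Series  # lineage id -> true conservation label
    breakpoints: dict[str, pd.DataFrame] = field(default_factory=dict)

    def check_consistency(
        self, clades: dict[str, list[str]], reference_species: dict[str, str]
    ) -> bool:
        """Every stored label equals the label recomputed from presence."""
        for lid in self.presence.index:
            present = self.presence.loc[lid].to_dict()
            if label_from_presence(present, clades, reference_species) != self.labels[lid]:
                return False
        return True


def _place_position(rng, occupied: list[int], params: EvolutionParams) -> int:
    """Draw a boundary start keeping min_spacing from occupied starts;
    reject-sample up to 1000 times."""
    lo, hi = 0, params.genome_length - params.boundary_width
    for _ in range(1000):
        pos = int(rng.integers(lo, hi + 1))
        if all(abs(pos - q) >= params.min_spacing for q in occupied):
            return pos
    raise RuntimeError("genome too small to place non-overlapping boundaries")


def simulate_boundary_evolution(
    tree: PhylogenySpec, params: EvolutionParams
) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """Evolve boundaries along the tree by Poisson gain and exponential loss.

    Ancestral boundaries keep a shared lineage ID down every branch, so
    the true n-way conservation of each union boundary is known.  Gains
    are uniform in position (subject to spacing); each new lineage gets a
    fixed genomic position shared by all descendants, i.e. boundary
    turnover, not movement, is modelled.  Returns per-taxon boundary
    tables (chrom/start/end/name/strength) and the SimTruth record.
    """
    ss = np.random.SeedSequence(params.seed)
    root_rng = np.random.default_rng(ss.spawn(1)[0])
    positions: dict[str, int] = {}
    strengths: dict[str, float] = {}
    occupied: list[int] = []
    lineage_counter = [0]

    def new_lineage(rng, strength_range) -> str:
        lid = f"L{lineage_counter[0]:05d}"
        lineage_counter[0] += 1
        pos = _place_position(rng, occupied, params)
        occupied.append(pos)
        positions[lid] = pos
        strengths[lid] = float(rng.uniform(*strength_range))
        return lid

    root_set = [new_lineage(root_rng, params.strength_range_root) for _ in range(params.n_boundaries_root)]

    tip_sets: dict[str, list[str]] = {}

    def descend(node: PhyloNode, current: list[str], seq: np.random.SeedSequence):
        child_seqs = seq.spawn(max(len(node.children), 1))
        if node.is_leaf:
            tip_sets[node.name] = list(current)
            return
        for ch, cseq in zip(node.children, child_seqs):
            rng = np.random.default_rng(cseq)
            t = ch.length
            survive_p = np.exp(-params.loss_rate * t)
            kept = [lid for lid in current if rng.random() < survive_p]
            n_gain = rng.poisson(params.gain_rate * params.genome_length * t)
            gained = [
                new_lineage(rng, params.strength_range_gained) for _ in range(n_gain)
            ]
            descend(ch, kept + gained, cseq.spawn(1)[0])

    descend(tree.root, root_set, ss.spawn(2)[1])

    taxa = tree.taxa
    all_lineages = sorted(positions)
    presence = pd.DataFrame(
        {tx: [lid in set(tip_sets[tx]) for lid in all_lineages] for tx in taxa},
        index=all_lineages,
    )
    # drop lineages that died out before reaching any tip
    alive = presence.any(axis=1)
    presence = presence[alive]
    labels = pd.Series(
        {
            lid: label_from_presence(
                presence.loc[lid].to_dict(), tree.clades, tree.reference_species
            )
            for lid in presence.index
        },
        name="label",
    )
    boundary_sets = {}
    for tx in taxa:
        lids = sorted(tip_sets[tx], key=lambda l: positions[l])
        boundary_sets[tx] = pd.DataFrame(
            {
                "chrom": params.chrom,
                "start": [positions[l] for l in lids],
                "end": [positions[l] + params.boundary_width for l in lids],
                "name": lids,
                "strength": [strengths[l] for l in lids],
            }
        )
    truth = SimTruth(
        lineage_positions={l: positions[l] for l in presence.index},
        lineage_strength={l: strengths[l] for l in presence.index},
        presence=presence,
        labels=labels,
    )
    return boundary_sets, truth


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------


def simulate_contact_matrix(
    boundaries: pd.DataFrame,
    chrom_length: int,
    bin_size: int = 10_000,
    decay_exponent: float = 1.0,
    base_count: float = 100.0,
    noise: str = "poisson",
    seed: int = 0,
    chrom: str = "chr1",
) -> ContactMatrix:
    """Power-law decay Hi-C matrix with planted boundary insulation.

    The expected count for bins ``i < j`` is
    ``A * (j - i) ** (-alpha)`` attenuated by the product of the
    strengths ``s`` of every boundary lying strictly between the two bins
    (a pair crosses the boundary in bin ``k`` iff ``i < k <= j``).  The
    diagonal is ``A``.  With ``noise="poisson"`` counts are Poisson
    samples of the expectation (symmetrised from the upper triangle).
    """
    if chrom_length % bin_size:
        raise ValueError("bin_size must divide chrom_length")
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be > 0")
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")
    n = chrom_length // bin_size
    if len(boundaries):
        s = boundaries["strength"].to_numpy(dtype=float)
        if ((s <= 0) | (s > 1)).any():
            raise ValueError("boundary strengths must be in (0, 1]")
        centers = ((boundaries["start"] + boundaries["end"]) // 2).to_numpy()
        bbins = (centers // bin_size).astype(int)
    else:
        s = np.empty(0)
        bbins = np.empty(0, dtype=int)
    # cumulative log-attenuation: logatt[k] = sum of log s over boundaries with bin <= k
    logatt = np.zeros(n)
    for b, sv in zip(bbins, s):
        if 0 <= b < n:
            logatt[b:] += np.log(sv)
    i = np.arange(n)
    d1 = np.arange(n, dtype=float)
    with np.errstate(divide="ignore"):
        decay1d = np.where(d1 > 0, d1 ** (-decay_exponent), 1.0)
    decay = decay1d[np.abs(i[:, None] - i[None, :])]
    # attenuation for pair (i, j), i<j: exp(logatt[j] - logatt[i]); logatt is
    # non-increasing so this is exp(-|logatt[i] - logatt[j]|)
    att = np.exp(-np.abs(logatt[:, None] - logatt[None, :]))
    expected = base_count * decay * att
    np.fill_diagonal(expected, base_count)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        upper = np.triu(rng.poisson(expected).astype(float))
        counts = upper + np.triu(upper, 1).T
    else:
        counts = expected
    return ContactMatrix(chrom, bin_size, counts)


# ---------------------------------------------------------------------------
# Genome rearrangement
# ---------------------------------------------------------------------------


def simulate_rearrangement(
    map_length: int,
    n_events: int,
    event_mix: tuple[float, float] = (0.5, 0.5),
    min_block: int = 100_000,
    seed: int = 0,
    src_chrom: str = "chrD",
    dst_chrom: str = "chrR",
) -> tuple[CoordinateMap, pd.DataFrame]:
    """Derive a rearranged genome by random inversions and translocations.

    Returns a bijective piecewise coordinate map from the derived genome
    (``src``) to the ancestral/reference genome (``dst``) plus the true
    breakpoints: the non-collinear block junctions in the derived genome.
    ``event_mix`` gives (inversion, translocation) proportions.
    """
    if n_events * 2 * min_block >= map_length:
        raise ValueError("map_length too small for n_events at min_block")
    rng = np.random.default_rng(seed)
    # derived genome as ordered (ref_start, ref_end, strand) segments
    segments: list[tuple[int, int, str]] = [(0, map_length, "+")]
    p_inv = event_mix[0] / (event_mix[0] + event_mix[1])
    for _ in range(n_events):
        kind = "inversion" if rng.random() < p_inv else "translocation"
        segments = _apply_event(rng, segments, kind, map_length, min_block)
    segments = _merge_collinear(segments)
    rows = []
    bps = []
    dpos = 0
    for k, (rs, re, strand) in enumerate(segments):
        length = re - rs
        rows.append(
            {
                "src_chrom": src_chrom,
                "src_start": dpos,
                "src_end": dpos + length,
                "dst_chrom": dst_chrom,
                "dst_start": rs,
                "dst_end": re,
                "strand": strand,
                "score": float(length),
                "chain_id": k,
            }
        )
        dpos += length
        if k + 1 < len(segments):
            bps.append({"chrom": src_chrom, "pos": dpos})
    cmap = CoordinateMap(pd.DataFrame(rows, columns=list(MAP_COLUMNS)))
    breakpoints = pd.DataFrame(bps, columns=["chrom", "pos"])
    return cmap, breakpoints


def _cut(segments, pos):
    """Split the segment list at derived coordinate pos."""
    out = []
    d = 0
    for rs, re, st in segments:
        ln = re - rs
        if d < pos < d + ln:
            off = pos - d
            if st == "+":
                out.append((rs, rs + off, st))
                out.append((rs + off, re, st))
            else:
                out.append((re - off, re, st))
                out.append((rs, re - off, st))
        else:
            out.append((rs, re, st))
        d += ln
    return out


def _segment_index_range(segments, lo, hi):
    """Indices of segments fully inside derived [lo, hi) (cuts done first)."""
    idx = []
    d = 0
    for k, (rs, re, st) in enumerate(segments):
        ln = re - rs
        if d >= lo and d + ln <= hi:
            idx.append(k)
        d += ln
    return idx


def _apply_event(rng, segments, kind, map_length, min_block):
    for _ in range(1000):
        a, b = sorted(rng.integers(min_block, map_length - min_block + 1, size=2))
        if b - a < min_block:
            continue
        segs = _cut(_cut(segments, a), b)
        inside = _segment_index_range(segs, a, b)
        if not inside:
            continue
        if kind == "inversion":
            mid = [
                (rs, re, "-" if st == "+" else "+")
                for rs, re, st in reversed([segs[k] for k in inside])
            ]
            return segs[: inside[0]] + mid + segs[inside[-1] + 1 :]
        # translocation: excise [a, b) and reinsert at a random outside cut
        for _ in range(100):
            c = int(rng.integers(0, map_length + 1))
            if c <= a or c >= b:
                break
        else:
            continue
        segs = _cut(segs, c)
        inside = _segment_index_range(segs, a, b)
        moved = [segs[k] for k in inside]
        rest = [sgl for k, sgl in enumerate(segs) if k not in inside]
        # locate insertion slot in the remaining sequence
        d = 0
        slot = len(rest)
        c_eff = c if c <= a else c - (b - a)
        for k, (rs, re, st) in enumerate(rest):
            if d >= c_eff:
                slot = k
                break
            d += re - rs
        else:
            slot = len(rest)
        return rest[:slot] + moved + rest[slot:]
    raise RuntimeError("failed to draw a rearrangement event")


def _merge_collinear(segments):
    out = []
    for seg in segments:
        if out:
            rs, re, st = out[-1]
            if st == seg[2] and st == "+" and seg[0] == re:
                out[-1] = (rs, seg[1], st)
                continue
            if st == seg[2] and st == "-" and seg[1] == rs:
                out[-1] = (seg[0], re, st)
                continue
        out.append(seg)
    return [s for s in out if s[1] > s[0]]


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class TEFamily:
    name: str
    te_class: str
    n_copies: int
    length: int


DEFAULT_TE_FAMILIES = (
    TEFamily("MIR", "SINE", 400, 200),       # old SINE family
    TEFamily("B1", "SINE", 400, 150),
    TEFamily("L1", "LINE", 200, 900),
    TEFamily("ERV-K", "LTR", 200, 500),      # young LTR family
    TEFamily("Charlie", "DNA", 150, 300),
)


@dataclass
class AnnotationParams:
    """Controls for the annotation layers.

    ``ctcf_at_boundary_prob`` is the chance a boundary receives a CTCF
    peak (echoing that under half of real boundaries carry one);
    ``te_planting_prob_old``/``_young`` plant the old family (MIR) on
    CTCF peaks inside ultraconserved boundaries and the young family
    (ERV-K) on peaks inside species-specific ones — set both to 0 for a
    null configuration.  ``cnv_case_frac``/``cnv_ctrl_frac`` are the
    per-boundary deletion probabilities for species-specific boundaries
    in the case and control cohorts (defaults echo the observed 335/1130
    vs 161/1130 recurrence).
    """

    ctcf_at_boundary_prob: float = 0.5
    ctcf_background_rate: float = 5e-6  # peaks per bp
    ctcf_peak_width: int = 200
    te_families: tuple[TEFamily, ...] = DEFAULT_TE_FAMILIES
    old_family: str = "MIR"
    young_family: str = "ERV-K"
    te_planting_prob_old: float = 0.5
    te_planting_prob_young: float = 0.5
    gene_density: float = 1.5e-5  # genes per bp
    gene_length: int = 20_000
    gc_baseline: float = 0.41
    gc_amplitude: float = 0.05
    gc_window: int = 1_000
    gc_smooth_windows: int = 50
    state_names: tuple[str, ...] = ("Tss", "Enh", "Tx", "Ctcf", "Quies")
    state_mean_length: int = 10_000
    cnv_case_frac: float = 335 / 1130
    cnv_ctrl_frac: float = 161 / 1130
    cnv_background_n: int = 50
    cnv_length: int = 50_000

    def __post_init__(self):
        for p in (
            self.ctcf_at_boundary_prob,
            self.te_planting_prob_old,
            self.te_planting_prob_young,
            self.cnv_case_frac,
            self.cnv_ctrl_frac,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class AnnotationSet:
    ctcf: pd.DataFrame
    te: pd.DataFrame
    genes: pd.DataFrame
    gc: pd.DataFrame
    states: pd.DataFrame
    cnv_case: pd.DataFrame
    cnv_control: pd.DataFrame


def _uniform_intervals(rng, n, length, genome_length, chrom, prefix):
    if n <= 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    starts = np.sort(rng.integers(0, max(genome_length - length, 1), size=n))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + length,
            "name": [f"{prefix}{k}" for k in range(n)],
        }
    )


def simulate_annotations(
    boundaries: pd.DataFrame,
    genome_length: int,
    params: AnnotationParams | None = None,
    seed: int = 0,
    chrom: str = "chr1",
    specific_labels: tuple[str, ...] | None = None,
) -> AnnotationSet:
    """Generate annotation layers consistent with a labelled boundary set.

    ``boundaries`` must carry chrom/start/end and a ``label`` column with
    conservation labels.  ``specific_labels`` names the labels treated as
    species-specific for TE planting and CNV recurrence (defaults to any
    label ending in ``_specific``).
    """
    params = params or AnnotationParams()
    rng_master = np.random.SeedSequence(seed)
    (r_ctcf, r_te, r_gene, r_gc, r_state, r_cnv) = (
        np.random.default_rng(s) for s in rng_master.spawn(6)
    )
    if specific_labels is None:
        specific_labels = tuple(
            sorted({l for l in boundaries.get("label", pd.Series(dtype=str)) if str(l).endswith("_specific")})
        )

    # --- CTCF peaks: at boundaries with stated probability + background
    w = params.ctcf_peak_width
    rows = []
    peak_label = []
    for _, b in boundaries.iterrows():
        if r_ctcf.random() < params.ctcf_at_boundary_prob:
            lo = int(b["start"])
            hi = max(int(b["end"]) - w, lo + 1)
            s = int(r_ctcf.integers(lo, hi))
            rows.append((chrom, s, s + w))
            peak_label.append(b.get("label", ""))
    n_bg = r_ctcf.poisson(params.ctcf_background_rate * genome_length)
    for _ in range(n_bg):
        s = int(r_ctcf.integers(0, genome_length - w))
        rows.append((chrom, s, s + w))
        peak_label.append("")
    ctcf = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    ctcf["name"] = [f"ctcf{k}" for k in range(len(ctcf))]
    ctcf = ctcf.sort_values("start").reset_index(drop=True)

    # --- TEs: uniform background per family + label-directed planting
    te_rows = []
    fam_by_name = {f.name: f for f in params.te_families}
    for f in params.te_families:
        df = _uniform_intervals(r_te, f.n_copies, f.length, genome_length, chrom, f"{f.name}_")
        df["class"] = f.te_class
        df["family"] = f.name
        te_rows.append(df)
    planted = []
    btree = boundaries.reset_index(drop=True)
    lab_order = list(zip(rows, peak_label))
    for (c, s, e), lab in lab_order:
        fam = None
        if lab == ULTRACONSERVED and r_te.random() < params.te_planting_prob_old:
            fam = fam_by_name.get(params.old_family)
        elif lab in specific_labels and r_te.random() < params.te_planting_prob_young:
            fam = fam_by_name.get(params.young_family)
        if fam is not None:
            off = int(r_te.integers(0, max(fam.length - w, 1)))
            ts = max(s - off, 0)
            planted.append(
                {
                    "chrom": chrom,
                    "start": ts,
                    "end": ts + fam.length,
                    "name": f"{fam.name}_p{len(planted)}",
                    "class": fam.te_class,
                    "family": fam.name,
                }
            )
    if planted:
        te_rows.append(pd.DataFrame(planted))
    te = pd.concat(te_rows, ignore_index=True).sort_values("start").reset_index(drop=True)

    # --- genes
    n_genes = r_gene.poisson(params.gene_density * genome_length)
    genes = _uniform_intervals(r_gene, n_genes, params.gene_length, genome_length, chrom, "gene")

    # --- GC track: smoothed gaussian field around the baseline
    n_win = genome_length // params.gc_window
    raw = r_gc.normal(0, 1, size=n_win + params.gc_smooth_windows)
    kernel = np.ones(params.gc_smooth_windows) / params.gc_smooth_windows
    smooth = np.convolve(raw, kernel, mode="valid")[:n_win]
    sd = smooth.std()
    gc_vals = params.gc_baseline + params.gc_amplitude * (smooth / sd if sd > 0 else smooth)
    gc_vals = np.clip(gc_vals, 0.2, 0.8)
    gc = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_win) * params.gc_window,
            "end": (np.arange(n_win) + 1) * params.gc_window,
            "value": gc_vals,
        }
    )

    # --- chromatin states: random partition with exponential segment lengths
    segs = []
    pos = 0
    while pos < genome_length:
        ln = max(int(r_state.exponential(params.state_mean_length)), 500)
        state = params.state_names[int(r_state.integers(0, len(params.state_names)))]
        segs.append((chrom, pos, min(pos + ln, genome_length), state))
        pos += ln
    states = pd.DataFrame(segs, columns=["chrom", "start", "end", "name"])

    # --- CNVs: per species-specific boundary, cohort-specific deletion odds
    spec = btree[btree.get("label", pd.Series(dtype=str)).isin(specific_labels)]
    cnv_case_rows, cnv_ctrl_rows = [], []
    L = params.cnv_length
    for _, b in spec.iterrows():
        mid = (int(b["start"]) + int(b["end"])) // 2
        if r_cnv.random() < params.cnv_case_frac:
            cnv_case_rows.append((chrom, max(mid - L // 2, 0), mid + L // 2))
        if r_cnv.random() < params.cnv_ctrl_frac:
            cnv_ctrl_rows.append((chrom, max(mid - L // 2, 0), mid + L // 2))
    for target, n in ((cnv_case_rows, params.cnv_background_n), (cnv_ctrl_rows, params.cnv_background_n)):
        for _ in range(n):
            s = int(r_cnv.integers(0, max(genome_length - L, 1)))
            target.append((chrom, s, s + L))
    cnv_case = pd.DataFrame(cnv_case_rows, columns=["chrom", "start", "end"])
    cnv_ctrl = pd.DataFrame(cnv_ctrl_rows, columns=["chrom", "start", "end"])
    return AnnotationSet(
        ctcf=ctcf,
        te=te,
        genes=genes,
        gc=gc,
        states=states,
        cnv_case=cnv_case.sort_values("start").reset_index(drop=True),
        cnv_control=cnv_ctrl.sort_values("start").reset_index(drop=True),
    )
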