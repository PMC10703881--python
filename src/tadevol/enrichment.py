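"""Annotation enrichment at boundary conservation groups.

Three statistics: transposable-element class/family enrichment at CTCF
sites inside boundaries of each conservation group (exact binomial test
against the genome-coverage expectation), chromatin-state fold enrichment
over boundary groups, and deletion-CNV recurrence at one boundary group
in a case versus a control cohort (Fisher's exact test).

Following the source analyses, no multiple-testing correction is applied
by default; Benjamini-Hochberg is available via a flag.  The primary TE
test is the exact binomial; an overdispersed (negative-binomial-style)
variant is available for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import (
    largest_overlap_label,
    overlap_bp,
    overlaps_any,
    total_coverage,
)
from .synteny import EnrichmentResult

__all__ = [
    "te_ctcf_enrichment",
    "chromatin_state_fold_enrichment",
    "cnv_recurrence_test",
    "binom_two_sided",
]


def binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p by tail doubling:
    min(1, 2 * min(P(X <= k), P(X >= k)))."""
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return float(min(1.0, 2 * min(lower, upper)))


def _binom_overdispersed(k: int, n: int, p: float, dispersion: float) -> float:
    """Beta-binomial tail-doubled p for overdispersed counts;
    ``dispersion`` > 0 is the overdispersion parameter (rho)."""
    rho = dispersion
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    lower = stats.betabinom.cdf(k, n, a, b)
    upper = stats.betabinom.sf(k - 1, n, a, b)
    return float(min(1.0, 2 * min(lower, upper)))


def te_ctcf_enrichment(
    boundary_groups: dict[str, pd.DataFrame],
    ctcf: pd.DataFrame,
    te: pd.DataFrame,
    genome_size: int,
    by: str = "family",
    bh_correct: bool = False,
    overdispersion: float | None = None,
) -> pd.DataFrame:
    """TE class/family enrichment at boundary CTCF sites, per group.

    CTCF peaks are assigned to a group by >= 1 bp overlap with its
    boundaries; each peak is labelled by the TE with the largest overlap
    (ties to the earliest interval).  For a unit covering fraction ``f``
    of the genome, the expected number of labelled peaks among ``n``
    group peaks is ``n * f``; significance is the two-sided exact
    binomial (or beta-binomial when ``overdispersion`` is set).  Also
    reports the fraction of group boundaries containing >= 1 CTCF site
    overlapping the unit.  ``by`` selects "class" or "family" units.
    """
    if by not in ("class", "family"):
        raise ValueError("by must be 'class' or 'family'")
    units = sorted(te[by].dropna().unique())
    unit_cov = {
        u: total_coverage(te[te[by] == u]) for u in units
    }
    peak_te = largest_overlap_label(ctcf, te, [by])
    rows = []
    for group, bounds in boundary_groups.items():
        if not len(bounds):
            continue
        in_group = overlaps_any(ctcf, bounds)
        n_peaks = int(in_group.sum())
        if n_peaks == 0:
            continue
        labels = peak_te[by][in_group]
        for u in units:
            frac = unit_cov[u] / genome_size
            obs = int((labels == u).sum())
            exp = n_peaks * frac
            if overdispersion:
                p = _binom_overdispersed(obs, n_peaks, frac, overdispersion)
                test = "betabinom_two_sided"
            else:
                p = binom_two_sided(obs, n_peaks, frac)
                test = "binom_two_sided"
            peaks_u = ctcf[in_group][(labels == u).to_numpy()]
            b_frac = (
                float(overlaps_any(bounds, peaks_u).mean()) if len(peaks_u) else 0.0
            )
            rows.append(
                {
                    "group": group,
                    "unit": u,
                    "level": by,
                    "observed": obs,
                    "expected": exp,
                    "obs_exp": obs / exp if exp > 0 else np.nan,
                    "n_peaks": n_peaks,
                    "boundary_fraction_with_unit_ctcf": b_frac,
                    "test": test,
                    "p": p,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "group",
            "unit",
            "level",
            "observed",
            "expected",
            "obs_exp",
            "n_peaks",
            "boundary_fraction_with_unit_ctcf",
            "test",
            "p",
        ],
    )
    if bh_correct and len(out):
        out["q"] = stats.false_discovery_control(out["p"])
    out["stars"] = [
        "***" if p < 0.0005 else "**" if p < 0.005 else "*" if p < 0.05 else ""
        for p in out["p"]
    ]
    return out


def chromatin_state_fold_enrichment(
    states: pd.DataFrame,
    boundary_groups: dict[str, pd.DataFrame],
    genome_size: int,
) -> pd.DataFrame:
    """Fold enrichment of each chromatin state within each boundary group:

    fold(u, g) = (bp of state u inside group-g boundaries / group-g bp)
               / (bp of u genome-wide / genome size).

    States absent genome-wide report NaN.
    """
    state_names = sorted(states["name"].dropna().unique()) if len(states) else []
    if not state_names:
        return pd.DataFrame(index=pd.Index([], name="state"))
    rows = []
    for group, bounds in boundary_groups.items():
        group_bp = int((bounds["end"] - bounds["start"]).sum())
        for u in state_names:
            su = states[states["name"] == u]
            genome_bp = total_coverage(su)
            if genome_bp == 0 or group_bp == 0:
                fold = np.nan
            else:
                inside = int(overlap_bp(bounds, su).sum())
                fold = (inside / group_bp) / (genome_bp / genome_size)
            rows.append({"group": group, "state": u, "fold": fold})
    return pd.DataFrame(rows).pivot(index="state", columns="group", values="fold")


def cnv_recurrence_test(
    boundaries: pd.DataFrame,
    case_cnvs: pd.DataFrame,
    control_cnvs: pd.DataFrame,
) -> EnrichmentResult:
    """Fisher's exact test of deletion recurrence at one boundary group.

    A boundary counts as deleted in a cohort iff >= 1 deletion CNV of
    that cohort overlaps it by >= 1 bp; the 2x2 table compares deleted
    vs intact over the same N boundaries in the two cohorts.
    """
    n = len(boundaries)
    if n == 0:
        raise ValueError("no boundaries to test")
    del_case = int(overlaps_any(boundaries, case_cnvs).sum())
    del_ctrl = int(overlaps_any(boundaries, control_cnvs).sum())
    table = np.array([[del_case, n - del_case], [del_ctrl, n - del_ctrl]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        unit="cnv_recurrence",
        observed=del_case,
        expected=del_ctrl,
        ratio=del_case / del_ctrl if del_ctrl else np.nan,
        test="fisher_exact",
        p=float(p),
        extra={"table": table, "odds_ratio": float(odds), "n_boundaries": n},
    )
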