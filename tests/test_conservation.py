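"""Liftover, union-boundary construction, conservation classification and
group statistics."""

import numpy as np
import pandas as pd
import pytest

from tadevol.conservation import (
    build_union,
    classify_conservation,
    group_summary,
    label_from_presence,
    liftover,
    matched_insulation_permutation,
    nway_histogram,
)
from tadevol.io_formats import CoordinateMap, identity_map
from tadevol.synthetic_data import (
    EvolutionParams,
    simulate_boundary_evolution,
    simulate_rearrangement,
)

from conftest import per_base_map_oracle, union_components_oracle


def iv(chrom, start, end, name=None, **extra):
    row = {"chrom": chrom, "start": start, "end": end}
    if name is not None:
        row["name"] = name
    row.update(extra)
    return row


class TestLiftover:
    def test_identity_map_is_identity(self):
        imap = identity_map("chr1", 1_000_000)
        ivs = pd.DataFrame([iv("chr1", 100, 5000, "a"), iv("chr1", 9000, 9100, "b")])
        lifted, failed = liftover(ivs, imap)
        assert failed == []
        assert lifted[["start", "end"]].values.tolist() == [[100, 5000], [9000, 9100]]

    def test_large_gap_fails_interval(self):
        blocks = pd.DataFrame(
            [
                dict(src_chrom="chr1", src_start=0, src_end=4000, dst_chrom="chrX",
                     dst_start=0, dst_end=4000, strand="+", score=1.0, chain_id=0),
                dict(src_chrom="chr1", src_start=6000, src_end=10_000, dst_chrom="chrX",
                     dst_start=6000, dst_end=10_000, strand="+", score=1.0, chain_id=0),
            ]
        )
        cmap = CoordinateMap(blocks)
        ivs = pd.DataFrame([iv("chr1", 3000, 7000, "straddle")])
        lifted, failed = liftover(ivs, cmap, min_match=0.95)
        assert failed == ["straddle"]  # only 2000 of 4000 bases map
        lifted, failed = liftover(ivs, cmap, min_match=0.25)
        assert failed == [] and len(lifted) == 1

    def test_inverted_map_matches_per_base_oracle(self):
        cmap, _ = simulate_rearrangement(
            10_000, 1, event_mix=(1, 0), min_block=1_000, seed=3
        )
        oracle = per_base_map_oracle(cmap)
        ivs = pd.DataFrame([iv("chrD", s, s + 500, f"x{s}") for s in range(0, 9500, 700)])
        lifted, failed = liftover(ivs, cmap, min_match=1.0)
        for _, row in lifted.iterrows():
            src0 = int(row["name"][1:])
            dst = sorted(
                oracle[("chrD", p)][1] for p in range(src0, src0 + 500)
            )
            assert row["start"] == dst[0]
            assert row["end"] == dst[-1] + 1

    def test_failures_reported_not_dropped_silently(self):
        imap = identity_map("chr1", 1000)
        ivs = pd.DataFrame([iv("chr2", 0, 100, "off")])
        lifted, failed = liftover(ivs, imap)
        assert failed == ["off"] and len(lifted) == 0


class TestUnion:
    def test_gap_5kb_merges(self):
        table = build_union(
            {
                "A": pd.DataFrame([iv("chr1", 100_000, 110_000, "a1")]),
                "B": pd.DataFrame([iv("chr1", 115_000, 125_000, "b1")]),
            }
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert row["present_A"] and row["present_B"] and row["n_way"] == 2
        assert (row["start"], row["end"]) == (100_000, 125_000)

    def test_gap_11kb_stays_split(self):
        table = build_union(
            {
                "A": pd.DataFrame([iv("chr1", 100_000, 110_000, "a1")]),
                "B": pd.DataFrame([iv("chr1", 121_000, 131_000, "b1")]),
            }
        )
        assert len(table) == 2

    def test_single_linkage_chain_spans_more_than_threshold(self):
        table = build_union(
            {
                "A": pd.DataFrame([iv("chr1", 0, 10_000, "a")]),
                "B": pd.DataFrame([iv("chr1", 18_000, 28_000, "b")]),
                "C": pd.DataFrame([iv("chr1", 36_000, 46_000, "c")]),
            }
        )
        assert len(table) == 1
        assert table.iloc[0]["n_way"] == 3

    def test_matches_transitive_closure_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            starts = rng.integers(0, 500_000, size=n)
            df = pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], size=n),
                    "start": starts,
                    "end": starts + rng.integers(1_000, 15_000, size=n),
                    "name": [f"iv{k}" for k in range(n)],
                    "species": rng.choice(["A", "B", "C"], size=n),
                }
            )
            sets = {sp: g.drop(columns="species") for sp, g in df.groupby("species")}
            table = build_union(sets, merge_distance=10_000)
            comps = union_components_oracle(df, 10_000)
            assert len(table) == len(comps)

    def test_permutation_invariance_and_idempotence(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.integers(0, 300_000, size=12))
        sets = {
            "A": pd.DataFrame([iv("chr1", int(s), int(s) + 8_000, f"a{k}") for k, s in enumerate(starts[::2])]),
            "B": pd.DataFrame([iv("chr1", int(s), int(s) + 8_000, f"b{k}") for k, s in enumerate(starts[1::2])]),
        }
        t1 = build_union(sets)
        t2 = build_union(dict(reversed(sets.items())))
        assert t1[["chrom", "start", "end", "n_way"]].equals(
            t2[["chrom", "start", "end", "n_way"]]
        )
        again = build_union({"U": t1})
        assert again[["start", "end"]].values.tolist() == t1[["start", "end"]].values.tolist()

    def test_merge_distance_zero_keeps_separate(self):
        table = build_union(
            {
                "A": pd.DataFrame([iv("chr1", 0, 10_000, "a")]),
                "B": pd.DataFrame([iv("chr1", 10_001, 20_000, "b")]),
            },
            merge_distance=0,
        )
        assert len(table) == 2


def make_table(vectors, species, start_step=100_000):
    rows = []
    for k, vec in enumerate(vectors):
        row = {"chrom": "chr1", "start": k * start_step, "end": k * start_step + 10_000}
        for sp, bit in zip(species, vec):
            row[f"present_{sp}"] = bool(int(bit))
        row["n_way"] = sum(int(b) for b in vec)
        row["members"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


SPECIES = ["human", "nomascus", "hylobates", "rhesus", "mouse", "caroli", "pahari", "rat"]
CLADES = {"primate": SPECIES[:4], "rodent": SPECIES[4:]}
REFS = {"primate": "human", "rodent": "mouse"}


class TestClassify:
    @pytest.mark.parametrize(
        "vector,label",
        [
            ("11111111", "ultraconserved"),
            ("11110000", "primate_conserved"),
            ("00001111", "rodent_conserved"),
            ("10000000", "human_specific"),
            ("00001000", "mouse_specific"),
            ("11100000", "other"),  # strict order conservation
            ("10001000", "other"),
            ("01000000", "other"),  # non-reference singleton
        ],
    )
    def test_presence_patterns(self, vector, label):
        table = classify_conservation(make_table([vector], SPECIES), CLADES, REFS)
        assert table["label"].iloc[0] == label

    def test_loose_order_conservation_option(self):
        table = classify_conservation(
            make_table(["11100000"], SPECIES), CLADES, REFS,
            strict_order_conservation=False,
        )
        assert table["label"].iloc[0] == "primate_conserved"

    def test_exclusion_set_demotes_species_specific(self):
        table = make_table(["10000000", "10000000"], SPECIES)
        # second row is near a chimp boundary
        excl = pd.DataFrame([iv("chr1", 105_000, 115_000)])
        out = classify_conservation(table, CLADES, REFS, exclusion_sets={"human": excl})
        assert out["label"].tolist() == ["human_specific", "other"]

    def test_unknown_species_rejected(self):
        table = make_table(["1"], ["yeti"])
        with pytest.raises(ValueError, match="yeti"):
            classify_conservation(table, CLADES, REFS)

    def test_nway_histogram_counts(self):
        table = make_table(["11111111", "11110000", "10000000"], SPECIES)
        hist = nway_histogram(table)
        assert hist[8] == 1 and hist[4] == 1 and hist[1] == 1 and hist.sum() == 3

    def test_truth_labels_recovered_with_perfect_boundaries(self, tree):
        """Classifying the simulated truth through the real union/classify
        path (perfect liftover) reproduces every true label."""
        params = EvolutionParams(
            gain_rate=8e-7, loss_rate=0.4, seed=5,
            genome_length=10_000_000, min_spacing=60_000, n_boundaries_root=40,
        )
        sets, truth = simulate_boundary_evolution(tree, params)
        table = build_union(sets)
        table = classify_conservation(table, tree.clades, tree.reference_species)
        pos = pd.Series(truth.lineage_positions)
        ok = 0
        for lid in truth.presence.index:
            mid = pos[lid] + 5_000
            sel = table[(table["start"] <= mid) & (table["end"] >= mid)]
            assert len(sel) == 1
            if sel["label"].iloc[0] == truth.labels[lid]:
                ok += 1
        assert ok == len(truth.presence)


class TestGroupSummary:
    def _table_with_scores(self, scores_by_label):
        rows = []
        k = 0
        for lab, scores in scores_by_label.items():
            for s in scores:
                rows.append(
                    {
                        "chrom": "chr1",
                        "start": k * 100_000,
                        "end": k * 100_000 + 10_000,
                        "present_human": True,
                        "n_way": 1,
                        "members": "",
                        "label": lab,
                        "score": s,
                    }
                )
                k += 1
        return pd.DataFrame(rows)

    def test_identical_distributions_p_near_one(self):
        t = self._table_with_scores({"a": [1, 2, 3], "b": [1, 2, 3]})
        summ = group_summary(t, "human")
        p = summ.pairwise.set_index(["group_a", "group_b"]).at[("a", "b"), "p"]
        assert p == pytest.approx(1.0, abs=0.05)

    def test_separated_distributions_exact_p(self):
        t = self._table_with_scores({"a": [1, 2, 3], "b": [4, 5, 6]})
        summ = group_summary(t, "human")
        row = summ.pairwise.set_index(["group_a", "group_b"]).loc[("a", "b")]
        assert row["W"] == 0.0
        assert row["p"] == pytest.approx(0.1)  # 2/20, full enumeration

    def test_small_group_reports_missing(self):
        t = self._table_with_scores({"a": [1.0], "b": [1, 2, 3]})
        summ = group_summary(t, "human")
        assert np.isnan(summ.per_group.loc["a", "median_score"])

    def test_counts_partition_reference_boundaries(self):
        t = self._table_with_scores({"a": [1, 2], "b": [3, 4, 5]})
        summ = group_summary(t, "human")
        assert summ.per_group.loc["all", "count"] == 5
        assert summ.per_group.drop("all")["count"].sum() == 5

    def test_planted_strength_difference_detected(self, tree):
        """Boundaries planted with strong insulation (s=0.1) score lower
        than weakly insulating ones (s=0.5), significantly by Wilcoxon."""
        from tadevol.insulation import call_boundaries, insulation_track
        from tadevol.synthetic_data import simulate_contact_matrix

        rng = np.random.default_rng(0)
        n = 60
        starts = (np.arange(n) * 15 + 70) * 10_000
        labels = np.array(["ultraconserved", "human_specific"] * (n // 2))
        strengths = np.where(labels == "ultraconserved", 0.1, 0.5)
        b = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 10_000,
             "strength": strengths}
        )
        L = int(starts[-1] + 1_000_000)
        m = simulate_contact_matrix(b, (L // 10_000) * 10_000, 10_000,
                                    noise="poisson", seed=1)
        tr = insulation_track(m)
        bins = (starts // 10_000).astype(int)
        t = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 10_000,
                "present_human": True,
                "n_way": 1,
                "members": "",
                "label": labels,
                "score": tr.score[bins],
            }
        )
        summ = group_summary(t, "human")
        med = summ.per_group["median_score"]
        assert med["ultraconserved"] < med["human_specific"]
        p = summ.pairwise.set_index(["group_a", "group_b"]).at[
            ("human_specific", "ultraconserved"), "p"
        ]
        assert p < 0.001


class TestMatchedPermutation:
    def _pool(self, rng, n=300):
        starts = np.sort(rng.choice(np.arange(0, 30_000_000, 20_000), n, replace=False))
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 10_000,
                "score": rng.normal(-0.5, 0.3, n),
                "label": "other",
            }
        )

    def _genes(self, rng):
        gs = np.sort(rng.integers(0, 30_000_000, 150))
        return pd.DataFrame({"chrom": "chr1", "start": gs, "end": gs + 20_000})

    def test_null_rejection_rate_within_binomial_ci(self):
        rng = np.random.default_rng(42)
        rej = 0
        n_runs = 200
        for t in range(n_runs):
            pool = self._pool(rng)
            grp = rng.choice(len(pool), size=40, replace=False)
            pool.loc[grp, "label"] = "g"
            r = matched_insulation_permutation(
                pool, "g", self._genes(rng), n_perm=199, seed=1000 + t
            )
            if r["p"] <= 0.05:
                rej += 1
        assert 0.02 <= rej / n_runs <= 0.09

    def test_extreme_group_gets_minimum_p(self):
        rng = np.random.default_rng(0)
        pool = self._pool(rng)
        lowest = pool["score"].nsmallest(30).index
        pool.loc[lowest, "label"] = "low"
        r = matched_insulation_permutation(pool, "low", self._genes(rng), n_perm=200, seed=3)
        assert r["p"] == pytest.approx(1 / 201)

    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(0)
        pool = self._pool(rng)
        pool.loc[pool.index[:5], "label"] = "g"
        with pytest.raises(ValueError, match="n_perm"):
            matched_insulation_permutation(pool, "g", self._genes(rng), n_perm=0)

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(0)
        pool = self._pool(rng, n=20)
        with pytest.raises(ValueError, match="empty"):
            matched_insulation_permutation(pool, "g", self._genes(rng), n_perm=10)


def test_label_partition_property():
    """Every presence vector gets exactly one label, reproducible from the
    flags alone."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        vec = rng.integers(0, 2, size=8)
        if vec.sum() == 0:
            continue
        present = dict(zip(SPECIES, map(bool, vec)))
        lab = label_from_presence(present, CLADES, REFS)
        assert lab in {
            "ultraconserved",
            "primate_conserved",
            "rodent_conserved",
            "human_specific",
            "mouse_specific",
            "other",
        }
        assert lab == label_from_presence(present, CLADES, REFS)
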