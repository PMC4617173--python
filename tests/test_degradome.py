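"""Degradome profiles, target scoring, coincidence, categories, p-values."""

import numpy as np
import pandas as pd
import pytest

from mircms._seq import revcomp
from mircms.degradome import (TargetHit, build_profiles, categorize,
                              find_targets, score_alignment, target_pvalue,
                              validate_targets)

from oracles import allen_score_bruteforce, category_reference


class TestBuildProfiles:
    def test_five_prime_end_coordinate(self):
        rng = np.random.default_rng(0)
        tx = {"t1": "".join(rng.choice(list("ACGT"), size=200))}
        tag = tx["t1"][100:120]  # positions 101-120, 1-based
        tags = pd.DataFrame({"sequence": [tag], "count": [7]})
        profiles = build_profiles(tags, tx)
        assert profiles["t1"][100] == 7
        assert profiles["t1"].sum() == 7

    def test_length_filter_excludes_19nt(self):
        tx = {"t1": "ACGT" * 50}
        tags = pd.DataFrame({"sequence": [tx["t1"][:19]], "count": [5]})
        assert build_profiles(tags, tx)["t1"].sum() == 0

    def test_matches_naive_substring_scan(self):
        rng = np.random.default_rng(1)
        tx = {f"t{i}": "".join(rng.choice(list("ACGT"), size=150))
              for i in range(3)}
        tags = []
        for _ in range(30):
            tid = f"t{rng.integers(3)}"
            L = int(rng.choice([19, 20, 21, 22]))
            p = int(rng.integers(0, 150 - L))
            tags.append((tx[tid][p:p + L], int(rng.integers(1, 9))))
        df = pd.DataFrame(tags, columns=["sequence", "count"])
        df = df.groupby("sequence", as_index=False)["count"].sum()
        profiles = build_profiles(df, tx)
        # naive scan
        expected = {tid: np.zeros(len(s), dtype=int) for tid, s in tx.items()}
        for seq, count in zip(df["sequence"], df["count"]):
            if len(seq) not in (20, 21):
                continue
            for tid, s in tx.items():
                start = s.find(seq)
                while start >= 0:
                    expected[tid][start] += count
                    start = s.find(seq, start + 1)
        for tid in tx:
            assert np.array_equal(profiles[tid], expected[tid])


class TestScoreAlignment:
    def test_perfect_complement_scores_zero(self):
        m = "TTGACAGAAGATAGAGAGCAC"
        score, pattern = score_alignment(m, revcomp(m))
        assert score == 0.0
        assert pattern == "|" * len(m)

    def test_wobble_penalty_doubles_in_core(self):
        m = "A" * 21
        m = m[:4] + "G" + m[5:14] + "G" + m[15:]  # G at positions 5 and 15
        site = list(revcomp(m))
        # wobble at miRNA position 15 (outside the 2-13 core): G:U pair
        site_end15 = site.copy()
        site_end15[21 - 15] = "T"
        assert score_alignment(m, "".join(site_end15))[0] == pytest.approx(0.5)
        # the same wobble at position 5 doubles
        site_core5 = site.copy()
        site_core5[21 - 5] = "T"
        assert score_alignment(m, "".join(site_core5))[0] == pytest.approx(1.0)

    def test_matches_bruteforce_on_toy_17mers(self):
        rng = np.random.default_rng(2)
        for _ in range(400):
            m = "".join(rng.choice(list("ACGT"), size=17))
            S = 17 + int(rng.integers(-1, 2))
            site = "".join(rng.choice(list("ACGT"), size=S))
            got, _ = score_alignment(m, site)
            assert got == pytest.approx(allen_score_bruteforce(m, site))

    def test_length_mismatch_beyond_one_gap_is_unalignable(self):
        assert score_alignment("ACGTACGTACGTACGTA", "ACGT")[0] == float("inf")


def _planted_case(score_fn_site=None):
    """One transcript with a perfect site for a fixed miRNA and a clean
    degradome peak at the position paired to miRNA position 10."""
    rng = np.random.default_rng(3)
    m = "TTGACAGAAGATAGAGAGCAC"
    tx_seq = "".join(rng.choice(list("ACGT"), size=300))
    site = revcomp(m) if score_fn_site is None else score_fn_site
    start = 120  # 0-based
    tx_seq = tx_seq[:start] + site + tx_seq[start + len(site):]
    tx = {"t1": tx_seq}
    site_start1 = start + 1
    cleavage = site_start1 + len(m) - 10
    profile = np.zeros(len(tx_seq), dtype=np.int64)
    profile[cleavage - 1] = 90
    return m, tx, cleavage, profile


class TestFindTargets:
    def test_planted_site_yields_hit_at_cleavage_position(self):
        m, tx, cleavage, profile = _planted_case()
        hits = find_targets({"mir": m}, tx, {"t1": profile})
        assert len(hits) == 1
        assert hits[0].cleavage_pos == cleavage
        assert hits[0].align_score == 0.0
        assert hits[0].mirna_cleavage_index == 10

    def test_signal_away_from_positions_10_11_is_ignored(self):
        m, tx, cleavage, profile = _planted_case()
        shifted = np.zeros_like(profile)
        shifted[cleavage - 1 + 4] = 50  # peak opposite miRNA position 14
        hits = find_targets({"mir": m}, tx, {"t1": shifted})
        assert [h for h in hits if h.cleavage_pos == cleavage + 4] == []

    def test_score_above_four_is_rejected(self):
        m, tx, cleavage, profile = _planted_case()
        hits = find_targets({"mir": m}, tx, {"t1": profile}, max_score=4.0)
        assert len(hits) == 1
        # mutate the site so the only alignment scores 4.5
        seq = list(tx["t1"])
        site_end = cleavage - 1 + 9
        for flip, pen_pos in [(0, 16), (1, 17), (2, 18), (3, 19)]:
            i = site_end - (pen_pos - 1)
            seq[i] = {"A": "C", "C": "A", "G": "A", "T": "C"}[seq[i]]
        seq[site_end - 14] = {"A": "C", "C": "A", "G": "A", "T": "C"}[seq[site_end - 14]]
        mutated = {"t1": "".join(seq)}
        score, _ = score_alignment(m, mutated["t1"][site_end - 20:site_end + 1])
        if score > 4.0:  # guard: the intended construction
            assert find_targets({"mir": m}, mutated, {"t1": profile}) == []


class TestCategorize:
    def test_unique_maximum_is_category_zero(self):
        profile = np.zeros(200, dtype=np.int64)
        profile[49] = 90
        profile[[10, 100, 150]] = 3
        hit = TargetHit("m", "t", 0.0, 50, 10, 90)
        assert categorize(hit, profile) == 0

    def test_tied_maximum_is_category_one(self):
        profile = np.zeros(100, dtype=np.int64)
        profile[[20, 60]] = 40
        hit = TargetHit("m", "t", 0.0, 21, 10, 40)
        assert categorize(hit, profile) == 1

    def test_single_read_is_category_four(self):
        profile = np.zeros(100, dtype=np.int64)
        profile[20] = 1
        profile[50] = 30
        hit = TargetHit("m", "t", 0.0, 21, 10, 1)
        assert categorize(hit, profile) == 4

    def test_matches_predicate_oracle_on_random_profiles(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            profile = rng.poisson(1.2, 80).astype(np.int64)
            nz = np.nonzero(profile)[0]
            if nz.size == 0:
                continue
            pos = int(rng.choice(nz)) + 1
            hit = TargetHit("m", "t", 0.0, pos, 10, int(profile[pos - 1]))
            assert categorize(hit, profile) == category_reference(profile, pos)


class TestTargetPvalue:
    def test_perfect_site_beats_all_shuffles(self):
        m, tx, cleavage, profile = _planted_case()
        hit = TargetHit("mir", "t1", 0.0, cleavage, 10, 90)
        p = target_pvalue(hit, m, tx["t1"], n_shuffles=100, seed=5)
        assert p == pytest.approx(1 / 101)

    def test_deterministic_under_fixed_seed(self):
        m, tx, cleavage, profile = _planted_case()
        hit = TargetHit("mir", "t1", 0.0, cleavage, 10, 90)
        p1 = target_pvalue(hit, m, tx["t1"], n_shuffles=20, seed=9)
        p2 = target_pvalue(hit, m, tx["t1"], n_shuffles=20, seed=9)
        assert p1 == p2

    def test_requires_at_least_20_shuffles(self):
        hit = TargetHit("m", "t", 0.0, 30, 10, 5)
        with pytest.raises(ValueError):
            target_pvalue(hit, "ACG" * 7, "ACGT" * 30, n_shuffles=5)


class TestRetainedSet:
    def test_every_retained_hit_satisfies_all_three_rules(self):
        m, tx, cleavage, profile = _planted_case()
        rng = np.random.default_rng(6)
        noisy = profile + rng.poisson(0.5, profile.size)
        hits = validate_targets({"mir": m}, tx, {"t1": noisy},
                                n_shuffles=50, seed=1)
        assert len(hits) >= 1
        assert (hits["align_score"] <= 4.0).all()
        assert (hits["p_value"] < 0.05).all()
        for _, h in hits.iterrows():
            assert noisy[h["cleavage_pos"] - 1] > 0
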