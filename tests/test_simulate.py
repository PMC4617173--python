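"""Synthetic-study generator: determinism, self-consistency, parameter
recovery at reduced scale."""

import numpy as np
import pandas as pd
import pytest

from mircms.degradome import build_profiles, categorize, score_alignment, TargetHit
from mircms.fold import HairpinCandidate, fold, validate_hairpin
from mircms.simulate import (MATURE_LEN, MATURE_OFFSET, SimulationConfig,
                             make_genome, simulate_srna, simulate_study,
                             write_study)
from mircms.stats import log2fc

from conftest import small_config


class TestDeterminism:
    def test_same_seed_gives_identical_outputs(self, tmp_path):
        a = simulate_study(small_config(seed=5))
        b = simulate_study(small_config(seed=5))
        assert a.genome == b.genome
        pd.testing.assert_frame_equal(a.srna_counts, b.srna_counts)
        pd.testing.assert_frame_equal(a.rnaseq_counts, b.rnaseq_counts)
        for sample in a.degradome:
            pd.testing.assert_frame_equal(a.degradome[sample],
                                          b.degradome[sample])
        write_study(a, tmp_path / "a")
        write_study(b, tmp_path / "b")
        for name in ("genome.fasta", "srna_counts.tsv", "degradome_cms.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_study(small_config(seed=5))
        b = simulate_study(small_config(seed=6))
        assert a.genome != b.genome


class TestSelfConsistency:
    def test_planted_precursors_pass_hairpin_validation(self, small_study):
        span = (MATURE_OFFSET, MATURE_OFFSET + MATURE_LEN - 1)
        for planted in small_study.truth.planted_mirnas:
            assert planted.mature in planted.precursor
            cand = HairpinCandidate(planted.precursor,
                                    fold(planted.precursor), span)
            decision = validate_hairpin(cand)
            assert decision.passed, (planted.name, decision.reasons)
            assert cand.fold.energy <= -28.0  # well clear of the ceiling

    def test_planted_sites_score_as_requested(self, small_study):
        for t in small_study.truth.planted_targets:
            tx = small_study.transcripts[t["transcript_id"]]
            site = tx[t["site_start"] - 1:t["site_start"] - 1 + MATURE_LEN]
            score, _ = score_alignment(t["mirna_sequence"], site)
            assert score == pytest.approx(t["expected_score"])

    def test_planted_cleavage_sites_are_category_zero_without_background(self):
        cfg = small_config(seed=21, background_fraction=0.0)
        study = simulate_study(cfg)
        deg = pd.concat(study.degradome.values(), ignore_index=True)
        deg = deg.groupby("sequence", as_index=False)["count"].sum()
        profiles = build_profiles(deg, study.transcripts)
        for t in study.truth.planted_targets:
            profile = profiles[t["transcript_id"]]
            hit = TargetHit("m", t["transcript_id"], 0.0, t["cleavage_pos"],
                            10, int(profile[t["cleavage_pos"] - 1]))
            assert categorize(hit, profile) == 0

    def test_no_background_means_every_tag_is_planted(self):
        cfg = small_config(seed=22, background_fraction=0.0)
        study = make_genome(cfg)
        import mircms.simulate as sim
        sim.make_transcriptome(cfg, study)
        counts = simulate_srna(cfg, study)
        planted = {m.mature for m in study.truth.planted_mirnas}
        planted |= {m.star for m in study.truth.planted_mirnas}
        assert set(counts["sequence"]).issubset(planted)

    def test_requested_unreachable_score_raises(self):
        cfg = small_config(seed=23,
                           planted_target_scores=(40.0, 0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            simulate_study(cfg)

    def test_genome_too_short_raises(self):
        with pytest.raises(ValueError, match="genome too short"):
            SimulationConfig(genome_length=2000).validate()


class TestParameterRecovery:
    def test_planted_fold_change_recovered(self):
        # planted two-fold suppression estimated within +/- 0.3 across seeds
        errs = []
        for seed in range(8):
            cfg = small_config(seed=100 + seed, srna_depth=200_000)
            study = make_genome(cfg)
            import mircms.simulate as sim
            sim.make_transcriptome(cfg, study)
            counts = simulate_srna(cfg, study)
            n1 = counts["count_control"].sum()
            n2 = counts["count_cms"].sum()
            for name, fc in study.truth.mirna_fc.items():
                mature = next(m.mature for m in study.truth.planted_mirnas
                              if m.name == name)
                row = counts[counts["sequence"] == mature].iloc[0]
                est = log2fc(row["count_control"] / n1 * 1e6,
                             row["count_cms"] / n2 * 1e6)
                errs.append(est - fc)
        assert np.mean(np.abs(errs)) < 0.3

    def test_tpm_invariant_under_depth_doubling(self):
        tpms = {}
        for depth in (100_000, 200_000):
            cfg = small_config(seed=30, srna_depth=depth)
            study = make_genome(cfg)
            import mircms.simulate as sim
            sim.make_transcriptome(cfg, study)
            counts = simulate_srna(cfg, study)
            total = counts["count_control"].sum()
            mature = study.truth.planted_mirnas[0].mature
            row = counts[counts["sequence"] == mature].iloc[0]
            tpms[depth] = row["count_control"] / total * 1e6
        ratio = tpms[200_000] / tpms[100_000]
        assert 0.9 < ratio < 1.1

    def test_null_genes_show_no_systematic_fold_change(self):
        cfg = small_config(seed=31, n_planted_targets=0, planted_log2fc=(),
                           planted_target_scores=())
        study = simulate_study(cfg)
        df = study.rnaseq_counts
        kept = df[(df.count_control > 50) & (df.count_cms > 50)]
        fcs = np.log2(kept.count_cms / kept.count_control)
        assert abs(np.median(fcs)) < 0.1
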