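"""Read cleaning, tag collapsing, known-miRNA matching, family expansion
and the annotation hierarchy."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mircms import catalog
from mircms._seq import revcomp
from mircms.catalog import (Adapters, clean_reads, collapse_tags,
                            annotate_hierarchy, expand_families, match_known,
                            mirna_family, shared_fraction)
from mircms.novel import GenomeIndex

ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
Q40 = [40]


def read(seq, qual=40):
    return ("r", seq + ADAPTER3, [qual] * (len(seq) + len(ADAPTER3)))


class TestCleanReads:
    def test_short_insert_counted_separately(self):
        clean, rep = clean_reads([read("ACGTACGTACGTACGTA")],  # 17 nt
                                 Adapters(three_prime=ADAPTER3))
        assert clean == []
        assert rep.n_shorter_than_18 == 1
        assert rep.balances()

    def test_polya_definition(self):
        clean, rep = clean_reads([read("A" * 20)], Adapters(three_prime=ADAPTER3))
        assert rep.n_polyA == 1 and clean == []
        # 75% adenine survives the 80% rule
        clean, rep = clean_reads([read("AAAG" * 5)], Adapters(three_prime=ADAPTER3))
        assert rep.n_polyA == 0 and len(clean) == 1

    def test_spiked_contaminant_fractions_recovered_exactly(self):
        rng = np.random.default_rng(0)
        reads = []
        n_good, n_contam, n_short, n_long = 60, 5, 10, 8
        a5 = "GTTCAGAGTTCTACAGTCCGACGATC"
        for _ in range(n_good):
            reads.append(read("".join(rng.choice(list("CGT"), size=21))))
        for _ in range(n_contam):
            reads.append(read(a5[-8:] + "CGTCGTCGTCGTC"))
        for _ in range(n_short):
            reads.append(read("CGTCG"))
        for _ in range(n_long):
            reads.append(read("".join(rng.choice(list("CGT"), size=35))))
        clean, rep = clean_reads(reads, Adapters(three_prime=ADAPTER3,
                                                 five_prime=a5))
        assert rep.n_raw == n_good + n_contam + n_short + n_long
        assert rep.n_5adapter_contaminant == n_contam
        assert rep.n_shorter_than_18 == n_short
        assert rep.n_longer_than_30 == n_long
        assert rep.n_clean == n_good == len(clean)
        assert rep.balances()

    def test_empty_input_is_not_an_error(self):
        clean, rep = clean_reads([])
        assert clean == [] and rep.n_raw == 0 and rep.balances()

    def test_malformed_record_skipped_with_count(self):
        reads = [("r1", "ACG" * 7, [40] * 10),  # quality length mismatch
                 ("r2", "", None),
                 ("r3", "ACGTACGTACGTACGTACGTA", None)]
        clean, rep = clean_reads(reads)
        assert rep.n_malformed == 2
        assert rep.n_clean == 1
        assert rep.balances()


class TestCollapse:
    def test_shared_tag_preserves_counts(self):
        df, stats = collapse_tags({"control": ["ACGT" * 5, "ACGT" * 5],
                                   "cms": ["ACGT" * 5]})
        assert len(df) == 1
        assert df.loc[0, "count_control"] == 2
        assert df.loc[0, "count_cms"] == 1
        assert stats["unique_shared"] == 1

    def test_matches_dictionary_oracle(self):
        rng = np.random.default_rng(1)
        pool = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(40)]
        s1 = [pool[i] for i in rng.integers(0, 40, 500)]
        s2 = [pool[i] for i in rng.integers(0, 40, 500)]
        df, stats = collapse_tags({"a": s1, "b": s2})
        c1, c2 = Counter(s1), Counter(s2)
        for _, row in df.iterrows():
            assert row["count_a"] == c1.get(row["sequence"], 0)
            assert row["count_b"] == c2.get(row["sequence"], 0)
        assert stats["total_tags"] == 1000
        shared = set(c1) & set(c2)
        assert stats["total_shared"] == sum(c1[s] + c2[s] for s in shared)

    def test_shared_fraction_arithmetic(self):
        assert shared_fraction(46.0, 33.8) == pytest.approx(0.7348, abs=1e-4)


def tiny_reference():
    rng = np.random.default_rng(2)
    mature = "".join(rng.choice(list("ACGT"), size=21))
    flank5 = "".join(rng.choice(list("ACGT"), size=20))
    flank3 = "".join(rng.choice(list("ACGT"), size=30))
    precursor = flank5 + mature + flank3
    return {"MIR1": precursor}, {"miR1-5p": mature}, precursor, mature


def tag_frame(seqs_counts):
    return pd.DataFrame([{"sequence": s, "count_control": a, "count_cms": b}
                         for s, a, b in seqs_counts])


class TestMatchKnown:
    def test_exact_mature_matched_with_full_count(self):
        precursors, matures, _, mature = tiny_reference()
        tags = tag_frame([(mature, 100, 40)])
        records, mask = match_known(tags, precursors, matures)
        assert mask.all()
        assert records.loc[0, "count_control"] == 100
        assert records.loc[0, "family"] == "miR1"

    def test_shifted_tag_with_16nt_overlap_matched(self):
        precursors, matures, precursor, mature = tiny_reference()
        start = precursor.find(mature)
        shifted = precursor[start + 3:start + 3 + 18]  # overlap 18 >= 16
        far = precursor[start + 6:start + 6 + 18]      # overlap 15 < 16
        tags = tag_frame([(shifted, 10, 0), (far, 5, 0)])
        records, mask = match_known(tags, precursors, matures)
        assert list(mask) == [True, False]
        assert records.loc[0, "count_control"] == 10

    def test_single_mismatch_against_precursor_not_matched(self):
        precursors, matures, _, mature = tiny_reference()
        mutated = ("G" if mature[0] != "G" else "C") + mature[1:]
        _, mask = match_known(tag_frame([(mutated, 50, 50)]),
                              precursors, matures)
        assert not mask.any()

    def test_order_independent_and_idempotent(self):
        precursors, matures, precursor, mature = tiny_reference()
        start = precursor.find(mature)
        rows = [(mature, 10, 1), (precursor[start + 2:start + 22], 5, 2),
                ("ACGT" * 5, 7, 7)]
        rec1, _ = match_known(tag_frame(rows), precursors, matures)
        rec2, _ = match_known(tag_frame(rows[::-1]), precursors, matures)
        pd.testing.assert_frame_equal(rec1, rec2)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            match_known(tag_frame([("ACGT" * 5, 1, 1)]), {}, {})

    def test_multi_precursor_mature_collapsed_to_one_record(self):
        precursors, matures, precursor, mature = tiny_reference()
        precursors = {"MIR1": precursor, "MIR1b": "GG" + precursor}
        matures = {"miR1-5p": mature, "miR1b-5p": mature}
        records, _ = match_known(tag_frame([(mature, 8, 3)]),
                                 precursors, matures)
        assert len(records) == 1
        assert set(records.loc[0, "precursor_ids"].split(",")) == {"MIR1", "MIR1b"}


class TestFamilyName:
    @pytest.mark.parametrize("name,family", [
        ("bra-miR157a-5p", "miR157"),
        ("ath-miR396b", "miR396"),
        ("osa-MIR166-3p", "miR166"),
    ])
    def test_family_parsing(self, name, family):
        assert mirna_family(name) == family


class TestExpandFamilies:
    def _genome_with_hairpin(self, small_study):
        # reuse a planted precursor locus as the valid genomic hairpin
        planted = small_study.truth.planted_mirnas[0]
        return small_study.genome, planted

    def test_two_substitutions_accepted_three_rejected(self, small_study):
        # the sequenced tag sits in the genome inside a valid hairpin; the
        # foreign reference mature differs from it by 2 (accept) or 3
        # (reject) substitutions
        genome, planted = self._genome_with_hairpin(small_study)
        foreign2 = list(planted.mature)
        foreign2[9] = "A" if foreign2[9] != "A" else "C"
        foreign2[15] = "A" if foreign2[15] != "A" else "C"
        foreign3 = list(foreign2)
        foreign3[18] = "A" if foreign3[18] != "A" else "C"
        tags = tag_frame([(planted.mature, 50, 10)])
        accepted = expand_families(tags, {"xxx-miR9001": "".join(foreign2)},
                                   genome)
        assert len(accepted) == 1
        assert accepted.loc[0, "source"] == "family_expansion"
        assert accepted.loc[0, "mature_sequence"] == planted.mature
        rejected = expand_families(tags, {"xxx-miR9001": "".join(foreign3)},
                                   genome)
        assert len(rejected) == 0

    def test_non_folding_locus_discarded_as_pseudo(self):
        rng = np.random.default_rng(3)
        tag = "".join(rng.choice(list("ACGT"), size=21))
        genome = ("".join(rng.choice(list("ACGT"), size=400)) + tag
                  + "".join(rng.choice(list("ACGT"), size=400)))
        out = expand_families(tag_frame([(tag, 30, 5)]),
                              {"zzz-miR9002": tag}, genome)
        assert len(out) == 0

    def test_missing_genome_skips_stage(self):
        out = expand_families(tag_frame([("ACGT" * 6, 9, 9)]),
                              {"m": "ACGT" * 6}, None)
        assert out.empty


class TestAnnotateHierarchy:
    def test_priority_and_forwarding(self, small_study):
        decoy = small_study.decoys["rRNA"][0]
        index = GenomeIndex(small_study.genome)
        intron = small_study.intervals.query("category == 'intron'").iloc[0]
        a, b, strand = int(intron["start"]), int(intron["end"]), intron["strand"]
        frag = small_study.genome[a - 1:a + 20]
        if strand == "-":
            frag = revcomp(frag)
        tags = tag_frame([
            (decoy[5:27], 3, 3),          # rRNA decoy
            (frag, 2, 2),                 # intron-derived
            ("GGCCGGTTAACCGGAAGGTCC", 1, 1),  # maps nowhere
        ])
        known_mask = pd.Series([False, False, False])
        out = annotate_hierarchy(tags, index, small_study.intervals,
                                 small_study.decoys, known_mask=known_mask)
        assert out.loc[0, "annotation"] == "rRNA"
        assert not out.loc[0, "forwarded"]
        assert out.loc[1, "annotation"] == "intron_sense"
        assert out.loc[1, "forwarded"]
        assert out.loc[2, "annotation"] == "unannotated"
        assert out.loc[2, "forwarded"]

    def test_known_mirna_never_forwarded(self, small_study):
        index = GenomeIndex(small_study.genome)
        mature = small_study.truth.planted_mirnas[0].mature
        tags = tag_frame([(mature, 9, 9)])
        out = annotate_hierarchy(tags, index, small_study.intervals,
                                 small_study.decoys,
                                 known_mask=pd.Series([True]))
        assert out.loc[0, "annotation"] == "known_miRNA"
        assert not out.loc[0, "forwarded"]

    def test_each_tag_gets_exactly_one_category(self, small_result):
        annotated = small_result.tags
        assert annotated["annotation"].notna().all()
        counts = annotated["annotation"].value_counts().sum()
        assert counts == len(annotated)
        assert set(annotated["annotation"]).issubset(set(catalog.ANNOTATION_PRIORITY))
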