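# mircms

Small-RNA miRNA discovery, degradome (PARE) target validation and
miRNA-target expression integration for two-condition plant studies —
typically a cytoplasmic-male-sterile (CMS) line against its isogenic
maintainer, one deep-sequenced library per condition and per layer
(small RNA, degradome, RNA-seq).

## Who this is for

Plant small-RNA researchers who want a transparent, testable
re-implementation of the classical BGI-era bud miRNA workflow: clean and
collapse 18–30 nt tags, identify known miRNAs against a miRBase-style
reference, annotate the remainder hierarchically, predict novel miRNAs from
genomic hairpins, quantify and test differential expression without
replicates, validate cleavage targets with degradome evidence, and join the
layers into miRNA–target regulation clusters.

## The methods at the core

* **Known miRNAs** — a tag is a known miRNA iff it matches a reference
  precursor exactly (no mismatches) *and* overlaps a reference mature by
  ≥ 16 nt in precursor coordinates; expression is the summed count of
  qualifying tags, one record per distinct mature sequence.
* **Novel miRNAs** — Mireap-style: genomic windows around each abundant
  forwarded tag are folded; a call requires a stem-loop with the mature on
  one arm, a miRNA:miRNA\* duplex with 2-nt 3′ overhangs, no large internal
  loops or bulges, minimum free energy ≤ −18 kcal/mol, and copy number > 5.
  Folding uses ViennaRNA when available, with a bundled simplified
  nearest-neighbour model solved exactly by dynamic programming as fallback.
* **Expression statistics** — TPM (count / total clean reads × 10⁶) for
  tags, RPKM (10⁹·C/(N·L)) for genes; the Audic–Claverie exact test for the
  unreplicated miRNA layer and a 2×2 Pearson chi-squared test for the gene
  layer; Benjamini–Hochberg FDR; regulation calls at |log2FC| ≥ 1 with
  p < 10⁻³ (miRNA) or FDR < 10⁻² (mRNA).
* **Degradome targets** — 20–21 nt tags mapped sense-strand to transcripts;
  Allen-rule complementarity score ≤ 4 (mismatch 1, G:U wobble 0.5, gap 1,
  doubled at miRNA positions 2–13); the tag 5′ end must sit on the
  transcript base paired to miRNA position 10 or 11; a seeded shuffled-miRNA
  permutation p-value < 0.05; t-plot categories 0–4.
* **Integration** — validated pairs classified into clusters I–IV (miRNA
  down/target up, both down, both up, miRNA up/target down) with nested
  1.5-fold and 2-fold tiers.

A fully deterministic synthetic-study generator plants miRNA hairpins,
cleavage sites and fold changes with recorded ground truth, so every stage
is testable offline; see `docs/methods.md` for the model and its limits.

## Worked example

```python
from mircms.simulate import SimulationConfig, simulate_study
from mircms.benchmark import run_pipeline, score_against_truth

cfg = SimulationConfig(seed=7, srna_depth=200_000, degradome_depth=60_000,
                       rnaseq_depth=600_000, genome_length=60_000,
                       n_transcripts=25)
study = simulate_study(cfg)
result = run_pipeline(study, n_shuffles=100)

print("unique sRNA tags:", len(study.srna_counts))
print("known miRNA records:", len(result.known_records))
print("novel miRNA calls:", len(result.novel_calls))
print("retained target hits:", len(result.target_hits))
print(result.target_hits.head(5).to_string(index=False))
metrics = score_against_truth(result)
print("planted novel miRNAs recovered: "
      f"{metrics.mirna_recall:.0%} of {metrics.n_planted_novel}")
print("planted cleavage targets recovered: "
      f"{metrics.target_recall:.0%} of {metrics.n_planted_targets}")
```

prints

```
unique sRNA tags: 119085
known miRNA records: 10
novel miRNA calls: 31
retained target hits: 9
 mirna_name transcript_id  align_score  cleavage_pos  mirna_cleavage_index  tag_count_at_site  category  p_value
novel-miR-1      gene0005          0.0           934                    10              11905         0 0.009901
novel-miR-6      gene0003          1.0           743                    11                  2         3 0.009901
novel-miR-6      gene0003          0.0           744                    11                  6         3 0.009901
novel-miR-6      gene0003          0.0           745                    10              12092         0 0.009901
novel-miR-8      gene0001          1.0           344                    11                  5         3 0.009901
planted novel miRNAs recovered: 100% of 10
planted cleavage targets recovered: 100% of 5
```

Every planted miRNA and cleavage site comes back: each planted site appears
as a category-0 hit (the unique degradome maximum of its transcript) at
exactly the position paired to miRNA position 10, with alignment score 0 and
the smallest possible permutation p-value (1/101 at 100 shuffles).  The 31
novel calls include the 10 planted matures plus their star strands and those
of the known precursors — star-arm sequences are genuine Dicer products and
are reported as miRNAs in their own right.  Low-count "echo" hits one or two
bases away from a true cleavage site (categories 2–4) come from background
degradation fragments and are distinguishable by their category.

The same pipeline is available from the shell:

```bash
mircms simulate --seed 7 --out demo/        # synthetic study + truth tables
mircms run --workdir demo_run --seed 7      # full pipeline, manifest-cached
mircms fold --seq GGGGGGGGGGAACAACCCCCCCCCCC --backend simple
mircms de demo/srna_counts.tsv --layer mirna --out demo/mirna_de.tsv
```

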