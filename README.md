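# mirdiverge

Conservation and divergence of plant miRNA binding sites in duplicated
genes.

After a gene duplication, the two (or, after a whole-genome triplication,
three) paralogs can diverge in which microRNAs regulate them: a binding
site can be lost from one copy by mutation, or a newly born, lineage-
specific miRNA can gain a site in one copy. `mirdiverge` is a library for
quantifying this process genome-wide. It is aimed at researchers studying
duplicate-gene evolution and post-transcriptional regulation in plants,
where miRNA–target pairing is near-perfectly complementary and therefore
predictable from sequence.

## What it computes

* **Binding-site scanning.** Every length-*L* transcript window is scored
  against the mature miRNA as an ungapped antiparallel duplex: 0 points
  per Watson–Crick pair, 0.5 per G:U wobble, 1 per other mismatch; a
  window is a hit when its score ≤ the cutoff *C* (default 3–3.5 points).
  Three configurable scoring profiles (plain, seed-weighted, strict-
  wobble) emulate the behaviour of the common plant prediction tools, and
  an interaction is called when at least *k* = 2 of the 3 profiles agree.
* **Duplicate cataloguing.** From all-vs-all protein similarity hits:
  duplicates (any nonself hit with *E* < 1e-10 and query coverage > 50%),
  singletons (no nonself hit with *E* < 1e-3), and an explicit
  unclassified class in between. A 2×2 chi-square test measures whether
  miRNA targets are enriched among duplicates.
* **Divergence classification.** A paralog pair/triplet is *same* when
  all members are targeted by an identical nonempty miRNA-family set,
  *divergent* when only some members are targeted or the families differ,
  summarised per duplication class (WGD / tandem / other / triplet) with
  round-half-up percentages.
* **Young-miRNA attribution.** miRNAs are young (genus-restricted) or
  ancient by cross-species homolog hits; a divergent pair is attributed
  to young miRNAs when the symmetric difference of its members' target
  sets contains a young family.
* **Statistics.** Pearson expression correlation per pair, Mann–Whitney U
  contrasts between same and divergent groups, and Ka/Ks by Nei–Gojobori
  (1986) counting with Jukes–Cantor correction.
* **Phylogenetic mapping.** Binding-site presence/absence per miRNA
  family on a gene-family tree, with Fitch small parsimony counting the
  minimal gains/losses (Dollo mode optional).
* **Synthetic data.** A seeded generator emits every input with ground
  truth (planted site coordinates and scores, loss/gain mechanisms,
  true ages, correlation structure), so the whole pipeline is testable
  end to end without external downloads.

## Worked example

```python
from mirdiverge import GenConfig, RunConfig, generate, run_all

bundle, truth = generate(GenConfig(seed=42, n_pairs_wgd=40, n_pairs_td=15,
                                   n_triplets=10, n_singletons=20), "demo")
report = run_all(RunConfig(mirnas=bundle.mirnas, transcripts=bundle.transcripts,
                           hits=bundle.hits, pairs=bundle.pairs,
                           homolog_hits=bundle.homolog_hits,
                           expression=bundle.expression, out_dir="demo_out"))
print(report.summary.by_class)
```

prints (see `examples/05_full_pipeline.py` for the full script):

```
           TD  WGD  triplet  Total
same        8   26        6     40
divergent   7   14        4     25
total      15   40       10     65
```

i.e. 25 of 65 paralog groups with at least one miRNA target (38%) show a
divergent binding-site pattern, which matches the generator's configured
loss/gain rates; the expression contrast gives median *r* = 0.79 for same
vs 0.21 for divergent pairs (Mann–Whitney *p* ≈ 2e-11), and 18/25 (72%)
of divergent groups are attributable to a young miRNA. Shorter scripts in
`examples/` demonstrate each capability (scanning, divergence calls,
Ka/Ks, Fitch mapping) individually, and a thin `mirdiverge` CLI wraps the
same functions (`mirdiverge simulate|scan|catalog|classify|stats|phylo|run-all`).

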