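# phagescreen

Pooled-fitness analysis for genome-wide phage-resistance screens in
bacteria, covering the three complementary screen chemistries used to map
host factors of phage infection in *E. coli*:

* **RB-TnSeq** (loss of function) — randomly barcoded transposon insertion
  pools assayed by barcode sequencing (BarSeq);
* **Dub-seq** (gain of function) — dual-barcoded shotgun expression
  libraries of ~2.5-kb genomic fragments on a multicopy vector;
* **CRISPRi** (knockdown) — pooled sgRNA libraries targeting genes,
  promoters and transcription-factor binding sites.

Phage selection is an extreme positive screen: a handful of resistant
strains (for example, receptor knockouts) absorb most of the sequencing
reads by the end of the assay, so the analyses center on large positive
fitness scores and stringent filters rather than the mild effects typical
of chemical-stress screens. A bundled simulator generates all three library
types and the selection experiments themselves, so the entire pipeline is
testable with no external data.

## The statistics

**Strain and gene fitness (RB-TnSeq).** A strain's fitness is the
normalized log2 ratio of its barcode abundance after selection to its
abundance at time zero,
`f_s = log2((n_end + ψ) / (n_start + ψ))` after scaling both samples to a
common depth (pseudocount ψ = 1/8). Gene fitness is the inverse-variance
weighted mean over the gene's central-insertion strains (10–90% of the
ORF), shifted so the experiment's median gene fitness is 0. Each gene also
gets a t-like statistic `t = fit / sqrt(max(Vw, 0.04))` with `Vw` the
weighted variance of the mean. A gene–experiment record is a **hit** iff

```
fit >= 5   and   t >= 5   and   se = fit/t <= 2   and   fit >= maxFit - 8
```

where `maxFit` is the top gene fitness in that experiment, and the
experiment has mean time-zero reads per gene >= 10.

**Fragment deconvolution (Dub-seq).** A fragment's score is the normalized
log2 ratio of its treatment counts to its summed time-zero counts
(barcodes need >= 10 reads in at least one time-zero sample to count).
Because fragments cover 2–3 genes, per-gene scores `g` solve the
nonnegative least squares problem

```
min_{g >= 0} || F - C g ||²
```

with `C[f,j] = 1` iff fragment `f` covers gene `j` start-to-stop. Hits
require NNLS score >= 4, mean covering-fragment score |mean| >= 2,
a consistent t test across covering fragments, and sufficient read
support; the false-discovery rate is estimated by shuffling the
barcode-to-fragment map 10 times and re-calling hits.

**Guide enrichment (CRISPRi).** Guide counts are filtered (< 10 reads in
every sample), depth-normalized by median-of-ratios factors, and tested
with a conditional negative-binomial exact test (beta-binomial law of the
time-zero count given the pair total, common dispersion estimated by
moments from the time-zero replicates; binomial limit at dispersion 0).
P-values are Benjamini–Hochberg adjusted; a feature is a hit iff at least
one guide has log2FC >= 2 and FDR < 0.05, and feature fitness is the
median guide log2FC.

## Worked example

```python
from phagescreen import synthetic as syn, rbtnseq

genome = syn.GenomeModel.regular(n_genes=500, gene_length_bp=1000, intergenic_gap_bp=100)
pool = syn.make_barcode_pool(genome, n_strains=5000, seed=1)
scenario = syn.SelectionScenario(
    phage_name="T5", moi=1.0,
    resistance_map={"g0042": "receptor_knockout"},
    kill_prob_sensitive=0.999, doublings_resistant=4.0,
    read_depth=1_000_000, seed=7,
)
counts = syn.simulate_selection(pool, scenario)
gene_fits, qc = rbtnseq.fit_all_experiments(counts, pool)
hits = rbtnseq.call_hits(gene_fits, qc=qc)
print(hits[["phage", "feature_id", "score", "t"]].round(2))
```

prints

```
  phage feature_id  score      t
0    T5      g0042  13.85  69.25
```

The simulated receptor knockout (`g0042`) is the unique hit: its fitness
score of 13.85 corresponds to a 2^13.85 ≈ 14,700-fold enrichment of its
insertion strains under selection, with a t-like statistic of 69 and a
standard error of 0.2, passing every gate of the stringent filter. All
other genes are swept from the population and score near or below zero.

The same flow is available from the shell:

```bash
phagescreen simulate --scenario scenario.yaml --seed 7 --out-dir sim/
phagescreen rbtnseq --counts sim/screen --pool sim/pool.tsv --out-dir fit/
phagescreen report fit/hits.tsv --out summary.json
```

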