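# dielortho

Cross-species day–night transcriptomics for diel-niche candidate discovery.

Closely related species sometimes occupy opposite temporal niches — one active
by day, the other by night. Comparing their head transcriptomes at midday and
midnight can expose the genes behind the switch: an ortholog that is
day-upregulated in the diurnal species and night-upregulated in the nocturnal
one (a *sign flip* that *coincides* with each species' activity phase) is a
prime candidate regulator. `dielortho` implements that comparison as a tested,
reusable pipeline, together with a synthetic-data generator that plants known
truth at every stage, so each step can be validated without any sequencing
data.

## What it computes

Starting from per-species gene × sample integer count matrices (day/night,
≥2 replicates each) and per-species protein FASTAs:

1. **Expression filter** — transcripts-per-million; genes below 1 TPM in
   every sample are removed.
2. **Differential expression**, two flavors per species, night-over-day sign
   convention (positive log2FC = night overexpression):
   - *exact*: condition on each gene's grand total after rescaling samples to
     a common effective library size, and sum the probabilities of all splits
     at least as extreme under a negative binomial with equal group means
     (variance μ + φμ²; φ estimated by moderated method-of-moments with a
     lowess mean–dispersion trend);
   - *Wald*: per-gene NB log-linear model with a night indicator fitted by
     IRLS, normal-tail p on the coefficient.
   Benjamini–Hochberg FDR; significance = adjusted p < 0.05 and |log2FC| ≥ 2;
   a consensus set intersects the two methods' calls.
3. **Orthology** — reciprocal best hits by Smith–Waterman (BLOSUM62, gap
   11/1) between each species and a reference proteome; connected components
   with one reference gene become orthogroups; one representative per species
   (highest identity to the reference, length breaking near-ties).
4. **Cross-species collapse and flip classification** — per-species results
   are collapsed onto reference genes (smallest adjusted p per gene), then
   each shared gene is classified: concordant day/night, **flipped**
   (significant in both species, opposite signs), or single-species-strong
   (|log2FC| ≥ 5 in one species only). Flips are checked for **diel
   coincidence**: day-up in the diurnal species and night-up in the nocturnal
   one. Direct ortholog-pair links recover flips with no reference anchor.
5. **Candidate ranking** — three criteria: expressed/DE in both species,
   diel-coincident, and annotated to a sensory or circadian functional
   category (vision, smell, hearing, circadian, behaviour, brain). Candidates
   are ordered by criteria met, then combined evidence (summed per-species
   log10 adjusted p, computed in log space).
6. **GO over-representation** — one-sided hypergeometric tail against the
   expressed-and-annotated background, BH within namespace, with fold-change
   strata (FC ≤ −5, FC ≥ 5, …).
7. **Co-expression network** — signed soft-threshold adjacency
   ((1+cor)/2)^β with β chosen by scale-free fit, topological overlap,
   average-linkage clustering with a static cut plus module-membership
   pruning, module eigengenes (first PC), and eigengene–trait correlation
   (diel phase, species) on the combined two-species matrix.
8. **Conservation profile** — per-column Shannon-entropy score on a protein
   family alignment (1 − H/ln 20, gap-penalized, smoothed, graded 1–9),
   conserved-block detection, and focal-pair mutation mapping with the
   in-block overlap count.

The synthetic generator (`dielortho.simulate`) emulates the full study: a
2-species × 2-time-point × 3-replicate NB design, an orthology structure
(1:1, many-to-1, species-specific) with mutated protein copies, planted
concordant/flipped/single-species genes, one "key" candidate (the strongest
coincident flip, always circadian-annotated), planted co-expression modules,
controlled GO enrichment, and a protein family with conserved blocks and a
controlled number of focal mutations (default 23 total, 3 in-block).

## Worked example

```python
from dielortho import SimConfig, run_pipeline

result = run_pipeline(SimConfig(seed=11))
print(result.report)
print(result.candidates.head())
```

prints (exactly, for this seed):

```
EvaluationReport(flip_sensitivity=1.0, flip_precision=1.0,
  candidate_rank_key_gene=1, module_ari=0.878, enrichment_detected=True,
  enrichment_min_adj_p=1.08e-05, block_jaccard_score=0.991,
  focal_mutations_total=23, focal_mutations_in_block=3)

ref_gene  score   evidence  max_abs_lfc pattern  rank
 BM01216      3 -38.656230     5.910687 flipped     1
 BM00140      3 -26.737683     3.851841 flipped     2
 BM00814      3 -25.587303     3.922500 flipped     3
```

Reading this: all 50 planted coincident flips were recovered with no false
flips (`flip_sensitivity`/`flip_precision`); the planted key candidate is
ranked first (`candidate_rank_key_gene=1` — it meets all three criteria and
carries the strongest combined DE evidence, −38.7 summed log10 adjusted p);
the planted circadian GO enrichment among flipped genes is detected at
adjusted p ≈ 1e−5; detected co-expression modules agree with the planted
structure (adjusted Rand 0.878 over non-grey genes); the conserved block is
recovered at Jaccard 0.991; and the two focal sequences differ at 23 aligned
positions of which 3 fall inside the conserved block.

The same stages are exposed on the command line (`dielortho simulate / de /
orthomap / enrich / conserve / run`), reading and writing plain TSV/FASTA so
any stage can be replaced by an external tool's output.

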