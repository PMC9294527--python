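# musselid

DNA-barcode species identification and method-agreement analysis for
smooth-shelled mussels (*Mytilus* spp.), built around a short nuclear
amplicon (~397 bp of the histone *H1C* gene) in which two commercially
traded species differ at a handful of fixed diagnostic sites.

The package is aimed at molecular traceability work: given aligned barcode
sequences and the species calls of an independent assay (e.g. a
high-resolution-melting test), it answers three questions.

1. **Which individuals are hybrids?**  Diploid F1 hybrids are heterozygous
   at every diagnostic column, which Sanger sequencing reports as a double
   peak and base callers encode as IUPAC ambiguity codes (Y = C/T, R = A/G,
   M = A/C).  `hybrid_detect` discovers the diagnostic panel from reference
   individuals and flags records whose base set contains both parental
   alleles.
2. **What does each identification method say?**  Five standard methods are
   implemented in `classifiers`:
   * **FINS** — placement in a neighbour-joining tree (Tamura–Nei distances,
     column-resampling bootstrap) among conspecific references;
   * **DSC** — direct sequence comparison: percent similarity above a fixed
     threshold (98 % by convention for this amplicon);
   * **BCM** — best close match: the species of the closest reference,
     accepted only within the 95th percentile of intraspecific K2P
     distances (Kimura 2-parameter, d = −½ ln(1−2P−Q) − ¼ ln(1−2Q));
   * **AB** — all barcodes: every conspecific reference must outrank every
     heterospecific one;
   * **ABGD** — automatic barcode gap discovery: recursive partitioning at
     the gap between intra- and inter-specific pairwise distances.
3. **Do the methods agree?**  `concordance` cross-tabulates any two call
   sets and reports Cohen's κ = (p₀ − pₑ)/(1 − pₑ) with its large-sample
   95 % interval, a one-sided p-value (Benjamini–Hochberg adjusted across
   method pairs), the multiclass Matthews correlation (Gorodkin's R_K) and
   the Landis–Koch verbal band.

A seeded generator (`synthetic`) emits study-shaped datasets — two species
pools at ~2 % divergence, ≤1 % intraspecific polymorphism, fixed diagnostic
sites, and F1 hybrids heterozygous at every divergent column — so the whole
pipeline runs without any sequence download.

## Worked example

```python
from musselid import simulate_paperlike, call_hybrids, find_diagnostic_sites
from musselid.classifiers import bcm_threshold, evaluate_method

aln, labels, truth = simulate_paperlike(seed=2020)   # 61 individuals, 9/52 labels
refs_a = [r.id for r in aln if r.label == "speciesA" and not r.is_ambiguous()]
refs_b = [r.id for r in aln if r.label == "speciesB" and not r.is_ambiguous()]
panel = find_diagnostic_sites(aln, refs_a, refs_b, "speciesA", "speciesB")
print("diagnostic columns:", panel.columns)
calls = call_hybrids(aln, panel)
hybrids = [c.id for c in calls.values() if c.status == "putative_hybrid"]
print("putative hybrids:", len(hybrids), "->", calls[hybrids[0]].genotype)
print("BCM threshold: %.2f %%" % bcm_threshold(aln).value)
summary = evaluate_method("DSC", aln, hybrid_flags=set(hybrids))
print("DSC summary: %.1f / %.1f / %.1f (correct/ambiguous/incorrect)"
      % (summary.pct_correct, summary.pct_ambiguous, summary.pct_incorrect))
```

prints

```
diagnostic columns: [95, 107, 169, 200, 233, 289, 293, 330]
putative hybrids: 12 -> RWSWYRRM
BCM threshold: 1.27 %
DSC summary: 77.0 / 23.0 / 0.0 (correct/ambiguous/incorrect)
```

All twelve planted hybrids are recovered from their heterozygous genotypes
(the first one is heterozygous at all eight columns where the two species
consensuses differ).  The best-close-match threshold — the 95th percentile
of intraspecific K2P distances — lands at 1.27 %, and direct sequence
comparison identifies the 49 pure individuals while the hybrids, being
similar to both species, end up in the ambiguous column.

The same workflow runs from the shell:

```
musselid report --seed 2020 --out run/
```

which writes the per-method call tables, the Table-style summary, the
pairwise agreement matrices for the full dataset and for the dataset with
hybrids excluded, the bootstrap-annotated newick tree, and a JSON manifest
recording every parameter and the seed.

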