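# mtpopgen

Population-genetic and demographic analysis of aligned mitochondrial DNA,
built for intraspecific phylogeography: the situation where a few hundred
individuals from a few dozen localities have been sequenced for a single
non-recombining mtDNA fragment (typically a protein-coding gene plus
flanking tRNAs), and the questions are *how is variation structured
geographically* and *have populations expanded recently*.

From an aligned FASTA plus two small TSV tables (individual → population
with coordinates; population → group), the package computes:

- **Sequence QC** — translation under the vertebrate mitochondrial code
  (premature-stop screen), base composition (mtDNA light strands show a
  characteristic deficit of G), variable / parsimony-informative / gapped
  site counts.
- **Diversity** — number of haplotypes *h*, haplotype diversity
  *Hd* = n/(n−1)·(1 − Σp², Nei's gene diversity) and nucleotide diversity
  π, with Nei (1987) standard errors.
- **Divergence** — Kimura 2-parameter distances,
  d = −½ ln(1−2P−Q) − ¼ ln(1−2Q), with pairwise deletion; between-lineage
  means with site-bootstrap standard errors.
- **Structure** — hierarchical haplotypic AMOVA (Excoffier et al. 1992)
  partitioning squared pairwise differences into among-group (Φ_CT),
  among-population-within-group (Φ_SC) and within-population (Φ_ST)
  components, each with its own permutation null; pairwise Φ_ST; Mantel
  isolation-by-distance test against great-circle distances.
- **Demography** — Tajima's D and Fu's Fs (Ewens-distribution log-odds via
  log-space Stirling numbers) with coalescent-simulation p-values; mismatch
  distributions fitted to the Rogers–Harpending sudden-expansion model
  (τ, θ₀, θ₁) with SSD and raggedness goodness-of-fit by parametric
  bootstrap; expansion dating via t = τ/(2u), u = μk.
- **Networks** — statistical-parsimony (TCS-style) haplotype networks under
  a 95% connection limit, with inferred intermediates, ambiguity loops and
  heuristic root scores; GraphML export.
- **Synthetic data** — coalescent generators (constant size, sudden
  expansion, structured multi-lineage) with finite-sites K2P/HKY mutations
  and truth records, so the whole pipeline is testable end to end.

## Worked example

Simulate three deeply diverged lineages (two populations each, eight
samples per population, founders ~8% divergent) and analyse them:

```sh
mtpopgen simulate --model structured --n 8 --groups 3 \
    --divergence-steps 92 --seed 11 --out demo
mtpopgen qc demo.fasta demo.popmap.tsv
mtpopgen amova demo.fasta demo.popmap.tsv demo.groups.tsv -R 1000 --seed 1
```

```
base composition: A=30.7%, C=31.0%, G=11.4%, T=26.9%
sites: 167 variable, 166 parsimony-informative, 0 gapped/missing
haplotypes: 21 among 48 individuals
                         source  df  variance  pct_total fixation_index    value  p_value
                   among_groups   2 45.474609  90.806152           F_CT 0.908062 0.069930
among_populations_within_groups   3  3.544643   7.078134           F_SC 0.769877 0.000999
             within_populations  42  1.059524   2.115714           F_ST 0.978843 0.000999
```

Nearly all molecular variance sits among the three lineages (F_CT = 0.91) —
the expected signature of deep matrilineal structure.  (With only three
groups of two populations, the F_CT permutation null has few distinct
arrangements, hence its coarse p-value.)

A single expanding lineage shows the classic star-genealogy signals:

```sh
mtpopgen simulate --model expansion --n 50 --theta0 0.5 --theta1 50 \
    --tau 3 --seed 4 --out exp
mtpopgen neutrality exp.fasta exp.popmap.tsv --reps 2000 --seed 1
mtpopgen mismatch exp.fasta exp.popmap.tsv -B 200 --seed 1
```

```
{ "n": 50, "S": 51, "pi_hat": 3.758, "h": 31,
  "D": -2.315, "p_D": 0.002, "Fs": -26.291, "p_Fs": 0.0 }
{ "tau": 2.997, "theta0": 0.933, "theta1": 90.661,
  "SSD": 0.0041, "p_SSD": 0.205, "raggedness": 0.0231, "p_raggedness": 0.455,
  "expansion_time_Ma": 0.272 }
```

Tajima's D and Fu's Fs are strongly negative and significant; the mismatch
fit recovers the simulated τ = 3 (τ̂ = 2.997) and the sudden-expansion model
is not rejected (p_SSD = 0.21).  At the default divergence rate of 0.957%
substitutions/site/Myr over 1,151 retained sites, τ̂ ≈ 3 corresponds to an
expansion ~0.27 Ma ago.

The full pipeline (`mtpopgen run config.yaml`) chains all stages and writes
TSV/JSON tables with a provenance manifest; `mtpopgen compare-groupings`
ranks candidate group assignments by among-group variance F_CT.

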