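# botryphylo

Phylogeographic analysis of mitochondrial COI haplotype alignments, built
around the question of where a set of marine populations originated and how
they dispersed.  The motivating system is the colonial ascidian *Botryllus
schlosseri* species complex, whose cryptic clades were surveyed with 524-bp
mtCOI fragments across European, Atlantic and Pacific harbours, but every
component works on any equal-length haploid alignment with a
sample → population → region map.

The package chains five analyses that population geneticists usually run
through separate GUIs (DnaSP, Arlequin, PopART, BEAST, DIYABC) into one
tested, scriptable library:

1. **Diversity and neutrality statistics** (`botryphylo.diversity`) — per
   population: haplotype count *h*, haplotype diversity
   *Hd = n/(n−1)·(1−Σp_i²)*, nucleotide diversity π (pairwise deletion),
   Watterson's *θ_w = S/(a₁L)*, Tajima's
   *D = (k̄ − S/a₁)/√(e₁S + e₂S(S−1))* with significance by neutral-coalescent
   simulation, Fu's *Fs = ln(S′/(1−S′))* where *S′ = Pr(K ≥ k_obs)* under the
   Ewens sampling formula with θ = k̄, and Ramos-Onsins & Rozas'
   *R2 = √(Σᵢ(Uᵢ − k̄/2)²/n)/S*.  Populations with ≤ 3 sequences are reported
   as missing, and populations can be filtered on sample size or on a
   significant *D* before downstream inference.
2. **Population structure** (`botryphylo.structure`) — hierarchical AMOVA
   (among regions / among populations within regions / within populations)
   from allele-identity or site-difference distances, with
   *F_CT = σ²_a/σ²_T*, *F_SC = σ²_b/(σ²_b+σ²_c)*, *F_ST = (σ²_a+σ²_b)/σ²_T*,
   permutation p-values, population-pairwise *F_ST* matrices under
   Benjamini–Yekutieli FDR control, and region-pair averages.
3. **Median-joining networks** (`botryphylo.network`) — Bandelt-style MJN:
   minimum spanning network plus cost-reducing median (consensus) vectors,
   with per-region frequency annotation and named haplotype groups.
4. **Discrete phylogeography** (`botryphylo.phylogeo`) — fixed-tree
   empirical-Bayes reconstruction of ancestral locations: a symmetric
   K-state CTMC (P(same,t) = 1/K + (1−1/K)e^{−Krt}) with the rate fitted by
   maximum likelihood, and marginal node posteriors by the up-down
   algorithm.  A UPGMA builder and newick input supply the tree.
5. **Coalescent ABC scenario choice** (`botryphylo.coalsim`,
   `botryphylo.abc`) — demographic scenarios over sampled and unsampled
   ("ghost") populations with merge/admixture events, uniform priors with
   time-order constraints (t₄ > t₃, t₄ > t₂, t₃ ≥ t₂), HKY+I sequence
   simulation on msprime genealogies, reference tables of summary
   statistics, prior-predictive checks, LDA + multinomial-logistic scenario
   posterior probabilities with bootstrap CIs, local-linear parameter
   estimation, posterior-predictive model checking, and a two-round
   scenario **tournament**: the best scenario(s) of each candidate
   ancestral region advance by a CI-overlap rule into a pooled final, with
   a head-to-head round when finalists' CIs overlap and a repeat under an
   alternate N_e prior maximum.

`botryphylo.synth` generates full synthetic studies (regions, populations,
skewed sample sizes, known generating scenario and parameters) so that every
stage can be exercised end-to-end against ground truth.

## Worked example

Run the whole analysis on a synthetic Clade-E-like study (4 regions, 14
populations, ~250 sequences of 524 bp) generated under the
French-Channel-origin scenario `s19`:

```sh
botryphylo synth --template cladeE_like --seed 7 --out study/
botryphylo stats   --fasta study/alignment.fasta --popmap study/popmap.tsv --out stats.csv
botryphylo amova   --fasta study/alignment.fasta --popmap study/popmap.tsv --out-prefix amova
botryphylo network --fasta study/alignment.fasta --popmap study/popmap.tsv --out-prefix net
```

or in one shot from a YAML config (`botryphylo run --config run.yaml`).
A representative run (seed 1 of `scripts/acceptance.py`) prints:

```
n_sequences                              242
n_haplotypes                              17
mean_haplotype_diversity               0.617
mean_nucleotide_diversity             0.0016
amova_f_ct                             0.080
amova_f_st                             0.096
amova_pct_within_populations            90.4
tournament_winner = s19, PP = 0.895 (95% CI 0.819–0.990)
```

Reading this: the study collapses to 17 haplotypes; most molecular variance
(90%) lies within populations with modest regional structure (F_CT = 0.08);
and the ABC tournament, comparing French-Channel, English-Channel and
Mediterranean ancestral scenarios against the simulated data, identifies the
true generating scenario (s19, French side of the English Channel ancestral)
with posterior probability 0.895.

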