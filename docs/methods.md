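# Methods

This note records the models, numerical choices and limitations behind each
module, in the order data flows through the pipeline.

## Alignments, haplotypes and filters

The data unit is an equal-length alignment over {A,C,G,T,N,-} with unique
sample ids, mapped by a 3-column TSV to populations and regions.  Haplotype
identity is exact string match; a sequence class containing ambiguity is
kept as its own haplotype only when it differs from every other class at an
unambiguous site, otherwise it merges into the most frequent compatible
class.  This keeps haplotype counts stable in the presence of occasional Ns
without inventing site-wise imputation.  Columns are 0-based internally and
1-based in reports.

Two population filters are provided: the minimum-sample rule (keep
populations with more than 3 sequences; statistics for smaller populations
are reported as missing rather than computed on unstable denominators) and
exclusion of populations whose Tajima's D deviates significantly from zero,
which is the conservative screen used before coalescent-based inference on
a locus that may experience selection.

## Diversity and neutrality statistics

π uses pairwise deletion: each pair of sequences is compared over the sites
unambiguous in both, and the per-pair proportions are averaged over all
unordered pairs (identical sequences are collapsed first, so cost scales
with haplotype count).  θ_w = S/(a₁L) with a₁ = Σ_{i<n} 1/i.  Tajima's D
uses the standard 1989 constants; its significance is assessed two-sided
against 1,000 neutral-coalescent replicates conditioned on n with θ set to
the observed Watterson estimate (an explicit simulation stands in for the
unpublished default of the desktop tools; note that D's null mean is
slightly negative because the variance normalisation is approximate).
Fu's Fs evaluates Pr(K ≥ k_obs) under the Ewens sampling formula with
θ = k̄, computing the unsigned Stirling numbers of the first kind in log
space (exact for the n seen here); boundary values S′ ∈ {0,1} are reported
as signed infinities and flagged.  R2 counts, per sequence, the singleton
sites whose unique carrier it is (for n = 2 both members carry each
variable site, which reproduces the R2 = 0.5 closed form).

## AMOVA and F-statistics

Distances default to allele identity (0/1 by haplotype), which yields
conventional F-statistics; site-difference distances give the Φ-statistic
analogue.  The nested sums of squares follow the standard decomposition of
squared distances with the unbalanced-design coefficients n₁, n₂, n₃;
negative variance components are retained (and flagged), not truncated, so
estimates remain comparable across runs.  P-values use three permutation
schemes — samples among populations overall (F_ST), samples among
populations within their region (F_SC), whole populations among regions
(F_CT) — with the unbiased estimator p = (#{perm ≥ obs}+1)/(n_perm+1) and
1,023 permutations by default.  Pairwise F_ST is the two-population special
case; its p-values are corrected with the Benjamini–Yekutieli step-up
procedure (valid under arbitrary dependence, appropriate for the strongly
dependent matrix of all population pairs).

## Median-joining networks

The network alternates two steps to a fixpoint: (1) build the minimum
spanning network over current nodes, where a link is feasible if its
Hamming distance (ambiguity excluded pairwise) is within ε (default 0) of
the threshold at which its endpoints' components first connect; (2) for
each triplet centred on a node with two MSN neighbours, propose the
per-site majority consensus as a median vector and add the proposal that
most reduces the minimum-spanning-tree length of the node set (ties broken
lexicographically on sequence, making output deterministic); unsampled
nodes that fall to degree ≤ 1 are deleted.  The final graph is the MSN over
the final node set — the guarantee asserted by the tests — which may omit
sampled-pair links that medians render redundant, exactly as in the
three-haplotype star example.  Unresolved three-way site ties take the
state minimising added length, then the lexicographically smallest base.

## Discrete-location reconstruction

The joint Bayesian tree-and-trait machinery of the original workflow is
deliberately replaced by a fixed-tree empirical-Bayes treatment: given a
rooted tree (UPGMA over haplotype distances, or any user newick), tip
locations evolve under a symmetric K-state CTMC with uniform stationary
frequencies, P(same,t) = 1/K + (1−1/K)e^{−Krt}.  The single rate r is
fitted by bounded 1-D maximum likelihood on a log scale (bounds 10⁻⁸–10³);
marginal node posteriors come from the up-down algorithm with a uniform
root prior.  This computes the same scientific quantity — node location
posteriors — at desk scale, but conditions on one tree: posterior
uncertainty about topology is not propagated, so posteriors are sharper
than a joint analysis would give, and numerical values are comparable only
qualitatively with tree-averaged ones.

## Coalescent scenarios and sequence simulation

Scenarios list haploid populations (sampled plus unsampled ghosts), each
with an N_e parameter in gene copies (so E[T₂] = N_e generations for a
maternal haploid locus), and a backward-time schedule of merges
(daughter → parent) and admixtures (target lineages to source A with
probability ra, else B).  Genealogies are generated by msprime
(continuous-time approximation; events encoded as mass migrations; events
at exactly t = 0 are nudged forward one tick).  Sequences evolve under
HKY+I: a Bernoulli(I) site mask never mutates and variable sites run at
μ/(1−I), so the mean per-site rate is μ; root states at unmutated sites are
drawn from the stationary frequencies.  Default uniform priors:
N_e ∈ [10, 2×10⁵] (alternate maximum 6×10⁵ for the prior-sensitivity
repeat), event times ∈ [10, 10⁵] generations, ra ∈ [0.001, 0.999],
μ ∈ [10⁻⁸, 10⁻⁶] per site per generation, κ ∈ [0.05, 20], I ∈ [0, 0.9];
times named t₂..t₄ obey t₄ > t₃, t₄ > t₂, t₃ ≥ t₂ by rejection sampling
(an error is raised if the acceptance rate falls below 10⁻⁴).  mtCOI does
not recombine and the scenarios use divergence/admixture only — no ongoing
migration and no within-epoch size change.

## ABC model choice and the tournament

Each simulated or observed dataset reduces to a fixed vector of one-locus
statistics per region and region pair: haplotype count, segregating and
private segregating sites, mean and variance of pairwise differences,
Tajima's D, between-region mean differences and a diversity-based pairwise
F_ST.  Statistics undefined on a dataset (D with S = 0, F_ST with no
between-region variation) are imputed as 0 alongside an indicator column so
vector length never varies.  Model choice standardises the statistics,
projects onto linear discriminant axes fitted to scenario labels, retains
the fraction (default 1%, minimum 50) of simulations nearest the observed
point, and fits a multinomial logistic regression evaluated at the observed
point; 95% CIs bootstrap the retained set (500 resamples by default), and a
plain rejection estimate is reported alongside.  If the LDA is singular the
standardised statistics are used directly.  Parameter estimation is the
classic local-linear adjustment (ridge-regularised against collinearity) of
retained draws; adjusted draws can leave the prior support, which the
quantiles report faithfully.  The tournament applies the CI-overlap rule:
select the top scenario plus every scenario whose CI overlaps the top's,
valid only if no selected CI overlaps an unselected one (otherwise the set
is flagged); selections pool into a final round, escalate to a head-to-head
when finalists overlap, and the final comparison repeats under the
alternate N_e maximum.

Desk-scale sizes: reference tables default to 10⁴ rows per scenario in the
library API and 400 per scenario in the acceptance script, against 10⁶ in
the original workflow.  At these sizes, scenario choice from a *single*
study realisation is stochastic: mirror topologies (e.g. which side of a
channel is ancestral) are distinguished mainly by diversity asymmetries,
and when the independently drawn regional N_e values happen to erase that
signature the wrong finalist can win.  The recovery tests therefore
quantify behaviour over replicates and on deliberately separable scenario
pairs, and the acceptance script reports whichever outcome its seed
produces.

## Synthetic studies

Templates mirror the two sampling designs: cladeE_like (4 regions, 14
populations, 1–41 sequences each, ≈300 total) and cladeA_like (4 regions,
29 populations, ≈1,000 total, per-population cap 80).  Sample sizes are
drawn log-uniformly and rescaled toward the template total, reproducing the
skew of opportunistic marina sampling.  Study generation narrows N_e to
[2×10⁴, 2×10⁵] and μ to [2×10⁻⁸, 8×10⁻⁸] so simulated studies land on the
diversity scale of real mtCOI surveys (tens of haplotypes per few hundred
sequences, π ≈ 0.002–0.03); inference against a study still uses the full
priors above.  What the generator does not emulate: sequencing error,
chimeric reads, within-region substructure (all populations of a region
are draws from one deme), and ongoing gene flow — so passing tests
demonstrate correctness of the machinery under the stated model, not
robustness to those real-data features.

## Determinism

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage substreams from one master seed by hashing, and identical
configurations reproduce identical output hashes.  msprime seeds are
reduced into [1, 2³¹); one HKY κ edge case (msprime's exact row-sum check
tripping on float round-off) is handled by nudging κ by ulp-scale steps
until the model builds.
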