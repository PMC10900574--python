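# Methods

`phylodisc` studies why gene trees disagree with species trees in rapid
radiations, using three interacting machineries: multispecies-coalescent
(MSC) simulation, anomaly-zone theory, and site-pattern introgression
statistics, tied together by a seeded synthetic-study generator that plants
known signals for every downstream analysis to recover.

## Units and the coalescent model

All simulation time runs in **mutational units** (expected substitutions per
site).  A species-tree branch carries a population mutation parameter
θ = 4·Ne·μ; within the branch every lineage pair coalesces at rate 2/θ per
mutational time unit.  A branch of coalescent length τ therefore leaves two
lineages uncoalesced with probability e^(−τ), and the three quantities are
linked by θ = 2·mut_len/τ.  This is the convention under which the
anomaly-zone boundary function is derived; trees whose branch lengths use a
different scaling (some species-tree programs print τ = T/4Ne) can be
rescaled with the `conversion` multiplier of the anomaly scanner
(default 1.0).

Gene trees are simulated branch-by-branch with exact exponential waiting
times (no time discretization).  Lineages surviving a branch enter the
parent; the root branch extends indefinitely.  Terminal branches, whose
coalescent lengths species-tree methods do not estimate, default to the mean
internal-branch θ.  Tied speciation times (zero-length branches) are
processed deepest-first so no lineage is orphaned.

**Pulse admixture.**  An `AdmixtureEvent(time, donor, recipient, m)` moves,
at the event time (backward in time), each lineage currently in the
recipient branch into the donor branch independently with probability m —
forward in time, a gene-flow pulse from donor into recipient with admixture
proportion m.  Events with `movers` pin the jump to a fixed set of sample
haplotypes; the synthetic-study generator uses this to make introgressed
tracts coherent across the loci of a genomic window (see below).

## Anomaly zone

For an internal branch of coalescent length x with an adjacent descendant
internal branch of length y, anomalous gene trees (a topology more probable
than the matching one) arise when y < a(x), with

    a(x) = log[ 2/3 + (3·e^{2x} − 2) / (18·(e^{3x} − e^{2x})) ].

a(x) decreases from +∞ (x→0⁺) to log(2/3), crossing zero at
x* = 0.2654031 (the root of 6e^{3x} − 9e^{2x} + 2).  The scanner reports
every adjacent internal-branch pair in preorder; a zero-length descendant
branch is always flagged (the y < a(x) rule and this convention differ only
where a(x) ≤ 0, where a zero-length branch is degenerate anyway), and a
zero-length parent branch flags all its descendants (a(x) → +∞).  The
simulation verifier tabulates canonical gene-tree topologies and asks
whether the species-tree topology is modal; at x = y = 0.05 the balanced
topology overtakes the caterpillar, the classic anomalous configuration.

## Sequence simulation and gene-tree re-estimation

GTR+I+G simulation uses the reversible-matrix eigendecomposition for branch
transition matrices, root states from the stationary frequencies, a
proportion p_inv of invariant sites and 4 discrete-gamma categories
(equal-probability slices, slice-mean rates, rescaled so the overall mean
rate is exactly 1).  Locus lengths default to the two empirical locus
classes: 500 bp (exon-like) and 1000 bp (intron-like).

Gene trees are re-estimated by neighbor joining on Jukes–Cantor (or LogDet)
distances.  This deliberately replaces maximum-likelihood tree search: it is
deterministic, orders of magnitude faster, and reproduces the property the
estimation-error analyses rely on — topological error that grows as
alignments shorten.  Saturated distances are capped (default 5
substitutions/site) with a warning.  Externally estimated trees can be
substituted anywhere a gene tree is consumed.

## Concordance, polytomy test, discordance ratio

Each internal species-tree branch defines four taxon groups (two child
clades A and B, the sister group C, the remainder D).  Among gene trees
decisive for the branch (≥ 1 taxon per group), gCF is the percentage
containing the split A∪B | C∪D, gDF1/gDF2 the two nearest-neighbor
alternatives (A∪C | B∪D and A∪D | B∪C; A holds the lexicographically
smallest tip, fixing the labelling), and gDFp the remainder; the four
percentages sum to 100 by construction.  The polytomy test classifies each
decisive gene tree by the majority of its one-tip-per-group quartets (ties
are not counted) and tests the three resolved counts against 1:1:1 with a
2-df chi-square; p < α rejects a hard polytomy.

The discordance-explained ratio compares the mean Robinson–Foulds (or
matching-cluster) distance of simulated gene trees to the species tree
against the mean distance of empirically estimated gene trees, with
mean ± 1.96·SE confidence intervals.  Low- and high-ILS regimes override
every branch θ with 0.001 and 0.1; the estimation-error arm passes each
simulated gene tree through sequence simulation and NJ re-estimation
(rooted with the outgroup) before measuring distances.

Tree distances follow the rooted-cluster convention: RF is the raw
symmetric-difference count of non-trivial clusters; the matching cluster
distance pads the smaller cluster set with empty clusters and solves the
assignment exactly (Hungarian algorithm), cost = symmetric difference.

## Introgression statistics

All statistics run on frequency-weighted site patterns over derived-allele
frequencies polarized against an outgroup; sites where the outgroup carries
any derived allele are dropped (strict polarization).  Patterson's D uses a
delete-one block jackknife over contiguous genomic blocks (default 1 Mb,
final partial block retained); trios are oriented without a prior topology
(P3 maximizes BBAA, then P1/P2 ordered so D ≥ 0) and Benjamini–Hochberg
adjusted.  The f4-ratio splits P3's haplotypes once at random (seeded;
optionally averaged over several splits) and clamps to [0, 1]; it is
accurate for recent pulses and attenuates for older ones (the numerator
only measures drift shared above the admixture time).  f-branch computes
median over sister-descendants A of the minimum over branch-descendants B
of positive f4-ratios, per (branch, P3) cell, masking P3 inside the branch
or its sister, with Z from jackknifing the entire median-min statistic.
Within f-branch the per-pair f4 sums are averaged over several (default 4)
haplotype splits of P3 — a single split is noisy when P3 has few
haplotypes, and that noise was the dominant source of mislocalized maxima
in calibration runs.

D_FOIL evaluates four contrasts (FO, IL, FI, OL) on the symmetric 5-taxon
tree ((P1,P2),(P3,P4)) + outgroup, each an (L−R)/(L+R) over four
site-pattern classes whose left and right sets are mirror images under the
relevant taxon swap (P3↔P4 for FO/IL, P1↔P2 for FI/OL), so all four have
expectation zero without gene flow.  Singleton patterns give the system its
directionality: introgression shortens the recipient's exclusive branch.
The sign signature at the chi-square threshold (default p < 0.001) maps to
an introgression class; the mapping was re-derived by running the package's
own pulse simulations for all eight directed terminal scenarios and the
four ancestral-branch scenarios, and is written in forward-flow
`donor => recipient` notation.  Flow involving the (P1,P2) ancestral branch
yields (s, s, 0, 0) signatures whose direction is not identifiable.

Windowed f_d uses the dynamic-donor denominator (PD = argmax(p2, p3) per
site substituted into both the P2 and P3 slots) over non-overlapping
windows anchored at coordinate 0 (default 50 kb; only full windows); f_d is
masked where the window D < 0 or informative sites are too few.  Note that
conditioning on D ≥ 0 makes the mean of *unmasked* null windows slightly
positive in sparse windows; null calibration therefore uses the genome-wide
mean including a zero for masked windows.

## Topology weighting and stratification

For a window tree whose tips belong to groups, the weight of a candidate
rooted group topology is the fraction of one-tip-per-group subsamples
(plus an outgroup tip used only for rooting) inducing it; with four ingroup
groups the space is the 15 rooted leaf-labelled topologies.  Exact mode
enumerates all combinations (refusing above 10^7); sample mode draws
combinations uniformly.  Window trees are estimated by neighbor joining
from the window's aligned sites, using only the grouped taxa — taxa not
assigned to any group would contribute placement noise without affecting
the weights.

Stratification ranks unmasked windows by a covariate (ties broken by
coordinate, so even a constant covariate splits deterministically) and
compares the top and bottom percentile sets (default 10%) with two-sided
Mann-Whitney tests per topology, BH-adjusted.  Because a planted
introgression event makes the recipient sister to the donor while the
arrangement of the remaining groups stays ILS-distributed, the natural
response for a planted signal is the **cherry weight** — the summed weight
of all topologies in which donor and recipient are sisters — available as
`response="cherry"`.

## The synthetic study

`make_species_tree("prunella-like")` builds a 10-tip tree: an outgroup, a
2-tip clade, three successive single lineages, and a focal subclade of four
lineages (`mod`, `mon`, `ful`, `ocu`) joined by three successive internal
branches of 0.05 coalescent units — inside the anomaly zone, since
a(0.05) ≈ 0.671 — with all other internal branches ≥ 1.  Default θ = 0.02
on every branch (mid-range of the low/high-ILS regimes 0.001–0.1), giving
ingroup sequence divergences of roughly 0.5–8% and ~16% to the outgroup,
the scale of a passerine genus with a family-level outgroup.

The default design plants 2373 exon-like (500 bp) and 6879 intron-like
(1000 bp) loci, packed six per 50-kb window (600 bp invariant gaps inside
the cluster, the rest of the window invariant) across two autosomes and one
"Z-like" chromosome, windows dealt round-robin.  Packing loci in window
clusters rather than spreading them uniformly keeps the aligned sequence
per window (~5 kb) large enough for a usable window tree while retaining
one analyzable window per cluster; at full scale the genome spans ~77 Mb.
A lognormal per-window covariate emulates recombination rate (mean 2
cM/Mb-like, σ_log = 0.7); the Z-like chromosome's covariate is shifted down
fourfold.

**Planted gene flow.**  The default event is a pulse from `mod` into `ful`
0.05 coalescent units before present.  Gene flow is applied only to loci in
autosomal windows whose covariate is above the 0.9 quantile — the
generative stand-in for introgressed ancestry persisting preferentially in
high-recombination regions — and never on the Z-like chromosome.  In the
default *tract* mode each recipient haplotype is introgressed for the whole
window (haplotype set drawn once per window, round(m·n) haplotypes), with
m = 0.9: where introgressed ancestry was retained it is close to local
fixation, while the genome-wide admixture proportion remains ~m/10 ≈ 0.09.
The *lineage* mode instead applies the bare per-locus, per-lineage pulse.
Calibration-style analyses (D-statistic null rates, f4-ratio recovery of a
known m) use lineage mode on small custom trees with genome-wide flow.

Genotypes come from either path: infinite-sites mutation dropping on the
gene trees (fast path; Poisson mutations per branch, one biallelic site
each) or GTR+I+G sequences with biallelic-site extraction against the
outgroup (full path; emits FASTA, an uncompressed VCF with diploid
individuals = consecutive haplotype pairs, popmap, window table and a truth
ledger).  Both drop sites where any outgroup haplotype carries the derived
allele, matching the strict polarization of the loaders.  Everything is
deterministic given the master seed: locus i uses generator seed
`seed + i`, and layout/covariate/tract draws use fixed offsets.

## What the generator does and does not emulate

It reproduces the *statistical structure* the analyses assume: ILS
gradients set by coalescent branch lengths, gene-tree estimation error
growing with shorter loci, window-coherent introgressed tracts coupled to a
recombination-like covariate, a depressed Z-like chromosome, and genomic
coordinates that make block jackknives and windows meaningful.  It does not
emulate: within-locus recombination, linkage between nearby loci beyond
shared window tract status, selection, base-composition heterogeneity
across lineages, sequencing error or missing data, or continuous (rather
than pulse) migration.  Passing tests therefore demonstrate correctness of
the statistics and detectability of planted signals under MSC assumptions,
not performance on real resequencing data.

## Problem sizes and numerical choices

Desk-scale runs use `scale(cfg, 0.1)` (237 exon-like + 687 intron-like
loci, ~7.7 Mb, ~150 windows), which keeps the full pipeline within minutes
on one CPU while leaving ~10 windows per covariate decile — enough for the
rank-sum comparison to resolve p < 10⁻³ when the planted coupling is real.
Simulation-based checks use 1,500–50,000 replicates depending on the
sharpness of the expectation being tested (binomial SEs are quoted in the
tests).  Tolerances: ultrametricity 1e-9 relative; gamma category means
1e-9; percentage sums 1e-6; brute-force distance equivalence exact.
Degenerate inputs are flagged rather than guessed: D with no informative
sites, jackknives with fewer than two non-empty blocks, f4-ratios with
non-positive denominators and empty f-branch cells all return
masked/flagged values.

## Known limitations

* The polytomy test uses tree-level majority-of-quartets counting without
  an effective-sample-size correction for non-independent quartets; its
  type-I error is calibrated by simulation (≈5% at α = 0.05) but can drift
  for gene trees with very many tips per group.
* The f4-ratio's haplotype split halves P3's sample; with very few
  haplotypes the denominator is noisy (an option averages over several
  splits).
* f_d's D ≥ 0 validity filter biases per-window means upward in sparse
  windows (documented above).
* The NJ window trees are point estimates; weight uncertainty within a
  window is not propagated into the stratified comparison.
* D_FOIL assumes the (P1,P2) split is younger than (P3,P4); the caller
  asserts the topology.
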