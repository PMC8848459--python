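# Methods

This note documents the models behind `admixdelim`, the defaults and the
reasoning for them, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## The analysis problem

The package targets radiations of dozens of candidate species connected
by gene flow at several depths: recent hybridization at contact zones,
broad clinal intergradation between phylogeographic lineages, ancient
reticulation between internal branches, and mitochondrial capture.
Delimitation in such groups must combine clustering that models
admixture, tree-based monophyly evidence, and site-pattern statistics
that separate introgression from incomplete lineage sorting (ILS) —
while recognizing that admixed specimens distort concatenated trees.

## Synthetic data generator

Two tiers, matched to what each downstream stage assumes.

**Frequency tier.** Per-site ancestral frequencies are uniform on
(0.05, 0.95) by default. In the *star* mode each population draws
`p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)` (mean `p`, variance `F p (1-p)`) —
the Balding–Nichols model clustering methods assume. In the *tree* mode
drift accumulates hierarchically: each branch of length `t` (coalescent
units) applies a Beta pull with `F = 1 - exp(-t)`, so sister populations
covary — the structure tree-aware site-pattern statistics assume.
Admixture pulses become frequency mixtures `(1-a) p_r + a p_d`; in tree
mode they are applied at the recipient node, oldest first, with the
shift propagated to descendants. Genotypes are `Binomial(2, q_i · p)`
draws from individual mixture frequencies. The tree mode degenerates at
deep divergences (branches with `t >> 1` fix nearly all sites), so
deep-divergence designs should use the coalescent tier; the frequency
tier is for clustering-scale problems.

**Coalescent tier.** A standard multispecies coalescent on a rooted
population tree with branch lengths in units where one lineage pair
coalesces at rate 1. Pulse admixture moves each recipient-branch lineage
to the donor branch with probability `a` at the event time (validated to
fall within both branches' existence intervals). Constructed hybrid
individuals are routed at the tips: an F1 takes one haplotype from each
parent; other classes draw each haplotype from the parents with the
target fractions. Sequences evolve under Jukes–Cantor (exact per-branch
transition probabilities, so closed-form pairwise expectations hold);
missing bases and IUPAC ambiguities are injected at configured rates. A
maternally inherited locus is simulated haploid and represented as two
identical haplotypes; mitochondrial capture replaces carriers' maternal
haplotypes with copies drawn round-robin from donor specimens (no extra
mutations — the construction is meant to be unambiguous, not subtle).

What the generator does **not** emulate: intra-locus recombination,
selection, spatial population continua, sequencing error models beyond
uniform ambiguity injection, and realistic per-locus mutation-rate
variation. Passing tests therefore demonstrate correctness of the
statistics under their own model assumptions, not robustness to every
property of real target-capture data.

Default shape mirrors the study system at roughly quarter scale — 12
populations in 3 clades plus a deep outgroup, 60 loci x 2 kb, 8 diploids
per population — with full scale reachable through `SimConfig`.

## QC filtering

Thresholds are applied with strict inequality exactly as printed in the
field's convention: alleles with >80% missing or >5% ambiguity, specimens
with >50% missing, SNP sites kept only below 20% missingness among the
clade members under analysis (an unstated alternative — computing
missingness over all specimens globally — is available via the API).
Ambiguity codes count as ambiguity; gaps and Ns as missing. Singletons
are defined on haplotypes (minor allele on exactly one haplotype), with
a genotype-level switch. Multi-allelic sites are dropped, not split,
because all downstream statistics are biallelic. PCA mean-imputes
missing genotypes per site; it is a visualization device only.

## Ancestry model

Genotypes 0/1/2 are one-hot expanded to three indicator columns per
site; missing entries are excluded from the loss. The factorization
`X ~ Q G` is fit by alternating least squares with ridge penalty α on
`Q`; unobserved entries are imputed with the current prediction before
each exact least-squares solve (an EM-style majorization), `Q` rows are
projected onto the probability simplex and each (cluster, site) block of
`G` onto the 3-simplex after every half-step, and a half-step is only
accepted if it does not increase the training loss — making the loss
non-increasing by construction. Initialization: by default `Q` is seeded
from a k-means partition of the mean-imputed genotypes (softened to 0.9
one-hot with jitter), which protects single fits against rotated local
optima; a flat-Dirichlet random init is available (`init="random"`) and
relies on replication for robustness. `G` starts from pooled
genotype-class frequencies plus noise; replicates differ by seed.

Model choice uses masked cross-entropy: 5% of observed entries per
replicate are hidden (the cited method's default; the masking fraction
is configurable), and CE is the negative mean log-probability of the
hidden genotype classes with predictions clipped to [1e-10, 1]. α is
chosen from the grid {1, 5, 10, 50, 100, 500, 1000} by minimum median
CE over replicates, ties broken toward the smallest α (least
interference with `Q`). `K` is chosen at the elbow — the interior K with
the largest positive second difference of the median CE curve, provided
the curve actually drops into that K; when no elbow forms, the fallback
is the boxplot-notch rule (median ± 1.57·IQR/√reps, non-overlap with
K-1 while K+1 overlaps K), and failing both, the argmin median with a
`no_elbow` flag.

Hybrid thresholds: >20% secondary ancestry = hybrid; (10%, 20%] =
notable; maximum ancestry ≤ 0.8 = highly admixed; a "streak" is ≥10%
total minor ancestry spread over ≥3 clusters each individually below
10%. Labels are not mutually exclusive. Cluster-to-population matching
uses Hungarian assignment on mean ancestry per labelled population.

## Tree statistics

Neighbor joining (Saitou–Nei) with deterministic tie-breaking by taxon
label order and negative branch lengths clamped to zero with the deficit
moved to the adjacent branch; it is exact on additive matrices. It is an
internal stand-in — the primary path ingests externally estimated ML
trees.

gCF: a gene tree is decisive for a branch when it has at least one taxon
in each of the four adjacent subtrees; it is concordant when, restricted
to its own taxa, it contains the branch's bipartition. sCF: per branch,
sampled quartets (one taxon per adjacent subtree, seeded, default 100);
a site is decisive for a quartet when all four taxa are called, two
alleles occur, and the split is 2+2. Branches with no decisive trees or
sites are flagged undefined, never reported as zero. The *terminal* gCF
of a specimen is the gCF of the internal branch immediately ancestral to
its terminal edge — hence sister specimens in a cherry share a value,
which is expected and documented.

Colless' `I` sums `|L - R|` over all internal nodes of a rooted binary
tree (cherries contribute 0). The PDA normalization divides by `n^{3/2}`,
the scaling of expected imbalance under the
proportional-to-distinguishable-arrangements null; division by the
caterpillar maximum `(n-1)(n-2)/2` is available as an option. Polytomies
are rejected (a seeded random resolver is provided but never applied
implicitly).

## Introgression statistics

All statistics run on population derived-allele frequencies polarized
against a designated outgroup (the outgroup's major allele is ancestral;
sites with outgroup minor-allele frequency above 0.1, configurable, are
dropped). Loci are the linkage blocks for the delete-one block
jackknife: `SE = sqrt((m-1)/m * sum (theta_(-j) - mean)^2)`.

Patterson's D uses the frequency form `ABBA = sum (1-p1) p2 p3 (1-p4)`,
`BABA = sum p1 (1-p2) p3 (1-p4)`, with P1/P2 oriented so D ≥ 0 (original
orientation recorded). D is only centred on zero for trios oriented
consistently with the species tree; the experiment drivers orient trios
by the true topology before testing.

The f4-ratio splits the donor population's called haplotypes per site
into random halves — implemented as a seeded hypergeometric draw on the
derived counts, which is distributionally identical to partitioning the
haplotypes — removing the same-sample `p^2` bias. The estimate is
`sum (pB - pA) pCa (1-pO) / sum (pCb - pA) pCa (1-pO)`, clamped to
[0, 1] with the raw value retained; a non-positive denominator flags the
result undefined.

f-branch: for branch `b` and donor `C` outside `b`'s subtree,
`f_b(C) = median over A in sister(b) of min over B in desc(b) of
f4(A, B, C, O)`, negative medians clamped to 0, donors inside the
recipient clade structurally masked. Significance is a block jackknife
of the full median-min statistic, recomputed from cached per-trio block
sums. Display cells require both value > 0.20 and jackknife p < 0.05
(reconciling the "values above 20%" and "truncated at significance"
readings); raw values and p-values are always emitted. A row-correlation
report is provided to spot the correlated-row signature of deep
branch-to-branch events; it is an observation aid, not a test. The
statistic is partially symmetric: a very recent tip-to-tip pulse hands
the recipient the donor's entire private drift and the mirrored cell can
rival the true one; localization is sharpest for pulses that predate
part of the donor's terminal drift.

## Delimitation rubric and distortion statistics

The rubric is deterministic and order-invariant: (R4) clusters whose
members all lack a majority single-source ancestry (no member with
q_max ≥ 0.5, configurable) are hybrid-flagged; (R1) prior candidates
whose specimens merge into one cluster and are not reciprocally
monophyletic are lumped under a compound name; (R3) non-monophyletic
clusters sharing a prior candidate and linked by admixture (≥10% of
members hybrid-classified, configurable) become phylogeographic lineages
within that candidate; (R2) reciprocally monophyletic, geographically
distinct clusters are kept (or recognized as new when a prior candidate
splits). Geography enters only as a boolean column supplied by the user
— the package does no spatial analysis. Anything unmatched is returned
as "unresolved", never silently assigned.

Distortion statistics: (i) the triangular envelope of terminal gCF
against maximum individual ancestry, formalized as the maxima over fixed
deciles of the ancestry scale with a one-sided Spearman trend test
(fixed [0, 1] deciles pool enough specimens per bin to make the maxima
meaningful; deciles of the observed range proved too narrow); and (ii)
OLS of PDA-normalized Colless imbalance of each candidate's induced
subtree on the SD of its members' maximum individual ancestry
(single-specimen candidates excluded; zero variance flagged). The
rootward-shift test compares hybrids' node-count distance from the
candidate crown against pure members' (one-sided rank-sum), with
terminal branch lengths compared likewise; ranks rather than
substitution depths make it robust to rate variation.

## Validation experiments and problem sizes

The replicated experiments in `admixdelim.experiments` use these sizes,
chosen to give each test clear signal at desk scale:

* Null calibration: the 12-population default community, 60 loci x
  400 bp, 3 diploids per population; 100 tree-consistent trios for D and
  20 replicates for f-branch.
* Pulse recovery: frequency tier, a = 0.3, 50,000 sites, 10 diploids per
  population; f-branch localization under the MSC with a = 0.4 at 2/4 of
  the donor branch height, 50 loci x 400 bp.
* Ancestry recovery: Balding–Nichols star model, K = 3, F = 0.2, 60
  individuals (10% admixed) plus one F1, 5000 SNPs; the recovery fit
  uses α = 1 (heavier ridge visibly shrinks admixed rows), K selection
  scans K = 1..5 with 3 masked replicates per K.
* Distortion experiment: 24 candidates in sister pairs (crowns at 2.5,
  two sublineages per candidate at 1.0, ladder step 0.8, outgroup at
  18), 14 diploids per candidate of which 30% in odd-numbered candidates
  are admixed with fractions spread evenly from 0.5 to 0.9, 90 loci x
  500 bp. The within-candidate sublineage structure (with a sparsely
  sampled second sublineage) matters: it is what lets pure specimens
  attain high terminal gCF, giving the envelope its contrast. The evenly
  spread ancestry fractions produce the ladder-like grades that drive
  the imbalance signal; identical F1s instead form a balanced hybrid
  clade and mask it.

## Known limitations

* The NJ builder is a stand-in; branch supports, model-based branch
  lengths, and ML topology search are out of scope by design.
* f-branch cannot distinguish donor from recipient in its partially
  symmetric cells, nor sampled donors from ghost lineages.
* The frequency tier's pulse model mixes population frequencies, which
  reproduces first moments but not the locus-level mosaicism of real
  hybrid genomes; analyses sensitive to that mosaicism (concordance,
  topology) must use the coalescent tier.
* The rubric encodes one defensible reading of the delimitation
  workflow; the thresholds it takes (hybrid fraction for lineages,
  majority-ancestry cutoff for hybrid flags) are exposed rather than
  asserted as canonical.
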