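# Methods

This note documents the models, estimators and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical conventions shared across the package.

## Data model

The unit of observation is a *clone*: one sequenced plasmid insert from a
PCR amplicon of a single fly's symbiont population. Clones carry
(site, individual, PCR replicate, clone tag) provenance in their FASTA ids.
All statistics operate on the aligned amplicon (600 bp by default in
simulations; in general, alignment length is a property of the input).
Haplotype identity is exact string identity including gaps and Ns;
ambiguity handling is deferred to each statistic rather than resolved at
parse time, so the raw data survive round trips unchanged.

Sequence comparisons everywhere (artifact distances, networks, AMOVA) count
substitutions only at columns where both sequences have an unambiguous base;
gaps and Ns never contribute mutational steps. Diversity statistics default
to *complete deletion* (drop any column with a gap or N in the analyzed
subset), the convention of the standard desktop tools for these estimators,
with pairwise deletion available as an option.

## Artifact filter

Polymerase errors along a clone's amplification lineage are modeled as
Poisson with mean

    lambda = rate_e * L * c,

where `rate_e` is the per-bp per-cycle error rate, `L` the amplicon length
and `c` the effective number of cycles summed over consecutive PCRs (two
rounds of 35 are treated as c = 70 on the analysis side: an error in either
round can propagate). The analysis default is rate_e = 4e-4, the midpoint of
the 1–7 × 10⁻⁴ per bp per cycle range quoted for the polymerase used in this
kind of protocol; both knobs are configurable.

A candidate singleton at substitution distance d ≥ 1 from its nearest
retained neighbour is explainable as PCR error with probability

    p_one = P(Poisson(lambda) >= d)
    p     = 1 - (1 - p_one)^n          (n = clones sequenced in the library)

and is flagged as an artifact when p ≥ α (default 0.05): the observed
distance is then within the error-plausible range. The two conditions the
retention rule could impose — "probability at least α" and "within the
error-plausible distance" — are the same condition, since p is monotone
decreasing in d; the implementation uses the probability directly.
Haplotypes seen twice or more (within or among individuals) and haplotypes
verified in two independent PCR replicates of one individual are retained
without testing. Nearest-neighbour ties break by smallest distance, then
largest count, then lexicographic sequence, so decisions are deterministic.

The filter emits the *complete* dataset (retained singletons included) and
the *conservative* dataset (count ≥ 2 only), plus a per-haplotype decision
log (rule fired, neighbour, distance, lambda, probability) from which a
false-haplotype rate against simulated ground truth can be read directly.

Known limitation: the multiplicity rule cannot distinguish a genuine rare
strain from two clones that independently acquired the *same* substitution.
With ~500 clones concentrated on a handful of abundant strains, the expected
number of such coincident duplicates is of order 0.2–0.6 per library for any
per-clone error mean in the range that leaves the conservative dataset
non-empty, so conservative haplotype counts occasionally exceed the true
strain count by one or two. This is a property of the retention rule itself
(shared with the laboratory protocol it models), not of the implementation;
the tests therefore distinguish the containment guarantee (every true strain
whose sequence recurs is recovered — which holds essentially always) from
strict count equality (which fails in the minority of libraries containing a
coincident duplicate).

## Recombinant screen

Restricted to polymorphic columns, a pair's *inner fragment* is its longest
mismatch-free run of consecutive polymorphic sites (infinite mismatch
penalty, the screening tool's default convention). The null distribution
jointly permutes the order of polymorphic columns across all sequences:
this preserves every pair's per-site agreement profile while destroying
positional contiguity, which is exactly the recombination signal (tree-like
relatedness produces agreement *density*, not contiguity, so star- or
subgroup-structured data are not flagged). Per-pair p-values compare the
observed pair score with the permuted distribution of the *global* maximum
score, p = (1 + #{null ≥ obs}) / (1 + n_perm), then Bonferroni-correct over
tested pairs. Which member of a significant pair is the recombinant is not
identifiable from the statistic, so the lower-frequency member is removed
(ties: the lexicographically later sequence), and both ids are logged.
Fewer than 3 haplotypes or fewer than 2 polymorphic sites yield a no-test
result, distinct from "tested, nothing flagged". Only within-alignment
(inner) fragments are implemented; comparisons against an external sequence
pool are out of scope.

## Diversity

* Haplotype diversity: Nei's unbiased Hd = n(1 − Σ pᵢ²)/(n − 1).
* Mean pairwise differences k and nucleotide diversity π = k/L_eff are
  computed over the exactly expanded multiset (multiplicities are never
  sampled), via per-column allele counts under complete deletion.
* Segregating sites S counts analyzed columns with ≥ 2 states.

Reports round Hd to 3 decimals and π to 5, matching the print precision of
the tables this kind of analysis produces. Groups with n < 2 are reported
as undefined (NaN) rather than dropped or zeroed.

## Parsimony network

Haplotypes are connected only while the mutation chain between them is
credibly homoplasy-free. The probability model: j mutational events falling
independently and uniformly on L sites are all at distinct sites with

    P_j = prod_{i=1}^{j-1} (1 - i/L),

and the connection limit is the largest j with P_j ≥ the confidence level
(default 0.95; L = 600 gives 8 steps). P_j is monotone decreasing in j and
increasing in L. The classical statistical-parsimony software uses a related
probability-of-parsimony series whose exact coefficients are not published
in a reproducible form; the distinct-sites model above is documented,
testable against an independent exact-fraction evaluation, and a fixed-limit
override is provided for users who want to force a specific published limit.

Within the limit every qualifying pair receives an edge annotated with its
step count and d − 1 inferred intermediates; ambiguity loops are retained
rather than broken (downstream use needs components and step distances, not
a unique tree), so components coincide with those of the distance-threshold
graph — which is also how they are verified. Components sorted by total
haplotype frequency become Group1, Group2, …; cutting within-group edges
longer than the subgroup threshold (default 5 steps, an assumption — the
source analyses give no numeric rule) yields subgroups labeled 1a, 1b, … by
descending frequency, only when a group actually splits.

## AMOVA

One-level analysis of molecular variance on squared substitution distances,
with haplotype multiplicities expanded to individual sequences:

    SSD_total  = sum_{i<j} d²ij / N
    SSD_within = sum_g sum_{i<j in g} d²ij / n_g
    sigma²_w   = SSD_within / (N − G)
    sigma²_a   = (SSD_among/(G − 1) − sigma²_w) / n',
    n'         = (N − Σ n_g²/N)/(G − 1)

Percentages are computed from the components, so pct_among + pct_within =
100 identically, including when sigma²_a < 0 (less structure than random
expectation — reported as negative, with pct_within > 100, not clipped).
Zero total variance reports 0/100 with a warning instead of NaN. The
permutation test shuffles sequence→group labels with group sizes fixed
(the permutation unit is the individual sequence) and uses the add-one
convention p = (1 + #{Φ_perm ≥ Φ_obs})/(1 + n_perm); default 10,000
permutations.

## Association tests

Both randomization tests shuffle the focal indicator across individuals
with its total fixed — Group 2 carriage for the carriage × southern-
haplogroup count (n = 47 sequenced flies), infection status for the
proportion of infected individuals carrying a contact-region mtDNA
haplotype (N = 366 screened flies). The default p-value is the plain
proportion #{null ≥ observed}/n_rand with n_rand = 100, matching the
convention of small randomization designs; an add-one variant (which cannot
return 0) is available by flag. Note that 100 randomizations resolve p only
to about ±0.1; configurations shipping larger n_rand are recommended for
borderline values. The count statistic at n = 47 is an exact conditional
test on a coarse (hypergeometric) lattice and is therefore conservative:
its realized type-I error at nominal 5% is ~3%. The N = 366 proportion
statistic has a fine lattice and is calibrated at nominal level. One-sided
"≥" is fixed by the directional hypotheses (excess, not deficit). The
per-haplotype infection test is the exact one-sided binomial tail
P(X ≥ k | n, ½); no multiple-testing correction is applied across
haplotypes by default (a Bonferroni flag exists).

## Synthetic data generator

The generator reproduces the study design: 10 collection sites with 2–8
flies each (47 total), 2–20 clones per fly, and host metadata with mtDNA
haplotypes in northern/southern haplogroups and a contact-region subset.

Strain geometry uses disjoint substitution position sets so that all
inter-strain distances are exact by construction: lineage 2 sits 40
substitutions from lineage 1 (far beyond the 8-step connection limit, so
two networks always emerge); within lineage 1 three subgroup centroids sit
7 steps from the lineage ancestor (above the 5-step subgroup cut, below the
connection limit); leaf strains sit 1–3 steps from their centroid.
Centroids get 5× the sampling weight of leaves, making a few strains common
across flies, as observed in real libraries. Flies carry 1–3 lineage-1
strains; Group 2 carriage is drawn with baseline probability 0.25 shifted
by log-odds θ (default 1.5) for southern flies, and superinfected flies
carry 1–2 lineage-2 strains in addition.

Per-site clone error uses the cycle-compounded probability
1 − (1 − rate_e)^c, matching the artifact filter's Poisson mean to first
order and keeping the simulator analytically checkable. The default error
regime is rate_e = 1e-4 with c = 35 (per-clone mean λ = 2.1): the low end
of the quoted polymerase fidelity range with a single effective
reconditioned round. The quoted range taken at face value with 70 effective
cycles implies λ ≈ 17 errors per clone — a regime in which no clone would
ever match its template and repeated identical haplotypes could not occur,
contradicting the observation the protocol is built on (haplotypes recurring
across clones and individuals); λ ≈ 2 reproduces the qualitative structure
real libraries show (roughly 10–15% of clones error-free, a conservative
dataset of ~10–16 haplotypes). In superinfected flies each clone is, with
probability 0.05, spliced from two co-resident templates at a uniform
breakpoint. Three flies at one site have their clones split across two PCR
replicates, feeding the replicate-verification rule.

Every clone's provenance — template, splice partner and breakpoint, error
positions, and which true strain (if any) the final sequence equals — is
recorded in a ground-truth event log. A splice whose breakpoint misses all
differing sites, or an error landing exactly on a sister strain's private
substitution, is booked as an observation of the strain it reproduces,
which makes "strain observed k times" well-defined at the sequence level.

What the generator does **not** emulate: indels and alignment error (the
statistics exclude gap columns anyway), transition/transversion bias and
rate heterogeneity along the amplicon, PCR jackpot effects (an early-cycle
error propagating into many clones of one reaction), chimera formation
mechanisms beyond a single uniform breakpoint, and any coalescent structure
within subgroups (star-shaped divergence only). Passing tests therefore
demonstrate correctness of the estimators and decision rules under a
clean, analytically tractable error process — not robustness to every
artifact of real capillary data.

## Pipeline and reproducibility

Stage order: filter → recombinant screen → datasets → network → diversity →
AMOVA → association. One global seed derives per-stage seeds through
`SeedSequence(seed, spawn_key=(stage_index,))` (all below 2³¹), so any
stochastic stage can be re-run in isolation; each run writes a config
snapshot and a manifest with SHA-256 checksums, and identical seeds and
inputs give identical checksums. Problem sizes in the shipped test suite
are chosen for tight feedback (e.g. 50-seed batteries for recovery and
network criteria, 500 datasets × 1000 shuffles for calibration, 10⁴
permutations where p-value stability is asserted).
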