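# Methods

## The branch test of episodic positive selection

The central statistic asks whether a single branch of a gene tree carries
more nonsynonymous change than its mutational opportunity predicts. For a
branch with parent and child coding sequences, we count

* potential sites per codon by the Nei–Gojobori rule: each of the three
  positions contributes one site, split into a synonymous fraction equal to
  the proportion of its single-base changes that preserve the amino acid.
  Changes that would create a stop codon are excluded and the fraction is
  renormalized over the remaining valid changes (the convention of the
  MEGA-style distance tools; counting stop-adjacent changes as
  nonsynonymous is the common alternative and could be added as a flag).
  An optional κ-weighted variant multiplies transition changes by κ before
  forming the fraction; κ = 1 reduces exactly to the unweighted rule.
* substitutions between two codons by pathway averaging: syn/nonsyn step
  counts are averaged over all orderings of the differing positions,
  pathways through stop codons are dropped from the average, and if every
  pathway is blocked the positions are classified independently (logged).

The branch's site totals N and S are the average of the parent- and
child-sequence totals (symmetric, standard). The test statistic is the
one-tailed Fisher exact probability of the 2×2 table
`[[ns, s], [N−ns, S−s]]`, summed by the hypergeometric tail toward
nonsynonymous excess. Fisher's test needs integers: fractional site totals
are rounded to the nearest integer and fractional pathway-averaged counts
half-up, and the table actually tested is always carried in the output,
because printed p-values are sensitive to this rounding and cannot be
regenerated without it. Branch dN/dS uses the Jukes–Cantor-style
correction d = −(3/4)·ln(1 − 4p/3) on pN = ns/N and pS = s/S; when s = 0
the ratio is reported as the +∞ sentinel with dS = 0 flagged rather than
silently dropped, since those rows are often the most interesting ones.

P-values are reported raw per branch; Bonferroni and Benjamini–Hochberg
corrections are available but off by default, matching the convention of
reporting each branch's evidence and letting the reader weigh the number
of branches examined.

### Power characteristics

The exact test is conservative when the site margins dwarf the
substitution counts. In pipeline simulations (500 codons, six taxa,
ω = 6 burst over an ω = 0.2 background), a burst leaving ~20–23
substitutions on the focal branch is flagged as the minimum-p branch in
effectively every replicate and rejects at α = 0.05 in roughly 70–90% of
them depending on how many synonymous changes co-occur; rejection
exceeds 0.95 for bursts of ~35+ substitutions. Under ω = 1 everywhere the
per-branch rejection rate at α = 0.05 is ~0.02 — the test is conservative,
not anticonservative, under the null.

## Ancestral reconstruction

Per-site marginal ML states under JC or K80 on the fixed rooted input
tree, by the standard two-pass algorithm: a postorder pass of conditional
likelihoods and a preorder pass of outside likelihoods, multiplied and
normalized into per-state posteriors at every internal node. Choices that
matter:

* K80's κ is estimated, when not supplied, as 2·(ts/tv) from pairwise
  counts (two transversion partners per base against one transition
  partner make 1:2 the equal-rate expectation).
* Branch lengths of zero are floored at 1e-9 so transition matrices stay
  nonsingular; a zero-length tree thus reconstructs the site consensus.
* Leaf gaps/ambiguities are masked per site (likelihood 1 for every
  state), not deleted, so a gap in one taxon does not erase the column.
* Ties in the marginal posterior are broken in lexicographic order
  A<C<G<T for determinism. On symmetric topologies this can place a
  substitution on one of two equally likely root-adjacent branches; path
  sums across the root are invariant.
* Marginal (not joint) reconstruction is implemented, and reports say so;
  for the closely related sequences this pipeline targets the two almost
  always coincide.

Rate heterogeneity (+I/+G) and richer models are deliberately out of
scope: reconstruction feeding a counting test is robust to them at small
divergences, and the tree itself is always an input.

## Population-genetic statistics

π, mean pairwise differences and segregating sites use complete deletion
of gap/ambiguous columns within the analysed region (DnaSP-like), with
the removed-column count logged. Tajima's D follows the 1989 constants
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) and is undefined — not zero — when
S = 0. Sliding windows default to 100 bp at a 25 bp step (both settable);
windows retaining fewer than 3 post-deletion sites are flagged undefined.

Linkage disequilibrium: D = p_AB − p_A·p_B, normalized to Lewontin's
D′ = |D|/D_max, with a two-tailed Fisher exact p on the haplotype table.
The "coding versus 3′-region" association of a dimorphic locus is
computed by first assigning each region's sub-haplotype to a clade via
diagnostic sites (threshold 0.9 of diagnostic sites matching; mixtures are
flagged as candidate recombinants) and then treating the two clade labels
as a two-locus haplotype; per-site D′ is also available.

Hardy–Weinberg: the default is the exact conditional test (all
heterozygote counts compatible with the observed allele counts are
enumerated; the p-value sums configurations no more probable than the
observed one); a 1-df chi-square is available.

Haplotype networks are minimum-spanning networks over pairwise Hamming
distances: edges enter by increasing distance class, and within a class
every edge joining components that were distinct *before* the class is
retained, so equal-length alternatives survive as reticulations instead of
being broken arbitrarily. Multi-step edges are expanded with inferred
intermediate haplotypes (sites mutated in coordinate order). The
"parsimony95" connection limit uses a birthday-problem approximation —
the largest m with exp(−m(m−1)/(2L)) ≥ 0.95 — as a documented
simplification of the full statistical-parsimony machinery; pairs beyond
the limit stay in separate components, which is exactly how a deep allelic
dimorphism splits into two subnetworks.

## Dating

Silent divergence pools synonymous coding differences (over synonymous
sites) with noncoding differences (over noncoding sites), per-site
weighted, on the assumption that both classes are effectively neutral. A
strict clock rate r = d/(2T) is calibrated from each dated split supplied
in config, and the focal divergence maps to the range
(d/(2r_hi), d/(2r_lo)). The only uncertainty carried is the min/max over
calibration points — no sampling CI, no relaxed clock — matching the
coarse-grained use of such dates.

## Synthetic data

The generators produce the statistical structure the analyses assume, and
define the conditions the tests run under:

* **Codon evolution**: Gillespie-style along each branch. Branch length is
  the expected number of candidate mutations per nucleotide site; targets
  are drawn with κ-weighting (default κ = 2); mutations creating stop
  codons are rejected; a nonsynonymous candidate fixes with probability
  ω/max(1, ω) and a synonymous one with 1/max(1, ω). This reduces to
  "synonymous always, nonsynonymous with probability ω" for ω ≤ 1 and
  preserves the ω ratio of fixation probabilities for ω > 1, where the
  naive rule is not a probability. Root sequences draw uniformly from the
  61 sense codons. True per-branch events are recorded, so the test's
  power can be benchmarked with and without reconstruction error.
* **Dimorphic population**: two core haplotypes separated by fixed
  differences in a 900 bp coding and a 600 bp 3′ block (defaults 10 and 8
  differences — deep dimorphism of roughly 1–2% in each block), 16 diploid
  individuals drawn at clade frequency 0.5, Poisson(0.5) private mutations
  per haplotype, optional inter-block recombination, and sequential random
  pairing of haplotypes into individuals (which is exactly Hardy–Weinberg
  sampling). These defaults mirror a balanced receptor-locus sample of the
  kind the analysis targets.
* **Neutral coalescent**: the textbook n-coalescent — Exp(k(k−1)/2)
  coalescence times, Poisson(θ/2 per unit branch) mutations, infinite-sites
  placement on distinct positions — so E[π] = θ and E[S] = θ·Σ1/i.
  Finite-site collisions are absent by construction, a documented
  divergence from real data.

What passing these simulations does *not* show: the codon generator has no
rate variation among sites or codon-usage bias; the population generator
has no demography, gene conversion or selection; the coalescent has no
recombination. Real-data deviations in these directions would mainly cost
power, not calibration, for the branch test.

## Numerical and interface conventions

Coordinates are 0-based half-open internally and 1-based closed in
human-readable reports. Gap policy is owned by each statistic (pairwise
codon deletion for dN/dS, per-site masking for reconstruction, complete
deletion for diversity) rather than applied at read time. Fractional site
and substitution counts stay real-valued everywhere except the Fisher
table. Neighbor joining breaks Q-matrix ties toward the lexicographically
smallest pair and clips negative branch-length estimates to zero. The JC
correction raises a saturation error at p ≥ 3/4 instead of returning NaN.
Sequence-logo information content applies no small-sample correction by
default (web logo tools subtract (19)/(2·ln2·n); the flag enables the
analogous correction).

## Problem sizes

The shipped tests and the acceptance script use: 1,000 random codon pairs
against enumeration oracles; every Fisher table with margins ≤ 30
(~244k tables); 200 neutral coalescent replicates at n = 20, θ = 5;
50 burst and 56 null full-pipeline replicates of a 500-codon, six-taxon
gene (504 null branch tests); ~1.2k Hardy–Weinberg configurations with
totals ≤ 50 against enumeration; and 50 clock-recovery replicates at
1,000 silent sites. These sizes give Monte-Carlo standard errors well
inside the asserted bounds while keeping a full run under a minute each
for the suite and the script.

## Known limitations

* The exact test's integer rounding of fractional site totals makes
  printed p-values tool-dependent; published per-branch p-values can
  differ from re-computations unless the exact 2×2 table is known, which
  is why reports always include it.
* Marginal reconstruction near equally likely states places substitutions
  deterministically but arbitrarily between tied branches.
* The statistical-parsimony limit is an approximation; it tracks the
  qualitative behavior (longer sequences connect deeper) rather than the
  exact published limits.
* Dating inherits every assumption of a strict clock and of neutrality of
  silent sites; its range reflects calibration spread only.
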