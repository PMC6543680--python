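# Methods

## The model

`hils` detects hybrid species from site-pattern frequencies under a
coalescent model with hybridization. A hybrid species network on four
taxa — an outgroup O, parental species P1 and P2, and a putative hybrid
H — is a mixture of two parental species trees that share all speciation
times τ1 < τ2 < τ3 (coalescent units, tips at time 0):

    S1 = (((H,P2):τ1, P1):τ2, O):τ3        weight γ
    S2 = (((P1,H):τ1, P2):τ2, O):τ3        weight 1 − γ

Each site (or locus) chooses S1 with probability γ, draws a gene tree
from the multispecies coalescent along the chosen tree, and evolves one
site (or locus) along that gene tree under a Markov substitution model.
The 256 ordered site patterns X_O X_P1 X_H X_P2 are therefore a
multinomial sample whose cell probabilities are the γ-mixture of the
two parental-tree pattern distributions.

## Invariants, the γ estimator, and the Hils statistic

Under the JC69 symmetry the informative patterns collapse into six
cumulative classes (iijj, ijij, ijji, ijii, iiji, iiij with i ≠ j).
Four linear invariants

    f1 = p_iijj − p_ijij     f3 = p_ijii − p_iiji
    f2 = p_ijji − p_ijij     f4 = p_iiij − p_iiji

satisfy f2 = f4 = 0 on S1 and f1 = f3 = 0 on S2, and the parent-swap
symmetry p_ijji(S2) = p_iijj(S1), p_ijij(S2) = p_ijij(S1) makes each of
f1/f2, f3/f4 and (f1+f3)/(f2+f4) equal to γ/(1−γ) on the mixture.
The point estimate is γ̂ = r/(1+r) for the chosen ratio r; it is
deliberately not clamped to [0,1] so replicate averages are unbiased
summaries. The default ratio is f1/f2, which is the most powerful of
the three in simulation; f3/f4 and the pooled ratio are retained for
study replication.

The test of H0: γ = 0 against H1: γ > 0 applies the Geary–Hinkley
transformation to the ratio of the two asymptotically normal invariant
estimates, with multinomial plug-in moments (means, variances,
covariance, all carrying the 1/N factor):

    H = f̂2 (f̂1/f̂2) / sqrt(σ̂²_f2 R² − 2 σ̂_f1f2 R + σ̂²_f1),  R = f̂1/f̂2,

compared to a standard normal with a one-sided upper-tail p-value.
The same statistic also covers the γ = 1 boundary via the model's
P1/P2 symmetry. Moments are computed from one generic formula for
linear combinations of disjoint multinomial classes, so all three
ratios share a single code path.

Within a quartet, the hybrid designation whose parents-share frequency
strictly dominates (p̂_ijij > max{p̂_iijj, p̂_ijji}) is eliminated: it
implies the designated parents are sisters. Ties retain the
assignment.

## Scans over many taxa

For n ingroup sequences and an outgroup, all C(n,3) triples are tested
under each hybrid designation; elimination removes one designation per
triple, giving the nominal M = C(n,3) × 2 comparisons that form the
Bonferroni denominator (a row is significant when p < α/M). M is
deliberately the nominal count, not the post-elimination count, so
per-test thresholds match the convention of published analyses.
Eliminated assignments are reported, flagged, without statistics, for
auditability. When several alleles are sampled per group, enumeration
draws one allele from each of three distinct groups (M = 2 × Σ over
3-subsets of the group-size products); an optional constraint requires
the three groups to span at least two species. Multiple outgroups are
handled as one scan family per outgroup, each with its own Bonferroni
correction.

The Hils statistic is not symmetric in the two parents: its derivation
puts the invariant that is non-zero under the null in the denominator.
In a blind scan the null-compatible order is unknown, so within each
retained designation the parents are ordered so that p̂_ijji ≥ p̂_iijj
(P1 = the parent sharing more states with the putative hybrid). This
choice puts the smaller excess in the numerator and is therefore
conservative in near-tied cases; four-taxon studies instead use the
fixed, known assignment (which is what makes slightly negative
replicate-mean estimates at γ = 0 possible).

Detections in simulation studies are scored at clade level: a
significant row is a true positive if it names one taxon from the
hybrid clade and one from each donor clade with the hybrid correctly
designated, a "true set" if the triple is correct but the hybrid is
mis-designated, and a false positive otherwise.

## The simulator

The simulator is vectorized across sites. Gene trees are drawn from
the multispecies coalescent population-by-population: within each
species-tree branch, k lineages coalesce at rate k(k−1)/2 with
exponential waiting times, uncoalesced lineages entering the parent
population at each speciation time; all sites advance through one
population simultaneously as flat arrays. Sequences evolve node-by-node
down each gene tree with GTR transition probabilities obtained from one
eigendecomposition of the symmetrized rate matrix, evaluated for all
sites' branch lengths at once. This makes the coalescent-independent-
sites design (one fresh gene tree per site) practical at 10^5–10^6
sites per replicate (≈ 2 s for 500,000 quartet sites), which is what
the replicated calibration studies require. A spot check against
closed forms guards the machinery: pairwise coalescent height
E = τ + 1, rooted-triple discordance (2/3)e^(−T), the JC69
transition function, and the stationary base frequencies.

Key numerical and design choices:

* **Units and scale.** Speciation times and gene-tree branch lengths
  are in coalescent units; the substitution model multiplies them by a
  `scale` factor, default 1.0 (coalescent lengths are handed to the
  substitution process unchanged, mirroring a pipeline that feeds
  coalescent gene trees directly to a sequence simulator).
* **Benchmark model.** The preset `benchmark-gtr` is GTR+I+Γ with
  exchangeabilities (1.0, 0.2, 10.0, 0.75, 3.2, 1.6) for
  (AC, AG, AT, CG, CT, GT), base frequencies (0.15, 0.35, 0.15, 0.35),
  proportion of invariable sites 0.2, gamma shape 5.0 with 3 discrete
  categories — the classic Seq-Gen-style option set used throughout the
  calibration studies. The rate matrix is normalized to mean rate 1 at
  stationarity.
* **Site-rate convention.** Discrete-gamma category rates are the
  category means of a mean-1 gamma distribution; invariable sites
  simply do not evolve. With p_inv = 0.2 the mean rate over all sites
  is therefore 0.8, matching the behaviour of the classic simulators
  this preset emulates (no compensatory 1/(1−p_inv) rescaling). This
  convention reproduces both the replicate-mean and the
  replicate-spread behaviour of γ̂ on the benchmark settings better
  than the mean-1-over-all-sites alternative.
* **Allocation.** The number of S1-derived sites (or loci) is fixed at
  round(total × γ) by default, with Bernoulli-per-tree sampling as an
  option.
* **Clock violations.** `stretch_tip` lengthens one tip's pendant
  branch by a factor at the substitution stage only — each parental
  tree adds (factor − 1) × (its own pendant species-branch length) to
  that tip's gene-tree pendant edges; coalescent times are unchanged.
* **Multilocus mode** draws one gene tree per locus and evolves
  locus_length sites on it with iid site rates; the coalescent-
  independent-sites mode is the limit of one-site loci.
* Only one hybrid edge per network is supported. Networks can be given
  as two clock trees plus γ, or as one-reticulation extended Newick
  (`#H1` tags, `:length::gamma` annotations).

## Benchmark settings and example networks

The four-taxon calibration studies use the "short" (τ = 0.25, 0.5,
1.0) and "long" (τ = 0.5, 1.0, 2.0) speciation-time settings with
γ ∈ {0, 0.1, …, 0.5} and 50,000–500,000 coalescent independent sites.

The shipped 9- and 20-taxon example networks are reconstructions, not
published trees: no branch lengths for such networks are in print.
They follow the long-setting depth scale (0.25–0.5 coalescent units
between speciations, outgroup split ≤ 2.75) and attach the hybrid
lineage between two *sister* donor lineages — sister tips for the
"shallow" event, sister two-taxon clades (donors of an ancestral hybrid
lineage) for the "deep" event. Sister donors matter structurally: they
confine the hybridization signal to triples containing the hybrid and
one taxon from each donor clade, so detection is clean; donors placed
in unrelated clades would leak genuine mixture signal into many
neighbouring triples. Quantitative claims about these networks are
limited to the family-wise null level of the scan; power against γ > 0
depends strongly on the (unknown) depths and is reported by the study
harness without a reference value.

## What the synthetic data do and do not show

The generator realizes exactly the model the test is derived under —
iid (or locus-wise iid) site patterns from a one-hybrid-edge clock
network mixture, with GTR+I+Γ substitution. Passing tests show
calibration and recovery under that model, including robustness of the
JC69-collapsed invariants to a strongly non-JC69 generating model.
They do not probe recombination within loci, continuous migration
(only the discrete γ-mixture), selection, alignment error, base
composition heterogeneity across lineages, or non-clock species trees
beyond the pendant-branch stretch scenarios; empirical-data behaviour
such as missing data and ambiguity codes is exercised only through the
column-exclusion rule.

## Numerical notes and limitations

* The asymptotic N(0,1) null of H is accurate near the centre of the
  distribution at N = 10^5 but its far right tail is heavier than
  normal when the denominator invariant's separation is weak (deep,
  saturated quartets): in exact multinomial resampling the
  P(H > 3.3) can be several times the nominal value. In Bonferroni
  scans (per-test levels ~10^-4) this makes the family-wise level
  depend on the network's depths; on the shipped example networks the
  125-replicate family-wise rate is ≈ 0.05–0.06, consistent with the
  mild excess reported for this class of tests.
* The γ estimator's sampling SD on the published benchmark is
  reproduced on the long setting; on the short setting the exact
  multinomial SD under this generating process is about half the
  published spread. This is robust: it holds under either site-rate
  convention, and lowering the branch-length scale (0.4–0.8) shrinks
  rather than widens the spread, so no scale choice closes the gap.
  Published short-setting spreads of that size (including order-1 SDs
  at 50,000 sites) require a smaller invariant separation than this
  generating process produces at those speciation times — consistent
  with a different coalescent time/rate unit convention in the original
  gene-tree simulation (more incomplete lineage sorting at the same
  nominal τ). The replicate means, which are the recovery claim, agree
  in all cells regardless.
* Degenerate cases are surfaced, not patched: a zero denominator
  invariant raises an undefined-estimate error; r = −1 yields a NaN
  γ̂; a non-positive variance expression raises a degeneracy error; in
  scans such rows are reported without statistics and never count as
  significant.
* Pseudocounting (default 0.005 per raw pattern cell, N recomputed)
  is off by default for single-quartet tests on clean data and on by
  default in scans, mirroring empirical practice; a mode that applies
  it only when a class total is zero is also provided because
  published descriptions do not state whether N was adjusted.
* Scan reports are deterministic given identical input: triples are
  enumerated in sorted order and rows sorted by p-value with a fixed
  tie-break.
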