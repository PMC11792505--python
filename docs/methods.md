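# Methods

## The two-step classification

For every pair of sampling sites the package asks, in order: is the
pair's *phylogenetic* turnover more (or less) extreme than random, and if
not, is its *taxonomic* turnover?

**Phylogenetic turnover.** The abundance-weighted beta mean nearest
taxon distance between communities k and m is

    βMNTD(k, m) = ½ [ Σ_i f_ik · min_{j∈m} d_ij  +  Σ_i f_im · min_{j∈k} d_ij ]

where f are within-site relative abundances, d is the patristic
(branch-length path) distance, and each minimum runs over taxa with
positive abundance in the *other* community.  A shared taxon finds itself
at distance zero, so βMNTD(k,k)=0.  The null model permutes taxon
identities on the cophenetic matrix — equivalently, shuffles the tree's
tip labels — over the *regional pool* (every tip of the aligned tree)
while abundances stay fixed.  The standardized effect size is

    SES.βMNTD = (observed − null mean) / null sd

over `n_reps` permutations (default 500).  SES > 2 is read as
heterogeneous (variable) selection, SES < −2 as homogeneous selection;
thresholds are strict, and boundary values fall through.  If the null
standard deviation vanishes (a star tree; a pair whose two sites have
identical taxon support, every shared taxon being a fixed point of the
shuffle) the pair is flagged `degenerate` and excluded from downstream
denominators — never silently labeled drift.

**Taxonomic turnover.** Pairs with |SES| ≤ 2 get a Raup–Crick test on
Bray–Curtis dissimilarity.  Each null replicate reassembles both sites:
the site's observed richness is drawn without replacement with
probability proportional to occupancy (number of sites occupied), then
the site's observed total abundance is allocated multinomially with
probability proportional to pooled abundance.  With B the observed
Bray–Curtis and B* the null ensemble,

    RC_bray = 2·[ (#{B* < B} + ½·#{B* = B}) / n_reps − ½ ]  ∈ [−1, 1].

RC > 0.95 is dispersal limitation, RC < −0.95 homogenizing dispersal,
the remainder drift.  Ties get half weight (counted at 1e-12 tolerance).
Sampling without replacement uses Gumbel-top-k keys on log-occupancy, so
zero-weight taxa can never be drawn and a removal run consumes the
random stream identically to a full run.

Real-valued tables are accepted; because the Raup–Crick null allocates
discrete individuals, site totals are rounded for that null (with a
warning) and positive values count as presences.

## Taxon (DTU) attribution by removal

A removal target — one taxon, or all members of a taxonomic rank label —
is deleted from both communities of a pair and the metrics are
recomputed **under the same randomizations**: the identical tip-label
permutation array (keyed by the base seed) and the identical per-pair
Raup–Crick stream (keyed by seed and site pair).  This eliminates
Monte-Carlo flip noise: a pair's metrics change only through the
target's absence, never through fresh randomness.  Concretely:

- the tip-shuffle pool is unchanged (the target's tips remain tree
  positions that permutations may use); the target is masked from both
  abundance vectors, which are renormalized;
- the target's occupancy and pooled-abundance weights are zeroed in the
  Raup–Crick null, and the pair's richness and totals shrink by the
  removed counts;
- a target absent from both sites of a pair contributes nothing there:
  removal is defined as the identity on that pair and rule 5 applies;
- a removal that empties a site makes the pair `inapplicable`, excluded
  from that target's denominators.

Because weights are raw counts (scale-free renormalization), a removal
run is bit-identical to re-running the whole pipeline on the
taxon-filtered table with the same seed and the original (unpruned)
tree — the test suite checks this at 1e-12.

The five decision rules attribute a pair to the process whose
significance the removal flipped (cut = 2, rcut = 0.95):

1. heterogeneous selection iff SES > cut and SES(−i) < cut;
2. homogeneous selection iff SES < −cut and SES(−i) > −cut;
3. dispersal limitation iff both SES values lie in the band, RC > rcut
   and RC(−i) ≤ rcut;
4. homogenizing dispersal iff both SES values lie in the band,
   RC < −rcut and RC(−i) ≥ −rcut;
5. drift otherwise.

`rule_labels="paper-literal"` swaps the labels of rules 3 and 4 to
reproduce a printed variant of this rule set whose labels conflict with
the step-2 definitions; the default keeps labels consistent with step 2.
Reverse flips (non-significant before removal, significant after) have
no printed rule; they are logged in a `masking` diagnostic column and do
not enter the five-way attribution.  A target's attribution row is the
fraction of evaluable pairs per process (rows sum to one); a target with
no evaluable pair is flagged NaN, not emitted as zeros.

## Sampling-unit (DSU) attribution by pair counting

A sampling unit (or group) is involved in every pair containing at least
one member: n−1 pairs for a single site, C(n,2) − C(n−g,2) for a group
of g.  Within-group pairs are included (a `between_only` flag excludes
them).  Per target the package reports the per-process fractions over
evaluable involved pairs, the headline significant fraction (pairs whose
label is anything but drift, i.e. significant SES or RC), and
stochasticity (dispersal limitation + homogenizing dispersal + drift).

## Phylogenetic-signal gate

βMNTD-based inference presumes niche conservatism among close relatives.
The gate estimates each taxon's niche as its abundance-weighted mean
environment, then builds a Mantel correlogram of |niche difference|
against patristic distance following the vegan `mantel.correlog`
conventions: Sturges' rule for the number of equal-width distance
classes; per class, Pearson correlation between the distance vector and
the class-membership indicator with the sign flipped (positive r =
within-class similarity); one-tailed permutation p in the direction of
the observed sign (999 taxon-label permutations by default); progressive
Holm correction; beyond the halfway class, classes in which some taxon
has no pair are cut off.  Per-class r is frozen-value-tested against
vegan's output on a fixed 8-taxon instance.  The permutation tail is
counted with 1e-12 slack so p is exactly invariant under affine
rescaling of the covariate.  The gate warns — it does not block —
when no class is significant.

## Synthetic communities

The simulator provides known-truth worlds: a Yule tree (`n_taxa` tips,
birth rate 1), Brownian traits (σ = 1, root 0; the stem edge the tree
simulator attaches is traversed, so E[trait²] = σ²·depth), and a
sites×taxa count table per regime.  Defaults (versioned in
`data/default_scenario.json`): 80 taxa, 12 sites, 1000 individuals per
site, niche width 0.3 trait SD, dispersal scale 0.1 of the unit
gradient, mixing 0.8, lognormal carrying capacities (σ = 1), per-site
lottery noise σ = 1.  Every generator is deterministic given its seed.

- *Heterogeneous selection*: sites along an environmental gradient
  spanning the trait range; expected abundance = carrying capacity ×
  Gaussian niche filter; multinomial site totals.
- *Homogeneous selection*: one shared environment plus per-site
  lognormal lottery (priority-effect) noise.  The noise is essential and
  bounded: identically selected sites are indistinguishable from
  homogenized ones, and noise stronger than the filter's suppression of
  distant taxa (σ ≳ 2) destroys the selection structure itself.
- *Drift*: iid multinomial draws from one lognormal metacommunity.
- *Dispersal limitation*: taxa have home positions on the site line;
  access decays exponentially.
- *Homogenizing dispersal*: the dispersal-limitation base mixed toward
  the common mean composition (mass effects).
- *Divergent-taxon variant* (heterogeneous selection): the premise "one
  taxon carries the divergent trait" requires that nothing else does, so
  the background trait-to-taxon assignment is shuffled (niches
  phylogenetically unconserved), while the most isolated tip becomes a
  relict lineage — terminal branch elongated to twice the tree depth,
  trait 1.5 niche widths beyond the background maximum (dominant at the
  top of the gradient but still coexisting, so removal never empties a
  site), median carrying capacity.  SES driven by a single taxon
  saturates unless its branch is genuinely long: the null's variance
  contains the taxon's own relocation, and only a deep position that
  permutations rarely load with comparable abundance yields SES ≫ 2.

**What the generators do not emulate**: real sequencing artifacts
(compositionality, rarefaction, chimeras), interaction-driven assembly
(competition, facilitation), multiple simultaneous processes, or the
taxon profiles of any real microbiome.  A green recovery test
establishes that the inference machinery identifies its own generative
regimes at these sizes — not that field data meet the framework's
assumptions.

**Identifiability limits found while validating.** With the regional
pool equal to the analyzed site set, whole-dataset recovery is possible
for heterogeneous selection, drift and dispersal limitation (all tested
modal at defaults), but *not* for homogeneous selection or homogenizing
dispersal: both homogenize the very pool their nulls are built from.
Shared taxa are fixed points of the tip shuffle, so identically selected
sites yield degenerate or near-zero SES; saturated occupancy collapses
the Raup–Crick null's scatter, so even iid draws from a single
metacommunity — the most homogeneous world possible — push only about a
third of pairs below RC = −0.95.  Both processes are detectable for
pairs *embedded in* a heterogeneous region (tested: a mass-effect-
coupled pair inside a patchy region classifies as homogenizing
dispersal; a same-niche pair inside a gradient shows RC < −0.95 but
reads as homogenized, because its shared taxa pin βMNTD near zero).  A
related caution: adding a trace "immigration floor" to selection worlds
destroys the βMNTD signal, because nearest-taxon distances are
presence-sensitive — trace immigrants serve as zero-distance targets.

## Numerical choices

- Null sd ≤ 1e-12 ⇒ degenerate; Raup–Crick ties counted at 1e-12;
  permutation tails with 1e-12 slack.
- The taxon pool is held in sorted label order, so results do not depend
  on input column order and filtered-table re-runs are bit-reproducible.
- All randomness derives from `numpy.random.default_rng([seed, tag, ...])`
  with fixed small integer tags; the tip-permutation array is generated
  once per seed and replayed by every removal target; each pair's
  Raup–Crick stream is keyed by (seed, pair).
- Null βMNTD is evaluated in permutation chunks of 128 to bound memory;
  results are exact, not approximate.
- Boundary conventions: |SES| ≤ 2 is "in the band"; SES = 2 or RC = 0.95
  are not significant (strict inequalities).

## Known limitations

- RCbray requires integer totals; heavily non-integer tables (relative
  abundances) are rounded per site total, which coarsens the null.
- The Mantel correlogram tests one covariate at a time; no multivariate
  niche synthesis.
- Per-ASV removal over thousands of taxa is quadratic in practice; rank-
  level groups are the intended unit at scale.
- The homogeneous-selection / homogenizing-dispersal identifiability
  limits above apply to any dataset whose sites are all shaped by the
  same process; interpret whole-dataset fractions of those two processes
  with care.
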