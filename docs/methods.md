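# Methods

## The question and the model

`metaprox` tests whether metabolic enzyme content predicts the order in
which bacterial species colonize a layered biofilm.  The running example
is the dental biofilm: eleven species organized into four layers, the
first bound to salivary-pellicle receptor sites, each later layer binding
the one beneath it.  The model reduces colonization to a combinatorial
object — a *colonization order*, a permutation of the community — and the
layered structure to the constraint that a consistent order is a
concatenation of within-layer permutations.  For layer sizes
(3, 3, 1, 4) this admits 3!·3!·1!·4! = 864 orders, against
11! = 39,916,800 unconstrained permutations.

An organism A is represented by its binary enzyme profile S^(A): the set
of EC numbers annotated in its genome, with abundance and stoichiometry
deliberately ignored.  Two metrics score an order:

* **Mean adjacent Jaccard distance** ⟨J⟩ = (1/(n−1)) Σᵢ J(oᵢ, oᵢ₊₁),
  with J(A,B) = 1 − |S^(A)∩S^(B)| / |S^(A)∪S^(B)|.  J is a true metric
  (identity, symmetry, triangle inequality — property-tested); the
  similarity form Jc = 1 − J is used for network overlap.
* **Summed added information** Σᵢ ΔI(oᵢ, oᵢ₊₁), where
  ΔI(A,B) = Σ_{k∈K(A,B)} −ln P_k over the features K(A,B) that B carries
  and A lacks, weighted by community prevalence P_k = N_k/N_organisms.
  Reported in nats.  ΔI is asymmetric, so it distinguishes an order from
  its reverse; ⟨J⟩ does not.

The hypothesis — adjacent organisms are metabolically closer than chance
— is evaluated by comparing the distribution of layered-order scores
against (a) uniformly random permutations of the same community, (b)
random groups of organisms drawn from a background pool, and (c) the same
comparison after random deletion of part of the enzyme universe
(robustness to incomplete annotation).  Distribution pairs are compared
with the two-sample Kolmogorov–Smirnov test (exact p-value when both
samples have ≤ 25 values, asymptotic otherwise).

The random-group baseline never iterates permutations: by linearity of
expectation, each adjacent slot of a uniform random permutation is a
uniform random unordered pair, so the permutation-average of the
adjacent-distance sum equals (g−1) × (mean pairwise J within the group)
exactly.  This identity is verified against exhaustive enumeration for
groups of up to 6.

### A calibration caveat

The layered-order sample is an exhaustive enumeration, not an iid draw.
Conditional on a community realization, its score distribution differs
from the random-permutation distribution for purely combinatorial reasons
(every layer-consistent order contains all within-layer pairs; boundary
pairs are reweighted) even when organisms are statistically exchangeable,
and the difference does not shrink with profile noise (KS is invariant to
monotone rescaling of scores).  Consequently the KS p-value of this
particular comparison is anti-conservative under a no-gradient null: it
detects the combinatorial structure of the enumeration itself, not only a
planted gradient.  The planted-gradient recovery test therefore
demonstrates power (the planted effect is detected in every seed), while
a nominal-level false-positive rate should not be expected from this
comparison and is not achieved by it; a calibrated null would require a
different baseline (e.g. re-randomizing layer assignments).  The KS test
itself is calibrated, as verified on iid same-generator samples.

## Layer enrichment

The layer profile B^(x) gives, for each enzyme in the community universe,
the exact fraction (a rational with denominator |L_x|) of layer-x
organisms carrying it.  For each layer, enzymes are ranked by the layer
specificity B^(x)ᵢ − mean_{y≠x} B^(y)ᵢ (descending, ties broken by
enzyme id), and each pathway receives a weighted running-sum enrichment
score: walking down the ranking, pathway members step the sum up by their
normalized |rank statistic|^w (w = 1) and non-members step it down by
1/(N − N_hit); the score is the maximum of the running sum.  Nominal
p-values come from an enzyme-label permutation null — random same-size
enzyme sets, cached per set size — because only a handful of layers exist,
far too few for sample permutation.  FDR is Benjamini–Hochberg across all
pathway × layer tests; a test is flagged at p ≤ 0.05 and q < 0.25.
Pathways with fewer than 3 universe enzymes are excluded (running sums on
1–2 enzymes are degenerate), and a constant ranking statistic is an error
rather than a silent zero.  Under an unstructured null the nominal
p ≤ 0.05 rate is ≈ 5% (verified over 300 simulated communities).

## Elementary flux modes and synergy

The synergy analysis asks how the pathway versatility of a joint
two-species network depends on how similar the species' reaction sets
are.  A stoichiometric network is a metabolites × reactions matrix of
exact rationals (consumed negative, produced positive) with per-reaction
reversibility and a set of external metabolites exempt from steady state.
For sampled subnetworks, a metabolite participating in exactly one
reaction is additionally treated as external (applied once, not
iterated): random subnetworks are riddled with dead ends that would
otherwise force near-zero mode counts.

**Paired construction.**  From a main network, a source of
R_s = round(P·R_TOT) reactions is sampled (P = 0.8 by default).  For a
target Jaccard coefficient Jc, R_int = round(Jc·R_s) shared reactions are
drawn (decremented by one if R_s − R_int is odd, incremented instead if
that would go negative), plus two disjoint private sets of
(R_s − R_int)/2 reactions each.  The realized overlap is exact by
construction: pair Jc = R_int/R_s and per-component shared fraction
R_int/|C⁽¹⁾| = 2Jc/(1+Jc) — 33.3% at Jc = 0.2.  In the joint network,
private metabolites not used by any shared reaction are renamed per side
(a metabolite used by both private sets but no shared reaction becomes
two species), so no overlap beyond the chosen reactions is introduced.

**Enumeration.**  An elementary flux mode is a steady-state flux vector
with minimal support.  Enumeration is a double-description sweep:
reversible reactions are split into forward/backward halves; starting
from the orthant's unit rays, one internal-metabolite balance is imposed
at a time (cheapest row first), combining positive/negative ray pairs
that pass the combinatorial support-minimality adjacency test.
Arithmetic is exact (integer-scaled columns, gcd-reduced rays), so every
returned mode satisfies S·v = 0 with zero residual.  Split-induced futile
two-cycles map to the zero net flux vector and are dropped; a mode whose
support is entirely reversible is reported once, in a canonical
orientation; all modes are scaled so the first nonzero flux has magnitude
1.  Networks with more than 32 columns after splitting (configurable)
are refused — the intended scale is desk-size networks, not genome scale.
An independent brute-force enumerator (every support subset is tested for
a one-dimensional, sign-feasible nullspace via sympy; minimal supports
kept) is the oracle: the two routes agree exactly on dozens of random
networks of ≤ 8 reactions.

**Score.**  ΔEFM = EFM(1,2) / (EFM(1) + EFM(2)) ("ratio", the default):
exactly 1 for a fully disjoint pair (a disconnected union's modes are the
union of the parts' modes — verified by enumeration) and 0.5 for an
identical pair.  The shifted form (EFM(1,2) − EFM(1) − EFM(2)) /
(EFM(1) + EFM(2)) is available as `mode="relative_increase"`.  The curve
routine reports mean ± SEM (sd/√n over replicates) per grid value;
replicates that exceed the enumeration cap or whose constituents have no
mode at all are counted as skipped.

## Synthetic data: what it emulates and what it does not

No annotation database ships with the package; generators produce inputs
with the structure the analysis assumes.

* **Planted-gradient community** (`make_community`).  Each layer has an
  archetype feature set of round(p0·U) features; consecutive archetypes
  share a fraction 1 − g (g = `gradient`, the fraction resampled per
  layer step); organisms are noisy archetype copies (features dropped at
  rate `noise`, gained at a rate matched to keep expected size).
  Defaults: layers (3, 3, 1, 4), U = 600, p0 = 0.3, noise = 0.05,
  g = 0.3 — an eleven-genome community over a universe of several hundred
  enzymatic functions, with within-layer similarity well above
  between-layer similarity and a monotone distance gradient across
  layers.  g = 0 gives exchangeable organisms (no planted structure).
* **Background pool** (`make_background_pool`).  Independent genomes with
  Beta-distributed per-feature prevalence (mean p0, concentration
  1/dispersion), emulating an unstructured list of prokaryotes; gradient
  communities are metabolically tighter than random groups from this
  pool.
* **Pathway maps** (`make_pathway_map`).  Uniform random enzyme
  assignment; planted pathways draw a configurable fraction of their
  enzymes from features private to a target layer.
* **Random metabolic networks** (`make_random_metabolic_network`).  A
  connected backbone chain, single-metabolite exchange reactions
  (fraction 0.2 — metabolic networks are open systems; without boundary
  fluxes random networks rarely support any steady-state mode), and
  1–2-substrate/1–2-product reactions whose metabolites are sampled with
  a 6-fold weight on a 20% subset of hub ("currency-like") metabolites,
  giving the right-skewed degree distribution of real metabolic networks.

What passing tests show is therefore structural: the pipeline detects a
planted gradient, recovers a planted pathway, and reproduces the
interior synergy optimum on networks with metabolic-like topology.  They
do not show anything about real KEGG annotations: synthetic profiles
have no EC-frequency realism, no phylogenetic correlation between
organisms, and the synergy networks are two orders of magnitude smaller
than a genome-scale model, so the exact peak location and p-values of a
real analysis are outside what the synthetic conditions can establish.

## Problem sizes and numerical choices

Default analysis sizes: 864 layered orders (exhaustive), 10⁵ random
orders in the CLI (10³ in tests), 1000 random groups, 1000 GSEA
permutations (150–500 in tests), synergy curves over
Jc ∈ {0, 0.2, …, 1} with 100 pairs per point in the CLI (20 in tests) on
~25-reaction networks at P = 0.8.  Tolerances: set arithmetic and EFM
balances are exact (rationals); floating comparisons in tests use 1e−12
where the quantity is an exact identity.  Degenerate inputs raise rather
than return conventions: a Jaccard distance between two empty profiles,
an added-information query outside the prevalence table, a constant
enrichment ranking, a synergy denominator of zero.

## Known limitations

* The adhesion-edge list of the packaged dental-biofilm model is a
  literature-informed reconstruction; only layer memberships and anchors
  affect computed quantities (enumeration uses layer blocks by design).
* The strict "bind to anything already present" enumeration (which would
  allow interleaved layers) is not implemented; the layer-block
  convention matches the 864-order model.
* EFM enumeration is deliberately capped; genome-scale counting requires
  specialized tools.
* The KS comparison of enumerated vs sampled order distributions is
  anti-conservative under the null (see the calibration caveat above).
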