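# Methods

This note records the models, conventions and numerical choices behind
`retrodict`, in the order the pipeline runs.

## Secondary structures and cloverleaf decomposition

Structures are nested sets of 1-based pairs (i, j), i < j; pseudoknots are
rejected outright rather than pruned, since every ensemble statistic
downstream assumes nestedness. Coordinates are 1-based with closed ranges
everywhere, matching biological tRNA numbering. The default cloverleaf
template places the acceptor stem at 1–7/66–72, D arm 10–25, anticodon arm
27–43 (anticodon 34–36), variable loop 44–48 and T arm 49–65 on a 76-nt
numbering. These coordinates are a convention of this package, supplied
through `CloverleafTemplate` and fully configurable; how the variable loop
is delimited for type I vs type II molecules is likewise a convention —
the type II flag fires when the template's variable-loop span exceeds
10 nt, since type II cognate tRNAs are characterised by a long variable
loop without a published cutoff.

A region counts as *present* when at least one base pair lies entirely
within its ranges. Pairs crossing a region boundary are excluded from
regional statistics and surfaced in a `context_pairs` diagnostic instead
of being silently dropped.

## Energy model and ensemble statistics

The folding engine uses a deliberately transparent additive model: pair
energies E(GC) = −3, E(AU) = −2, E(GU) = −1 kT, a −1 kT bonus per stacked
adjacency, and a minimum hairpin loop of 3 nt. Two independent routes
compute the same ensemble: exhaustive enumeration of all nested canonical
structures (the oracle, capped at 25 nt) and a McCaskill-style
inside–outside dynamic programme. Their base-pairing probability matrices
agree to ~1e−15 in tests; the DP also satisfies the exact normalisation
q_i + Σ_j p_ij = 1 per position. The engine is an interface: a
nearest-neighbour (Turner) backend could be swapped in, at the price of
losing the exact oracle.

Ensemble entropy Q is computed in bits and normalised per nucleotide, with
0·log 0 = 0 — the ensemble-entropy convention of the RNA morphospace
literature. P and S are computed on the MFE structure rather than
probability-weighted; MFE ties are broken deterministically (fewest pairs,
then lexicographically smallest pair set) so outputs are
platform-independent. Statistics can be computed per whole molecule or per
substructure; both modes are exposed because either could underlie a
substructure tree, and the pipeline defaults to per-substructure
characters for trees of molecules.

## Character coding and polarization

Continuous statistics are binned into k = 24 equal-width ordered states
(the largest alphabet a classic parsimony program accepts, written 0–9,
A–N in NEXUS output); boundary ties go to the lower state and rounding is
half-up, for determinism. Constant columns are retained, coded 0, and
flagged parsimony-uninformative so matrix dimensions always match the
input. Abundance censuses are coded
state = round((k−1)·ln(g+1)/ln(g_max+1)) with g_max the per-proteome
maximum: the logarithm spreads heavy-tailed abundances across the ordered
series, and coding is scale-monotone.

Polarization follows the order-increases-in-evolution model: the
hypothetical ancestor ANC carries state k−1 for entropy-derived characters
(maximal disorder) and state 0 for propensity and stem-length characters
(minimal order). For abundance characters the ancestor carries the
*maximal* state: the most abundant, most widely distributed domains are
taken as the most ancient, which is the convention under which the oldest
(root-born) domain in the accretion simulations is recovered as the most
basal taxon. The opposite convention is available via configuration, and
outputs record which was used. Whether substructure-tree polarity should
flip under matrix transposition is undocumented territory; the default
keeps per-statistic polarity unchanged.

## Parsimony engine

Tree length under ordered states (cost |i−j|) uses the Farris interval
algorithm, exact on binary trees and vectorised over characters; a Sankoff
dynamic programme over explicit states (min-plus with a linear metric in
O(k) per node) serves as an independent check, and both are validated
against brute-force minimisation over all internal labelings.

Rooting is Lundberg-style: ANC joins the search as an ordinary leaf and
the root is its attachment edge. Searches: exhaustive enumeration (≤ 9
ingroup taxa), depth-first branch and bound (initial upper bound from the
heuristic, taxon addition by decreasing state variance, pruning by current
length plus a per-character remaining-range bound; provably optimal and
checked against exhaustive search), and stepwise random addition plus NNI
hill climbing for large matrices (deterministic per seed). Equally
parsimonious trees are retained up to 1,000 with strict consensus
available; tie-breaks are lexicographic by taxon label. The pipeline uses
branch and bound by default up to 12 taxa and the heuristic with 25
random-addition restarts above that; exact search on matrices of many
dozens of taxa is worst-case intractable, so forcing branch and bound is
an explicit choice (`--force-bnb`), and the library routine falls back to
the heuristic with a warning above its 60-taxon cap.

Fit statistics use the classical definitions (CI = M/s, RI = (G−s)/(G−M)
with G the star-tree length, RC = CI·RI). g1 is the adjusted
Fisher–Pearson skewness of the tree-length distribution over rooted
topologies — complete enumeration up to 7 taxa, otherwise 10,000 uniform
samples by sequential random edge insertion (sample size configurable; a
flat distribution yields an undefined g1, reported as null rather than 0).
Node distance nd counts internal nodes from the root inclusive; relative
age is 1 − nd/nd_max with ANC excluded from nd_max.

## Chronology

The clock is an ordinary least-squares line from calibration points
(x, age in Gy), requiring at least two distinct x values and reporting
slope, intercept, standard error and R². The x variable defaults to
relative age rather than raw nd so calibrations transfer across trees of
different depth. Predictions are clamped to [0, 4.2] Gy — never silently:
clamping and extrapolation beyond the calibration range each raise flags.

"The age of an interaction is the age of its interacting components" is
operationalised as two explicit aggregation rules: an interaction is as
old as its *youngest* component (coexistence bound), and a substructure's
anchored age is the *maximum* over its interacting domains' ages (the
oldest partner sets a lower bound on the substructure). Both rules are
visible in configuration. When substructure relative ages from a tree
contradict the anchored order, both values are reported and the conflict
is flagged rather than resolved.

## Synthetic generators and what they do (not) show

The generators define the study conditions; their defaults are fixed here.

**tRNA families.** A 76-nt consensus cloverleaf scaffold (consistent with
the default template) evolves along a uniform-attachment random rooted
tree: per-site substitution probability 0.03 per edge, and stem
substitutions compensatory with probability 1 (the partner follows to
restore Watson–Crick pairing), so every leaf still decomposes into the
four arms. No indels, keeping the template numbering valid; substitutions
are uniform over alternative bases. The family size only, not the
taxonomic composition, of a real several-hundred-tRNA data set is matched
in the scale demonstration (64 molecules by default here, for tractable
run times; the generator accepts any n).

**Ordered-character accretion-drift.** For direct recovery experiments on
the parsimony engine, each of 40 characters *activates* at a node drawn
uniformly from the tree and increases by round(N(1.0, 0.5)) states per
edge inside that clade only (negative draws model reversals), plus
non-heritable leaf noise round(N(0, 0.25)); k = 24. This is the
generality-criterion picture that justifies ancestor rooting: order is
gained clade-wise, primitive lineages genuinely retain low states, and
activations at internal nodes are shared-derived characters. An earlier
clock-like variant (every lineage advancing equally per edge) was
discarded because it is root-unidentifiable by construction — the
ancestor then attaches to the shallowest terminal and, as noise shrinks,
leaf states collapse onto depth alone and all topological signal
vanishes. The leaf-noise sd of 0.25 states (a quarter state rms against
unit drift) is what "low noise" means throughout the tests.

**Domain census.** Domains are born at most once per node (probability
0.75; the root always births the first domain, so at least one domain is
present in every proteome) and abundance grows by a factor 1.5 per edge
with multiplicative lognormal noise (σ = 0.2). Per-edge log-growth
(ln 1.5 ≈ 0.41) roughly twice the noise encodes the strong age–abundance
coupling the clock method presumes — the emulated process is one in which
abundance tracks age well; with noise comparable to growth, birth order
stops being recoverable and the generator would model a world in which
the method's premise fails. True ages fall linearly with birth-node depth
from 3.8 Gy at the root; the faithful interaction map pairs cloverleaf
regions with domains in true age order (acceptor oldest, anticodon arm
youngest).

Passing recovery tests on these generators shows the machinery — coding,
search, rooting, anchoring — is sound under its own model assumptions. It
does not show that three morphospace statistics resolve the topology of
real, closely related molecules: the end-to-end sequence route (fold →
code → search) is deliberately reported unasserted, because Q/P/S are
highly convergent at small divergence (with fully compensatory stems, P
and S barely vary), and its recovery error is measured rather than
promised. Real data also contain modified nucleotides, indels and
tertiary constraints that no generator here emulates.

## Problem sizes and tolerances

Oracle equivalence is tested at ≤ 20 nt (folding, tolerance 1e−9), ≤ 6
leaves / ≤ 4 states (brute-force labelings, exact), and 7 taxa (branch and
bound vs exhaustive, exact). Recovery experiments use 8 taxa × 40
characters × 20 replicates; the scale demonstration uses 64 molecules,
chosen as a desk-scale stand-in for the hundreds-of-molecules analyses
the method targets. The g1 sample default is 10,000 topologies. All
simulations are byte-deterministic given (config, seed); every pipeline
seed is derived from one global seed via named substreams.
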