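# Methods

## Graphs, Laplacians and steady states

A model is a labelled directed graph `G`: vertices 1..n are DNA
microstates (vertex 1 is, by convention, the reference microstate),
edges are transitions, labels are positive rates with units of 1/s.
Labels may be compound sympy expressions (e.g. a Hill function of an
activator concentration); every label must be positive under positive
assignments, which is checked by evaluation at a fixed randomised
positive environment rather than proved symbolically.  Self-loops are
rejected; parallel edges between the same ordered pair are merged by
summing labels, which leaves the Laplacian dynamics unchanged.  Vertex
indexing is 1-based throughout the public surface.

The column-Laplacian `L(G)` has `L[j,i]` equal to the label of `i→j`
and diagonal entries minus the total exit rate, so columns sum to zero
exactly and total probability is conserved.  The master equation
`du/dt = L u` defines a continuous-time Markov chain whose stationary
behaviour the package computes exactly:

* **Strongly connected graphs.**  `ker L` is one-dimensional; the
  canonical basis vector is the matrix-tree vector: `rho_j` is the sum
  over in-trees rooted at `j` of the product of tree-edge labels.  Two
  routes are implemented and cross-checked: explicit backtracking
  enumeration of in-trees (exact, symbolic; reverse-reachability
  pruning, correctness defined by the determinant oracle), and the
  principal minors of `−L` (numeric, no enumeration).  Symbolic entries
  are homogeneous polynomials of total degree n−1 with positive integer
  coefficients — each tree contributes coefficient 1, so the all-ones
  evaluation of `Σ_j rho_j` equals the total tree count.
* **Reversible graphs satisfying the cycle condition.**  The
  equilibrium path formula: `rho_1 = 1` and `rho_j` is the product of
  forward/reverse label ratios along a breadth-first path from vertex 1.
  The cycle condition is verified first on a fundamental cycle basis
  (cycles closed by the non-tree edges of an undirected spanning tree);
  basis checking suffices because any cycle product factors over basis
  cycles, and the tests confirm this against exhaustive cycle checking
  on small graphs.  Path independence is certified in tests by
  recomputing along a second (depth-first) tree.  `ΔG = −RT ln(a/b)`
  with RT defaulting to 2.577 kJ/mol (310 K), always reported together
  with the RT used.
* **General graphs.**  One kernel basis vector per terminal SCC — the
  matrix-tree vector of the induced subgraph, zero elsewhere.  The
  steady state from an initial condition x0 is `Σ_k z_k rho^k/(1·rho^k)`
  where the conservation values z_k come from the left null space of
  the numeric Laplacian dualised against the normalised right basis.

Polynomial arithmetic uses an exponent-vector representation with
rational (in practice integer) coefficients, written for this package
because the matrix-tree outputs are its entire subject: monomial
counting, per-symbol degree bounds and all-ones evaluation must be
exact at the ~50,000-monomial scale.  Symbols are ordered
lexicographically and terms graded-lexicographically, which fixes the
printed form and the normalisation of polynomial GCDs (the GCD itself
is delegated to sympy).  "Distinct monomials" always means after
collecting like terms and before cancelling or factoring anything.

## Product graphs

`G×H` has vertex pairs `(i,j)` enumerated lexicographically and
flattened 1-based; each factor edge is copied once per vertex of the
other factor with its label retained, and there are no other edges.
The kernel basis of the product is the set of pairwise Kronecker
products of the factors' terminal-SCC basis vectors (a singleton
`rho^G ⊗ rho^H` when both factors are strongly connected).  The
matrix-tree vector of the product equals that Kronecker vector times a
single polynomial common factor, which `common_scalar_factor` recovers;
tests verify the identity entrywise by exact division.

## Model systems

**Nucleosome arrays.**  n sites, each marked (1) or unmarked (0);
microstates are bit strings (index = base-2 value + 1), the nucleation
site is the rightmost character.  Nucleation (k_plus, nucleation site
only), propagation (k_plus, unmarked site with a marked immediate
neighbour), turnover (k_minus, any marked site); each single-bit flip is
one edge however many causes apply.  Turnover of an isolated mark has
no reverse edge, so the graph is irreversible for n ≥ 2 yet strongly
connected; probabilities depend on k_plus/k_minus only (all trees have
2^n − 1 edges).  The stabilised variant adds digit 2 (stable mark,
reached from 1 at k_star, no exit transitions for that site); a site
with digit 1 or 2 counts as marked for propagation — necessary for the
n=2 graph without nucleation to have exactly five SCCs with the two
extreme microstates as its terminal SCCs.  The reversibilised
(equilibrium) array allows every flip, up k_plus / down k_minus, and
has closed form `K^β(j)/(1+K)^n`, β = number of marked sites.  Exact
computations are exercised up to n = 10 (1024 states); beyond ~64
states the steady state switches from principal minors to a direct
kernel solve with the conservation law as closing equation.

**PHO5.**  Microstates over: Pho4 at the exposed low-affinity site
UASp1; the UASp2 position (occluded by nucleosome −2 / exposed / Pho4
bound); nucleosome −1 (occludes TATA; the gene transcribes exactly when
it is absent) — 12 states after the occlusion constraint.  Labels:
`a` = Pho4 association to either exposed site (concentration-dependent,
Hill exponent 2 with half-point K, saturating at k*_max);
`b`, `c` = dissociation from the low-/high-affinity position;
`d`, `e` = nucleosome disassembly/reassembly.  Transition rules:
nucleosome −2 disassembles only with Pho4 at UASp1 and reassembles
whenever UASp2 is unoccupied; nucleosome −1 disassembles only when the
promoter is already open at −2 with Pho4 bound at either site, and
reassembles unconditionally.  The published summary statistics of this
model — 53,376 spanning trees; homogeneous degree 11; maximal
`a`-degree 8 with leading layers 4d²(d+e)a⁸ / 4d(d+e)²a⁸; 261/500
distinct GRF monomials — are all reproduced exactly by this scheme and
serve as its validation gate in the acceptance tests; they pin the
scheme uniquely among the mechanistically plausible alternatives we
examined (every other candidate that matches the tree count fails the
monomial counts or the leading layers).  Variant codes (site1, site2)
over {H, L, X} move only the dissociation labels; `X` deletes a site's
binding edges and bound states — 8 vertices when the nucleosomal site
is deleted (the measured X variants), 6 when the exposed site is
deleted, in which case the promoter can never open and the graph is not
strongly connected.  Nucleosome −3 and the variants that use it are
outside the model.

**Titratable detailed-balance graphs.**  Reversible trees/sequences
where a receptor complex R (concentration `R_tot·S/(K_R+S)`, a
first-order Hill curve in the hormone S) and a co-regulator U each bind
at most once along any path from the reference vertex.  Trees satisfy
detailed balance for arbitrary labels, so the steady state follows from
the path formula.  With expression confined to states with both R and U
bound, the GRF in S is itself a first-order Hill curve `M_G·S/(K_G+S)`;
the package verifies this numerically on a 24-point grid log-spaced
over four decades around K_R (tolerance 1e-6 relative) rather than
symbolically, and additionally checks the parameter interpretation
`K_G = K_R ×` (saturation probability of the R-unbound states).

## Dynamics oracles

The master equation is integrated as `u(t) = expm(L t) u0` — the system
is linear, so the matrix exponential is exact and stiffness-proof; the
"long-time" horizon for steady-state agreement checks is 50 divided by
the smallest total exit rate, with agreement required at 1e-6.
Gillespie simulation draws exponential holding times (one seeded
generator per trajectory, seed stored in the trajectory) and estimates
occupancies time-weighted, with standard errors from 10 batch means
after a default burn-in of 10% of the horizon.  Stochastic checks
compare against exact probabilities within 3 standard errors at frozen
seeds; horizons of 3,000–12,000 time units at rates of order 1 keep
every simulation in seconds.

## Dose–response fitting

The synthetic generator emulates the structure of single-cell
reporter-gene flow data: per cell a constitutive normaliser
rfp ~ lognormal(median 1, cv 0.2); an input nYFP drawn per dose from
lognormals (sigma 0.3) whose medians are log-spaced from K/20 to 16K so
the response range brackets the half-point; yfp = nYFP·rfp; and
cfp = GRF(nYFP)·rfp·lognormal(1, noise_cv) with multiplicative noise
chosen to respect positivity (noise_cv = 0.05 default, 400–450 cells
per dose, ten doses).  It does not emulate instrument background,
dose-dependent cell-state shifts, measurement noise on YFP/RFP, or
extrinsic correlations between reporters — so passing recovery tests
show the estimator is consistent under the stated noise model, not that
real data are this benign.

The pipeline ranks cells by nYFP = YFP/RFP, smooths nCFP with a ±7
moving average (window shrinking symmetrically at the boundaries — the
natural choice when the window must stay centred), scales the smoothed
output to maximum 1, and fits the variant's GRF with
`a = hill(nYFP; K, 1)`.  De-dimensionalising by k*_max leaves five free
parameters (K absorbs the unknown nYFP-to-concentration factor; r_b,
r_c, r_d, r_e are rate ratios); positivity is enforced by optimising in
log space.  The model prediction applies the *same* smoothing and
max-scaling operators to the model curve, so the noise-free round trip
has an exactly zero-residual optimum and recovers the generating point
to optimiser precision (the tests require 1%).  A far-off start can
strand the optimiser in a poor local minimum, so the default parameter
point is kept as a fallback start and the better optimum wins;
non-convergence is flagged, never raised.  A collective mode fits one
shared parameter vector across variants by summed residuals.

Identifiability: the normalised curve determines the parameters only
sloppily.  Under 5% noise the curve itself is recovered to ~5% maximal
error while median parameter errors are 40–80% for K, r_b, r_c, r_d and
an order of magnitude for r_e — whole parameter directions barely move
the normalised curve.  The tests therefore assert curve recovery under
noise and exact parameter recovery in the noise-free limit, which is
the honest content of the simulation study.

## Numerical conventions

Relative tolerance 1e-9 for floating comparisons unless stated;
Laplacian column sums checked at 1e-12 relative; steady-state
normalisation at 1e-12.  Numeric cycle-condition checks use the
caller's environment (tests use fixed seeds for randomised positive
environments).  Tree enumeration order follows vertex index order;
ties in all printed output are broken by the graded-lexicographic
term order and by vertex index.  Degenerate inputs fail loudly:
non-positive labels, disconnected graphs (reporting the detached
vertex set), zero polynomials in GCDs, empty post-burn-in windows,
non-increasing curves in the Hill-fit extractor.

## Limitations

Finite graphs only — mRNA/protein copy-number dynamics need infinite
state spaces and are out of scope.  Exact methods are exponential in
array size (capped at n = 20 two-state / n = 12 three-state sites);
larger arrays are reachable only through simulation.  The symbolic
route requires polynomial edge labels; compound labels (Hill factors,
rapid-equilibrium functions) are supported numerically.  Products are
binary (iterate for more factors); no factorisation of a given graph
into a product is attempted.
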