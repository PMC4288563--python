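# linframe

Linear-framework graphs for gene regulation: exact steady-state
probabilities of DNA microstates at and away from thermodynamic
equilibrium, and the gene-regulation functions they generate.

## The problem

Quantitative models of gene regulation have mostly assumed that
transcription-factor binding reaches thermodynamic equilibrium, so that
microstate probabilities follow from free energies alone.  Eukaryotic
regulation, however, runs on energy-dissipating machinery — nucleosome
remodelling, histone modification, DNA methylation — for which detailed
balance cannot be assumed.  `linframe` models a regulatory system as a
labelled directed graph: vertices are DNA microstates (patterns of
transcription-factor and nucleosome occupancy), edges are biochemical
transitions, and edge labels are transition rates, possibly compound
expressions in the concentrations of components in solution.  The graph
defines a master equation

    du/dt = L(G) · u,

where `L(G)` is the column-Laplacian of the graph (entry `(j,i)` for
`i≠j` is the label of edge `i→j`; columns sum to zero).  The package is
for modellers of transcriptional regulation and chromatin who want
exact, symbolic steady states for such models rather than Monte Carlo
estimates.

## What it computes

**Away from equilibrium** (strongly connected `G`) the kernel of `L(G)`
is one-dimensional and a basis vector is given by the matrix-tree
theorem: the entry at vertex `j` is the sum over all spanning trees
rooted at `j` (in-trees) of the product of tree-edge labels,

    rho_j = Σ_{T ∈ Θ_j(G)} Π_{(k→l) ∈ T} a_{kl},

and steady-state probabilities are `u*_j = rho_j / Σ_k rho_k`.  Every
`rho_j` is a polynomial in the rate symbols, computed exactly.

**At equilibrium** (reversible `G` satisfying the cycle condition —
equal label products clockwise and counterclockwise around every cycle)
no trees are needed: `rho_j` is the product of forward/reverse label
ratios along any path from the reference vertex, and `Σ_k rho_k` is the
partition function.  Ratios map to free-energy differences by van't
Hoff, `a/b = exp(−ΔG/RT)`.

**General graphs** decompose into strongly connected components; the
kernel has one basis vector per terminal SCC, and the steady state
reached from an initial condition is fixed by the graph's conservation
laws.

**Independence**: if two modules `G` and `H` operate independently the
joint system is the product graph `G×H`, and its kernel basis is the
Kronecker product of the factor bases, `rho^{G×H} = rho^G ⊗ rho^H` —
independent modules multiply, rather than compound, their complexity.

**Gene-regulation functions (GRFs)**: the expression rate is the
average `g_1 u*_1 + … + g_n u*_n` of per-microstate rates over the
steady state; with binary `g` it is a ratio of label polynomials.

Model builders are included for chromatin-mark nucleosome arrays (with
and without mark stabilisation), the 12-state yeast *PHO5* promoter with
its H/L/X binding-site variants, and detailed-balance sequence/tree
graphs with titratable components, plus Gillespie simulation and
master-equation integration as independent checks, and a synthetic
single-cell dose–response generator with a least-squares GRF fitter.

## Worked example

The wild-type *PHO5* promoter graph has 12 microstates over Pho4
occupancy of its two binding sites and the presence of nucleosomes −2
and −1, with five rate symbols: `a` (Pho4 association, the only
concentration-dependent label), `b`/`c` (dissociation from the low-/
high-affinity site), `d` (nucleosome disassembly), `e` (reassembly).

```
$ linframe trees model:pho5 --count-only
53376

$ linframe grf model:pho5 --symbolic --stats
numerator   distinct=261  degrees=11  max_degree=a=8;b=5;c=4;d=5;e=6  coefficient_sum=11958
denominator distinct=500  degrees=11  max_degree=a=8;b=6;c=4;d=5;e=8  coefficient_sum=53376
```

The promoter has 53,376 rooted spanning trees in total; the transcribing
microstates (nucleosome −1 absent) collect 11,958 of them into the GRF
numerator.  Every monomial has total degree 11 (a spanning tree of a
12-vertex graph has 11 edges) and the Pho4-dependent symbol `a` appears
with exponent up to 8 — a measure of how strongly history enters the
steady state of this non-equilibrium mechanism.  Written out, the GRF
has 261 distinct numerator and 500 distinct denominator monomials, a
complexity that collapses at equilibrium, where a single path to each
microstate suffices.

The chromatin-array contrast, at marking/turnover ratio 1.5 on a
two-nucleosome array:

```
$ linframe steady model:array?n=2 --env k_plus=1.5,k_minus=1.0
1   0.275862068966     # state 00
2   0.289655172414     # state 01 (nucleation site marked)
3   0.124137931034     # state 10
4   0.310344827586     # state 11

$ linframe equilibrium model:eqarray?n=2 --env k_plus=1.5,k_minus=1.0
vertex  rho    probability  delta_g
1       1      0.16         -0
2       1.5    0.24         -1.04488358359
3       1.5    0.24         -1.04488358359
4       2.25   0.36         -2.08976716719
```

Away from equilibrium the marking probability depends on position
(state `01`, marked at the nucleation site, is more likely than `10`) —
the signature of an inherently bounded domain.  The reversibilised
(equilibrium) model gives `K^β/(1+K)^n`, identical for `01` and `10`:
no positional structure, hence no bound on the marked domain.

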