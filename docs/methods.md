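# Methods

## The mapping metric

A decimation mapping of an n-heavy-atom structure is a selection vector
χ ∈ {0,1}ⁿ with Σᵢχᵢ = N. Identifying a mapping with the field
φ_M(r) = Σᵢ C e^{−(r−rᵢ)²/2σ²} χᵢ built on its retained atoms embeds the
discrete mapping space into L₂(ℝ³); with C² = π^{−3/2}σ^{−3} the overlap
integral of two atomic Gaussians evaluates in closed form to
J(r) = e^{−r²/4σ²}, so every inner product, norm and distance is a
quadratic form over the coupling matrix Jᵢⱼ computed once from the
structure. The closed form is validated in the test suite against direct
3D quadrature of the fields.

Two conventions matter:

* **z̄ normalisation.** The raw norm of the all-atom mapping is n·z̄ with
  z̄ = (1/n)ΣᵢⱼJᵢⱼ the atomistic coordination number. All downstream
  modules divide J by z̄ (on by default), which makes the all-atom norm
  exactly n and places globular mappings at 𝓔 ≈ N even at high N. The
  cosine is invariant under this rescaling; distances scale by z̄^{−1/2}.
* **Coordination observables** Z_i, Z̄, T_i, T̄ are soft neighbour counts
  and therefore always use *unnormalised* couplings; the API separates
  the two variants so units cannot be mixed silently. The identity
  𝓔 = N·Z̄/z̄ ties them together and is asserted to 1e−10.

`sigma` defaults to 1.9 Å — half the separation of consecutive α-carbons —
so that "neighbour" means "within one bond length or so" (the Gaussian
overlap decays on the scale √2·σ ≈ 2.7 Å). It is overridable everywhere;
all norms scale smoothly with it.

## Structure input

PDB files are parsed with biotite. Heavy polymer atoms of one chain and
model are kept, in file order: hydrogens (by element, falling back to the
atom-name initial when the element column is blank), waters, and all
HETATM records are discarded; for alternate locations only the first
conformer is kept, ignoring occupancies. Multi-model files become
uniform-weight conformational ensembles; explicit weights are accepted
for reweighted ensembles. Ensemble-averaged couplings apply the per-frame
z̄ inside the average, ⟨J⟩ᵢⱼ = Σ_f w_f e^{−r²ᵢⱼ(f)/4σ²}/z̄(f), so a
single-frame ensemble reproduces the static matrix exactly.

## Random sampling

Uniform N-subsets are drawn with numpy's generator; moments of P_N(𝓔) are
computed from the raw samples rather than the binned histogram to avoid
binning bias. The exact mean under uniform sampling,
E[𝓔] = (N/n)·tr J + [N(N−1)/(n(n−1))]·Σ_{i≠j}Jᵢⱼ, follows from the
hypergeometric pair-inclusion probability and serves as the oracle for
the sampler. The default norm bin width is δ𝓔 = 0.1.

## Wang–Landau reconstruction

The flat-histogram walk accepts an N-conserving move M → M′ with
probability min[1, e^{S(𝓔(M))−S(𝓔(M′))}] and adds ln f to the entropy of
every visited bin. Schedule: ln f starts at 1.0, halves whenever the
stage histogram is flat (min ≥ 0.8 × mean over the bins discovered so
far, checked every 10⁴ moves), and stops below 1e−6. Because the norm
spectrum of a finite structure is discrete, some grid bins are genuinely
unreachable; flatness is therefore judged over the bins seen so far
rather than the whole grid, which would never flatten. Proposals leaving
the requested norm range are rejected with the current bin re-incremented
(standard boundary handling).

The move set swaps one uniformly chosen retained atom against one
uniformly chosen discarded atom — symmetric, and irreducible over the
fixed-N mapping space. The energy change is O(1) given the cached field
h_i = Σ_j Jᵢⱼχⱼ, with an O(n) update on acceptance and a periodic exact
recomputation (every 10⁵ accepted moves) to cancel floating-point drift.

A single canonical bin rule (floor(𝓔/δ𝓔 + 1e−9), bins [lo, hi)) is shared
by the walks and the exact enumeration; the small guard keeps values that
are mathematically on an edge, but land an ulp below it in floating
point, in the upper bin. Without a shared rule the stochastic and exact
grids drift apart by one bin near representable edges, which is fatal for
bin-by-bin comparisons.

Range finding runs a single non-iterative pass (fixed ln f = 1) on an
unbounded dictionary grid and reports the outermost visited bin edges.
Windowed runs split the range into overlapping windows (default width
25 𝓔-units, 25% overlap), align consecutive windows by the visit-weighted
mean entropy offset on shared bins (the least-squares solution for a
chain of additive constants) and average the overlaps. Edge bins visited
fewer than 10 times may be trimmed before analysis; exact enumerations
are never trimmed.

Saddle-point moments fit a parabola to S_N(𝓔) over ±max(5 bins, 5% of the
support) around the maximum: the peak position estimates ⟨𝓔⟩_N and
|S″|^{−1/2} estimates σ_{𝓔,N}. On strongly skewed entropies (small
systems, small N) the quadratic expansion carries an O(skewness·σ) bias;
the cross-check against direct sampling therefore asserts agreement to a
fraction of σ rather than to statistical error.

Stratified harvesting continues the biased walk (optionally still
updating S with the current ln f) and saves one mapping every n proposed
moves into macro-bins of the norm axis until each holds the requested
count; the resulting pool is correlated by construction but spans the
entire accessible norm range, unlike equal-size random pools.

## Lattice-gas thermodynamics

With E = −𝓔 the mapping ensemble at fixed N is an n-site lattice gas of N
particles with hard-core repulsion and Gaussian attraction. The package
implements both the exact log-sum-exp free energy −ln Σ e^{S−βE} and the
Legendre–Fenchel (saddle) form βF = min_E [βE − S(E)], the latter being
the default for phase diagnostics. Degenerate minimisers break toward
lower E, making E*(β) right-continuous at a transition. C_V is a centred
second difference of βF on a uniform β grid (default 200 points spanning
[0, ~max|dS/dE|], where E* sweeps from the entropy peak to the support
edge). A transition is recorded when |ΔE*| between adjacent grid points
exceeds 10 bin widths *and* C_V has a local maximum within 3 grid points
— both thresholds configurable; the jump criterion is deliberately much
larger than the bin width so that discrete-grid stair-steps are never
counted.

## Embedding

Mapping distance matrices are embedded in 2D either by classical scaling
(top-2 eigenpairs of the double-centred −D²/2; deterministic, also the
initialisation) or by sketch-map-style stress minimisation: both the
input distances and the embedded distances pass through the sigmoid
s(r; σ, a, b) = 1 − (1 + (2^{a/b} − 1)(r/σ)^a)^{−b/a} (s(0) = 0,
s(σ) = ½, s(∞) = 1) before being compared, focusing the optimiser on
mid-range structure. The optimiser is plain batch gradient descent with
step halving (so the stress history is non-increasing by construction),
a 10⁴-iteration cap and relative tolerance 1e−8, deterministic for a
given seed. Preset parameter sets: a tight focus (σ = 2, a_d = b_d = 2,
a_D = b_D = 5), a wide focus (σ = 20, same exponents), and the set used
for entropy-scored ensembles (σ = 5, a_D = b_D = 5, a_d = b_d = 2).

## Mapping entropy

S_map quantifies the information lost by a mapping as the KL divergence
between the Boltzmann microstate distribution and its macrostate-smeared
reconstruction; to second order in energy fluctuations this is
k_B β²/2 Σ_R p(R) Var(u|R). Frames are assumed to be canonical samples,
so empirical macrostate frequencies estimate p(R); the within-macrostate
variance is the population variance (the estimator targets an
expectation, and its small-count bias is dominated by the partition
choice). Macrostates come from clustering mapped coordinates:
exact-match, cubic-grid quantisation (cells centred on multiples of the
resolution so the coarse limit collapses to one macrostate), or greedy
RMSD leader clustering. The full discrete KL form is implemented for
enumerable toy systems and verifies the variance form in the
small-fluctuation limit. Refining a partition never increases the
estimate (law of total variance), which the suite asserts on random
partition pairs.

The synthetic-ensemble generator draws frames from equally weighted
Gaussian basins (isotropic positional noise around fixed centers,
Gaussian energies), for which any basin-resolving partition has the
analytic value k_B β²/2 Σ_b w_b σ_b². It emulates well-separated
metastable states with uncorrelated energy fluctuations; it does not
emulate anharmonicity, basin overlap, or coordinate–energy correlation,
so passing recovery tests demonstrate estimator correctness, not
robustness to ambiguous clustering on real trajectories.

## Problem sizes and determinism

The test suite and the acceptance script run on synthetic structures
sized so the exact oracles stay available: 12 atoms at N = 6 (924 states)
for enumeration-vs-WL, 16 atoms for dense-regime scaling, 30 atoms for
saddle-vs-sampling consistency, 40–50 atoms for sampler and metric
checks. Wang–Landau at these sizes converges in seconds per run. Every
stochastic routine takes an explicit integer seed, and every CLI output
carries a JSON sidecar recording the full configuration, so deterministic
outputs reproduce bit-for-bit and stochastic ones reproduce exactly for
the same seed.

Reference values for the 4AKE adenylate-kinase structure (1656 heavy
atoms, 214 residues in one chain) are asserted in the acceptance tests;
since the crystal structure cannot be redistributed with the package,
those two tests require the user to supply `tests/data/4ake.pdb` and
report a clear failure otherwise.

## Known limitations

* Only decimation (binary selection) mappings: no continuous per-atom
  weights, and a single global σ.
* The WL implementation is the canonical two-loop schedule; no 1/t
  refinement or replica exchange.
* Transition detection is a heuristic on a discrete grid; near-degenerate
  phases separated by less than the jump threshold are reported as none.
* The mapping-entropy estimator inherits the bias of the chosen
  macrostate partition; it is exact only in the small-fluctuation,
  well-separated-basin regime.
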