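# mapspace

Metric and thermodynamic characterisation of the space of coarse-grained
(CG) *decimation mappings* of a molecular structure.

## The problem

A decimation mapping of a molecule with `n` heavy atoms retains a subset of
`N` of them as CG sites and discards the rest — a binary selection vector
χ ∈ {0,1}ⁿ with Σχᵢ = N. Choosing the mapping is the first step of every
coarse-graining workflow, yet the space of possible choices is
astronomically large (C(n, N) ≈ 10⁴⁹⁶ for a 1656-atom protein at N = 856)
and, until recently, had no notion of *distance* between its elements.

`mapspace` equips that space with a metric and the tools to explore it:

* **Metric** — each mapping is identified with the sum of 3D Gaussians of
  width σ centred on its retained atoms. The L₂ inner product of two such
  fields reduces to a quadratic form ⟨M,M′⟩ = Σᵢⱼ Jᵢⱼ χ_{M,i} χ_{M′,j} over
  the coupling matrix Jᵢⱼ = exp(−r²ᵢⱼ/4σ²), computed once from the
  structure. It induces the squared norm 𝓔(M) (a measure of how globular
  vs. homogeneous a mapping is), the cosine between mappings (spatial
  overlap) and the distance 𝓓(M,M′)² = 𝓔(M)+𝓔(M′)−2⟨M,M′⟩. Couplings are
  normalised by the atomistic coordination number z̄ = (1/n)ΣᵢⱼJᵢⱼ so the
  all-atom mapping has 𝓔 = n exactly.
* **Random sampling** — histograms and moments of P_N(𝓔) over uniform
  random mappings, with an exact closed form for the mean as an oracle.
* **Wang–Landau sampling** — flat-histogram reconstruction of the density
  of states Ω_N(𝓔) = exp S_N(𝓔), reaching the exponentially rare
  maximally-homogeneous and globular tails that random sampling never
  sees; window decomposition/merging, saddle-point moments
  (⟨𝓔⟩ = argmax S, σ = |S″|^(−1/2)), stratified mapping harvesting, and an
  exact-enumeration oracle for small systems.
* **Lattice-gas thermodynamics** — retained sites behave like gas
  particles with hard-core repulsion and Gaussian attraction on the
  molecular "lattice"; with E = −𝓔, the Legendre–Fenchel transform
  βF_N(β) = min_E [βE − S_N(E)] yields the equilibrium energy E*(β) and
  heat capacity C_V = −β² ∂²(βF)/∂β², whose jump discontinuities / sharp
  peaks mark first-order transitions between sparse (gas), dense (liquid)
  and frozen (solid) classes of mappings.
* **Embedding** — sketch-map-style 2D embeddings of mapping distance
  matrices (sigmoid-transformed stress minimisation with classical
  scaling as initialisation/fallback).
* **Mapping entropy** — the estimator
  S_map ≈ k_B β²/2 Σ_R p(R)·Var(u|R): the macrostate-weighted
  within-macrostate energy variance of an equilibrium sample, measuring
  the information a mapping discards.

Everything runs on plain PDB input or on built-in synthetic structures
(chains, cubic lattices, random gas clouds, two-cluster dumbbells), so no
external data is required.

## Worked example

```python
import mapspace as ms

# two dense blobs 50 A apart: mappings confined to different blobs are
# orthogonal; mappings inside one blob are globular
st2 = ms.make_fixture(ms.FixtureSpec(kind="two-cluster", n_atoms=16, seed=2))
cm2 = ms.compute_couplings(st2, sigma=1.9)
left = ms.Mapping.from_indices(range(8), 16)
right = ms.Mapping.from_indices(range(8, 16), 16)
print(f"E(left) = {ms.norm_squared(left, cm2):.3f}, "
      f"cos(left, right) = {ms.cosine(left, right, cm2):.4f}, "
      f"D = {ms.distance(left, right, cm2):.3f}")

# a dense 16-atom random gas: random-scan vs Wang-Landau moments at N = 8
st = ms.make_fixture(ms.FixtureSpec(kind="random-gas", n_atoms=16,
                                    box=7.0, min_separation=1.2, seed=11))
cm = ms.compute_couplings(st, sigma=1.9)
print(f"zbar = {cm.zbar:.3f}")
cfg = ms.WLConfig(seed=5)
rng = ms.find_norm_range(cm, 8, cfg)
dos = ms.wl_run(cm, 8, rng, cfg)
sp = ms.saddle_point(dos.trimmed())
h = ms.norm_histogram(cm, N=8, count=100_000, seed=1)
print(f"norm range = [{rng[0]:.2f}, {rng[1]:.2f}]")
print(f"random sampling: <E> = {h.mean:.2f}, sigma = {h.sigma:.2f}")
print(f"WL saddle point: <E> = {sp.mean:.2f}, sigma = {sp.sigma:.2f}")
```

Output:

```
E(left) = 9.513, cos(left, right) = 0.0000, D = 4.000
zbar = 5.054
norm range = [3.00, 7.40]
random sampling: <E> = 4.58, sigma = 0.58
WL saddle point: <E> = 4.46, sigma = 0.54
```

Read: the two blob-confined mappings cover complementary regions, so
their cosine vanishes and their distance is the Pythagorean combination
of their norms; each is strongly globular (𝓔 = 9.5 for N = 8 retained in
one dense blob). On the dense gas (z̄ ≈ 5) random 8-site mappings
concentrate near 𝓔 ≈ 4.6 ± 0.6 of the accessible range [3.0, 7.4], whose
upper edge approaches the globular scaling 𝓔 ≈ N = 8 — territory only
the flat-histogram walk reaches — and the saddle-point moments read off
the reconstructed entropy agree with direct sampling to a few percent.

The same pipeline is scriptable from the shell:

```bash
mapspace fixture --kind random-gas --n-atoms 20 --box 14 --seed 1 --out gas.pdb
mapspace random-scan --pdb gas.pdb --N 8 --count 100000 --seed 1 --out hist.tsv
mapspace wl --pdb gas.pdb --N 8 --seed 7 --out dos.tsv
mapspace thermo --dos dos.tsv --out thermo.tsv
```

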