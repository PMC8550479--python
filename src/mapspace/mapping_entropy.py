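"""Mapping entropy: the information a coarse-grained mapping discards.

For a system sampled in the canonical ensemble at inverse temperature
beta, the mapping entropy S_map is the Kullback-Leibler divergence between
the true microstate distribution and its "smeared" reconstruction in which
all microstates projecting onto the same CG macrostate R share one
probability.  To second order in the energy fluctuations this reduces to

    S_map ~= kB * beta^2 / 2 * sum_R p(R) Var(u | R),

the macrostate-weighted within-macrostate variance of the potential
energy: a mapping is poor exactly where it lumps energetically
heterogeneous microstates together.  Frames are assumed to be Boltzmann
samples, so empirical macrostate frequencies estimate p(R) and the
population variance estimates Var(u | R).

Macrostates are built by clustering mapped (retained-atom) coordinates;
exact matching, grid quantisation and greedy RMSD leader clustering are
provided.  The full discrete KL form is implemented for enumerable toy
systems as a cross-check of the variance estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mapping_algebra import Mapping

__all__ = [
    "EnsembleSample",
    "MacrostatePartition",
    "SmapEstimate",
    "Basin",
    "partition_macrostates",
    "smap_estimate",
    "smap_scan",
    "generate_synthetic_ensemble",
    "smap_kl_discrete",
]


@dataclass
class EnsembleSample:
    """Mapped coordinates and energies of canonically sampled frames."""

    frames: np.ndarray    # (n_frames, n_sites, 3) mapped coordinates
    energies: np.ndarray  # (n_frames,) potential energies
    beta: float = 1.0     # inverse temperature, 1/energy units
    kB: float = 1.0       # Boltzmann constant convention

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_sites, 3)")
        if self.energies.shape != (self.frames.shape[0],):
            raise ValueError("one energy per frame required")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class MacrostatePartition:
    """Frame -> macrostate labelling."""

    labels: np.ndarray
    method: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_macrostates(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


@dataclass(frozen=True)
class SmapEstimate:
    """S_map value (kB units by default) and its decomposition."""

    value: float
    per_macrostate: np.ndarray  # weighted variance contribution per state
    n_macrostates: int


def _flat(frames: np.ndarray) -> np.ndarray:
    return frames.reshape(frames.shape[0], -1)


def partition_macrostates(sample: EnsembleSample, method: str = "grid",
                          resolution: float = 1.0) -> MacrostatePartition:
    """Group frames whose mapped configurations coincide.

    ``exact-match``: identical coordinates share a macrostate.
    ``grid``: coordinates quantised to a cubic grid of the given
    resolution (length units), then exact-matched.
    ``radius``: greedy leader clustering; a frame joins the first leader
    within the given RMSD radius, else founds a new macrostate.
    """
    if sample.n_frames < 1:
        raise ValueError("no frames")
    X = _flat(sample.frames)
    if method == "exact-match":
        keys = X
    elif method == "grid":
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        # cells centred on multiples of the resolution, so the coarse
        # limit collapses everything into one macrostate
        keys = np.floor(X / resolution + 0.5)
    elif method == "radius":
        if resolution <= 0:
            raise ValueError("radius must be positive")
        return _leader_cluster(sample, resolution)
    else:
        raise ValueError(f"unknown method {method!r}")
    _, labels = np.unique(keys, axis=0, return_inverse=True)
    return MacrostatePartition(labels=labels, method=method)


def _leader_cluster(sample: EnsembleSample, radius: float) -> MacrostatePartition:
    X = _flat(sample.frames)
    n_sites = sample.frames.shape[1]
    leaders: list[np.ndarray] = []
    labels = np.empty(sample.n_frames, dtype=int)
    for i, x in enumerate(X):
        for k, lead in enumerate(leaders):
            rmsd = math.sqrt(((x - lead) ** 2).sum() / n_sites)
            if rmsd <= radius:
                labels[i] = k
                break
        else:
            labels[i] = len(leaders)
            leaders.append(x)
    return MacrostatePartition(labels=labels, method="radius")


def smap_estimate(sample: EnsembleSample,
                  partition: MacrostatePartition) -> SmapEstimate:
    """S_map = kB beta^2/2 * sum_R (n_R/n) Var_pop(u | R)."""
    if partition.labels.shape != (sample.n_frames,):
        raise ValueError("partition does not label every frame")
    labels = partition.labels
    u = sample.energies
    n = sample.n_frames
    k = labels.max() + 1
    contribs = np.zeros(k)
    for R in range(k):
        sel = labels == R
        nR = int(sel.sum())
        if nR == 0:
            continue
        contribs[R] = (nR / n) * float(np.var(u[sel]))  # population variance
    value = sample.kB * sample.beta ** 2 / 2.0 * contribs.sum()
    return SmapEstimate(value=float(value),
                        per_macrostate=sample.kB * sample.beta ** 2 / 2.0
                        * contribs,
                        n_macrostates=int(np.unique(labels).size))


def smap_scan(frames_full: np.ndarray, energies: np.ndarray, beta: float,
              mappings: list[Mapping], method: str = "grid",
              resolution: float = 1.0, kB: float = 1.0
              ) -> list[tuple[Mapping, SmapEstimate]]:
    """Estimate S_map for each mapping over one shared microstate sample."""
    frames_full = np.asarray(frames_full, dtype=float)
    out = []
    for m in mappings:
        if m.n != frames_full.shape[1]:
            raise ValueError("mapping length does not match frame atoms")
        sample = EnsembleSample(frames=frames_full[:, m.retained, :],
                                energies=energies, beta=beta, kB=kB)
        part = partition_macrostates(sample, method=method,
                                     resolution=resolution)
        out.append((m, smap_estimate(sample, part)))
    return out


# ---------------------------------------------------------------------------
# Synthetic ensembles with known ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Basin:
    """One metastable basin: a coordinate blob with Gaussian energies."""

    center: np.ndarray       # (n_atoms, 3)
    coord_spread: float      # isotropic positional std, length units
    energy_mean: float
    energy_spread: float     # within-basin energy std

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("center must be (n_atoms, 3)")
        object.__setattr__(self, "center", c)
        if self.coord_spread < 0 or self.energy_spread < 0:
            raise ValueError("spreads must be non-negative")


def generate_synthetic_ensemble(n_atoms: int, n_frames: int,
                                basins: list[Basin], seed: int = 0
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Frames and energies from equally weighted Gaussian basins.

    Frames are split across basins as evenly as possible (so basin weights
    w_b are exact), each frame being the basin center plus isotropic
    Gaussian positional noise, with a Gaussian energy.  Any partition that
    recovers the basins has the analytic mapping entropy
    kB beta^2/2 * sum_b w_b energy_spread_b^2.
    """
    if not basins:
        raise ValueError("at least one basin required")
    for b in basins:
        if b.center.shape[0] != n_atoms:
            raise ValueError("basin center has wrong atom count")
    rng = np.random.default_rng(seed)
    counts = [n_frames // len(basins)] * len(basins)
    for k in range(n_frames - sum(counts)):
        counts[k] += 1
    frames = np.empty((n_frames, n_atoms, 3))
    energies = np.empty(n_frames)
    pos = 0
    for b, cnt in zip(basins, counts):
        sl = slice(pos, pos + cnt)
        frames[sl] = (b.center[None, :, :]
                      + b.coord_spread * rng.standard_normal((cnt, n_atoms, 3)))
        energies[sl] = b.energy_mean + b.energy_spread * rng.standard_normal(cnt)
        pos += cnt
    perm = rng.permutation(n_frames)
    return frames[perm], energies[perm]


# ---------------------------------------------------------------------------
# Discrete KL cross-check
# ---------------------------------------------------------------------------

def smap_kl_discrete(p_micro: np.ndarray, macro_of_micro: np.ndarray,
                     kB: float = 1.0) -> float:
    """Exact S_map = kB sum_r p_r ln(p_r / pbar_r) for enumerable systems.

    ``pbar_r`` spreads the total macrostate probability evenly over the
    microstates of that macrostate: pbar_r = p(R(r)) / Omega1(R(r)).
    """
    p = np.asarray(p_micro, dtype=float)
    lab = np.asarray(macro_of_micro, dtype=int)
    if p.shape != lab.shape:
        raise ValueError("one macrostate label per microstate required")
    if np.any(p < 0) or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("p_micro must be a probability vector")
    pR = np.bincount(lab, weights=p)
    omega1 = np.bincount(lab)
    pbar = pR[lab] / omega1[lab]
    nz = p > 0
    return float(kB * np.sum(p[nz] * np.log(p[nz] / pbar[nz])))
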