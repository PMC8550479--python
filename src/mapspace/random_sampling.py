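"""Uniform random exploration of mapping space at fixed N.

With n candidate atoms and N retained sites there are C(n, N) decimation
mappings — about 10^496 for a 1656-atom protein at N = 856 — so the space
can only be probed statistically.  Drawing N-subsets uniformly at random
and histogramming their squared norms estimates the conditional density
P_N(E); because a uniform subset includes any fixed pair of atoms with the
hypergeometric probability N(N-1)/(n(n-1)), the mean of that density has
the closed form implemented in :func:`expected_norm_closed_form`, which
serves as an exact oracle for the sampler.

Random pools concentrate tightly around the entropy peak; the companion
:mod:`mapspace.wang_landau` module reaches the exponentially rare tails.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.special import gammaln

from .mapping_algebra import Mapping, cosine, norm_squared
from .structure_io import CouplingMatrix

__all__ = [
    "NormHistogram",
    "CosineHistogram",
    "sample_uniform_mappings",
    "count_mappings",
    "norm_histogram",
    "expected_norm_closed_form",
    "cosine_histogram",
]

DEFAULT_BIN_WIDTH = 0.1  # delta-E of the norm grid


@dataclass
class NormHistogram:
    """Binned estimate of P_N(E) plus raw-sample moments."""

    N: int
    n: int
    bin_edges: np.ndarray
    density: np.ndarray
    n_samples: int
    seed: int
    mean: float
    sigma: float

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def normalization(self) -> float:
        """sum(density) * delta-E; equals 1 for a proper density."""
        return float(self.density.sum() * self.bin_width)

    def save(self, path) -> None:
        _save_hist_tsv(path, self.bin_edges, self.density, {
            "kind": "norm_histogram", "N": self.N, "n": self.n,
            "n_samples": self.n_samples, "seed": self.seed,
            "mean": self.mean, "sigma": self.sigma,
        })


@dataclass
class CosineHistogram:
    """Binned distribution of cos(theta) over mapping pairs."""

    N: int
    bin_edges: np.ndarray
    density: np.ndarray
    n_pairs: int
    seed: int
    pool_label: str
    min: float
    max: float
    mean: float

    def save(self, path) -> None:
        _save_hist_tsv(path, self.bin_edges, self.density, {
            "kind": "cosine_histogram", "N": self.N, "n_pairs": self.n_pairs,
            "seed": self.seed, "pool_label": self.pool_label,
            "min": self.min, "max": self.max, "mean": self.mean,
        })


def _save_hist_tsv(path, edges, density, meta):
    path = Path(path)
    lines = ["bin_left\tbin_right\tdensity"]
    for lo, hi, d in zip(edges[:-1], edges[1:], density):
        lines.append(f"{lo:.10g}\t{hi:.10g}\t{d:.10g}")
    path.write_text("\n".join(lines) + "\n")
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------


def sample_uniform_mappings(n: int, N: int, count: int,
                            seed: int) -> Iterator[Mapping]:
    """Yield ``count`` uniform random N-subsets of {0..n-1} as Mappings."""
    if not 1 <= N <= n:
        raise ValueError(f"N must satisfy 1 <= N <= n, got N={N}, n={n}")
    rng = np.random.default_rng(seed)
    for k in range(count):
        idx = rng.choice(n, size=N, replace=False)
        yield Mapping.from_indices(idx, n, label=f"random:{seed}:{k}")


def count_mappings(n: int, N) -> float:
    """log10 of the number of decimation mappings.

    ``N`` an integer gives log10 C(n, N); ``N="all"`` gives
    log10(2^n - 1), the total over every resolution.
    """
    if N == "all":
        return math.log10(2 ** n - 1)  # exact big-int arithmetic
    if not 0 <= N <= n:
        raise ValueError("N out of range")
    lg = gammaln(n + 1) - gammaln(N + 1) - gammaln(n - N + 1)
    return float(lg / math.log(10.0))


def _norm_of_subsets(J: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """Squared norms of many index subsets (rows of ``subsets``)."""
    out = np.empty(len(subsets))
    for k, idx in enumerate(subsets):
        out[k] = J[np.ix_(idx, idx)].sum()
    return out


def _bin_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = math.floor(values.min() / width)
    hi = math.floor(values.max() / width) + 1
    return width * np.arange(lo, hi + 1)


def norm_histogram(couplings: CouplingMatrix, N: int, count: int,
                   bin_width: float = DEFAULT_BIN_WIDTH,
                   seed: int = 0) -> NormHistogram:
    """Estimate P_N(E) from ``count`` uniform random mappings.

    Moments are computed from the raw samples, not the binned density,
    to avoid binning bias.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if not 1 <= N <= couplings.n:
        raise ValueError("N out of range")
    rng = np.random.default_rng(seed)
    n = couplings.n
    # sorted rows make the norm of a given subset bitwise reproducible
    subsets = np.sort(np.array([rng.choice(n, size=N, replace=False)
                                for _ in range(count)]), axis=1)
    values = _norm_of_subsets(couplings.J, subsets)
    edges = _bin_edges(values, bin_width)
    hist, edges = np.histogram(values, bins=edges)
    density = hist / (count * bin_width)
    return NormHistogram(
        N=N, n=n, bin_edges=edges, density=density, n_samples=count,
        seed=seed, mean=float(values.mean()), sigma=float(values.std()),
    )


def expected_norm_closed_form(couplings: CouplingMatrix, N: int) -> float:
    """Exact mean of E(M) under uniform N-subset sampling.

    Every diagonal term enters with probability N/n and every off-diagonal
    pair with probability N(N-1)/(n(n-1)) (hypergeometric pair inclusion),
    so the expectation needs only the diagonal and off-diagonal masses of J.
    """
    n = couplings.n
    if not 1 <= N <= n:
        raise ValueError("N out of range")
    diag = float(np.trace(couplings.J))
    off = float(couplings.J.sum()) - diag
    p_pair = N * (N - 1) / (n * (n - 1)) if n > 1 else 0.0
    return (N / n) * diag + p_pair * off


def cosine_histogram(couplings: CouplingMatrix,
                     pool_a: Sequence[Mapping], pool_b: Sequence[Mapping],
                     pairs: int, seed: int = 0,
                     bin_width: float = 0.01,
                     pool_label: str = "random") -> CosineHistogram:
    """Histogram cos(theta) over random cross-pairs of two mapping pools."""
    if not pool_a or not pool_b:
        raise ValueError("pools must be non-empty")
    Ns = {m.N for m in pool_a} | {m.N for m in pool_b}
    if len(Ns) != 1:
        raise ValueError(f"pools mix several N values: {sorted(Ns)}")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(pool_a), size=pairs)
    ib = rng.integers(0, len(pool_b), size=pairs)
    # cache norms; compute inner products pairwise
    J = couplings.J
    norm_a = {k: norm_squared(pool_a[k], couplings) for k in np.unique(ia)}
    norm_b = {k: norm_squared(pool_b[k], couplings) for k in np.unique(ib)}
    vals = np.empty(pairs)
    for t, (ka, kb) in enumerate(zip(ia, ib)):
        ip = J[np.ix_(pool_a[ka].retained, pool_b[kb].retained)].sum()
        vals[t] = min(ip / math.sqrt(norm_a[ka] * norm_b[kb]), 1.0)
    lo = math.floor(vals.min() / bin_width)
    hi = max(math.floor(vals.max() / bin_width) + 1, lo + 1)
    edges = bin_width * np.arange(lo, hi + 1)
    hist, edges = np.histogram(vals, bins=edges)
    density = hist / (pairs * bin_width)
    return CosineHistogram(
        N=Ns.pop(), bin_edges=edges, density=density, n_pairs=pairs,
        seed=seed, pool_label=pool_label, min=float(vals.min()),
        max=float(vals.max()), mean=float(vals.mean()),
    )
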