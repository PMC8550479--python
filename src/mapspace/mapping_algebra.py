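"""Decimation mappings and the metric they induce.

A decimation mapping of an n-atom structure is a binary selection vector
chi in {0,1}^n retaining N = sum_i chi_i atoms.  Associating with every
mapping the sum of Gaussians centred on its retained atoms turns the set of
mappings into a subset of L2(R^3); the induced inner product, squared norm

    E(M) = sum_ij J_ij chi_i chi_j,

cosine and distance

    D(M, M')^2 = E(M) + E(M') - 2 <M, M'>

make the mapping space a metric space.  E measures how globular a mapping
is (E ~ N/zbar for maximally spread-out selections, E ~ N for locally
atomistic blobs, in zbar-normalised units), the cosine measures spatial
overlap of two selections, and D combines the two.

Coordination observables Z_i (soft count of retained neighbours within
~sqrt(2) sigma) are defined with *unnormalised* couplings, as in the
identity E_norm = N * Zbar / zbar; the API enforces the correct variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import CouplingMatrix

__all__ = [
    "Mapping",
    "MappingObservables",
    "norm_squared",
    "inner_product",
    "cosine",
    "distance",
    "coordination",
    "cross_coordination",
    "save_mapping",
    "load_mapping",
]

#: clamp tolerance for tiny negative radicands in the distance
_RADICAND_TOL = 1e-10

#: cosine thresholds used by the parallel/orthogonal classifiers
PARALLEL_COS = 0.95
ORTHOGONAL_COS = 0.05


@dataclass(frozen=True)
class Mapping:
    """A binary selection vector over the heavy atoms of one structure."""

    chi: np.ndarray
    label: str = ""

    def __post_init__(self):
        chi = np.asarray(self.chi)
        if chi.ndim != 1:
            raise ValueError("chi must be one-dimensional")
        if not np.all((chi == 0) | (chi == 1)):
            raise ValueError("chi entries must be 0 or 1")
        chi = chi.astype(bool)
        if chi.sum() < 1:
            raise ValueError("a mapping must retain at least one atom")
        chi.setflags(write=False)
        object.__setattr__(self, "chi", chi)

    @property
    def n(self) -> int:
        return self.chi.size

    @property
    def N(self) -> int:
        return int(self.chi.sum())

    @property
    def retained(self) -> np.ndarray:
        """Sorted 0-based indices of the retained atoms."""
        return np.where(self.chi)[0]

    @classmethod
    def from_indices(cls, indices, n: int, label: str = "") -> "Mapping":
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError("index out of range")
        if np.unique(idx).size != idx.size:
            raise ValueError("duplicate retained index")
        chi = np.zeros(n, dtype=bool)
        chi[idx] = True
        return cls(chi, label=label)

    def __eq__(self, other):
        return isinstance(other, Mapping) and np.array_equal(self.chi, other.chi)

    def __hash__(self):
        return hash(self.chi.tobytes())


@dataclass(frozen=True)
class MappingObservables:
    """Norm and coordination summary of one mapping."""

    norm_sq: float          # zbar-normalised squared norm E(M)
    Zbar: float             # average CG coordination number
    per_site_Z: np.ndarray  # Z_i for retained atoms (0 elsewhere)


def _check(mapping: Mapping, couplings: CouplingMatrix):
    if mapping.n != couplings.n:
        raise ValueError(
            f"mapping length {mapping.n} != coupling dimension {couplings.n}")


def norm_squared(mapping: Mapping, couplings: CouplingMatrix) -> float:
    """Squared norm E(M) = sum_ij J_ij chi_i chi_j."""
    _check(mapping, couplings)
    idx = mapping.retained
    sub = couplings.J[np.ix_(idx, idx)]
    return float(sub.sum())


def inner_product(m1: Mapping, m2: Mapping, couplings: CouplingMatrix) -> float:
    """Bilinear Gaussian-overlap inner product between two mappings."""
    _check(m1, couplings)
    _check(m2, couplings)
    sub = couplings.J[np.ix_(m1.retained, m2.retained)]
    return float(sub.sum())


def cosine(m1: Mapping, m2: Mapping, couplings: CouplingMatrix) -> float:
    """cos(theta) between two mappings; invariant under zbar rescaling."""
    e1 = norm_squared(m1, couplings)
    e2 = norm_squared(m2, couplings)
    if e1 <= 0 or e2 <= 0:
        raise ValueError("zero-norm mapping")
    c = inner_product(m1, m2, couplings) / np.sqrt(e1 * e2)
    return float(min(c, 1.0))


def distance(m1: Mapping, m2: Mapping, couplings: CouplingMatrix) -> float:
    """Metric distance D(M, M') induced by the inner product."""
    rad = (norm_squared(m1, couplings) + norm_squared(m2, couplings)
           - 2.0 * inner_product(m1, m2, couplings))
    if rad < -_RADICAND_TOL:
        raise ValueError(f"negative radicand {rad}: corrupted couplings?")
    return float(np.sqrt(max(rad, 0.0)))


def coordination(mapping: Mapping, couplings: CouplingMatrix) -> MappingObservables:
    """Per-site and average CG coordination numbers Z_i, Zbar.

    Z_i is a neighbour count and therefore always uses unnormalised
    couplings; the returned ``norm_sq`` is zbar-normalised and satisfies
    norm_sq = N * Zbar / zbar.
    """
    _check(mapping, couplings)
    raw = couplings.unnormalized()
    chi = mapping.chi.astype(float)
    Z = raw.J @ chi
    Z = Z * chi  # only retained atoms carry a coordination number
    N = mapping.N
    Zbar = float(Z.sum() / N)
    return MappingObservables(norm_sq=N * Zbar / couplings.zbar,
                              Zbar=Zbar, per_site_Z=Z)


def cross_coordination(m1: Mapping, m2: Mapping,
                       couplings: CouplingMatrix) -> tuple[float, np.ndarray]:
    """T_i(M') for atoms of m1, and the average Tbar(M, M').

    Tbar counts, on average, how many retained neighbours an atom of ``m1``
    has in ``m2``; with equal globularity, Tbar ~ Zbar signals parallelism.
    """
    _check(m1, couplings)
    _check(m2, couplings)
    raw = couplings.unnormalized()
    T = (raw.J @ m2.chi.astype(float)) * m1.chi
    return float(T.sum() / m1.N), T


def classify_alignment(m1: Mapping, m2: Mapping, couplings: CouplingMatrix,
                       parallel_cos: float = PARALLEL_COS,
                       orthogonal_cos: float = ORTHOGONAL_COS) -> str:
    """Label a pair as 'parallel', 'orthogonal' or 'intermediate'."""
    c = cosine(m1, m2, couplings)
    if c >= parallel_cos:
        return "parallel"
    if c <= orthogonal_cos:
        return "orthogonal"
    return "intermediate"


# ---------------------------------------------------------------------------
# Mapping file format: one 0-based heavy-atom index per line, '#' comments
# ---------------------------------------------------------------------------

def save_mapping(mapping: Mapping, path, source_label: str = "") -> None:
    lines = [f"# n = {mapping.n}"]
    if source_label:
        lines.append(f"# source = {source_label}")
    if mapping.label:
        lines.append(f"# label = {mapping.label}")
    lines += [str(i) for i in mapping.retained]
    Path(path).write_text("\n".join(lines) + "\n")


def load_mapping(path, n: int | None = None) -> Mapping:
    indices, label, n_header = [], "", None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("n ") or body.startswith("n="):
                n_header = int(body.split("=")[1])
            elif body.startswith("label"):
                label = body.split("=", 1)[1].strip()
            continue
        indices.append(int(line))
    size = n if n is not None else n_header
    if size is None:
        raise ValueError("mapping file lacks an '# n = ...' header; pass n=")
    return Mapping.from_indices(indices, size, label=label)
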