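"""Synthetic structure generators.

These deterministic stand-ins (linear chains, cubic lattices, random gas
clouds, two-cluster dumbbells) provide structures of arbitrary size on
which every operation of the package can be exercised and validated
without any external input.  The 3.8-Angstrom chain spacing mirrors the
consecutive C-alpha separation in proteins, so the default Gaussian width
sigma = 1.9 A is half a bond, as in protein work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import MolecularStructure

__all__ = ["FixtureSpec", "make_fixture", "write_pdb"]

KINDS = ("chain", "cubic-lattice", "random-gas", "two-cluster")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure."""

    kind: str
    n_atoms: int = 0
    spacing: float = 3.8          # chain / lattice constant, Angstrom
    box: float = 20.0             # random-gas box edge, Angstrom
    min_separation: float = 1.5   # random-gas hard core, Angstrom
    cluster_separation: float = 50.0  # two-cluster gap, Angstrom
    cluster_spread: float = 2.0   # two-cluster internal std, Angstrom
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        for name in ("spacing", "box", "min_separation",
                     "cluster_separation", "cluster_spread"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def make_fixture(spec: FixtureSpec) -> MolecularStructure:
    """Deterministically build the structure described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    if spec.kind == "chain":
        coords = np.zeros((n, 3))
        coords[:, 0] = spec.spacing * np.arange(n)
    elif spec.kind == "cubic-lattice":
        k = round(n ** (1.0 / 3.0))
        if k ** 3 != n:
            raise ValueError("cubic-lattice requires n_atoms = k^3")
        g = spec.spacing * np.arange(k)
        coords = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
    elif spec.kind == "random-gas":
        coords = _random_gas(rng, n, spec.box, spec.min_separation)
    else:  # two-cluster
        half = n // 2
        sizes = (half, n - half)
        centers = np.array([[0.0, 0.0, 0.0],
                            [spec.cluster_separation, 0.0, 0.0]])
        parts = [c + spec.cluster_spread * rng.standard_normal((m, 3))
                 for c, m in zip(centers, sizes)]
        coords = np.vstack(parts)
    label = f"fixture:{spec.kind}:n={n}:seed={spec.seed}"
    return MolecularStructure.from_coords(coords, source_label=label)


def _random_gas(rng, n, box, min_sep, max_tries=20000):
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "infeasible minimum separation for the requested density")
    return np.array(pts)


def write_pdb(structure: MolecularStructure, path) -> None:
    """Write a minimal single-model PDB for round-tripping fixtures."""
    lines = []
    for a in structure.atoms:
        x, y, z = a.coords
        lines.append(
            f"ATOM  {a.index + 1:5d} {a.name[:4]:>4s} {a.residue_name[:3]:>3s} "
            f"{a.chain_id[:1]:1s}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{a.element[:2]:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
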