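"""Molecular structures and Gaussian coupling matrices.

A molecular structure is reduced to its ordered list of heavy atoms; those
atoms form the "lattice" on which decimation mappings live.  The geometry
enters all downstream analysis exclusively through the symmetric matrix of
Gaussian couplings

    J_ij = exp(-r_ij^2 / 4 sigma^2),

the overlap integral of two unit-normalised 3D Gaussians of width ``sigma``
centred on atoms i and j.  The atomistic coordination number

    zbar = (1/n) sum_ij J_ij

measures how densely packed the structure is at scale ~sigma; dividing J by
zbar rescales the metric so that the squared norm of the all-atom mapping is
exactly n, and so that globular (locally atomistic) mappings of N sites have
norm ~N.  All modules downstream consume the zbar-normalised couplings by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "ConformationalEnsemble",
    "CouplingMatrix",
    "read_structure",
    "read_ensemble",
    "compute_couplings",
    "ensemble_average_couplings",
    "save_couplings",
    "load_couplings",
]

DEFAULT_SIGMA = 1.9  # Angstrom; half a typical consecutive C-alpha separation


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of the filtered structure."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if self.element.upper() == "H":
            raise ValueError("hydrogen atoms are excluded from structures")


@dataclass
class MolecularStructure:
    """Ordered heavy-atom list defining the candidate CG sites."""

    atoms: list[AtomRecord]
    source_label: str = ""

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValueError("structure must contain at least one heavy atom")
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise ValueError("atom indices must be 0..n-1 in order")

    @property
    def n(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def n_residues(self) -> int:
        seen = {(a.chain_id, a.residue_number) for a in self.atoms}
        return len(seen)

    @classmethod
    def from_coords(cls, coords: np.ndarray, source_label: str = "synthetic",
                    element: str = "C") -> "MolecularStructure":
        """Build a bare structure from an (n, 3) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        atoms = [
            AtomRecord(i, f"{element}{i}", element, "UNK", i + 1, "A", xyz)
            for i, xyz in enumerate(coords)
        ]
        return cls(atoms, source_label=source_label)


@dataclass
class ConformationalEnsemble:
    """Frames sharing one atom ordering, with normalised weights."""

    frames: np.ndarray  # (n_frames, n, 3)
    weights: np.ndarray = None  # type: ignore[assignment]
    source_label: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.weights is None:
            self.weights = np.full(self.n_frames, 1.0 / self.n_frames)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.n_frames,) or np.any(w < 0):
                raise ValueError("weights must be non-negative, one per frame")
            s = w.sum()
            if s <= 0:
                raise ValueError("weights must not all vanish")
            self.weights = w / s

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n(self) -> int:
        return self.frames.shape[1]


@dataclass
class CouplingMatrix:
    """Symmetric Gaussian coupling matrix plus its normalisation metadata.

    ``J`` holds exp(-r_ij^2/4 sigma^2), divided by ``zbar`` when
    ``normalized`` is set.  ``zbar`` is always the atomistic coordination
    number of the underlying structure (>= 1).
    """

    J: np.ndarray
    sigma: float
    zbar: float
    normalized: bool = True
    source_label: str = ""

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("J must be square")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if np.any(self.J < -1e-15):
            raise ValueError("couplings must be non-negative")

    @property
    def n(self) -> int:
        return self.J.shape[0]

    def unnormalized(self) -> "CouplingMatrix":
        """Return the raw exp(-r^2/4sigma^2) matrix (neighbour-count units)."""
        if not self.normalized:
            return self
        return CouplingMatrix(self.J * self.zbar, self.sigma, self.zbar,
                              normalized=False, source_label=self.source_label)

    def as_normalized(self) -> "CouplingMatrix":
        if self.normalized:
            return self
        return CouplingMatrix(self.J / self.zbar, self.sigma, self.zbar,
                              normalized=True, source_label=self.source_label)


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def _load_atom_array(path, model):
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if not 1 <= model <= n_models:
        raise ValueError(f"model {model} not in file ({n_models} models)")
    return pdb.get_structure(model=model, altloc="first",
                             extra_fields=["atom_id"])


def _heavy_polymer_mask(atoms, chain: str):
    import biotite.structure as struc

    mask = ~atoms.hetero  # drop HETATM: waters, ions, ligands
    mask &= ~struc.filter_solvent(atoms)
    element = np.char.upper(np.char.strip(atoms.element))
    # fall back on the atom-name leading character when element is blank
    blank = element == ""
    if np.any(blank):
        lead = np.array([nm.strip()[:1].upper() if nm.strip() else "X"
                         for nm in atoms.atom_name])
        element = np.where(blank, lead, element)
    mask &= (element != "H") & (element != "D")
    if chain != "first":
        cmask = atoms.chain_id == chain
        if not np.any(cmask):
            raise ValueError(f"chain {chain!r} not found")
        mask &= cmask
    else:
        chains = atoms.chain_id[mask]
        if chains.size == 0:
            raise ValueError("no heavy polymer atoms in file")
        mask &= atoms.chain_id == chains[0]
    return mask, element


def read_structure(path, chain: str = "first", model: int = 1) -> MolecularStructure:
    """Read a PDB file and keep the heavy polymer atoms of one chain/model.

    Hydrogens, waters and HETATM records are discarded; for alternate
    locations only the first (typically altloc A) is kept.  ``chain`` may be
    a chain identifier or ``"first"`` for the first chain containing heavy
    polymer atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    atoms = _load_atom_array(path, model)
    mask, element = _heavy_polymer_mask(atoms, chain)
    if not np.any(mask):
        raise ValueError("zero heavy atoms after filtering")
    sel = np.where(mask)[0]
    records = [
        AtomRecord(
            index=k,
            name=str(atoms.atom_name[i]).strip(),
            element=str(element[i]),
            residue_name=str(atoms.res_name[i]).strip(),
            residue_number=int(atoms.res_id[i]),
            chain_id=str(atoms.chain_id[i]).strip(),
            coords=atoms.coord[i],
        )
        for k, i in enumerate(sel)
    ]
    label = f"{path.name}:chain={records[0].chain_id}:model={model}"
    return MolecularStructure(records, source_label=label)


def read_ensemble(path, chain: str = "first") -> ConformationalEnsemble:
    """Read a multi-model PDB as a uniform-weight conformational ensemble."""
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    frames = []
    ref_mask = None
    for m in range(1, n_models + 1):
        atoms = _load_atom_array(path, m)
        mask, _ = _heavy_polymer_mask(atoms, chain)
        if ref_mask is None:
            ref_mask = mask
        coords = atoms.coord[mask]
        if frames and coords.shape != frames[0].shape:
            raise ValueError(
                f"model {m} has {coords.shape[0]} heavy atoms, "
                f"expected {frames[0].shape[0]}"
            )
        frames.append(coords)
    return ConformationalEnsemble(np.stack(frames),
                                  source_label=f"{path.name}:chain={chain}")


# ---------------------------------------------------------------------------
# Couplings
# ---------------------------------------------------------------------------

def _raw_couplings(coords: np.ndarray, sigma: float) -> np.ndarray:
    sq = squareform(pdist(coords, metric="sqeuclidean"))
    return np.exp(-sq / (4.0 * sigma * sigma))


def compute_couplings(structure, sigma: float = DEFAULT_SIGMA,
                      normalize: bool = True) -> CouplingMatrix:
    """Gaussian couplings J_ij = exp(-r_ij^2/4 sigma^2) of a static structure.

    With ``normalize`` (default) the matrix is divided by the atomistic
    coordination number zbar so that the all-atom mapping has squared norm n.
    ``structure`` may be a :class:`MolecularStructure` or an (n, 3) array.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if isinstance(structure, MolecularStructure):
        coords = structure.coords
        label = structure.source_label
    else:
        coords = np.asarray(structure, dtype=float)
        label = "coords"
    J = _raw_couplings(coords, sigma)
    zbar = float(J.sum() / J.shape[0])
    if normalize:
        J = J / zbar
    return CouplingMatrix(J, sigma=float(sigma), zbar=zbar,
                          normalized=normalize, source_label=label)


def ensemble_average_couplings(ensemble: ConformationalEnsemble,
                               sigma: float = DEFAULT_SIGMA) -> CouplingMatrix:
    """Canonically averaged couplings <J_ij> over a conformational ensemble.

    The per-frame zbar normalisation is applied inside the average:
    <J>_ij = sum_f w_f exp(-r_ij^2(f)/4 sigma^2) / zbar(f).  The stored zbar
    is the weighted mean of the per-frame values (diagnostic only).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if ensemble.n_frames < 1:
        raise ValueError("empty ensemble")
    acc = np.zeros((ensemble.n, ensemble.n))
    zbar_mean = 0.0
    for w, frame in zip(ensemble.weights, ensemble.frames):
        Jf = _raw_couplings(frame, sigma)
        zf = float(Jf.sum() / Jf.shape[0])
        acc += w * (Jf / zf)
        zbar_mean += w * zf
    return CouplingMatrix(acc, sigma=float(sigma), zbar=zbar_mean,
                          normalized=True,
                          source_label=ensemble.source_label or "ensemble")


# ---------------------------------------------------------------------------
# Serialization: binary array container + JSON sidecar
# ---------------------------------------------------------------------------

def save_couplings(cm: CouplingMatrix, path) -> None:
    """Write ``path`` (.npz) and a ``<path>.json`` sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    np.savez_compressed(path, J=cm.J)
    sidecar = {
        "sigma": cm.sigma,
        "zbar": cm.zbar,
        "normalized": cm.normalized,
        "source_label": cm.source_label,
        "n": cm.n,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_couplings(path) -> CouplingMatrix:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    meta = json.loads(Path(str(path) + ".json").read_text())
    J = np.load(path)["J"]
    return CouplingMatrix(J, sigma=meta["sigma"], zbar=meta["zbar"],
                          normalized=meta["normalized"],
                          source_label=meta.get("source_label", ""))
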