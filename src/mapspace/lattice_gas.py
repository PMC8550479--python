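"""Lattice-gas thermodynamics of the mapping density of states.

Retained atoms behave like N gas particles on the n molecular sites, with
a hard core (one atom per site) and a short-range Gaussian attraction: the
squared mapping norm is minus the configurational energy, E = -norm.  Once
Wang-Landau sampling provides the microcanonical entropy S_N(E), coupling
the gas to a thermostat at inverse temperature beta gives the dimensionless
Helmholtz free energy via the Legendre-Fenchel transform

    beta F_N(beta) = min_E [beta E - S_N(E)]

(the saddle-point form of -ln Z), the equilibrium energy E*(beta) as the
argmin, and the heat capacity C_V = -beta^2 d^2(beta F)/d beta^2.  A jump
discontinuity of E* co-located with a sharp C_V peak signals a first-order
transition between mapping phases: sparse/homogeneous (gas) at high
temperature, dense localised blobs (liquid) and near-atomistic frozen
domains (solid) at low temperature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .wang_landau import DOSEstimate

__all__ = [
    "ThermoProfile",
    "Transition",
    "energy_from_norm",
    "free_energy",
    "free_energy_integral",
    "thermo_scan",
    "phase_census",
    "default_beta_grid",
]


@dataclass(frozen=True)
class Transition:
    """A detected first-order jump of the equilibrium energy."""

    beta_c: float
    delta_E: float       # E*(beta+) - E*(beta-), negative across a freeze
    cv_peak_beta: float


@dataclass
class ThermoProfile:
    """beta F, E*(beta) and C_V(beta) on a beta grid."""

    N: int
    beta_grid: np.ndarray
    betaF: np.ndarray
    E_star: np.ndarray
    C_V: np.ndarray      # NaN where the second difference is unstable
    transitions: list[Transition] = field(default_factory=list)

    def save(self, path) -> None:
        lines = ["beta\tbetaF\tE_star\tC_V"]
        for b, f, e, c in zip(self.beta_grid, self.betaF, self.E_star, self.C_V):
            ctxt = f"{c:.10g}" if np.isfinite(c) else "nan"
            lines.append(f"{b:.10g}\t{f:.10g}\t{e:.10g}\t{ctxt}")
        Path(path).write_text("\n".join(lines) + "\n")
        Path(str(path) + ".json").write_text(json.dumps({
            "kind": "thermo", "N": self.N,
            "transitions": [
                {"beta_c": t.beta_c, "delta_E": t.delta_E,
                 "cv_peak_beta": t.cv_peak_beta}
                for t in self.transitions
            ],
        }, indent=1))


def energy_from_norm(dos: DOSEstimate) -> tuple[np.ndarray, np.ndarray]:
    """Convert the norm grid to lattice-gas energies E = -norm.

    Returns ascending E bin centers and the entropy carried over
    (reversed; -inf on unvisited bins).
    """
    centers = dos.centers
    return -centers[::-1].copy(), dos.entropy[::-1].copy()


def free_energy(S_of_E: tuple[np.ndarray, np.ndarray],
                beta: float) -> tuple[float, float]:
    """Legendre-Fenchel transform at one beta: (betaF, E*).

    Discrete minimisation of beta*E - S(E) over the visited bin centers;
    exact degeneracies break toward lower E (the low-temperature phase),
    making E*(beta) right-continuous at a transition.
    """
    E, S = S_of_E
    vis = np.isfinite(S)
    if not vis.any():
        raise ValueError("entropy has no support")
    E, S = E[vis], S[vis]
    obj = beta * E - S
    k = int(np.argmin(obj))
    # tie-break: among minima within strict float equality, take lowest E
    ties = np.where(obj == obj[k])[0]
    k = int(ties[np.argmin(E[ties])])
    return float(obj[k]), float(E[k])


def free_energy_integral(S_of_E: tuple[np.ndarray, np.ndarray],
                         beta: float) -> float:
    """Exact integral form betaF = -ln sum exp(S - beta E) (log-sum-exp)."""
    E, S = S_of_E
    vis = np.isfinite(S)
    return float(-logsumexp(S[vis] - beta * E[vis]))


def canonical_mean_energy(S_of_E: tuple[np.ndarray, np.ndarray],
                          beta: float) -> float:
    """Exact canonical <E>_beta over the discretised density of states."""
    E, S = S_of_E
    vis = np.isfinite(S)
    E, S = E[vis], S[vis]
    logw = S - beta * E
    w = np.exp(logw - logw.max())
    return float((E * w).sum() / w.sum())


def default_beta_grid(dos: DOSEstimate, n_points: int = 200,
                      margin: float = 1.2) -> np.ndarray:
    """beta range covering the full sweep of E*.

    E*(beta) leaves the entropy peak at beta = 0 and reaches the support
    edge once beta exceeds the largest slope of S(E); the grid spans
    [0, margin * max |dS/dE|].
    """
    E, S = energy_from_norm(dos)
    vis = np.isfinite(S)
    Ev, Sv = E[vis], S[vis]
    if Ev.size < 2:
        return np.linspace(0.0, 1.0, n_points)
    slopes = np.abs(np.diff(Sv) / np.diff(Ev))
    bmax = margin * float(np.percentile(slopes, 99))
    if not np.isfinite(bmax) or bmax <= 0:
        bmax = 1.0
    return np.linspace(0.0, bmax, n_points)


def thermo_scan(dos: DOSEstimate, beta_grid: np.ndarray,
                jump_threshold: float | None = None,
                cv_window: int = 3, form: str = "saddle") -> ThermoProfile:
    """Free energy, equilibrium energy and heat capacity across beta.

    ``form="saddle"`` uses the Legendre-Fenchel minimum (the default);
    ``form="integral"`` uses the exact log-sum-exp partition function.
    A transition is recorded where |dE*| between adjacent beta points
    exceeds ``jump_threshold`` (default 10 bin widths) and C_V has a local
    maximum within ``cv_window`` grid points.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if beta_grid.size < 5 or np.any(np.diff(beta_grid) <= 0):
        raise ValueError("beta_grid must be ascending with >= 5 points")
    S_of_E = energy_from_norm(dos)
    if jump_threshold is None:
        jump_threshold = 10.0 * dos.bin_width

    betaF = np.empty_like(beta_grid)
    E_star = np.empty_like(beta_grid)
    for i, b in enumerate(beta_grid):
        if form == "integral":
            betaF[i] = free_energy_integral(S_of_E, b)
            E_star[i] = canonical_mean_energy(S_of_E, b)
        else:
            betaF[i], E_star[i] = free_energy(S_of_E, b)

    C_V = np.full_like(beta_grid, np.nan)
    db = np.diff(beta_grid)
    if np.allclose(db, db[0], rtol=1e-6):
        h = db[0]
        d2 = (betaF[2:] - 2 * betaF[1:-1] + betaF[:-2]) / (h * h)
        C_V[1:-1] = -beta_grid[1:-1] ** 2 * d2
    else:
        warnings.warn("non-uniform beta grid: heat capacity masked")

    transitions = _detect_transitions(beta_grid, E_star, C_V,
                                      jump_threshold, cv_window)
    return ThermoProfile(N=dos.N, beta_grid=beta_grid, betaF=betaF,
                         E_star=E_star, C_V=C_V, transitions=transitions)


def _detect_transitions(beta, E_star, C_V, jump_threshold, cv_window):
    out = []
    jumps = np.where(np.abs(np.diff(E_star)) > jump_threshold)[0]
    # collapse runs of adjacent jump indices into one event
    groups: list[list[int]] = []
    for j in jumps:
        if groups and j - groups[-1][-1] == 1:
            groups[-1].append(j)
        else:
            groups.append([j])
    for grp in groups:
        i0, i1 = grp[0], grp[-1] + 1
        beta_c = 0.5 * (beta[i0] + beta[i1])
        dEj = float(E_star[i1] - E_star[i0])
        lo = max(1, i0 - cv_window)
        hi = min(len(beta) - 1, i1 + cv_window + 1)
        peak = None
        for k in range(lo, hi):
            if (np.isfinite(C_V[k]) and C_V[k] >= C_V[max(k - 1, 0)]
                    and C_V[k] >= C_V[min(k + 1, len(beta) - 1)]
                    and C_V[k] > 0):
                if peak is None or C_V[k] > C_V[peak]:
                    peak = k
        if peak is not None:
            out.append(Transition(beta_c=float(beta_c), delta_E=dEj,
                                  cv_peak_beta=float(beta[peak])))
    return out


def phase_census(dos_by_N: dict[int, DOSEstimate], beta_grid=None,
                 **scan_kwargs) -> dict[int, list[Transition]]:
    """Per-N transition table over a family of densities of states."""
    table: dict[int, list[Transition]] = {}
    for N, dos in sorted(dos_by_N.items()):
        bg = beta_grid if beta_grid is not None else default_beta_grid(dos)
        if np.isfinite(dos.entropy).sum() < 3:
            table[N] = []
            continue
        prof = thermo_scan(dos, bg, **scan_kwargs)
        table[N] = prof.transitions
    return table
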