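"""Wang-Landau reconstruction of the norm density of states Omega_N(E).

Random sampling only sees the narrow peak of P_N(E); the flat-histogram
scheme of Wang and Landau walks in mapping space with acceptance

    alpha(M -> M') = min[1, exp(S(E(M)) - S(E(M')))]

while *penalising* every visited norm bin (S += ln f), so the walk is
driven into exponentially rare regions — maximally homogeneous mappings at
low E, globular ones at E ~ N.  Stages with ln f halved each time refine
the running entropy estimate S_N(E) = ln Omega_N(E) until ln f underflows
a tolerance; the final S is defined up to an additive constant and is
shifted so its minimum over visited bins is zero.

The move set conserves N: one retained atom is exchanged with one
non-retained atom, a symmetric proposal whose energy change is computed
incrementally from the two affected coupling rows.

For structures small enough that C(n, N) fits in memory,
:func:`exact_enumeration` provides the exact density of states and serves
as the oracle against which the stochastic reconstruction is validated.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .mapping_algebra import Mapping
from .structure_io import CouplingMatrix

__all__ = [
    "WLConfig",
    "DOSEstimate",
    "SaddlePointSummary",
    "wl_accept",
    "propose_swap_move",
    "find_norm_range",
    "wl_run",
    "wl_windows",
    "exact_enumeration",
    "saddle_point",
    "harvest_stratified_mappings",
]


@dataclass(frozen=True)
class WLConfig:
    """Schedule and bookkeeping knobs of the flat-histogram run."""

    ln_f_init: float = 1.0
    ln_f_min: float = 1e-6
    f_update: float = 0.5            # ln_f -> f_update * ln_f per stage
    flatness_threshold: float = 0.8  # min(H) >= threshold * mean(H)
    check_interval: int = 10_000     # moves between flatness checks
    max_moves: int = 50_000_000      # hard cap on proposed moves per run
    bin_width: float = 0.1
    window_overlap: float = 0.25
    preliminary_moves: int = 200_000  # length of the range-finding pass
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.flatness_threshold < 1:
            raise ValueError("flatness_threshold must be in (0, 1)")
        if self.ln_f_min <= 0 or self.ln_f_init <= 0:
            raise ValueError("ln_f values must be positive")
        if not 0 < self.f_update < 1:
            raise ValueError("f_update must be in (0, 1)")


@dataclass
class DOSEstimate:
    """Discretised microcanonical entropy S_N(E) on a norm grid.

    ``entropy`` is ln Omega up to an additive constant, -inf on unvisited
    bins, and shifted so the minimum over visited bins is zero.
    """

    N: int
    grid: np.ndarray          # bin edges, length n_bins + 1
    entropy: np.ndarray       # length n_bins
    histogram: np.ndarray     # final-stage visit counts
    window_bounds: list = field(default_factory=list)
    converged: bool = True
    ln_f_final: float = 0.0
    exact: bool = False

    @property
    def bin_width(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.grid[:-1] + self.grid[1:])

    @property
    def support(self) -> np.ndarray:
        return np.isfinite(self.entropy)

    def shifted(self) -> "DOSEstimate":
        s = self.entropy.copy()
        vis = np.isfinite(s)
        if vis.any():
            s[vis] -= s[vis].min()
        return replace(self, entropy=s)

    def trimmed(self, min_visits: int = 10) -> "DOSEstimate":
        """Drop noisy edge bins visited fewer than ``min_visits`` times.

        Exact enumerations are never trimmed: their counts are not noise.
        """
        if self.exact:
            return self
        keep = np.isfinite(self.entropy) & (self.histogram >= min_visits)
        if not keep.any():
            return self
        lo, hi = np.where(keep)[0][[0, -1]]
        return replace(
            self,
            grid=self.grid[lo:hi + 2],
            entropy=self.entropy[lo:hi + 1],
            histogram=self.histogram[lo:hi + 1],
        ).shifted()

    def save(self, path) -> None:
        from pathlib import Path
        lines = ["bin_left\tbin_right\tentropy\tvisits"]
        for lo, hi, s, h in zip(self.grid[:-1], self.grid[1:],
                                self.entropy, self.histogram):
            stxt = f"{s:.10g}" if np.isfinite(s) else "nan"
            lines.append(f"{lo:.10g}\t{hi:.10g}\t{stxt}\t{int(h)}")
        Path(path).write_text("\n".join(lines) + "\n")
        Path(str(path) + ".json").write_text(json.dumps({
            "kind": "dos", "N": self.N, "converged": self.converged,
            "ln_f_final": self.ln_f_final, "exact": self.exact,
            "window_bounds": [list(map(float, w)) for w in self.window_bounds],
        }, indent=1))

    @classmethod
    def load(cls, path) -> "DOSEstimate":
        from pathlib import Path
        rows = Path(path).read_text().strip().splitlines()[1:]
        lo, hi, S, H = [], [], [], []
        for r in rows:
            a, b, s, h = r.split("\t")
            lo.append(float(a)); hi.append(float(b))
            S.append(float(s) if s != "nan" else -np.inf)
            H.append(int(h))
        meta = {}
        side = Path(str(path) + ".json")
        if side.exists():
            meta = json.loads(side.read_text())
        grid = np.array(lo + [hi[-1]])
        return cls(N=meta.get("N", 0), grid=grid, entropy=np.array(S),
                   histogram=np.array(H, dtype=float),
                   window_bounds=[tuple(w) for w in meta.get("window_bounds", [])],
                   converged=meta.get("converged", True),
                   ln_f_final=meta.get("ln_f_final", 0.0),
                   exact=meta.get("exact", False))


@dataclass(frozen=True)
class SaddlePointSummary:
    """Peak position and curvature of S_N(E), and the implied moments."""

    E_tilde: float
    S2: float            # second derivative at the peak (< 0)
    mean: float          # <E>_N = E_tilde
    sigma: float         # |S''|^(-1/2)
    S1_profile: np.ndarray
    S2_profile: np.ndarray
    centers: np.ndarray


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------

def _bin_index(E: float, width: float) -> int:
    """Canonical [lo, hi) bin of a norm value.

    A 1e-9 guard (in units of the ratio E/width) keeps values that are
    mathematically on a bin edge, but land an ulp below it in floating
    point, in the upper bin — the same convention everywhere, so the
    stochastic walks and the exact enumeration share one grid.
    """
    return math.floor(E / width + 1e-9)


def wl_accept(S_current: float, S_proposed: float, uniform_draw: float) -> bool:
    """Flat-histogram acceptance: min[1, exp(S_current - S_proposed)]."""
    if not (np.isfinite(S_current) and np.isfinite(S_proposed)):
        raise ValueError("entropies must be finite")
    if S_proposed <= S_current:
        return True
    return uniform_draw < math.exp(S_current - S_proposed)


class _Walker:
    """Mutable N-conserving walk state with O(1) proposals, O(n) accepts.

    Maintains the field h_i = sum_j J_ij chi_j, from which the energy
    change of swapping retained atom a for free atom b is

        dE = -(2 h_a - J_aa) + 2 (h_b - J_ab) + J_bb.
    """

    RESYNC = 100_000  # moves between exact energy recomputations

    def __init__(self, J: np.ndarray, retained: np.ndarray, rng):
        self.J = J
        self.n = J.shape[0]
        self.rng = rng
        chi = np.zeros(self.n, dtype=bool)
        chi[retained] = True
        self.chi = chi
        self.ret = list(np.where(chi)[0])
        self.free = list(np.where(~chi)[0])
        self.h = J @ chi.astype(float)
        self.E = float(self.h[chi].sum())
        self._moves_since_sync = 0
        self._buf_u = np.empty(0)
        self._buf_pos = 0

    # -- chunked RNG -------------------------------------------------------
    def _uniforms(self, k=3):
        if self._buf_pos + k > self._buf_u.size:
            self._buf_u = self.rng.random(30000)
            self._buf_pos = 0
        out = self._buf_u[self._buf_pos:self._buf_pos + k]
        self._buf_pos += k
        return out

    # -- moves ---------------------------------------------------------------
    def propose(self):
        """Return (ia, ib, dE): positions in ret/free lists and energy change."""
        u = self._uniforms(2)
        ia = int(u[0] * len(self.ret))
        ib = int(u[1] * len(self.free))
        a, b = self.ret[ia], self.free[ib]
        J = self.J
        dE = (-(2.0 * self.h[a] - J[a, a])
              + 2.0 * (self.h[b] - J[a, b]) + J[b, b])
        return ia, ib, float(dE)

    def accept(self, ia: int, ib: int, dE: float):
        a, b = self.ret[ia], self.free[ib]
        self.ret[ia], self.free[ib] = b, a
        self.chi[a] = False
        self.chi[b] = True
        self.h += self.J[b] - self.J[a]
        self.E += dE
        self._moves_since_sync += 1
        if self._moves_since_sync >= self.RESYNC:
            idx = np.where(self.chi)[0]
            self.E = float(self.J[np.ix_(idx, idx)].sum())
            self.h = self.J @ self.chi.astype(float)
            self._moves_since_sync = 0

    def mapping(self, label: str = "") -> Mapping:
        return Mapping(self.chi.copy(), label=label)


def propose_swap_move(mapping: Mapping, couplings: CouplingMatrix,
                      rng) -> tuple[Mapping, float]:
    """One uniform retained/non-retained exchange and its exact dE."""
    if mapping.N >= mapping.n:
        raise ValueError("the all-atom mapping admits no N-conserving move")
    w = _Walker(couplings.J, mapping.retained, rng)
    ia, ib, dE = w.propose()
    w.accept(ia, ib, dE)
    return w.mapping(), dE


# ---------------------------------------------------------------------------
# Range finding
# ---------------------------------------------------------------------------

def find_norm_range(couplings: CouplingMatrix, N: int,
                    config: WLConfig = WLConfig()) -> tuple[float, float]:
    """Bracket [E_min, E_max] with a single fixed-ln_f WL pass.

    The penalty landscape is kept on an unbounded (dictionary) grid so the
    walk keeps extending the explored range; the returned bounds are the
    outer edges of the extreme visited bins.
    """
    _validate_N(couplings, N)
    rng = np.random.default_rng(config.seed)
    if N == couplings.n:
        e = float(couplings.J.sum())
        return e - config.bin_width / 2, e + config.bin_width / 2
    w = _Walker(couplings.J, _initial_indices(couplings.n, N, rng), rng)
    dE = config.bin_width
    S: dict[int, float] = {}
    ln_f = config.ln_f_init
    for _ in range(config.preliminary_moves):
        ia, ib, d = w.propose()
        b_cur = _bin_index(w.E, dE)
        b_new = _bin_index(w.E + d, dE)
        s_cur = S.get(b_cur, 0.0)
        s_new = S.get(b_new, 0.0)
        if s_new <= s_cur or w._uniforms(1)[0] < math.exp(s_cur - s_new):
            w.accept(ia, ib, d)
            b_cur = b_new
        S[b_cur] = S.get(b_cur, 0.0) + ln_f
    bins = sorted(S)
    return bins[0] * dE, (bins[-1] + 1) * dE


def _validate_N(couplings, N):
    if not 1 <= N <= couplings.n:
        raise ValueError(f"N={N} out of range for n={couplings.n}")


def _initial_indices(n, N, rng):
    return rng.choice(n, size=N, replace=False)


# ---------------------------------------------------------------------------
# The iterative WL scheme
# ---------------------------------------------------------------------------

def _grid_from_range(e_lo: float, e_hi: float, width: float) -> np.ndarray:
    lo = _bin_index(e_lo, width)
    hi = _bin_index(e_hi, width) + 1
    if hi <= lo:
        hi = lo + 1
    return width * np.arange(lo, hi + 1)


def wl_run(couplings: CouplingMatrix, N: int,
           norm_range: tuple[float, float],
           config: WLConfig = WLConfig()) -> DOSEstimate:
    """Iterative Wang-Landau estimate of S_N(E) on ``norm_range``.

    Every visit adds ln_f to the bin entropy and 1 to the stage histogram;
    when the histogram over the reachable bins is flat (min >= threshold *
    mean) the histogram is reset and ln_f is multiplied by ``f_update``,
    until ln_f < ln_f_min.  Proposals leaving the range are rejected, with
    the current bin re-incremented.  Flatness is judged over the bins
    discovered so far: with a discrete norm spectrum some bins of the grid
    are genuinely unreachable and must not stall the schedule.
    """
    _validate_N(couplings, N)
    e_lo, e_hi = norm_range
    if not e_hi > e_lo:
        raise ValueError("degenerate norm range")
    dE = config.bin_width
    grid = _grid_from_range(e_lo, e_hi, dE)
    nb = len(grid) - 1
    first = _bin_index(grid[0], dE)

    rng = np.random.default_rng(config.seed)
    S = np.zeros(nb)
    H = np.zeros(nb, dtype=np.int64)
    ever = np.zeros(nb, dtype=bool)

    w, b_cur = _seed_walker(couplings, N, grid, rng)
    ln_f = config.ln_f_init
    moves = 0
    converged = True

    if couplings.n == N:  # single state: nothing to iterate
        ever[b_cur] = True
        S[b_cur] = config.ln_f_init
        H[b_cur] = 1
        return _finalize(N, grid, S, H, ever, [norm_range], True, 0.0)

    while ln_f >= config.ln_f_min:
        since_check = 0
        while True:
            ia, ib, d = w.propose()
            e_new = w.E + d
            b_new = _bin_index(e_new, dE) - first
            if 0 <= b_new < nb:
                if (S[b_new] <= S[b_cur]
                        or w._uniforms(1)[0] < math.exp(S[b_cur] - S[b_new])):
                    w.accept(ia, ib, d)
                    b_cur = b_new
            # out-of-range proposals fall through: reject, re-increment
            S[b_cur] += ln_f
            H[b_cur] += 1
            ever[b_cur] = True
            moves += 1
            since_check += 1
            if since_check >= config.check_interval:
                since_check = 0
                vis = H[ever]
                if vis.size and vis.min() >= config.flatness_threshold * vis.mean():
                    break
                if moves >= config.max_moves:
                    warnings.warn("WL did not converge within max_moves")
                    return _finalize(N, grid, S, H, ever, [norm_range],
                                     False, ln_f)
        ln_f *= config.f_update
        if ln_f >= config.ln_f_min:
            H[:] = 0
    return _finalize(N, grid, S, H, ever, [norm_range], converged, ln_f)


def _seed_walker(couplings, N, grid, rng, max_tries=200):
    """Start the walk, steering its energy into the grid if necessary."""
    dE = grid[1] - grid[0]
    nb = len(grid) - 1
    first = _bin_index(grid[0], dE)
    w = _Walker(couplings.J, _initial_indices(couplings.n, N, rng), rng)
    if couplings.n == N:
        return w, min(max(_bin_index(w.E, dE) - first, 0), nb - 1)
    for _ in range(max_tries * couplings.n):
        b = _bin_index(w.E, dE) - first
        if 0 <= b < nb:
            return w, b
        target = 0.5 * (grid[0] + grid[-1])
        ia, ib, d = w.propose()
        if abs(w.E + d - target) < abs(w.E - target):
            w.accept(ia, ib, d)
    raise RuntimeError("could not steer the walker into the requested range")


def _finalize(N, grid, S, H, ever, windows, converged, ln_f):
    entropy = np.where(ever, S, -np.inf)
    vis = np.isfinite(entropy)
    if vis.any():
        entropy[vis] -= entropy[vis].min()
    return DOSEstimate(N=N, grid=np.asarray(grid, dtype=float),
                       entropy=entropy, histogram=np.asarray(H, dtype=float),
                       window_bounds=[tuple(map(float, wd)) for wd in windows],
                       converged=converged, ln_f_final=float(ln_f))


# ---------------------------------------------------------------------------
# Window decomposition
# ---------------------------------------------------------------------------

def wl_windows(couplings: CouplingMatrix, N: int,
               norm_range: tuple[float, float],
               config: WLConfig = WLConfig(),
               n_windows: int | None = None) -> DOSEstimate:
    """Divide the range into overlapping windows, run WL in each, merge.

    Window results are aligned by the visit-weighted mean entropy offset on
    the bins shared by consecutive windows (the least-squares solution for
    a chain of additive constants), then averaged on overlaps.
    """
    e_lo, e_hi = norm_range
    if n_windows is None:
        n_windows = max(1, math.ceil((e_hi - e_lo) / 25.0))
    if n_windows == 1:
        return wl_run(couplings, N, norm_range, config)
    if config.window_overlap <= 0:
        raise ValueError("disjoint windows cannot be merged: "
                         "window_overlap must be positive")

    span = (e_hi - e_lo) / (n_windows - (n_windows - 1) * config.window_overlap)
    step = span * (1.0 - config.window_overlap)
    if step <= 0:
        raise ValueError("window overlap leaves no forward step")
    windows = []
    for k in range(n_windows):
        lo = e_lo + k * step
        hi = min(lo + span, e_hi)
        windows.append((lo, hi))
    parts = []
    for k, wd in enumerate(windows):
        cfg = replace(config, seed=config.seed + 1000 * (k + 1))
        parts.append(wl_run(couplings, N, wd, cfg))

    return _merge_windows(N, parts, windows, config)


def _merge_windows(N, parts, windows, config):
    dE = config.bin_width
    first = min(math.floor(p.grid[0] / dE + 0.5) for p in parts)
    last = max(math.floor(p.grid[-1] / dE + 0.5) for p in parts)
    nb = last - first
    grid = dE * np.arange(first, last + 1)
    S_acc = np.zeros(nb)
    W_acc = np.zeros(nb)
    H_acc = np.zeros(nb)
    merged_vis = np.zeros(nb, dtype=bool)
    converged = all(p.converged for p in parts)

    for k, p in enumerate(parts):
        off_bins = math.floor(p.grid[0] / dE + 0.5) - first
        idx = off_bins + np.arange(len(p.entropy))
        vis = np.isfinite(p.entropy)
        if k == 0:
            shift = 0.0
        else:
            both = np.zeros(nb, dtype=bool)
            both[idx[vis]] = True
            both &= merged_vis
            if not both.any():
                raise ValueError("windows share no visited overlap bins")
            local = both[idx]  # overlap, in window coordinates
            merged_S = S_acc[idx[local]] / W_acc[idx[local]]
            wgt = np.minimum(p.histogram[local] + 1.0,
                             W_acc[idx[local]])
            shift = float(np.average(merged_S - p.entropy[local],
                                     weights=wgt))
        wv = p.histogram[vis] + 1.0
        S_acc[idx[vis]] += wv * (p.entropy[vis] + shift)
        W_acc[idx[vis]] += wv
        H_acc[idx[vis]] += p.histogram[vis]
        merged_vis[idx[vis]] = True

    entropy = np.full(nb, -np.inf)
    entropy[merged_vis] = S_acc[merged_vis] / W_acc[merged_vis]
    entropy[merged_vis] -= entropy[merged_vis].min()
    return DOSEstimate(N=N, grid=grid, entropy=entropy, histogram=H_acc,
                       window_bounds=[tuple(map(float, wd)) for wd in windows],
                       converged=converged,
                       ln_f_final=max(p.ln_f_final for p in parts))


# ---------------------------------------------------------------------------
# Exact oracle
# ---------------------------------------------------------------------------

def exact_enumeration(couplings: CouplingMatrix, N: int,
                      bin_width: float = 0.1,
                      max_states: int = 10_000_000) -> DOSEstimate:
    """Exact density of states by visiting every N-subset.

    Entropy is ln(count) per bin on the same [lo, hi) grid convention as
    the stochastic estimates, so sum(exp(S)) = C(n, N) exactly.
    """
    _validate_N(couplings, N)
    n = couplings.n
    total = math.comb(n, N)
    if total > max_states:
        raise ValueError(f"C({n},{N}) = {total} exceeds max_states")
    J = couplings.J
    values = np.empty(total)
    for k, idx in enumerate(itertools.combinations(range(n), N)):
        ii = np.asarray(idx)
        values[k] = J[np.ix_(ii, ii)].sum()
    # bin with the canonical index rule so the grid matches the WL walks
    idx = np.floor(values / bin_width + 1e-9).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    grid = bin_width * np.arange(lo, hi + 2)
    entropy = np.where(counts > 0, np.log(np.maximum(counts, 1)), -np.inf)
    return DOSEstimate(N=N, grid=grid, entropy=entropy,
                       histogram=counts.astype(float),
                       window_bounds=[(float(values.min()), float(values.max()))],
                       converged=True, ln_f_final=0.0, exact=True)


# ---------------------------------------------------------------------------
# Saddle point
# ---------------------------------------------------------------------------

def saddle_point(dos: DOSEstimate,
                 fit_halfwidth: int | None = None) -> SaddlePointSummary:
    """Quadratic expansion of S_N(E) around its maximum.

    Returns the peak position E_tilde (the saddle-point mean), the local
    curvature S'' (< 0) and sigma = |S''|^(-1/2), plus finite-difference
    first/second derivative profiles over the support.
    """
    vis = dos.support
    if vis.sum() < 3:
        raise ValueError("need at least 3 visited bins")
    centers = dos.centers[vis]
    S = dos.entropy[vis]
    k_max = int(np.argmax(S))
    if k_max in (0, len(S) - 1):
        raise ValueError("entropy maximum on the range boundary")
    if fit_halfwidth is None:
        fit_halfwidth = max(5, int(0.05 * len(S)))
    lo = max(0, k_max - fit_halfwidth)
    hi = min(len(S), k_max + fit_halfwidth + 1)
    coef = np.polyfit(centers[lo:hi], S[lo:hi], 2)
    a, b = coef[0], coef[1]
    if a >= 0:
        raise ValueError("local fit is not concave at the entropy peak")
    E_tilde = -b / (2 * a)
    S2 = 2.0 * a
    S1_prof = np.gradient(S, centers)
    S2_prof = np.gradient(S1_prof, centers)
    return SaddlePointSummary(E_tilde=float(E_tilde), S2=float(S2),
                              mean=float(E_tilde),
                              sigma=float(1.0 / math.sqrt(-S2)),
                              S1_profile=S1_prof, S2_profile=S2_prof,
                              centers=centers)


# ---------------------------------------------------------------------------
# Stratified harvesting
# ---------------------------------------------------------------------------

def harvest_stratified_mappings(couplings: CouplingMatrix, N: int,
                                norm_range: tuple[float, float],
                                config: WLConfig = WLConfig(),
                                bin_width_macro: float = 20.0,
                                per_bin: int = 100,
                                dos: DOSEstimate | None = None,
                                save_interval: int | None = None,
                                update_entropy: bool = True,
                                max_moves: int | None = None) -> list[Mapping]:
    """Collect mappings stratified over the norm range via a WL-biased walk.

    The walk continues (optionally still updating the running entropy with
    the current ln_f) and stores one mapping every ``save_interval``
    proposed moves — by default every n moves — into macro-bins of width
    ``bin_width_macro``, until each macro-bin holds ``per_bin`` mappings.
    Macro-bins the walk cannot fill before ``max_moves`` are returned
    short, with a warning.  The pool is correlated by construction.
    """
    _validate_N(couplings, N)
    e_lo, e_hi = norm_range
    dE = config.bin_width
    if save_interval is None:
        save_interval = couplings.n
    if max_moves is None:
        max_moves = config.max_moves
    n_macro = max(1, math.ceil((e_hi - e_lo) / bin_width_macro))

    grid = _grid_from_range(e_lo, e_hi, dE)
    nb = len(grid) - 1
    first = _bin_index(grid[0], dE)
    S = np.zeros(nb)
    if dos is not None:
        # project the prior entropy onto this grid
        prior_first = math.floor(dos.grid[0] / dE + 0.5)
        for j, s in enumerate(dos.entropy):
            t = prior_first + j - first
            if 0 <= t < nb and np.isfinite(s):
                S[t] = s
    rng = np.random.default_rng(config.seed + 7)
    w, b_cur = _seed_walker(couplings, N, grid, rng)
    ln_f = dos.ln_f_final if (dos is not None and dos.ln_f_final > 0) \
        else config.ln_f_init
    if not update_entropy:
        ln_f = 0.0

    pools: list[list[Mapping]] = [[] for _ in range(n_macro)]
    filled = 0
    moves = 0
    while filled < n_macro and moves < max_moves:
        ia, ib, d = w.propose()
        e_new = w.E + d
        b_new = _bin_index(e_new, dE) - first
        if 0 <= b_new < nb:
            if (S[b_new] <= S[b_cur]
                    or w._uniforms(1)[0] < math.exp(S[b_cur] - S[b_new])):
                w.accept(ia, ib, d)
                b_cur = b_new
        S[b_cur] += ln_f
        moves += 1
        if moves % save_interval == 0:
            macro = int((w.E - e_lo) / bin_width_macro)
            if 0 <= macro < n_macro and len(pools[macro]) < per_bin:
                pools[macro].append(
                    w.mapping(label=f"wl-harvest:{macro}:{len(pools[macro])}"))
                if len(pools[macro]) == per_bin:
                    filled += 1
    if filled < n_macro:
        short = [k for k, p in enumerate(pools) if len(p) < per_bin]
        warnings.warn(f"macro-bins {short} returned short after {moves} moves")
    return [m for pool in pools for m in pool]
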