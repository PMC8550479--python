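"""Low-dimensional embeddings of mapping ensembles.

Pairwise mapping distances D(M, M') define a finite metric space; to see
its shape, points are embedded in the plane either by classical
multidimensional scaling (deterministic, used as initialisation and
fallback) or by sketch-map-style stress minimisation, where both the
high-dimensional and the embedded distances are passed through sigmoids

    s(r; sigma, a, b) = 1 - (1 + (2^(a/b) - 1) (r/sigma)^a)^(-b/a)

before being compared.  The sigmoids flatten distances shorter and longer
than the focus scale sigma, so the optimiser spends its freedom resolving
the mid-range structure — the regime where mapping ensembles organise into
qualitatively distinct clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mapping_algebra import Mapping
from .structure_io import CouplingMatrix

__all__ = [
    "DistanceMatrix",
    "SketchMapParams",
    "EmbeddingResult",
    "distance_matrix",
    "classical_embed",
    "sketch_map_embed",
    "gradient_correlation",
    "sigmoid",
    "PRESETS",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of mapping distances with provenance labels."""

    D: np.ndarray
    labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("D must be square")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise ValueError("D must have zero diagonal")
        if len(self.labels) != self.D.shape[0]:
            raise ValueError("one label per row required")

    @property
    def P(self) -> int:
        return self.D.shape[0]

    def save(self, path) -> None:
        from pathlib import Path
        lines = ["\t".join(["label"] + self.labels)]
        for lab, row in zip(self.labels, self.D):
            lines.append("\t".join([lab] + [f"{v:.10g}" for v in row]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "DistanceMatrix":
        from pathlib import Path
        rows = Path(path).read_text().strip().splitlines()
        labels = rows[0].split("\t")[1:]
        D = np.array([[float(v) for v in r.split("\t")[1:]] for r in rows[1:]])
        return cls(D, labels)


@dataclass(frozen=True)
class SketchMapParams:
    """The six sigmoid parameters: (sigma, a, b) in each space."""

    sigma_D: float = 2.0
    a_D: float = 5.0
    b_D: float = 5.0
    sigma_d: float = 2.0
    a_d: float = 2.0
    b_d: float = 2.0

    def __post_init__(self):
        for name in ("sigma_D", "a_D", "b_D", "sigma_d", "a_d", "b_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: named parameter sets: a tight and a wide focus scale for norm-stratified
#: pools, and the set used for mapping-entropy-scored ensembles
PRESETS = {
    "low-sigma": SketchMapParams(sigma_D=2.0, a_D=5.0, b_D=5.0,
                                 sigma_d=2.0, a_d=2.0, b_d=2.0),
    "high-sigma": SketchMapParams(sigma_D=20.0, a_D=5.0, b_D=5.0,
                                  sigma_d=20.0, a_d=2.0, b_d=2.0),
    "smap": SketchMapParams(sigma_D=5.0, a_D=5.0, b_D=5.0,
                            sigma_d=5.0, a_d=2.0, b_d=2.0),
}


@dataclass
class EmbeddingResult:
    """2D coordinates per mapping plus the final stress."""

    points: np.ndarray
    stress: float
    params: SketchMapParams | None
    seed: int | None
    stress_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    labels: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        from pathlib import Path
        lines = ["label\tx\ty"]
        labs = self.labels or [str(i) for i in range(len(self.points))]
        for lab, (x, y) in zip(labs, self.points):
            lines.append(f"{lab}\t{x:.10g}\t{y:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------


def distance_matrix(mappings: list[Mapping],
                    couplings: CouplingMatrix) -> DistanceMatrix:
    """All-pairs mapping distances with cached norms (O(P^2) pair work)."""
    if not mappings:
        raise ValueError("empty mapping list")
    n = couplings.n
    for m in mappings:
        if m.n != n:
            raise ValueError("mapping length inconsistent with couplings")
    X = np.array([m.chi for m in mappings], dtype=float)  # P x n
    G = X @ couplings.J @ X.T                             # Gram matrix
    e = np.diag(G)
    D2 = e[:, None] + e[None, :] - 2.0 * G
    np.fill_diagonal(D2, 0.0)
    if D2.min() < -1e-8:
        raise ValueError("negative squared distance: corrupted couplings?")
    D = np.sqrt(np.clip(D2, 0.0, None))
    labels = [m.label or f"m{i}" for i, m in enumerate(mappings)]
    return DistanceMatrix(D, labels, metadata={
        "sigma": couplings.sigma, "zbar": couplings.zbar,
        "normalized": couplings.normalized,
        "source_label": couplings.source_label,
    })


def classical_embed(D: DistanceMatrix | np.ndarray) -> EmbeddingResult:
    """Classical scaling: top-2 eigenpairs of the double-centred -D^2/2."""
    mat = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    P = mat.shape[0]
    H = np.eye(P) - np.ones((P, P)) / P
    B = -0.5 * H @ (mat ** 2) @ H
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order[:2]], vecs[:, order[:2]]
    pts = vecs * np.sqrt(np.clip(vals, 0.0, None))
    d_emb = _pairwise(pts)
    stress = float(np.sqrt(((d_emb - mat) ** 2).sum()))
    labels = D.labels if isinstance(D, DistanceMatrix) else []
    return EmbeddingResult(points=pts, stress=stress, params=None,
                           seed=None, labels=list(labels))


def sigmoid(r, sigma: float, a: float, b: float):
    """Sketch-map sigmoid: 0 at r=0, ~1 for r >> sigma, s(sigma)=1/2."""
    r = np.asarray(r, dtype=float)
    c = 2.0 ** (a / b) - 1.0
    return 1.0 - (1.0 + c * (r / sigma) ** a) ** (-b / a)


def _sigmoid_deriv(r, sigma, a, b):
    c = 2.0 ** (a / b) - 1.0
    u = 1.0 + c * (r / sigma) ** a
    return (b * c / sigma) * (r / sigma) ** (a - 1.0) * u ** (-b / a - 1.0)


def _pairwise(pts):
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def sketch_map_embed(D: DistanceMatrix | np.ndarray,
                     params: SketchMapParams | str = "low-sigma",
                     seed: int = 0, iterations: int = 10_000,
                     tol: float = 1e-8) -> EmbeddingResult:
    """Minimise the sigmoid-transformed stress by gradient descent.

    Starts from the classical-scaling solution plus a tiny seeded jitter
    (which also breaks exact degeneracies); the step is halved whenever a
    step would increase the stress, so the stress history is
    non-increasing.  Deterministic for a given seed.
    """
    if isinstance(params, str):
        params = PRESETS[params]
    mat = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite distances")
    P = mat.shape[0]
    F = sigmoid(mat, params.sigma_D, params.a_D, params.b_D)
    np.fill_diagonal(F, 0.0)

    rng = np.random.default_rng(seed)
    pts = classical_embed(mat).points
    scale = mat[mat > 0].mean() if (mat > 0).any() else 1.0
    pts = pts + 1e-4 * scale * rng.standard_normal(pts.shape)

    mask = ~np.eye(P, dtype=bool)

    def stress_of(p):
        d = _pairwise(p)
        f = sigmoid(np.where(mask, d, 1.0), params.sigma_d, params.a_d,
                    params.b_d)
        resid = np.where(mask, F - f, 0.0)
        return 0.5 * float((resid ** 2).sum()), d, resid

    step = 0.1 * scale ** 2 if scale > 0 else 0.1
    s_cur, d_cur, resid = stress_of(pts)
    history = [s_cur]
    for _ in range(iterations):
        dsafe = np.where(mask & (d_cur > 1e-12), d_cur, 1.0)
        fprime = _sigmoid_deriv(dsafe, params.sigma_d, params.a_d, params.b_d)
        w = np.where(mask, -2.0 * resid * fprime / dsafe, 0.0)
        grad = (w.sum(1)[:, None] * pts) - w @ pts
        gnorm = np.abs(grad).max()
        if gnorm == 0:
            break
        improved = False
        while step * gnorm > 1e-15:
            cand = pts - step * grad
            s_new, d_new, r_new = stress_of(cand)
            if s_new < s_cur:
                pts, s_cur, d_cur, resid = cand, s_new, d_new, r_new
                history.append(s_cur)
                step *= 1.2
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        if len(history) > 1 and history[-2] - history[-1] < tol * max(history[-2], 1e-30):
            break
    labels = D.labels if isinstance(D, DistanceMatrix) else []
    return EmbeddingResult(points=pts - pts.mean(0), stress=s_cur,
                           params=params, seed=seed,
                           stress_history=np.array(history),
                           labels=list(labels))


def gradient_correlation(points: np.ndarray,
                         scores: np.ndarray) -> tuple[int, float, np.ndarray]:
    """Pearson correlation of each embedding axis with a score vector.

    Returns (index of the max-|r| axis, its r, r per axis).  Used to test
    whether a quality score such as the mapping entropy organises the
    embedded ensemble along one direction.
    """
    points = np.asarray(points, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(points) != len(scores):
        raise ValueError("points and scores must have equal length")
    if np.std(scores) == 0:
        raise ValueError("scores have zero variance")
    rs = []
    for k in range(points.shape[1]):
        x = points[:, k]
        if np.std(x) == 0:
            raise ValueError(f"axis {k} has zero variance")
        rs.append(float(np.corrcoef(x, scores)[0, 1]))
    rs = np.array(rs)
    best = int(np.argmax(np.abs(rs)))
    return best, float(rs[best]), rs
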