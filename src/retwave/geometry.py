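"""Representation-geometry suite: manifold capacity, dimension, radius,
simulation capacity, participation ratio, center correlations, and
explained-variance dimension.

An *object manifold* is the set of feature-space responses of one network
layer to all presentations of one object (its translations, recolorations,
or the frames of one wave event).  Linear separability of P such manifolds
in N feature dimensions is governed by the manifold capacity alpha_c: for
P/N < alpha_c the manifolds are separable with high probability, for
P/N > alpha_c they are not.  For point-cloud manifolds of M points,
2/M <= alpha_c <= 2.

Two independent routes to capacity are provided:

* :func:`simulation_capacity` — the empirical route: vary the feature
  dimension N (by Gaussian random projection), test separability of random
  balanced manifold dichotomies with an exact zero-misclassification linear
  program, and locate the N where the separable fraction crosses 0.5;
  alpha_sim = P / N_c.
* :func:`meanfield_geometry` — the mean-field replica route for point
  clouds: for Gaussian directions T in the manifold-plus-center subspace,
  project T onto the polar cone of the manifold's convex hull; the residual
  norm gives the inverse capacity, and the active hull point is the *anchor
  point* from which the manifold radius R_M and dimension D_M are read off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import nnls

from .contrastive import Encoder
from .task_eval import color_jitter, _translate
from .wave_data import WaveEvent, WaveMovie

__all__ = [
    "ManifoldSet",
    "ManifoldGeometry",
    "CapacityEstimate",
    "GeometrySummary",
    "extract_activations",
    "build_translation_manifolds",
    "build_color_manifolds",
    "build_classification_manifolds",
    "build_wave_event_manifolds",
    "simulation_capacity",
    "meanfield_geometry",
    "participation_ratio",
    "center_correlation",
    "explained_variance_dims",
    "layer_geometry_summary",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ManifoldSet:
    """P manifolds x M points x N features from one layer."""

    points: np.ndarray
    layer_name: str = "features"
    task: str = ""
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 3:
            raise ValueError("points must be P x M x N")
        if self.points.shape[2] < 2:
            raise ValueError("need at least N=2 features")
        if self.labels is None:
            self.labels = np.arange(self.points.shape[0])

    @property
    def P(self) -> int:
        return self.points.shape[0]

    @property
    def M(self) -> int:
        return self.points.shape[1]

    @property
    def N(self) -> int:
        return self.points.shape[2]


@dataclass
class ManifoldGeometry:
    """Mean-field capacity/dimension/radius of a ManifoldSet."""

    capacity_alpha_c: float
    dimension_D_M: float
    radius_R_M: float
    per_manifold_alpha_c: np.ndarray
    per_manifold_D_M: np.ndarray
    per_manifold_R_M: np.ndarray
    n_gaussian_samples: int
    seed: int


@dataclass
class CapacityEstimate:
    alpha_sim: float
    N_c: float
    P: int
    M: int
    n_dichotomies: int
    separability_curve: List[Tuple[int, float]]


@dataclass
class GeometrySummary:
    """Per-layer geometry record (the tabular form of the figure panels)."""

    layer_name: str
    alpha_c: float
    D_M: float
    R_M: float
    center_corr: float
    participation_ratio: float
    ev_dims: int
    alpha_sim: Optional[float] = None


# ---------------------------------------------------------------------------
# Activation extraction
# ---------------------------------------------------------------------------

def _random_projection(X: np.ndarray, n_out: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, X.shape[1], n_out]))
    G = rng.standard_normal((X.shape[1], n_out)) / np.sqrt(n_out)
    return X @ G


def extract_activations(encoder: Encoder, images: np.ndarray,
                        layer_policy: str = "per-block",
                        max_N: int = 2000, seed: int = 0,
                        include_pixels: bool = True) -> Dict[str, np.ndarray]:
    """Flattened activations per layer, input -> output order.

    ``images`` is (K, H, W, C) in [0, 1].  Raw pixels are included as layer
    ``"pixels"``.  Layers wider than ``max_N`` are reduced by a seeded
    Gaussian random projection.  ``per-block`` records each conv-block
    output (for the residual backbone: the stem plus its 8 residual blocks);
    ``every-relu`` additionally keeps no pooling stages out — for the small
    backbone the two policies coincide with the block outputs.
    """
    if layer_policy not in ("per-block", "every-relu"):
        raise ValueError(f"unknown layer_policy {layer_policy!r}")
    x = np.ascontiguousarray(images.transpose(0, 3, 1, 2).astype(np.float32))
    acts: Dict[str, np.ndarray] = {}
    if include_pixels:
        acts["pixels"] = images.reshape(images.shape[0], -1).astype(np.float64)
    acts.update(encoder.piece_activations(x))
    out: Dict[str, np.ndarray] = {}
    for name, A in acts.items():
        A = np.asarray(A, dtype=np.float64)
        if A.shape[1] > max_N:
            A = _random_projection(A, max_N, seed)
        out[name] = A
    return out


# ---------------------------------------------------------------------------
# Manifold builders
# ---------------------------------------------------------------------------

def _stimuli_to_manifolds(stimuli: np.ndarray, encoder: Optional[Encoder],
                          task: str, layer_policy: str, max_N: int,
                          seed: int) -> Dict[str, ManifoldSet]:
    P, M = stimuli.shape[:2]
    flat = stimuli.reshape((P * M,) + stimuli.shape[2:])
    if encoder is None:
        acts = {"pixels": flat.reshape(P * M, -1).astype(np.float64)}
        if acts["pixels"].shape[1] > max_N:
            acts["pixels"] = _random_projection(acts["pixels"], max_N, seed)
    else:
        acts = extract_activations(encoder, flat, layer_policy, max_N, seed)
    return {name: ManifoldSet(A.reshape(P, M, A.shape[1]), name, task)
            for name, A in acts.items()}


def build_translation_manifolds(bases: np.ndarray, encoder: Optional[Encoder],
                                M: int = 20, max_shift_px: int = 3,
                                seed: int = 0, layer_policy: str = "per-block",
                                max_N: int = 2000) -> Dict[str, ManifoldSet]:
    """One manifold per base image; M random shifts with |dx|,|dy| <= 3."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A51]))
    P = bases.shape[0]
    stim = np.empty((P, M) + bases.shape[1:], dtype=np.float32)
    for p in range(P):
        for m in range(M):
            dx, dy = rng.integers(-max_shift_px, max_shift_px + 1, size=2)
            stim[p, m] = _translate(bases[p], int(dx), int(dy))
    return _stimuli_to_manifolds(stim, encoder, "translation", layer_policy,
                                 max_N, seed)


def build_color_manifolds(bases: np.ndarray, encoder: Optional[Encoder],
                          M: int = 20, jitter_lo: float = 0.5,
                          jitter_hi: float = 1.5, seed: int = 0,
                          layer_policy: str = "per-block",
                          max_N: int = 2000) -> Dict[str, ManifoldSet]:
    """One manifold per base image; M random 50-150% color jitters."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC011]))
    P = bases.shape[0]
    stim = np.empty((P, M) + bases.shape[1:], dtype=np.float32)
    for p in range(P):
        mag = rng.uniform(jitter_lo, jitter_hi, size=(M, 4))
        sign = rng.choice([-1.0, 1.0], size=(M, 4))
        fac = np.maximum(1.0 + sign[:, :3] * mag[:, :3], 0.0)
        stim[p] = color_jitter(np.repeat(bases[p][None], M, axis=0), fac,
                               sign[:, 3] * mag[:, 3] * 0.5)
    return _stimuli_to_manifolds(stim, encoder, "color", layer_policy,
                                 max_N, seed)


def build_classification_manifolds(images: np.ndarray, labels: np.ndarray,
                                   encoder: Optional[Encoder], P: int = 50,
                                   M: int = 20, seed: int = 0,
                                   classifier_scores: Optional[np.ndarray] = None,
                                   layer_policy: str = "per-block",
                                   max_N: int = 2000) -> Dict[str, ManifoldSet]:
    """One manifold per class.  With ``classifier_scores`` (per-image softmax
    probability of its own class), the M top-ranked exemplars are used;
    otherwise M exemplars are drawn uniformly at random."""
    classes = np.unique(labels)
    if P > classes.size:
        raise ValueError(f"P={P} exceeds the {classes.size} available classes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1A5]))
    chosen = rng.choice(classes, size=P, replace=False)
    picks = []
    for c in chosen:
        idx = np.flatnonzero(labels == c)
        if idx.size < M:
            raise ValueError(f"class {c} has fewer than M={M} exemplars")
        if classifier_scores is not None:
            idx = idx[np.argsort(classifier_scores[idx])[::-1][:M]]
        else:
            idx = rng.choice(idx, size=M, replace=False)
        picks.append(idx)
    stim = images[np.concatenate(picks)].reshape((P, M) + images.shape[1:])
    out = _stimuli_to_manifolds(stim, encoder, "classification", layer_policy,
                                max_N, seed)
    for ms in out.values():
        ms.labels = chosen
    return out


def build_wave_event_manifolds(movie: WaveMovie, events: Sequence[WaveEvent],
                               encoder: Optional[Encoder], P: int, M: int,
                               seed: int = 0, layer_policy: str = "per-block",
                               max_N: int = 2000) -> Dict[str, ManifoldSet]:
    """One manifold per wave event; M frames sampled without replacement."""
    long_enough = [ev for ev in events if len(ev) >= M]
    for ev in events:
        if len(ev) < M and len(long_enough) < P:
            raise ValueError(
                f"event [{ev.start_frame}, {ev.end_frame}) has fewer than "
                f"M={M} frames and only {len(long_enough)} events are long enough")
    if len(long_enough) < P:
        raise ValueError(f"P={P} exceeds the {len(long_enough)} usable events")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE4E7]))
    chosen = rng.choice(len(long_enough), size=P, replace=False)
    frames = movie.frames
    stim = np.empty((P, M) + frames.shape[1:] + (3,), dtype=np.float32)
    for i, ei in enumerate(chosen):
        ev = long_enough[ei]
        fi = rng.choice(ev.frame_indices(), size=M, replace=False)
        stim[i] = np.repeat(frames[fi][..., None], 3, axis=-1)
    return _stimuli_to_manifolds(stim, encoder, "wave-event", layer_policy,
                                 max_N, seed)


# ---------------------------------------------------------------------------
# Simulation capacity
# ---------------------------------------------------------------------------

def _is_separable(X: np.ndarray, y: np.ndarray, tol: float = 1e-7) -> bool:
    """Exact linear-separability decision (with bias, zero misclassification).

    The labeled points are separable iff the origin lies outside the convex
    hull of the label-signed augmented points y_i * (x_i, 1).  The minimum-
    norm point of that hull is found by non-negative least squares (the dual
    of the max-margin program); a positive residual certifies separability.
    """
    Xa = y[:, None] * np.column_stack([X, np.ones(X.shape[0])])
    B = np.vstack([Xa.T, np.ones(X.shape[0])])
    e = np.zeros(B.shape[0])
    e[-1] = 1.0
    _, resid = nnls(B, e)
    return resid > tol


def _balanced_dichotomies(P: int, n: int, rng: np.random.Generator) -> np.ndarray:
    half = np.array([1.0] * (P // 2) + [-1.0] * (P - P // 2))
    return np.stack([rng.permutation(half) for _ in range(n)])


def _fraction_separable(points: np.ndarray, labels_PM: np.ndarray, N: int,
                        dichotomies: np.ndarray, seed: int,
                        early_majority: bool = True) -> float:
    """Fraction of dichotomies separable after projection to N dims."""
    X = _random_projection(points, N, seed) if N < points.shape[1] else points
    n = dichotomies.shape[0]
    n_sep = n_insep = 0
    for d in range(n):
        y = dichotomies[d][labels_PM]
        if _is_separable(X, y):
            n_sep += 1
        else:
            n_insep += 1
        if early_majority and (n_sep > n / 2 or n_insep > n / 2):
            # side of 0.5 is decided; fraction approximated by the tally
            break
    return n_sep / (n_sep + n_insep)


def simulation_capacity(manifolds: ManifoldSet, n_dichotomies: int = 50,
                        seed: int = 0, N_max: Optional[int] = None,
                        rel_tol: float = 0.02) -> CapacityEstimate:
    """Empirical manifold capacity by the varying-N procedure.

    For candidate feature dimensions N (Gaussian random projections of the
    full features), the fraction of ``n_dichotomies`` random balanced
    manifold dichotomies that are exactly linearly separable is measured;
    N_c brackets the 0.5 crossing by bisection and is refined by linear
    interpolation.  Returns alpha_sim = P / N_c.
    """
    P, M, N_full = manifolds.P, manifolds.M, manifolds.N
    if P < 4:
        raise ValueError("need P >= 4 manifolds")
    if n_dichotomies < 20:
        raise ValueError("need n_dichotomies >= 20")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1C0]))
    dich = _balanced_dichotomies(P, n_dichotomies, rng)
    labels_PM = np.repeat(np.arange(P), M)
    points = manifolds.points.reshape(P * M, N_full)

    if N_max is None:
        N_max = N_full
    curve: Dict[int, float] = {}

    def frac(N: int, full: bool = False) -> float:
        if N not in curve or full:
            curve[N] = _fraction_separable(points, labels_PM, N, dich, seed,
                                           early_majority=not full)
        return curve[N]

    lo, hi = 1, 2
    while frac(hi) < 0.5:
        lo, hi = hi, hi * 2
        if hi >= N_max:
            hi = N_max
            if frac(hi) < 0.5:
                raise RuntimeError(
                    "separable fraction never reaches 0.5 within the feature "
                    f"rank (curve: {sorted(curve.items())})")
            break
    while hi - lo > max(1, int(rel_tol * lo)):
        mid = (lo + hi) // 2
        if frac(mid) < 0.5:
            lo = mid
        else:
            hi = mid

    f_lo, f_hi = frac(lo, full=True), frac(hi, full=True)
    if f_hi == f_lo:
        N_c = 0.5 * (lo + hi)
    else:
        N_c = lo + (0.5 - f_lo) * (hi - lo) / (f_hi - f_lo)
    N_c = float(np.clip(N_c, 1.0, N_max))
    return CapacityEstimate(alpha_sim=P / N_c, N_c=N_c, P=P, M=M,
                            n_dichotomies=n_dichotomies,
                            separability_curve=sorted(curve.items()))


# ---------------------------------------------------------------------------
# Mean-field point-cloud geometry
# ---------------------------------------------------------------------------

def _manifold_mft(points_M_N: np.ndarray, center: np.ndarray,
                  t_draws: np.ndarray, eps: float = 1e-10):
    """Mean-field quantities of a single point-cloud manifold.

    ``points_M_N`` are the manifold's points after global centering, and
    ``t_draws`` (n_t, D+1) the Gaussian directions in the manifold-plus-
    center subspace.  Each direction is projected onto the polar cone of the
    hull of the normalized points s̃_j = (s_j, 1); the squared residual
    averages to the inverse capacity, and the active hull point (the anchor)
    gives radius and dimension contributions.
    """
    M = points_M_N.shape[0]
    c_norm = max(float(np.linalg.norm(center)), eps)
    A = points_M_N - center
    # orthonormal basis of the point-cloud span (reduced if rank-deficient)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int((s > max(s.max(), eps) * 1e-10).sum()) if s.size else 0
    basis = Vt[:rank]
    S = (A @ basis.T) / c_norm                      # (M, D) axis coords
    S_tilde = np.column_stack([S, np.ones(M)])      # (M, D+1)

    D = rank
    t_sub = t_draws[:, :D + 1]
    inv_cap_terms = np.zeros(t_sub.shape[0])
    r2_terms, dim_terms = [], []
    for i, t in enumerate(t_sub):
        g = S_tilde @ t
        if g.max() < 0:           # t interior to the polar cone: zero margin cost
            continue
        mu, _ = nnls(S_tilde.T, t)
        h = S_tilde.T @ mu        # = t - v, a conic combination of hull points
        inv_cap_terms[i] = h @ h  # squared margin cost ||t - v||^2
        if h[-1] > eps:
            anchor = h[:D] / h[-1]
            a_norm = np.linalg.norm(anchor)
            r2_terms.append(a_norm ** 2)
            if a_norm > eps and D > 0:
                dim_terms.append(float(t[:D] @ (anchor / a_norm)) ** 2)
            else:
                dim_terms.append(0.0)
    inv_cap = float(np.mean(inv_cap_terms))
    R_M = float(np.sqrt(np.mean(r2_terms))) if r2_terms else 0.0
    D_M = float(np.mean(dim_terms)) if dim_terms else 0.0
    return inv_cap, D_M, R_M


def meanfield_geometry(manifolds: ManifoldSet, n_gaussian_samples: int = 200,
                       seed: int = 0) -> ManifoldGeometry:
    """Mean-field replica estimate of capacity, dimension, and radius.

    Points are centered by the global mean; per manifold the convex program
    over ``n_gaussian_samples`` Gaussian directions yields the anchor
    points.  The reported capacity is the inverse of the mean inverse
    capacity across manifolds (the mean-field combination rule), and obeys
    2/M <= alpha_c <= 2 up to Monte-Carlo tolerance.
    """
    pts = manifolds.points - manifolds.points.reshape(-1, manifolds.N).mean(0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3F7]))
    max_D1 = min(manifolds.M, manifolds.N) + 1
    t_draws = rng.standard_normal((n_gaussian_samples, max_D1))

    inv_caps, dims, radii = [], [], []
    for p in range(manifolds.P):
        center = pts[p].mean(axis=0)
        inv_cap, D_M, R_M = _manifold_mft(pts[p], center, t_draws)
        inv_caps.append(inv_cap)
        dims.append(D_M)
        radii.append(R_M)
    inv_caps = np.array(inv_caps)
    alpha = 1.0 / np.mean(inv_caps)
    per_alpha = 1.0 / np.maximum(inv_caps, 1e-12)
    return ManifoldGeometry(
        capacity_alpha_c=float(alpha),
        dimension_D_M=float(np.mean(dims)),
        radius_R_M=float(np.mean(radii)),
        per_manifold_alpha_c=per_alpha,
        per_manifold_D_M=np.array(dims),
        per_manifold_R_M=np.array(radii),
        n_gaussian_samples=n_gaussian_samples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Scalar geometry measures
# ---------------------------------------------------------------------------

def participation_ratio(activations: np.ndarray) -> float:
    """PR = (sum lambda)^2 / sum lambda^2 over covariance eigenvalues.

    1 when all variance sits in one feature; N when spread isotropically.
    """
    X = np.asarray(activations, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = X - X.mean(axis=0)
    s = np.linalg.svd(X, compute_uv=False)
    lam = s ** 2
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    return float(total ** 2 / np.sum(lam ** 2))


def center_correlation(manifolds: ManifoldSet) -> float:
    """Mean absolute Pearson correlation over all pairs of manifold centers
    (global mean subtracted)."""
    if manifolds.P < 2:
        raise ValueError("need P >= 2 manifolds")
    centers = manifolds.points.mean(axis=1)
    centers = centers - centers.mean(axis=0)
    sd = centers.std(axis=1)
    if np.any(sd <= 1e-15):
        raise ValueError("zero-variance center vector; correlation undefined")
    C = np.corrcoef(centers)
    iu = np.triu_indices(manifolds.P, k=1)
    return float(np.mean(np.abs(C[iu])))


def explained_variance_dims(activations: np.ndarray,
                            fraction: float = 0.9) -> int:
    """Smallest k whose top-k covariance eigenvalues reach ``fraction`` of
    total variance."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    X = np.asarray(activations, dtype=np.float64)
    X = X - X.mean(axis=0)
    lam = np.sort(np.linalg.svd(X, compute_uv=False) ** 2)[::-1]
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    return int(np.searchsorted(np.cumsum(lam) / total, fraction) + 1)


def layer_geometry_summary(manifolds: ManifoldSet,
                           n_gaussian_samples: int = 200, seed: int = 0,
                           with_simulation: bool = False,
                           n_dichotomies: int = 50) -> GeometrySummary:
    """All geometry measures of one layer's manifold set."""
    geo = meanfield_geometry(manifolds, n_gaussian_samples, seed)
    flat = manifolds.points.reshape(-1, manifolds.N)
    alpha_sim = None
    if with_simulation:
        alpha_sim = simulation_capacity(manifolds, n_dichotomies, seed).alpha_sim
    return GeometrySummary(
        layer_name=manifolds.layer_name,
        alpha_c=geo.capacity_alpha_c,
        D_M=geo.dimension_D_M,
        R_M=geo.radius_R_M,
        center_corr=center_correlation(manifolds),
        participation_ratio=participation_ratio(flat),
        ev_dims=explained_variance_dims(flat),
        alpha_sim=alpha_sim,
    )
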