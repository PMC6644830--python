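"""Wormlike-chain simulator, random labeling, and image-error model.

Generates ground-truth chromosome contours, places colored labels along
them, and corrupts the resulting 3D label positions with localization
error, missing labels, and nonspecific (extra) spots, recording the true
locus-to-spot mapping throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Conformation",
    "ErrorModel",
    "GroundTruth",
    "LocusTrack",
    "SpotField",
    "MISSING",
    "simulate_wlc",
    "simulate_wlc_batch",
    "place_labels",
    "render_image",
]

#: sentinel spot index for a locus with no detected spot
MISSING = -1


@dataclass(frozen=True)
class Conformation:
    """A discretized polymer contour.

    ``vertices`` are 3D points in nm; ``contour_positions`` gives the
    genomic coordinate (kb) of each vertex, strictly increasing.
    """

    vertices: np.ndarray            # (V, 3) nm
    contour_positions: np.ndarray   # (V,) kb

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        c = np.asarray(self.contour_positions, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] != c.shape[0]:
            raise ValueError("vertices must be (V, 3) aligned with contour_positions")
        if v.shape[0] < 2:
            raise ValueError("a conformation needs at least 2 vertices")
        if np.any(np.diff(c) <= 0):
            raise ValueError("contour_positions must be strictly increasing")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "contour_positions", c)

    @property
    def length_kb(self) -> float:
        return float(self.contour_positions[-1] - self.contour_positions[0])


@dataclass(frozen=True)
class LocusTrack:
    """Ordered labeled loci: genomic coordinate (kb) and color index per locus."""

    genomic_kb: np.ndarray  # (N,) strictly increasing
    colors: np.ndarray      # (N,) int in [0, n_colors)
    n_colors: int
    ids: tuple[str, ...] = ()

    def __post_init__(self):
        g = np.asarray(self.genomic_kb, dtype=float)
        c = np.asarray(self.colors, dtype=int)
        if g.ndim != 1 or g.shape != c.shape:
            raise ValueError("genomic_kb and colors must be 1-D and aligned")
        if g.size and np.any(np.diff(g) <= 0):
            raise ValueError("loci must be strictly increasing in genomic coordinate")
        if c.size and (c.min() < 0 or c.max() >= self.n_colors):
            raise ValueError("locus color outside palette")
        object.__setattr__(self, "genomic_kb", g)
        object.__setattr__(self, "colors", c)
        if not self.ids:
            object.__setattr__(self, "ids", tuple(f"L{i}" for i in range(g.size)))

    def __len__(self) -> int:
        return self.genomic_kb.size


@dataclass(frozen=True)
class SpotField:
    """Imaged spots: 3D positions (nm) and color index per spot."""

    xyz: np.ndarray     # (M, 3) nm
    colors: np.ndarray  # (M,) int
    n_colors: int
    ids: tuple[str, ...] = ()

    def __post_init__(self):
        x = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        c = np.asarray(self.colors, dtype=int)
        if x.shape[0] != c.shape[0]:
            raise ValueError("xyz and colors must be aligned")
        if not np.all(np.isfinite(x)):
            raise ValueError("spot coordinates must be finite")
        if c.size and (c.min() < 0 or c.max() >= self.n_colors):
            raise ValueError("spot color outside palette")
        object.__setattr__(self, "xyz", x)
        object.__setattr__(self, "colors", c)
        if not self.ids:
            object.__setattr__(self, "ids", tuple(f"s{i}" for i in range(x.shape[0])))

    def __len__(self) -> int:
        return self.colors.size


@dataclass(frozen=True)
class ErrorModel:
    """Imaging-error parameters: Gaussian localization sigmas and label-error rates."""

    sigma_xy: float = 100.0  # nm, per lateral axis
    sigma_z: float = 200.0   # nm
    p_fn: float = 0.1        # missing-label rate per locus
    p_extra: float = 0.1     # nonspecific-label rate per locus

    def __post_init__(self):
        if self.sigma_xy < 0 or self.sigma_z < 0:
            raise ValueError("localization sigmas must be >= 0")
        if not (0 <= self.p_fn < 1):
            raise ValueError("p_fn must be in [0, 1)")
        if self.p_extra < 0 or not np.isfinite(self.p_extra):
            raise ValueError("p_extra must be finite and >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True locus positions, locus->spot mapping, and extra-spot identities."""

    locus_positions: np.ndarray  # (N, 3) nm
    true_mapping: np.ndarray     # (N,) spot index or MISSING
    extra_spots: np.ndarray      # (E,) spot indices with no source locus

    def __post_init__(self):
        mapped = self.true_mapping[self.true_mapping != MISSING]
        if mapped.size != np.unique(mapped).size:
            raise ValueError("true mapping must be injective on spots")
        if np.intersect1d(mapped, self.extra_spots).size:
            raise ValueError("extra spots must be disjoint from mapped spots")


def _vmf_kappa(mean_cos: float) -> float:
    """Concentration of p(cos) ∝ exp(kappa cos) with the given mean cosine."""
    if mean_cos >= 1.0 - 1e-12:
        return np.inf
    if mean_cos <= 1e-12:
        return 0.0
    # <cos> = coth(kappa) - 1/kappa, monotone in kappa
    def f(k):
        return 1.0 / np.tanh(k) - 1.0 / k - mean_cos
    return brentq(f, 1e-8, 1e8)


def _sample_cos(kappa: float, u: np.ndarray) -> np.ndarray:
    if np.isinf(kappa):
        return np.ones_like(u)
    if kappa == 0.0:
        return 2.0 * u - 1.0
    # inverse CDF of exp(kappa c) on [-1, 1]
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def simulate_wlc_batch(
    n_l: float,
    l_p: float,
    total_length: float,
    step: float,
    n_chains: int,
    seed=None,
) -> np.ndarray:
    """Simulate many wormlike chains at once; returns vertices (n_chains, V, 3) nm.

    The chain is a sequence of fixed-length segments of spatial length
    ``step / n_l`` nm whose consecutive tangents satisfy
    ``<t_i . t_{i+1}> = exp(-step / l_p)`` (genomic persistence length
    ``l_p``, spatial persistence length ``l_p / n_l``).
    """
    if n_l <= 0 or l_p <= 0 or step <= 0:
        raise ValueError("n_l, l_p and step must be positive")
    if total_length < step:
        raise ValueError("total_length must be >= step")
    rng = np.random.default_rng(seed)
    n_seg = int(round(total_length / step))
    b = step / n_l  # segment length, nm
    kappa = _vmf_kappa(np.exp(-step / l_p))

    t = np.zeros((n_chains, 3))
    t[:, 2] = 1.0  # initial tangent along z
    verts = np.zeros((n_chains, n_seg + 1, 3))
    for i in range(n_seg):
        if i > 0:
            c = _sample_cos(kappa, rng.random(n_chains))
            phi = rng.uniform(0.0, 2.0 * np.pi, n_chains)
            s = np.sqrt(np.clip(1.0 - c * c, 0.0, None))
            # orthonormal frame around the current tangent
            ref = np.where(np.abs(t[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
            e1 = np.cross(t, ref)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(t, e1)
            t = (
                c[:, None] * t
                + (s * np.cos(phi))[:, None] * e1
                + (s * np.sin(phi))[:, None] * e2
            )
            t /= np.linalg.norm(t, axis=1, keepdims=True)
        verts[:, i + 1] = verts[:, i] + b * t
    return verts


def simulate_wlc(
    n_l: float,
    l_p: float,
    total_length: float,
    step: float,
    seed=None,
) -> Conformation:
    """Simulate one discrete wormlike chain; see :func:`simulate_wlc_batch`."""
    verts = simulate_wlc_batch(n_l, l_p, total_length, step, 1, seed)[0]
    n_seg = verts.shape[0] - 1
    contour = np.arange(n_seg + 1) * step
    return Conformation(verts, contour)


def place_labels(
    conf: Conformation,
    density: float,
    n_colors: int,
    seed=None,
) -> tuple[LocusTrack, np.ndarray]:
    """Place labels along the contour as a Poisson process.

    ``density`` is loci per Mb; positions are uniform along the genomic
    axis (count Poisson with the stated mean), colors uniform over the
    palette.  Returns the sorted track and the interpolated 3D positions.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if n_colors < 1:
        raise ValueError("need at least one color")
    rng = np.random.default_rng(seed)
    lo = float(conf.contour_positions[0])
    hi = float(conf.contour_positions[-1])
    mean = density * (hi - lo) / 1000.0  # density is per Mb, coords in kb
    n = rng.poisson(mean)
    pos = np.sort(rng.uniform(lo, hi, n))
    # strictly increasing coordinates (duplicates have measure zero, but be safe)
    pos = np.unique(pos)
    colors = rng.integers(0, n_colors, pos.size)
    track = LocusTrack(pos, colors, n_colors)
    xyz = np.column_stack(
        [np.interp(pos, conf.contour_positions, conf.vertices[:, k]) for k in range(3)]
    )
    return track, xyz


def render_image(
    locus_xyz: np.ndarray,
    locus_colors: np.ndarray,
    n_colors: int,
    err: ErrorModel,
    seed=None,
) -> tuple[SpotField, GroundTruth]:
    """Corrupt true label positions into an imaged spot field.

    Each locus is dropped with probability ``p_fn``; survivors become
    spots displaced by axis-wise Gaussian noise.  Extra spots
    (count ~ Binomial(N, p_extra)) get uniform colors and positions
    uniform in the bounding box of the labeled contour.
    """
    rng = np.random.default_rng(seed)
    locus_xyz = np.asarray(locus_xyz, dtype=float).reshape(-1, 3)
    locus_colors = np.asarray(locus_colors, dtype=int)
    n = locus_xyz.shape[0]

    detected = rng.random(n) >= err.p_fn
    n_det = int(detected.sum())
    noise = np.column_stack(
        [
            rng.normal(0.0, err.sigma_xy, n_det),
            rng.normal(0.0, err.sigma_xy, n_det),
            rng.normal(0.0, err.sigma_z, n_det),
        ]
    )
    spot_xyz = locus_xyz[detected] + noise
    spot_colors = locus_colors[detected]

    if err.p_extra <= 1.0:
        n_extra = int(rng.binomial(n, err.p_extra)) if n else 0
    else:  # rate > 1 per label: split into <=1 sub-rates
        parts = int(np.ceil(err.p_extra))
        n_extra = int(rng.binomial(n * parts, err.p_extra / parts)) if n else 0
    if n:
        lo, hi = locus_xyz.min(axis=0), locus_xyz.max(axis=0)
    else:
        lo, hi = np.zeros(3), np.ones(3)
    extra_xyz = rng.uniform(lo, hi, (n_extra, 3))
    extra_colors = rng.integers(0, n_colors, n_extra)

    m = n_det + n_extra
    xyz = np.vstack([spot_xyz, extra_xyz]) if m else np.zeros((0, 3))
    colors = np.concatenate([spot_colors, extra_colors]).astype(int)

    # shuffle spot order so spot index carries no information
    perm = rng.permutation(m)          # final position j holds stacked spot perm[j]
    inv = np.empty(m, dtype=int)
    inv[perm] = np.arange(m)           # stacked spot k lands at final position inv[k]
    field = SpotField(xyz[perm], colors[perm], n_colors)

    mapping = np.full(n, MISSING, dtype=int)
    mapping[detected] = inv[:n_det]
    truth = GroundTruth(locus_xyz, mapping, inv[n_det:].copy())
    return field, truth
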