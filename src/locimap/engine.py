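"""Baseline and constrained partition-function terms via layer-skipping DP.

Each locus is a DP layer; transitions connect consecutive *mapped* loci,
skipping runs of missing loci by propagating over the summed genomic gap
and paying one missing penalty per skipped locus.  Consecutive mapped loci
may not occupy the same spot.  Constrained terms force given loci onto a
given spot; two exclusion conventions control whether unconstrained loci
may still use constrained spots.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import _kernels
from .dna_model import DnaModelParams, rms_distance
from .polymer import LocusTrack, SpotField

__all__ = [
    "IllegalConstraint",
    "MappingTable",
    "PartitionEstimate",
    "ProblemSpec",
    "baseline_uncertainty",
    "default_penalties",
    "evaluate_term",
    "mapping_probabilities",
    "missing_rate_targets",
]

#: exclusion conventions for constrained terms
SERIES1 = "series1"
SERIES2 = "series2"

#: pruning cutoff (nats below the realized layer maximum) for the skip DP;
#: set near the float64 underflow range so pruning only drops mass that
#: would underflow anyway, while still short-circuiting deep missing-skips
DP_THRESHOLD = 700.0


@dataclass(frozen=True)
class IllegalConstraint:
    """A forced overlap: >= 2 pairwise non-adjacent loci on a single spot."""

    loci: tuple[int, ...]
    spot: int

    def __post_init__(self):
        loci = tuple(sorted(int(l) for l in self.loci))
        object.__setattr__(self, "loci", loci)
        if len(loci) < 2:
            raise ValueError("an illegal constraint needs >= 2 loci")
        if len(set(loci)) != len(loci):
            raise ValueError("constraint loci must be distinct")
        if any(b - a == 1 for a, b in zip(loci, loci[1:])):
            raise ValueError("constraint loci must be pairwise non-adjacent")

    @property
    def order(self) -> int:
        return len(self.loci)


@dataclass
class MappingTable:
    """N x (M+1) probability table; the last column is the missing outcome."""

    probs: np.ndarray  # (N, M+1)

    @property
    def n_loci(self) -> int:
        return self.probs.shape[0]

    @property
    def n_spots(self) -> int:
        return self.probs.shape[1] - 1

    @property
    def mapped(self) -> np.ndarray:
        return self.probs[:, :-1]

    @property
    def missing(self) -> np.ndarray:
        return self.probs[:, -1]

    def row_sums(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def spot_totals(self) -> np.ndarray:
        """P(s) = sum_L p(L -> s), total mapped probability per spot."""
        return self.mapped.sum(axis=0)


@dataclass
class PartitionEstimate:
    """Log partition values: total, per (locus, spot), and per-locus missing."""

    log_Z: float
    log_Z_map: np.ndarray   # (N, M), -inf where zero
    log_Z_miss: np.ndarray  # (N,)
    log_Z_backward: float = np.nan  # cross-check from the reverse pass


@dataclass
class ProblemSpec:
    """A mapping problem: loci, spots, DNA model, penalties, error targets."""

    loci: LocusTrack
    spots: SpotField
    model: DnaModelParams
    penalties: "object | None" = None   # PenaltySet; default built lazily
    p_fn_targets: np.ndarray | None = None  # per-color missing-rate targets
    #: longest run of consecutive missing loci the DP will bridge; runs
    #: beyond it are dropped (negligible at ~0.1 missing odds per skip)
    max_skip_window: int = 64

    def __post_init__(self):
        if len(self.loci) < 1:
            raise ValueError("need at least one locus")
        if self.loci.n_colors != self.spots.n_colors:
            raise ValueError("loci and spots must share one color palette")
        if self.p_fn_targets is None:
            self.p_fn_targets = np.full(self.loci.n_colors, 0.1)
        self.p_fn_targets = np.asarray(self.p_fn_targets, dtype=float)
        if self.penalties is None:
            self.penalties = default_penalties(self)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @cached_property
    def _ws(self) -> "_Workspace":
        return _Workspace(self)


class _Workspace:
    """Precomputed candidate structure and propagator cache shared by all terms.

    The cache stores, for every locus pair inside the skip window, the
    matrix of Gaussian-chain factors between their candidate spots, so
    that optimizer iterations and series terms (which change only the
    penalties) re-run the DP without touching the model.
    """

    def __init__(self, spec: ProblemSpec):
        loci, spots = spec.loci, spec.spots
        n, m = len(loci), len(spots)
        self.coords = np.ascontiguousarray(loci.genomic_kb, dtype=float)
        by_color = [np.flatnonzero(spots.colors == c) for c in range(spots.n_colors)]
        cand_lists = [by_color[c] for c in loci.colors]
        self.off = np.zeros(n + 1, dtype=np.int64)
        self.off[1:] = np.cumsum([len(c) for c in cand_lists])
        self.cand = (
            np.concatenate(cand_lists).astype(np.int64)
            if self.off[-1]
            else np.zeros(0, dtype=np.int64)
        )
        d = spots.xyz[:, None, :] - spots.xyz[None, :, :]
        self.D2 = np.ascontiguousarray(np.einsum("ijk,ijk->ij", d, d))
        # flat position of spot s in locus i's candidate list (-1 if absent)
        self.flat_pos = np.full((n, m), -1, dtype=np.int64)
        for i in range(n):
            sl = self.cand[self.off[i] : self.off[i + 1]]
            self.flat_pos[i, sl] = np.arange(self.off[i], self.off[i + 1])
        # flat positions per spot, across all loci
        self.spot_flat = [np.flatnonzero(self.cand == s) for s in range(m)]

        # propagator cache over the skip window
        w = min(n - 1, spec.max_skip_window) if n > 1 else 0
        self.window = w
        self.win_lo = np.maximum(np.arange(n) - w, 0).astype(np.int64)
        self.pc_off = np.full((n, max(w, 1)), -1, dtype=np.int64)
        self.pc_logc = np.full((n, max(w, 1)), -np.inf)
        blocks = []
        pos = 0
        for i in range(n):
            ci = cand_lists[i]
            for j in range(int(self.win_lo[i]), i):
                gap = self.coords[i] - self.coords[j]
                R = rms_distance(gap, spec.model)
                a = 1.5 / (R * R)
                self.pc_logc[i, i - 1 - j] = 1.5 * np.log(a / np.pi)
                block = np.exp(-a * self.D2[np.ix_(ci, cand_lists[j])])
                self.pc_off[i, i - 1 - j] = pos
                pos += block.size
                blocks.append(block.ravel())
        self.pc_val = (
            np.ascontiguousarray(np.concatenate(blocks))
            if blocks
            else np.zeros(0)
        )


def default_penalties(spec: ProblemSpec):
    """Unit spot penalties and density-matched initial missing penalties.

    The missing penalty per color is set to (target missing odds) times a
    typical propagator density so that mapped and missing outcomes start
    on a comparable scale; the optimizer then converges it properly.
    """
    from .penalties import PenaltySet

    g = spec.loci.genomic_kb
    mean_gap = float(np.mean(np.diff(g))) if len(g) > 1 else 1000.0
    R = max(rms_distance(max(mean_gap, 1e-9), spec.model), 1e-9)
    sigma_typ = (3.0 / (2.0 * np.pi * R * R)) ** 1.5
    odds = spec.p_fn_targets / (1.0 - spec.p_fn_targets)
    return PenaltySet(
        q=np.ones(spec.n_spots),
        q_miss=np.maximum(odds * sigma_typ, 1e-300),
    )


def missing_rate_targets(
    loci: LocusTrack,
    spots: SpotField,
    p_extra: float,
    eps: float = 1e-3,
) -> np.ndarray:
    """Per-color missing-rate targets from realized spot counts.

    Uses the global extra-spot rate to estimate how many spots of each
    color are nonspecific: ``p_fn(c) = 1 - (M_c - E[extra_c]) / N_c``
    clipped to (eps, 1-eps), with ``E[extra_c] = N * p_extra / n_colors``.
    """
    k = loci.n_colors
    n_c = np.bincount(loci.colors, minlength=k).astype(float)
    m_c = np.bincount(spots.colors, minlength=k).astype(float)
    e_extra = len(loci) * p_extra / k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = 1.0 - (m_c - e_extra) / np.where(n_c > 0, n_c, 1.0)
    t[n_c == 0] = 0.5
    return np.clip(t, eps, 1.0 - eps)


def _term_arrays(spec: ProblemSpec, constraints, exclusion_mode: str):
    """Build (logqm, logq) for a constrained term; None if the term is zero."""
    from .penalties import PenaltySet  # noqa: F401  (duck-typed)

    ws = spec._ws
    pen = spec.penalties
    logq = np.take(pen.log_q, ws.cand) if ws.cand.size else np.zeros(0)
    logqm = pen.log_q_miss[spec.loci.colors].astype(float).copy()

    if constraints:
        seen_loci: set[int] = set()
        seen_spots: set[int] = set()
        for con in constraints:
            if seen_loci.intersection(con.loci) or con.spot in seen_spots:
                return None, None  # overlapping constraints: term is zero
            seen_loci.update(con.loci)
            seen_spots.add(con.spot)
        if exclusion_mode == SERIES1:
            for con in constraints:
                logq[ws.spot_flat[con.spot]] = -np.inf
        for con in constraints:
            for l in con.loci:
                pos = ws.flat_pos[l, con.spot]
                if pos < 0:
                    return None, None  # color mismatch: no such conformation
                lo, hi = ws.off[l], ws.off[l + 1]
                logq[lo:hi] = -np.inf
                logq[pos] = pen.log_q[con.spot]
                logqm[l] = -np.inf
    return logqm, logq


def evaluate_term_raw(
    spec: ProblemSpec,
    constraints=(),
    exclusion_mode: str = SERIES2,
    threshold: float = DP_THRESHOLD,
):
    """Run the DP for one term; returns (log_Zf, log_Zb, flat log_Z_map) or None."""
    if exclusion_mode not in (SERIES1, SERIES2):
        raise ValueError(f"unknown exclusion mode {exclusion_mode!r}")
    logqm, logq = _term_arrays(spec, tuple(constraints), exclusion_mode)
    if logqm is None:
        return None
    ws = spec._ws
    return _kernels.dp_engine(
        logqm,
        ws.off,
        ws.cand,
        logq,
        ws.win_lo,
        ws.pc_off,
        ws.pc_val,
        ws.pc_logc,
        threshold,
    )


def _dense_from_flat(spec: ProblemSpec, flat: np.ndarray) -> np.ndarray:
    ws = spec._ws
    dense = np.full((spec.n_loci, spec.n_spots), -np.inf)
    for i in range(spec.n_loci):
        sl = ws.cand[ws.off[i] : ws.off[i + 1]]
        dense[i, sl] = flat[ws.off[i] : ws.off[i + 1]]
    return dense


def _miss_by_subtraction(log_z: float, log_z_map: np.ndarray) -> np.ndarray:
    """log Z_{L->miss} = log(Z - sum_s Z_{L->s}), clipped at zero."""
    with np.errstate(invalid="ignore"):
        mapped_frac = np.exp(log_z_map - log_z)
    mapped_frac[~np.isfinite(mapped_frac)] = 0.0
    miss_frac = np.clip(1.0 - mapped_frac.sum(axis=1), 0.0, None)
    with np.errstate(divide="ignore"):
        return log_z + np.log(miss_frac)


def evaluate_term(
    spec: ProblemSpec,
    constraints=(),
    exclusion_mode: str = SERIES2,
    threshold: float = DP_THRESHOLD,
) -> PartitionEstimate:
    """Evaluate one (possibly constrained) partition-function term.

    With no constraints this is the baseline term counting all
    conformations in which consecutive mapped loci occupy distinct spots.
    Overlapping constraints yield an identically-zero term (-inf logs).
    """
    out = evaluate_term_raw(spec, constraints, exclusion_mode, threshold)
    n, m = spec.n_loci, spec.n_spots
    if out is None:
        return PartitionEstimate(
            -np.inf, np.full((n, m), -np.inf), np.full(n, -np.inf), -np.inf
        )
    log_zf, log_zb, flat = out
    dense = _dense_from_flat(spec, flat)
    if np.isneginf(log_zf):
        return PartitionEstimate(-np.inf, dense, np.full(n, -np.inf), log_zb)
    return PartitionEstimate(log_zf, dense, _miss_by_subtraction(log_zf, dense), log_zb)


def mapping_probabilities(estimate: PartitionEstimate) -> MappingTable:
    """Normalize partition terms into mapping probabilities.

    ``p(L->s) = Z_{L->s} / Z`` with the missing outcome in the last
    column; rows sum to 1 and color-mismatched entries are exactly zero.
    """
    if not np.isfinite(estimate.log_Z):
        raise ValueError("total partition value is not finite; no legal conformation")
    with np.errstate(invalid="ignore"):
        pm = np.exp(estimate.log_Z_map - estimate.log_Z)
        pmiss = np.exp(estimate.log_Z_miss - estimate.log_Z)
    pm[~np.isfinite(pm)] = 0.0
    pmiss[~np.isfinite(pmiss)] = 0.0
    probs = np.column_stack([pm, pmiss])
    rows = probs.sum(axis=1)
    bad = np.abs(rows - 1.0) > 1e-6
    if np.any(bad):
        raise ValueError(
            f"{bad.sum()} mapping rows do not normalize (worst sum "
            f"{rows[bad].max():.6g}); term-selection rule violated?"
        )
    return MappingTable(probs)


def baseline_uncertainty(spec: ProblemSpec) -> float:
    """Bits/locus of the color-only uniform table (inherent uncertainty).

    Each locus is assigned uniform probability over its same-color spots
    plus the missing outcome, so the unrecovered information is
    ``mean log2(M_c + 1)``.
    """
    m_c = np.bincount(spec.spots.colors, minlength=spec.loci.n_colors)
    return float(np.mean(np.log2(m_c[spec.loci.colors] + 1.0)))


def color_uniform_table(spec: ProblemSpec) -> MappingTable:
    """The color-only uniform mapping table used as the uncertainty reference."""
    n, m = spec.n_loci, spec.n_spots
    probs = np.zeros((n, m + 1))
    for i in range(n):
        same = spec.spots.colors == spec.loci.colors[i]
        probs[i, :-1][same] = 1.0 / (same.sum() + 1.0)
        probs[i, -1] = 1.0 / (same.sum() + 1.0)
    return MappingTable(probs)
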