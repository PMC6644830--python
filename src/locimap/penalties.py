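"""Iterative spot-penalty and missing-penalty optimization.

Multiplicative fixed-point updates drive the mapping table toward the two
published contracts: per-color missing rates equal to their targets, and
total per-spot mapped probability ``P(s) <= 1``.  A steepest-descent
polish (approximate gradient, backtracking line search) finishes the job
when the multiplicative phase plateaus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import engine

__all__ = [
    "NormalizationState",
    "OptimizeResult",
    "OptimizerSettings",
    "PenaltySet",
    "cost_function",
    "normalization_state",
    "optimize",
    "update_missing_penalties",
    "update_spot_penalties",
]

CLAMP_LO, CLAMP_HI = 1e-300, 1e300


@dataclass(frozen=True)
class PenaltySet:
    """Strictly positive multiplicative penalties: per-spot q and per-color q-."""

    q: np.ndarray       # (M,)
    q_miss: np.ndarray  # (n_colors,)

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        qm = np.asarray(self.q_miss, dtype=float)
        if np.any(q <= 0) or np.any(~np.isfinite(q)):
            raise ValueError("spot penalties must be strictly positive and finite")
        if np.any(qm <= 0) or np.any(~np.isfinite(qm)):
            raise ValueError("missing penalties must be strictly positive and finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "q_miss", qm)

    @property
    def log_q(self) -> np.ndarray:
        return np.log(self.q)

    @property
    def log_q_miss(self) -> np.ndarray:
        return np.log(self.q_miss)


@dataclass
class NormalizationState:
    """Spot totals P(s) and realized per-color missing fractions of a table."""

    spot_totals: np.ndarray       # (M,)
    missing_fraction: np.ndarray  # (n_colors,)
    mapped_fraction: np.ndarray   # (n_colors,) = 1 - missing_fraction
    n_loci: int
    n_loci_per_color: np.ndarray


def normalization_state(table: engine.MappingTable, spec: engine.ProblemSpec) -> NormalizationState:
    colors = spec.loci.colors
    k = spec.loci.n_colors
    n_c = np.bincount(colors, minlength=k).astype(float)
    miss = np.zeros(k)
    for c in range(k):
        sel = colors == c
        miss[c] = table.missing[sel].mean() if sel.any() else 0.0
    return NormalizationState(
        spot_totals=table.spot_totals(),
        missing_fraction=miss,
        mapped_fraction=1.0 - miss,
        n_loci=spec.n_loci,
        n_loci_per_color=n_c,
    )


def _odds(x: np.ndarray) -> np.ndarray:
    """(1 - x) / x with safe handling of the 0 and 1 endpoints."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(x > 0, (1.0 - x) / np.maximum(x, 1e-300), np.inf)


def update_missing_penalties(
    state: NormalizationState,
    p_fn_targets: np.ndarray,
    penalties: PenaltySet,
    gamma: float = 1.0,
    max_factor: float = 1e3,
) -> PenaltySet:
    """Multiplicative q- update toward the per-color missing-rate targets.

    ``q-' = q- * [1/(1-p_fn) - 1] / [1/m_c - 1]`` where ``m_c`` is the
    per-color mean mapped probability; the realized missing fraction
    equals the target at the fixed point.
    """
    m = state.mapped_fraction
    empty = state.n_loci_per_color == 0
    target_miss_odds = p_fn_targets / (1.0 - p_fn_targets)
    cur_miss_odds = _odds(m)  # (1 - m) / m
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = target_miss_odds / cur_miss_odds
    degenerate = (~np.isfinite(factor) | (factor <= 0) | (m <= 0) | (m >= 1)) & ~empty
    if np.any(degenerate):
        warnings.warn(
            "degenerate per-color mapped fraction; damping missing-penalty update",
            stacklevel=2,
        )
        factor = np.where(degenerate, np.where(m <= 0, max_factor, 1.0 / max_factor), factor)
    factor = np.where(empty, 1.0, np.clip(factor, 1.0 / max_factor, max_factor)) ** gamma
    return replace(penalties, q_miss=np.clip(penalties.q_miss * factor, CLAMP_LO, CLAMP_HI))


def update_spot_penalties(
    state: NormalizationState,
    p_fn_targets: np.ndarray,
    penalties: PenaltySet,
    spot_colors: np.ndarray,
    gamma: float = 1.0,
    max_factor: float = 1e3,
    maintain_missing: bool = True,
) -> PenaltySet:
    """Multiplicative per-spot q update.

    Two factors: a per-color factor maintaining the missing rate (the
    reverse of the q- update; disabled with ``maintain_missing=False``,
    in which case the missing rate is held by separate q- steps) and a
    per-spot factor driving ``P(s)`` toward ``min(1, P(s))`` so
    overloaded spots are penalized.
    """
    n = float(state.n_loci)
    # factor A: reverse missing-rate update, per color of the spot
    if maintain_missing:
        m = state.mapped_fraction
        target_miss_odds = p_fn_targets / (1.0 - p_fn_targets)
        with np.errstate(divide="ignore", invalid="ignore"):
            fa_color = _odds(m) / target_miss_odds
        fa_color = np.where(np.isfinite(fa_color) & (fa_color > 0), fa_color, 1.0)
        fa_color[state.n_loci_per_color == 0] = 1.0
        fa = fa_color[spot_colors]
    else:
        fa = 1.0
    # factor B: normalization, P(s) -> min(1, P(s))
    P = state.spot_totals
    x = P / n
    xs = np.minimum(1.0, P) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        fb = (1.0 / np.maximum(x, 1e-300) - 1.0) / (1.0 / np.maximum(xs, 1e-300) - 1.0)
    fb = np.where((P > 0) & np.isfinite(fb) & (fb > 0), fb, 1.0)
    factor = np.clip(fa * fb, 1.0 / max_factor, max_factor) ** gamma
    return replace(penalties, q=np.clip(penalties.q * factor, CLAMP_LO, CLAMP_HI))


def cost_function(state: NormalizationState, p_fn_targets: np.ndarray) -> float:
    """Sum of squared P(s) > 1 violations plus squared missing-rate mismatch."""
    over = np.clip(state.spot_totals - 1.0, 0.0, None)
    miss_err = state.missing_fraction - p_fn_targets
    weights = state.n_loci_per_color > 0
    return float(np.sum(over**2) + np.sum((miss_err * weights) ** 2))


def _missing_cost(state: NormalizationState, p_fn_targets: np.ndarray) -> float:
    weights = state.n_loci_per_color > 0
    return float(np.sum(((state.missing_fraction - p_fn_targets) * weights) ** 2))


@dataclass
class OptimizerSettings:
    max_iter_missing: int = 40
    cycles: int = 6                 # alternations of (q phase, q- maintenance)
    max_iter_spot: int = 50         # q iterations per cycle
    max_iter_polish: int = 30
    gamma_missing: float = 0.8
    gamma_spot: float = 0.7
    step_cap_init: float = 2.0      # nats; per-iteration q- step in phase 1
    step_cap_cycle: float = 0.5     # nats; q- maintenance step between cycles
    cost_tol: float = 1e-12
    rel_tol: float = 1e-6
    rel_tol_window: int = 5
    missing_tol: float = 1e-4
    #: colors whose missing rate barely responds to q- get their target
    #: frozen at the realized rate (unattainable-target guard)
    saturation_slope: float = 0.02
    polish: bool = True


@dataclass
class OptimizeResult:
    penalties: PenaltySet
    table: engine.MappingTable
    estimate: engine.PartitionEstimate
    trace: list = field(default_factory=list)  # (phase, iteration, cost, maxP, miss_err)
    converged: bool = False
    n_iterations: int = 0


def _approx_gradient(table, spec, p_fn_targets):
    """Gradient of the cost in (log q, log q-) under row-softmax independence."""
    p = table.mapped  # (N, M)
    pm = table.missing  # (N,)
    colors = spec.loci.colors
    k = spec.loci.n_colors
    n_c = np.maximum(np.bincount(colors, minlength=k).astype(float), 1.0)
    P = table.spot_totals()
    v = np.clip(P - 1.0, 0.0, None)
    w = np.zeros(k)
    for c in range(k):
        sel = colors == c
        w[c] = pm[sel].mean() - p_fn_targets[c] if sel.any() else 0.0

    A = p.T @ p  # sum_L p_Ls p_Lt
    g_q = 2.0 * (v * P - A @ v)
    # missing-rate part wrt log q
    wc_per_locus = (w / n_c)[colors]
    g_q += 2.0 * (-(p * (pm * wc_per_locus)[:, None]).sum(axis=0))
    # wrt log q-
    g_qm = np.zeros(k)
    for c in range(k):
        sel = colors == c
        if not sel.any():
            continue
        g_qm[c] = 2.0 * w[c] / n_c[c] * np.sum(pm[sel] * (1.0 - pm[sel]))
        g_qm[c] += 2.0 * np.sum(v * (-(p[sel] * pm[sel, None]).sum(axis=0)))
    return g_q, g_qm


def optimize(
    spec: engine.ProblemSpec,
    series_terms=None,
    exclusion_mode: str = engine.SERIES2,
    settings: OptimizerSettings | None = None,
) -> OptimizeResult:
    """Penalty optimization: q- phase, alternating q phases, then polish.

    Phase 1 converges the per-color missing penalties with damped,
    step-capped multiplicative updates; colors whose realized rate stops
    responding (unattainable target) are frozen at their realized rate.
    Then several cycles alternate a block of per-spot normalization
    updates with one gentle q- maintenance step, which reaches the joint
    fixed point without the oscillation that simultaneous updates cause.
    A steepest-descent polish (approximate gradient, backtracking line
    search on the true cost) finishes.  When ``series_terms`` is given,
    every evaluation re-computes the full weighted series with the
    current penalties (penalties-on-series mode).

    The returned state is the best-cost iterate encountered.
    """
    settings = settings or OptimizerSettings()
    pen: PenaltySet = spec.penalties
    targets = spec.p_fn_targets
    spot_colors = spec.spots.colors
    k = spec.loci.n_colors
    has_loci = np.bincount(spec.loci.colors, minlength=k) > 0
    trace: list = []
    n_eval = 0

    def evaluate(p: PenaltySet):
        nonlocal n_eval
        n_eval += 1
        work = replace_penalties(spec, p)
        if series_terms is None:
            est = engine.evaluate_term(work, (), exclusion_mode)
        else:
            from .series import evaluate_series

            est = evaluate_series(work, series_terms, exclusion_mode).estimate
        table = engine.mapping_probabilities(est)
        return est, table, normalization_state(table, spec)

    def record(phase, it, cost, state):
        trace.append((phase, it, cost,
                      float(state.spot_totals.max(initial=0.0)),
                      float(np.abs(state.missing_fraction - targets)[has_loci]
                            .max(initial=0.0))))

    est, table, state = evaluate(pen)

    # ---- phase 1: missing penalties ----
    saturated = np.zeros(k, dtype=bool)
    cap1 = float(np.exp(settings.step_cap_init))
    record("q_miss", 0, _missing_cost(state, targets), state)
    prev_logqm = prev_logit = None
    for it in range(settings.max_iter_missing):
        err = np.abs(state.missing_fraction - targets)[has_loci & ~saturated]
        if err.max(initial=0.0) < settings.missing_tol:
            break
        cand = update_missing_penalties(state, targets, pen,
                                        settings.gamma_missing, cap1)
        qm_frozen = np.where(saturated, pen.q_miss, cand.q_miss)
        cand = replace(cand, q_miss=qm_frozen)
        est, table, state = evaluate(cand)
        # saturation: large q- moves with no realized-rate response
        miss = np.clip(state.missing_fraction, 1e-12, 1.0 - 1e-12)
        logit = np.log(miss) - np.log1p(-miss)
        logqm = np.log(cand.q_miss)
        if prev_logqm is not None:
            d = logqm - prev_logqm
            big = np.abs(d) > 0.5
            with np.errstate(divide="ignore", invalid="ignore"):
                slope = np.where(big, (logit - prev_logit) / np.where(big, d, 1.0), 1.0)
            saturated |= big & (np.abs(slope) < settings.saturation_slope) & (
                np.abs(state.missing_fraction - targets) > 10 * settings.missing_tol
            )
        prev_logqm, prev_logit = logqm, logit
        pen = cand
        record("q_miss", it + 1, _missing_cost(state, targets), state)

    # unattainable targets are frozen at the realized rate for the q phase
    eff_targets = np.where(saturated, np.clip(state.missing_fraction, 1e-6, 1 - 1e-6),
                           targets)

    # ---- alternating q / q- cycles ----
    cap2 = float(np.exp(settings.step_cap_cycle))
    cost = cost_function(state, eff_targets)
    best = (cost, pen, est, table, state)
    for cycle in range(settings.cycles):
        history = [cost]
        for it in range(settings.max_iter_spot):
            if cost < settings.cost_tol:
                break
            # q- held fixed inside the block: pass realized rates as targets
            pen = update_spot_penalties(state, targets, pen, spot_colors,
                                        settings.gamma_spot,
                                        maintain_missing=False)
            est, table, state = evaluate(pen)
            cost = cost_function(state, eff_targets)
            if cost < best[0]:
                best = (cost, pen, est, table, state)
            history.append(cost)
            record("q", it + 1, cost, state)
            if (
                len(history) > settings.rel_tol_window
                and history[-settings.rel_tol_window - 1] - cost
                <= settings.rel_tol * max(cost, 1e-300)
            ):
                break
        if cost < settings.cost_tol:
            break
        for it in range(settings.max_iter_missing // 2):
            err = np.abs(state.missing_fraction - eff_targets)[has_loci]
            if err.max(initial=0.0) < settings.missing_tol:
                break
            pen = update_missing_penalties(state, eff_targets, pen,
                                           settings.gamma_missing, cap2)
            est, table, state = evaluate(pen)
            cost = cost_function(state, eff_targets)
            if cost < best[0]:
                best = (cost, pen, est, table, state)
            record("q_miss_maintain", it, cost, state)
        max_p_now = float(state.spot_totals.max(initial=0.0))
        miss_now = float(
            np.abs(state.missing_fraction - eff_targets)[has_loci].max(initial=0.0)
        )
        if max_p_now <= 1.0 + 5e-4 and miss_now <= settings.missing_tol:
            best = (cost, pen, est, table, state)
            break

    cost, pen, est, table, state = best

    # ---- steepest-descent polish ----
    if settings.polish and cost > settings.cost_tol:
        step = 0.25
        for it in range(settings.max_iter_polish):
            g_q, g_qm = _approx_gradient(table, spec, eff_targets)
            gnorm = np.sqrt(np.sum(g_q**2) + np.sum(g_qm**2))
            if gnorm < 1e-14:
                break
            improved = False
            while step > 1e-6:
                cand = PenaltySet(
                    q=np.clip(pen.q * np.exp(-step * g_q / gnorm), CLAMP_LO, CLAMP_HI),
                    q_miss=np.clip(
                        pen.q_miss * np.exp(-step * g_qm / gnorm), CLAMP_LO, CLAMP_HI
                    ),
                )
                est2, table2, state2 = evaluate(cand)
                c2 = cost_function(state2, eff_targets)
                if c2 < cost:
                    pen, est, table, state, cost = cand, est2, table2, state2, c2
                    step *= 1.5
                    improved = True
                    break
                step *= 0.5
            record("polish", it + 1, cost, state)
            if not improved or cost < settings.cost_tol:
                break

    max_p = float(state.spot_totals.max(initial=0.0))
    miss_err = float(
        np.abs(state.missing_fraction - targets)[has_loci].max(initial=0.0)
    )
    at_clamp = bool(
        np.any(pen.q <= CLAMP_LO * 10) or np.any(pen.q >= CLAMP_HI / 10)
        or np.any(pen.q_miss <= CLAMP_LO * 10) or np.any(pen.q_miss >= CLAMP_HI / 10)
    )
    converged = (max_p <= 1.0 + 1e-3) and (miss_err <= 1e-3) and not at_clamp
    return OptimizeResult(pen, table, est, trace, converged, n_eval)


def replace_penalties(spec: engine.ProblemSpec, pen: PenaltySet) -> engine.ProblemSpec:
    """A cheap view of ``spec`` with different penalties (shares the workspace)."""
    new = engine.ProblemSpec.__new__(engine.ProblemSpec)
    new.loci = spec.loci
    new.spots = spec.spots
    new.model = spec.model
    new.penalties = pen
    new.p_fn_targets = spec.p_fn_targets
    new.max_skip_window = spec.max_skip_window
    new.__dict__["_ws"] = spec._ws
    return new
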