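"""Series expansions correcting the baseline term toward the exact partition.

Each term forces a set of disjoint illegal constraints (>= 2 non-adjacent
same-color loci overlapping at one spot) and enters the sum with a signed
integer weight chosen so that every overlapping conformation cancels.
Two conventions exist: expansion 1 forbids unconstrained loci from using
constrained spots (weights ``(-1)^n_phi``), expansion 2 allows it
(weights ``prod_k (-1)^(n_k - 1) (n_k - 1)``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .engine import SERIES1, SERIES2, IllegalConstraint, PartitionEstimate, ProblemSpec

__all__ = [
    "SeriesResult",
    "SeriesTerm",
    "TermSelection",
    "enumerate_constraints",
    "evaluate_series",
    "select_terms",
    "select_terms_by_count",
    "term_weight",
]


@dataclass(frozen=True)
class SeriesTerm:
    """A set of disjoint illegal constraints with its signed series weight."""

    constraints: tuple[IllegalConstraint, ...]

    def __post_init__(self):
        object.__setattr__(
            self,
            "constraints",
            tuple(sorted(self.constraints, key=lambda c: (c.loci, c.spot))),
        )

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)

    @property
    def orders(self) -> tuple[int, ...]:
        return tuple(c.order for c in self.constraints)

    def is_disjoint(self) -> bool:
        loci = [l for c in self.constraints for l in c.loci]
        spots = [c.spot for c in self.constraints]
        return len(set(loci)) == len(loci) and len(set(spots)) == len(spots)


def term_weight(term: SeriesTerm, mode: str) -> int:
    """Signed series weight of a term; the empty term always has weight +1."""
    if mode == SERIES1:
        return (-1) ** term.n_constraints
    if mode == SERIES2:
        w = 1
        for nk in term.orders:
            w *= (-1) ** (nk - 1) * (nk - 1)
        return w
    raise ValueError(f"unknown series mode {mode!r}")


@dataclass
class TermSelection:
    """Outcome of term selection for one series mode."""

    mode: str
    n_psi: int
    #: series 1: selected constraints; series 2: selected (locus, spot) mappings
    psi: tuple = ()
    terms: list[SeriesTerm] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.terms)


def _non_adjacent_subsets(loci, max_order=None):
    """All subsets of >= 2 pairwise non-adjacent locus indices."""
    loci = sorted(loci)
    top = len(loci) if max_order is None else min(max_order, len(loci))
    for r in range(2, top + 1):
        for combo in itertools.combinations(loci, r):
            if all(b - a > 1 for a, b in zip(combo, combo[1:])):
                yield combo


def enumerate_constraints(spec: ProblemSpec, max_order=None):
    """The full constraint set: every same-color non-adjacent overlap choice."""
    out = []
    for s in range(spec.n_spots):
        c = spec.spots.colors[s]
        loci = np.flatnonzero(spec.loci.colors == c)
        for combo in _non_adjacent_subsets(loci.tolist(), max_order):
            out.append(IllegalConstraint(combo, s))
    return out


def _disjoint_subsets(constraints, cap):
    """All pairwise-disjoint subsets of a constraint list (including the empty one)."""
    terms = [()]
    spots = [c.spot for c in constraints]
    locisets = [set(c.loci) for c in constraints]

    def rec(start, chosen_idx):
        if len(terms) > cap:
            raise RuntimeError(
                f"series term enumeration exceeded cap of {cap} terms"
            )
        for i in range(start, len(constraints)):
            ok = True
            for j in chosen_idx:
                if spots[j] == spots[i] or (locisets[j] & locisets[i]):
                    ok = False
                    break
            if ok:
                terms.append(tuple(constraints[k] for k in chosen_idx + [i]))
                rec(i + 1, chosen_idx + [i])

    rec(0, [])
    return [SeriesTerm(t) for t in terms]


def _constraint_score(con: IllegalConstraint, logp: np.ndarray) -> float:
    """Log product of baseline mapping probabilities over the constraint."""
    return float(sum(logp[l, con.spot] for l in con.loci))


def select_terms(
    table: engine.MappingTable,
    spec: ProblemSpec,
    mode: str,
    n_psi: int,
    max_order=None,
    term_cap: int = 200_000,
) -> TermSelection:
    """Choose series terms from a baseline mapping table.

    Series 1 ranks candidate constraints by the product of their mapping
    probabilities and keeps the top ``n_psi``; terms are all disjoint
    subsets of the kept constraints.  Series 2 keeps the ``n_psi`` largest
    single mappings and admits every constraint all of whose mappings were
    kept.  Ties break lexicographically so selection is deterministic.
    """
    if n_psi < 0:
        raise ValueError("n_psi must be >= 0")
    with np.errstate(divide="ignore"):
        logp = np.log(table.mapped)

    if mode == SERIES1:
        cands = enumerate_constraints(spec, max_order)
        scored = sorted(
            ((c, _constraint_score(c, logp)) for c in cands),
            key=lambda cs: (-cs[1], cs[0].loci, cs[0].spot),
        )
        scored = [(c, sc) for c, sc in scored if np.isfinite(sc)]
        psi = tuple(c for c, _ in scored[:n_psi])
        terms = _disjoint_subsets(list(psi), term_cap)
    elif mode == SERIES2:
        n, m = table.mapped.shape
        flat = [
            (l, s, logp[l, s])
            for l in range(n)
            for s in range(m)
            if np.isfinite(logp[l, s])
        ]
        flat.sort(key=lambda x: (-x[2], x[0], x[1]))
        psi = tuple((l, s) for l, s, _ in flat[:n_psi])
        by_spot: dict[int, list[int]] = {}
        for l, s in psi:
            by_spot.setdefault(s, []).append(l)
        cands = []
        for s, loci in sorted(by_spot.items()):
            for combo in _non_adjacent_subsets(loci, max_order):
                cands.append(IllegalConstraint(combo, s))
        cands.sort(key=lambda c: (-_constraint_score(c, logp), c.loci, c.spot))
        terms = _disjoint_subsets(cands, term_cap)
    else:
        raise ValueError(f"unknown series mode {mode!r}")

    # evaluation order: empty term first, then |w| * estimated magnitude
    def sort_key(t: SeriesTerm):
        if not t.constraints:
            return (0, 0.0)
        mag = sum(_constraint_score(c, logp) for c in t.constraints)
        return (1, -(np.log(abs(term_weight(t, mode)) + 1e-300) + mag))

    terms.sort(key=sort_key)
    return TermSelection(mode=mode, n_psi=n_psi, psi=psi, terms=terms)


def select_terms_by_count(
    table: engine.MappingTable,
    spec: ProblemSpec,
    mode: str,
    min_terms: int,
    max_order=None,
    term_cap: int = 200_000,
    max_terms: int | None = None,
) -> TermSelection:
    """Grow ``n_psi`` until the closed term list holds >= ``min_terms`` terms.

    Term counts jump discontinuously with ``n_psi``; when the smallest
    selection reaching ``min_terms`` overshoots ``max_terms``, the largest
    selection not exceeding ``max_terms`` is returned instead, so the
    result is always closed under the inclusion rule (and therefore safe
    to evaluate strictly).
    """
    def attempt(n):
        try:
            return select_terms(table, spec, mode, n, max_order, term_cap)
        except RuntimeError:
            return None  # enumeration would blow past the term cap

    lo = max(1, min_terms // 4)
    sel = attempt(lo)
    while sel is None and lo > 1:
        lo //= 2
        sel = attempt(lo)
    if sel is None:
        return select_terms(table, spec, mode, 0)

    # grow until we reach the requested count or hit the cap
    hi_fail = None
    while len(sel) < min_terms:
        hi = sel.n_psi + max(1, sel.n_psi // 4)
        grown = attempt(hi)
        if grown is None:
            hi_fail = hi
            break
        if len(grown) == len(sel) and hi >= _max_psi(table, spec, mode):
            return grown  # exhausted all candidates
        sel = grown

    # the next step overflowed: bisect up to the largest feasible selection
    if hi_fail is not None:
        lo = sel.n_psi
        while hi_fail - lo > 1:
            mid = (lo + hi_fail) // 2
            cand = attempt(mid)
            if cand is None:
                hi_fail = mid
            else:
                lo, sel = mid, cand
                if len(sel) >= min_terms:
                    break
    else:
        # minimality: smallest selection whose closed list reaches min_terms
        lo = max(0, sel.n_psi // 2)
        hi = sel.n_psi
        while hi - lo > 1:
            mid = (lo + hi) // 2
            cand = attempt(mid)
            if cand is not None and len(cand) >= min_terms:
                hi, sel = mid, cand
            else:
                lo = mid

    if max_terms is not None and len(sel) > max_terms:
        # step back to the largest closed selection within the budget
        lo, hi = 0, sel.n_psi
        best = select_terms(table, spec, mode, 0)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            cand = attempt(mid)
            if cand is not None and len(cand) <= max_terms:
                lo, best = mid, cand
            else:
                hi = mid
        return best
    return sel


def _max_psi(table, spec, mode) -> int:
    if mode == SERIES1:
        return len(enumerate_constraints(spec))
    return int((table.mapped > 0).sum())


@dataclass
class SeriesResult:
    """Weighted-sum outcome of a series evaluation."""

    estimate: PartitionEstimate
    term_log: list  # (SeriesTerm, weight, log term value, cumulative log Z)
    n_terms: int
    mode: str


def evaluate_series(
    spec: ProblemSpec,
    selection,
    mode: str | None = None,
    strict: bool = True,
    threshold: float = engine.DP_THRESHOLD,
) -> SeriesResult:
    """Sum weighted constrained terms into a combined partition estimate.

    ``selection`` is a TermSelection or an iterable of SeriesTerm.  For
    rule-conforming (closed) selections all combined per-mapping values
    are nonnegative; with ``strict`` a materially negative value raises.
    Small negative round-off is clipped to zero either way.
    """
    if isinstance(selection, TermSelection):
        terms = selection.terms
        mode = mode or selection.mode
    else:
        terms = list(selection)
        if mode is None:
            raise ValueError("mode required when passing a bare term list")
    if not any(len(t.constraints) == 0 for t in terms):
        terms = [SeriesTerm(())] + terms

    ws = spec._ws
    base = engine.evaluate_term_raw(spec, (), mode, threshold)
    ref = base[0]
    if not np.isfinite(ref):
        raise ValueError("baseline term is zero; nothing to expand")

    z_acc = 0.0
    flat_acc = np.zeros(ws.cand.shape[0])
    term_log = []

    for term in terms:
        w = term_weight(term, mode)
        if not term.constraints:
            out = base
        else:
            if not term.is_disjoint():
                term_log.append((term, w, -np.inf, np.nan))
                continue
            out = engine.evaluate_term_raw(spec, term.constraints, mode, threshold)
        if out is None:
            term_log.append((term, w, -np.inf, np.nan))
            continue
        log_zf, _, flat = out
        if np.isfinite(log_zf):
            z_acc += w * np.exp(log_zf - ref)
            contrib = np.exp(flat - ref, where=np.isfinite(flat),
                             out=np.zeros_like(flat))
            flat_acc += w * contrib
        cum = ref + np.log(z_acc) if z_acc > 0 else -np.inf
        term_log.append((term, w, log_zf, cum))

    if z_acc <= 0:
        raise ValueError("combined series partition value is not positive")

    neg = flat_acc < 0
    if np.any(neg):
        worst = flat_acc.min() / z_acc
        if strict and worst < -1e-9:
            raise ValueError(
                f"negative combined mapping value (relative {worst:.3g}); "
                "the selection is not closed under the term-inclusion rule "
                "(series 1: all subsets of psi; series 2: all constraints "
                "within Psi)"
            )
        flat_acc = np.clip(flat_acc, 0.0, None)
    if not strict:
        # truncated sums may also over-fill a row once negatives are
        # clipped; scale offending rows back onto the simplex
        for i in range(spec.n_loci):
            sl = slice(ws.off[i], ws.off[i + 1])
            row_tot = flat_acc[sl].sum()
            if row_tot > z_acc:
                flat_acc[sl] *= z_acc / row_tot

    log_z = ref + np.log(z_acc)
    with np.errstate(divide="ignore"):
        flat_log = np.where(flat_acc > 0, ref + np.log(np.maximum(flat_acc, 1e-300)), -np.inf)
    dense = engine._dense_from_flat(spec, flat_log)
    miss = engine._miss_by_subtraction(log_z, dense)
    est = PartitionEstimate(log_z, dense, miss, log_z)
    return SeriesResult(est, term_log, len(terms), mode)
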