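"""Reconstruction-quality metrics and the greedy conformation caller.

Unrecovered information I scores the probability the table assigns to the
true mappings; entropy S is its truth-free proxy.  The caller turns a
probability table into one injective locus-to-spot assignment, scored by
sequence alignment against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import MappingTable
from .polymer import MISSING

__all__ = [
    "CallResult",
    "QualityReport",
    "call_conformation",
    "contour_accuracy",
    "edit_distance",
    "entropy",
    "quality_report",
    "unrecovered_information",
]


@dataclass
class QualityReport:
    unrecovered_bits: float       # I, bits/locus
    entropy_bits: float           # S, bits/locus
    excluded_loci: list[int]      # loci whose true mapping had zero probability
    n_loci: int


@dataclass
class CallResult:
    assignment: np.ndarray        # (N,) spot index or MISSING
    n_alignment_errors: int = -1  # filled by contour_accuracy
    accuracy: float = np.nan


def unrecovered_information(
    table: MappingTable,
    true_mapping: np.ndarray,
    exclude_zero: bool = False,
) -> tuple[float, list[int]]:
    """I = -<log2 p(true mapping)> over loci, in bits/locus.

    Loci whose truth is MISSING are scored on the missing column.  With
    ``exclude_zero``, loci given zero probability are dropped from the
    average and reported; without it a zero sends I to infinity.
    """
    truth_cols = np.where(true_mapping == MISSING, table.n_spots, true_mapping)
    p = table.probs[np.arange(table.n_loci), truth_cols]
    excluded = np.flatnonzero(p <= 0.0).tolist()
    with np.errstate(divide="ignore"):
        logs = -np.log2(p)
    if exclude_zero:
        keep = p > 0.0
        value = float(np.mean(logs[keep])) if keep.any() else np.inf
    else:
        value = float(np.mean(logs)) if logs.size else 0.0
    return value, excluded


def entropy(table: MappingTable) -> float:
    """S = mean per-locus Shannon entropy of the table rows, bits/locus."""
    p = table.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return float(terms.sum(axis=1).mean()) if p.size else 0.0


def quality_report(
    table: MappingTable,
    true_mapping: np.ndarray,
    exclude_zero: bool = False,
) -> QualityReport:
    i_bits, excluded = unrecovered_information(table, true_mapping, exclude_zero)
    return QualityReport(i_bits, entropy(table), excluded, table.n_loci)


def call_conformation(table: MappingTable) -> CallResult:
    """Greedy injective assignment from a mapping table.

    Loci are processed in descending order of their best available spot
    probability; a locus is called MISSING when its missing mass
    (1 - sum of its spot probabilities) exceeds its best remaining spot
    probability.  Taking a spot displaces it from every other locus,
    which then re-competes on the remaining spots.
    """
    n, m = table.n_loci, table.n_spots
    avail = np.ones(m, dtype=bool)
    assignment = np.full(n, MISSING, dtype=int)
    undecided = set(range(n))
    mapped = table.mapped
    miss_col = 1.0 - mapped.sum(axis=1)
    while undecided:
        best_locus, best_spot, best_p = -1, -1, -1.0
        for l in sorted(undecided):
            row = mapped[l]
            if avail.any():
                s = int(np.argmax(np.where(avail, row, -1.0)))
                p = float(row[s]) if avail[s] else 0.0
            else:
                s, p = -1, 0.0
            if p > best_p:
                best_locus, best_spot, best_p = l, s, p
        if best_locus < 0:
            break
        miss_mass = float(miss_col[best_locus])
        if best_p <= 0.0 or miss_mass > best_p:
            # no decidable spot left; everything still undecided goes missing
            if best_p <= 0.0:
                break
            assignment[best_locus] = MISSING
            undecided.remove(best_locus)
            continue
        assignment[best_locus] = best_spot
        avail[best_spot] = False
        undecided.remove(best_locus)
    return CallResult(assignment)


def edit_distance(a, b) -> int:
    """Levenshtein distance with unit mismatch/indel cost."""
    a, b = list(a), list(b)
    prev = np.arange(len(b) + 1)
    for i, x in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        for j, y in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y))
        prev = cur
    return int(prev[-1])


def contour_accuracy(called: CallResult, true_mapping: np.ndarray) -> CallResult:
    """Alignment errors between true and called spot sequences along the contour.

    MISSING entries are elided from both sequences; errors are the edit
    distance and accuracy is ``1 - errors / max(len)`` (1 if both empty).
    """
    true_seq = [int(s) for s in true_mapping if s != MISSING]
    call_seq = [int(s) for s in called.assignment if s != MISSING]
    errors = edit_distance(true_seq, call_seq)
    longest = max(len(true_seq), len(call_seq))
    accuracy = 1.0 - errors / longest if longest else 1.0
    return CallResult(called.assignment, errors, accuracy)
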