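"""Assembly of motif occurrences into complete ALPH calls.

A protein is called an ALPH when one occurrence of each of the six motifs
can be chosen, in sequence order without overlap, such that the conserved
inter-motif spacings (1→2, 2→3, 5→6) fall within their bounds and at most
``extended_budget`` (default 2) of the six motifs are matched only by the
relaxed/extended matrix.  Among valid assignments the screen prefers the
one using the fewest extended motifs, then the leftmost start positions.

Two audit modes support matrix curation and the detection of truncated
family members: a one-motif-missing scan (the remaining five motifs must
assemble with the bounds touching the missing motif waived) and, when the
missing motif is terminal, a truncated-ALPH flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

from .motif_model import (
    DistanceConstraints,
    MatrixSet,
    MotifHit,
    builtin_matrix_set,
    find_occurrences,
    occurrence_starts,
)

__all__ = [
    "MotifHit",
    "AlphCall",
    "ScreenOutcome",
    "RunSummary",
    "screen_protein",
    "missing_motif_scan",
    "screen_proteome",
    "normalise_sequence",
    "motif_candidates",
]

logger = logging.getLogger("alphscreen")

MOTIF_ORDER = (1, 2, 3, 4, 5, 6)
DISTANCE_PAIRS = ((1, 2), (2, 3), (3, 4), (4, 5), (5, 6))


@dataclass(frozen=True)
class AlphCall:
    """A complete six-motif assignment in one protein.

    ``distances`` holds d12..d56 under the active convention;
    ``extended_count`` is the number of motifs matched only by the relaxed
    matrix.
    """

    protein_id: str
    hits: tuple[MotifHit, ...]
    distances: tuple[int, int, int, int, int]
    extended_count: int

    def __post_init__(self) -> None:
        if tuple(h.motif_index for h in self.hits) != MOTIF_ORDER:
            raise ValueError("an ALPH call needs exactly one hit per motif, in order")
        for prev, nxt in zip(self.hits, self.hits[1:]):
            if nxt.start < prev.end:
                raise ValueError("motif hits must be ordered and non-overlapping")


@dataclass(frozen=True)
class ScreenOutcome:
    """Result of screening (or auditing) one protein."""

    protein_id: str
    status: str  # "alph" | "negative" | "missing_one"
    call: AlphCall | None = None
    missing_index: int | None = None
    truncated_terminal: str | None = None  # "N" | "C"
    partial_hits: tuple = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if (self.status == "alph") != (self.call is not None):
            raise ValueError("status 'alph' iff a call is present")
        if self.status == "missing_one" and self.missing_index is None:
            raise ValueError("missing_one outcome needs the missing motif index")


@dataclass
class RunSummary:
    """Aggregate counts for one proteome screen."""

    n_records: int = 0
    n_alph: int = 0
    n_negative: int = 0
    extended_motifs: int = 0

    @property
    def extended_motif_fraction(self) -> float:
        """Fraction of motifs (6 per call) matched via the extended matrix."""
        total = 6 * self.n_alph
        return self.extended_motifs / total if total else 0.0

    @property
    def extended_call_fraction(self) -> float:
        """Fraction of calls using at least one extended motif."""
        return self._calls_with_extended / self.n_alph if self.n_alph else 0.0

    _calls_with_extended: int = 0

    def add(self, outcome: ScreenOutcome) -> None:
        self.n_records += 1
        if outcome.status == "alph":
            self.n_alph += 1
            self.extended_motifs += outcome.call.extended_count
            if outcome.call.extended_count:
                self._calls_with_extended += 1
        else:
            self.n_negative += 1


def normalise_sequence(sequence: str) -> str:
    """Uppercase and strip whitespace; other characters pass through and
    simply never match a matrix position."""
    return "".join(sequence.split()).upper()


def motif_candidates(
    sequence: str, matrices: MatrixSet
) -> dict[int, list[MotifHit]]:
    """Per motif, all occurrences with their flavour label.

    A window matched by the primary matrix is labelled with the primary
    flavour; a window matched only by the relaxed matrix is labelled
    ``extended`` and will count against the extended budget.
    """
    candidates: dict[int, list[MotifHit]] = {}
    for k in MOTIF_ORDER:
        primary, relaxed = matrices.matrices(k)
        hits = find_occurrences(sequence, primary)
        if relaxed is not None:
            primary_starts = {h.start for h in hits}
            for start in occurrence_starts(sequence, relaxed):
                start = int(start)
                if start in primary_starts:
                    continue
                end = start + relaxed.length
                hits.append(
                    MotifHit(k, start, end, sequence[start:end], "extended")
                )
            hits.sort(key=lambda h: h.start)
        candidates[k] = hits
    return candidates


def _hit_cost(hit: MotifHit) -> int:
    return 1 if hit.flavour_used == "extended" else 0


def _assign(
    candidates: Sequence[Sequence[MotifHit]],
    constraints: DistanceConstraints,
    motif_order: Sequence[int],
    max_extended: int,
) -> tuple[MotifHit, ...] | None:
    """Depth-first search for the leftmost valid assignment using at most
    ``max_extended`` extended motifs.

    ``candidates[i]`` are the occurrences of ``motif_order[i]`` in ascending
    start order.  The scan over a level is cut as soon as a bounded
    consecutive distance exceeds its upper limit (later candidates are only
    farther).  Because candidates are explored in ascending start order, the
    first complete assignment found has the lexicographically smallest start
    tuple among all valid assignments within the budget.
    """
    n = len(motif_order)
    chosen: list[MotifHit] = []

    def recurse(level: int, budget: int) -> bool:
        if level == n:
            return True
        prev = chosen[-1] if chosen else None
        pair = (
            (motif_order[level - 1], motif_order[level]) if level > 0 else None
        )
        for hit in candidates[level]:
            if prev is not None:
                if hit.start < prev.end:
                    continue
                dist = constraints.distance(prev, hit)
                if pair is not None and not constraints.satisfied(pair, dist):
                    bound = constraints.bounds.get(pair)
                    if bound is not None and dist > bound[1]:
                        break  # later candidates are only farther
                    continue
            cost = _hit_cost(hit)
            if cost > budget:
                continue
            chosen.append(hit)
            if recurse(level + 1, budget - cost):
                return True
            chosen.pop()
        return False

    if recurse(0, max_extended):
        return tuple(chosen)
    return None


def _distances(
    hits: Sequence[MotifHit], constraints: DistanceConstraints
) -> tuple[int, ...]:
    return tuple(
        constraints.distance(prev, nxt) for prev, nxt in zip(hits, hits[1:])
    )


def screen_protein(
    protein_id: str,
    sequence: str,
    matrices: MatrixSet | None = None,
    constraints: DistanceConstraints | None = None,
    extended_budget: int = 2,
    multi_domain: bool = False,
) -> ScreenOutcome:
    """Screen one protein for a complete six-motif ALPH signature.

    Returns an outcome with status ``alph`` (and an :class:`AlphCall`) when
    a valid assignment exists, else ``negative``.  The chosen assignment
    minimises the number of extended motifs first, ties broken by the
    leftmost start-position tuple.  With ``multi_domain`` the remainder of
    the sequence after a call is rescanned and additional candidate ALPH
    domains are reported in ``notes``.
    """
    if matrices is None:
        matrices = builtin_matrix_set()
    if constraints is None:
        constraints = DistanceConstraints()
    sequence = normalise_sequence(sequence)
    if not sequence:
        raise ValueError(f"{protein_id}: empty sequence after normalisation")

    candidates = motif_candidates(sequence, matrices)
    outcome = _screen_from_candidates(
        protein_id, candidates, constraints, extended_budget
    )
    if multi_domain and outcome.status == "alph":
        tail_start = outcome.call.hits[-1].end
        tail_candidates = {
            k: [h for h in candidates[k] if h.start >= tail_start]
            for k in MOTIF_ORDER
        }
        extra = _screen_from_candidates(
            protein_id, tail_candidates, constraints, extended_budget
        )
        if extra.status == "alph":
            span = (extra.call.hits[0].start + 1, extra.call.hits[-1].end)
            outcome = replace(
                outcome,
                notes=(outcome.notes + "; " if outcome.notes else "")
                + f"additional candidate ALPH domain at {span[0]}-{span[1]}",
            )
    return outcome


def _screen_from_candidates(
    protein_id: str,
    candidates: dict[int, list[MotifHit]],
    constraints: DistanceConstraints,
    extended_budget: int,
) -> ScreenOutcome:
    if any(not candidates[k] for k in MOTIF_ORDER):
        return ScreenOutcome(protein_id, "negative")
    ordered = [candidates[k] for k in MOTIF_ORDER]
    for budget in range(extended_budget + 1):
        hits = _assign(ordered, constraints, MOTIF_ORDER, budget)
        if hits is not None:
            call = AlphCall(
                protein_id,
                hits,
                _distances(hits, constraints),
                sum(_hit_cost(h) for h in hits),
            )
            return ScreenOutcome(protein_id, "alph", call=call)
    return ScreenOutcome(protein_id, "negative")


def missing_motif_scan(
    protein_id: str,
    sequence: str,
    matrices: MatrixSet | None = None,
    constraints: DistanceConstraints | None = None,
    missing: int = 1,
    extended_budget: int = 2,
) -> ScreenOutcome:
    """One-motif-missing audit: can the other five motifs assemble?

    Reports ``missing_one`` when the full six-motif screen is negative but
    the five motifs other than ``missing`` admit a valid ordered assignment
    with every bound touching the missing motif waived.  A missing terminal
    motif (1 or 6) additionally flags a candidate truncated ALPH at the N
    or C terminus.
    """
    if missing not in MOTIF_ORDER:
        raise ValueError(f"missing motif index must be 1..6, got {missing}")
    if matrices is None:
        matrices = builtin_matrix_set()
    if constraints is None:
        constraints = DistanceConstraints()
    sequence = normalise_sequence(sequence)
    if not sequence:
        raise ValueError(f"{protein_id}: empty sequence after normalisation")

    candidates = motif_candidates(sequence, matrices)
    full = _screen_from_candidates(protein_id, candidates, constraints, extended_budget)
    if full.status == "alph":
        return ScreenOutcome(
            protein_id, "negative", notes="full six-motif screen already positive"
        )

    order = tuple(k for k in MOTIF_ORDER if k != missing)
    ordered = [candidates[k] for k in order]
    if any(not group for group in ordered):
        return ScreenOutcome(protein_id, "negative")
    # Bounds whose pair includes the missing motif are waived; the remaining
    # bounds apply between the motifs that are still adjacent in the scan.
    waived = {
        pair: bound
        for pair, bound in constraints.bounds.items()
        if missing not in pair
    }
    reduced = DistanceConstraints(bounds=waived, convention=constraints.convention)
    for budget in range(extended_budget + 1):
        hits = _assign(ordered, reduced, order, budget)
        if hits is not None:
            terminal = {1: "N", 6: "C"}.get(missing)
            return ScreenOutcome(
                protein_id,
                "missing_one",
                missing_index=missing,
                truncated_terminal=terminal,
                partial_hits=hits,
            )
    return ScreenOutcome(protein_id, "negative")


def screen_proteome(
    records,
    matrices: MatrixSet | None = None,
    constraints: DistanceConstraints | None = None,
    extended_budget: int = 2,
    multi_domain: bool = False,
) -> Iterator[ScreenOutcome]:
    """Screen a stream of proteome records, preserving input order.

    ``records`` is an iterable of objects with ``record_id`` and
    ``sequence`` attributes (see :mod:`alphscreen.proteome_io`) or a path to
    a FASTA file.  Yields one :class:`ScreenOutcome` per record; the
    summary is attached afterwards via :func:`summarise_outcomes` or by
    consuming through :class:`RunSummary`.
    """
    from .proteome_io import read_proteome

    if isinstance(records, (str, bytes)) or hasattr(records, "__fspath__"):
        records = read_proteome(records)
    for record in records:
        yield screen_protein(
            record.record_id,
            record.sequence,
            matrices,
            constraints,
            extended_budget=extended_budget,
            multi_domain=multi_domain,
        )


def summarise_outcomes(outcomes) -> RunSummary:
    """Fold a sequence of outcomes into a :class:`RunSummary`."""
    summary = RunSummary()
    for outcome in outcomes:
        summary.add(outcome)
    return summary
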