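"""Shared fixtures: a hand-built positive sequence and a brute-force
assignment oracle that enumerates every 6-tuple of motif occurrences."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from alphscreen.motif_model import DistanceConstraints, builtin_matrix_set
from alphscreen.screener import motif_candidates, normalise_sequence

# One motif string per position, joined by gaps that satisfy every bound.
FIXTURE_PARTS = {
    "n_term": "A" * 10,
    1: "GDVHG",
    "d12": "A" * 29,
    2: "GDLVGKG",
    "d23": "A" * 26,
    3: "GNHE",
    "d34": "A" * 60,
    4: "HGG",
    "d45": "A" * 40,
    5: "VIFGH",
    "d56": "A" * 19,
    6: "LDTG",
    "c_term": "A" * 20,
}
FIXTURE_ORDER = ("n_term", 1, "d12", 2, "d23", 3, "d34", 4, "d45", 5, "d56", 6, "c_term")


def build_fixture(overrides: dict | None = None, **kwargs) -> str:
    """Fixture sequence with parts replaced: int keys override motif
    strings, string keys override spacers/termini."""
    parts = dict(FIXTURE_PARTS)
    parts.update(overrides or {})
    parts.update(kwargs)
    return "".join(parts[key] for key in FIXTURE_ORDER)


@pytest.fixture
def positive_sequence() -> str:
    return build_fixture()


def oracle_best_assignment(
    sequence: str,
    matrices=None,
    constraints: DistanceConstraints | None = None,
    extended_budget: int = 2,
):
    """Exhaustive enumeration over all one-occurrence-per-motif 6-tuples.

    Returns ``None`` or ``(extended_count, start_tuple, hits)`` for the
    assignment minimising (extended_count, starts).  Independent of the
    screener's depth-first search; shares only the per-window candidate
    scan, which is itself checked against per-window re-matching elsewhere.
    """
    sequence = normalise_sequence(sequence)
    matrices = matrices or builtin_matrix_set()
    constraints = constraints or DistanceConstraints()
    candidates = motif_candidates(sequence, matrices)
    best = None
    groups = [candidates[k] for k in range(1, 7)]
    if any(not g for g in groups):
        return None
    for combo in itertools.product(*groups):
        valid = True
        for prev, nxt in zip(combo, combo[1:]):
            if nxt.start < prev.end:
                valid = False
                break
            distance = constraints.distance(prev, nxt)
            if not constraints.satisfied(
                (prev.motif_index, nxt.motif_index), distance
            ):
                valid = False
                break
        if not valid:
            continue
        extended = sum(1 for h in combo if h.flavour_used == "extended")
        if extended > extended_budget:
            continue
        key = (extended, tuple(h.start for h in combo))
        if best is None or key < best[:2]:
            best = (extended, key[1], combo)
    return best


@pytest.fixture
def oracle():
    return oracle_best_assignment


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210623)
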