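"""Position-specific residue-set matrices for the six ALPH signature motifs.

ApaH-like phosphatases (ALPHs) carry the four PPP-phosphatase signature
motifs (GDxHG, GDxxDRG-like, GNHE, HGG — motifs 1-4) plus two family-specific
C-terminal motifs (5 and 6).  Each motif is modelled as a short window of
allowed-residue sets: a window matches when every residue is a member of the
set at its position.  Two built-in flavours exist per motif: a strict
*narrow* matrix used for the primary screen and a relaxed *extended* matrix
(a superset at every position, additionally admitting the unknown-residue
token ``X``) of which a screened protein may use at most a small budget.

A distinguishing feature of ALPHs is the replacement of the arginine of the
PPP GDxxDRG motif by lysine; arginine at position 6 of motif 2 is therefore
categorically rejected, as it would re-admit the related ApaH/RLPH/SLP
phosphatases.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MOTIF_LENGTHS",
    "MotifMatrix",
    "MotifHit",
    "DistanceConstraints",
    "MatrixSet",
    "MatrixConfigError",
    "builtin_matrices",
    "builtin_matrix_set",
    "load_custom_matrices",
    "matches_at",
    "find_occurrences",
    "format_matrices",
]

#: Window length of each motif, 1-based motif index.
MOTIF_LENGTHS: dict[int, int] = {1: 5, 2: 7, 3: 4, 4: 3, 5: 5, 6: 4}

# Strict per-position residue sets used in the primary screening pass.
_NARROW = {
    1: ("G", "D", "VILT", "HQ", "G"),
    2: ("G", "DN", "LMIFVT", "EIVTLAC", "NSATFGVQIDHM", "KQN", "GASHT"),
    3: ("G", "N", "HNWQ", "ED"),
    4: ("H", "AG", "G"),
    5: ("VIT", "IVYFLAMT", "FY", "G", "H"),
    6: ("LVIMT", "DE", "STG", "GASRN"),
}

# Relaxed sets; the unknown-residue token X is a member at every position.
# (Lower-case x in input data is folded to X on ingest.)
_EXTENDED = {
    1: ("GX", "DX", "VILTX", "HQX", "GX"),
    2: ("GX", "DNX", "TIFLYVMX", "ETIALCVMX", "EQTIASDFGHCVNMX", "KQNX", "GASHTX"),
    3: ("GX", "NX", "HNWQX", "EDX"),
    4: ("HX", "AGLVX", "GX"),
    5: ("AVILCMTX", "IVYFLAMTX", "FYX", "GX", "HX"),
    6: ("LVIMTX", "DEX", "LATGSVX", "LMGRASNEX"),
}

_FLAVOURS = ("narrow", "extended", "custom")


class MatrixConfigError(ValueError):
    """Raised when a custom matrix configuration is malformed."""


@dataclass(frozen=True)
class MotifMatrix:
    """One motif as an ordered list of allowed-residue sets.

    Parameters
    ----------
    motif_index:
        Which of the six motifs (1..6) this matrix describes.
    flavour:
        ``"narrow"``, ``"extended"`` or ``"custom"``.
    positions:
        One frozen set of uppercase one-letter residue codes per window
        position.
    allow_motif2_r:
        Escape hatch for the hard-wired rejection of R at position 6 of
        motif 2.  Off by default; a custom configuration must set it
        explicitly to re-admit arginine there.
    """

    motif_index: int
    flavour: str
    positions: tuple[frozenset, ...]
    allow_motif2_r: bool = False

    def __post_init__(self) -> None:
        if self.motif_index not in MOTIF_LENGTHS:
            raise MatrixConfigError(f"motif index must be 1..6, got {self.motif_index}")
        if self.flavour not in _FLAVOURS:
            raise MatrixConfigError(f"unknown matrix flavour {self.flavour!r}")
        expected = MOTIF_LENGTHS[self.motif_index]
        if len(self.positions) != expected:
            raise MatrixConfigError(
                f"motif {self.motif_index}: expected {expected} positions, "
                f"got {len(self.positions)}"
            )

    @property
    def length(self) -> int:
        return len(self.positions)

    def allowed(self, position: int) -> frozenset:
        """Effective allowed set at 0-based ``position``.

        Applies the motif-2 position-6 arginine exclusion unless explicitly
        overridden.
        """
        residues = self.positions[position]
        if self.motif_index == 2 and position == 5 and not self.allow_motif2_r:
            residues = residues - {"R"}
        return residues


@dataclass(frozen=True)
class MotifHit:
    """A located match of one motif in one protein (0-based, half-open)."""

    motif_index: int
    start: int
    end: int
    matched: str
    flavour_used: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched):
            raise ValueError("hit span and matched string length disagree")


#: Inter-motif distance bounds (residues) for the conserved spacings.
DEFAULT_DISTANCE_BOUNDS: dict[tuple[int, int], tuple[int, int]] = {
    (1, 2): (14, 150),
    (2, 3): (25, 80),
    (5, 6): (17, 40),
}


@dataclass(frozen=True)
class DistanceConstraints:
    """Inter-motif spacing restrictions.

    ``convention`` selects how a distance between motif *i* and motif *j* is
    measured: ``"gap"`` counts the residues strictly between the last
    residue of motif *i* and the first residue of motif *j*;
    ``"start_to_start"`` counts from first residue to first residue.  The
    gap convention is the default.  Pairs (3,4) and (4,5) carry no bound —
    those spacings are poorly conserved across the family.
    """

    bounds: Mapping = field(
        default_factory=lambda: dict(DEFAULT_DISTANCE_BOUNDS)
    )
    convention: str = "gap"

    def __post_init__(self) -> None:
        if self.convention not in ("gap", "start_to_start"):
            raise ValueError(f"unknown distance convention {self.convention!r}")
        for pair, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound for motif pair {pair} has lower > upper")

    def distance(self, prev_hit: MotifHit, next_hit: MotifHit) -> int:
        if self.convention == "gap":
            return next_hit.start - prev_hit.end
        return next_hit.start - prev_hit.start

    def satisfied(self, pair: tuple[int, int], value: int) -> bool:
        bound = self.bounds.get(pair)
        if bound is None:
            return True
        lo, hi = bound
        return lo <= value <= hi


@dataclass(frozen=True)
class MatrixSet:
    """The matrices driving one screen: a primary tier and an optional
    relaxed tier.

    For the built-in model the primary tier is the narrow matrices and the
    relaxed tier the extended ones; a motif matched only by the relaxed tier
    counts against the screen's extended-motif budget.  A custom set may
    omit the relaxed tier, in which case every hit is budget-free.
    """

    primary: tuple[MotifMatrix, ...]
    relaxed: tuple | None = None

    def __post_init__(self) -> None:
        if tuple(m.motif_index for m in self.primary) != (1, 2, 3, 4, 5, 6):
            raise MatrixConfigError("primary tier must hold motifs 1..6 in order")
        if self.relaxed is not None:
            if tuple(m.motif_index for m in self.relaxed) != (1, 2, 3, 4, 5, 6):
                raise MatrixConfigError("relaxed tier must hold motifs 1..6 in order")

    def matrices(self, motif_index: int) -> tuple:
        """(primary, relaxed-or-None) matrices for one motif."""
        relaxed = self.relaxed[motif_index - 1] if self.relaxed is not None else None
        return self.primary[motif_index - 1], relaxed


def builtin_matrices(flavour: str) -> tuple[MotifMatrix, ...]:
    """The six built-in matrices of the requested flavour, in motif order."""
    if flavour == "narrow":
        source = _NARROW
    elif flavour == "extended":
        source = _EXTENDED
    else:
        raise MatrixConfigError(f"no built-in flavour {flavour!r}")
    return tuple(
        MotifMatrix(k, flavour, tuple(frozenset(p) for p in source[k]))
        for k in range(1, 7)
    )


def builtin_matrix_set() -> MatrixSet:
    """Narrow primary tier plus extended relaxed tier."""
    return MatrixSet(builtin_matrices("narrow"), builtin_matrices("extended"))


# ---------------------------------------------------------------------------
# Matching


def matches_at(window: str, matrix: MotifMatrix) -> bool:
    """Does ``window`` satisfy ``matrix`` position by position?

    ``window`` must be uppercase and exactly ``matrix.length`` long (a
    length mismatch is a programming error and raises).  Residues outside
    the allowed set — including non-alphabetic characters such as ``*`` or
    gaps — simply fail to match.
    """
    if len(window) != matrix.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {matrix.length} "
            f"for motif {matrix.motif_index}"
        )
    return all(window[i] in matrix.allowed(i) for i in range(matrix.length))


def encode_sequence(sequence: str) -> np.ndarray:
    """Uint8 view of an uppercase protein sequence for vectorised scans.

    Characters outside ASCII are replaced by ``?`` which matches nothing.
    """
    return np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)


@lru_cache(maxsize=256)
def _membership_table(matrix: MotifMatrix) -> np.ndarray:
    """(length, 256) boolean table: table[i, ord(c)] == c allowed at i."""
    table = np.zeros((matrix.length, 256), dtype=bool)
    for i in range(matrix.length):
        for residue in matrix.allowed(i):
            table[i, ord(residue)] = True
    return table


def occurrence_starts(sequence: str | np.ndarray, matrix: MotifMatrix) -> np.ndarray:
    """0-based start positions of all windows matching ``matrix``."""
    arr = encode_sequence(sequence) if isinstance(sequence, str) else sequence
    length = matrix.length
    n = arr.size
    if n < length:
        return np.empty(0, dtype=np.intp)
    table = _membership_table(matrix)
    ok = table[0][arr[: n - length + 1]]
    for i in range(1, length):
        ok &= table[i][arr[i : n - length + 1 + i]]
    return np.nonzero(ok)[0]


def find_occurrences(sequence: str, matrix: MotifMatrix) -> list[MotifHit]:
    """All matches of one matrix in a sequence, in ascending start order."""
    hits = []
    for start in occurrence_starts(sequence, matrix):
        start = int(start)
        end = start + matrix.length
        hits.append(
            MotifHit(matrix.motif_index, start, end, sequence[start:end], matrix.flavour)
        )
    return hits


# ---------------------------------------------------------------------------
# Custom matrix configuration
#
# Grammar (INI-style):
#
#   [options]              # optional
#   allow_motif2_r = false
#
#   [motif 1]              # required, motifs 1..6, primary tier
#   1 = G
#   2 = D
#   3 = VILT
#   4 = HQ
#   5 = G
#
#   [motif 1 relaxed]      # optional per motif; if any is given, all six
#   1 = GX                 # must be, and they form the relaxed tier
#   ...
#
# Each key is a 1-based window position, each value the allowed residues as
# a run of one-letter codes (case-insensitive; X marks the unknown residue).


def _parse_section(
    parser: configparser.ConfigParser,
    section: str,
    motif_index: int,
    flavour: str,
    allow_motif2_r: bool,
) -> MotifMatrix:
    expected = MOTIF_LENGTHS[motif_index]
    entries: dict[int, frozenset] = {}
    for key, value in parser.items(section):
        try:
            position = int(key)
        except ValueError as exc:
            raise MatrixConfigError(
                f"[{section}]: position key {key!r} is not an integer"
            ) from exc
        if not 1 <= position <= expected:
            raise MatrixConfigError(
                f"[{section}]: position {position} out of range 1..{expected}"
            )
        residues = frozenset(value.upper()) - {" ", ","}
        if not residues or not all(c.isalpha() for c in residues):
            raise MatrixConfigError(
                f"[{section}] position {position}: residues must be letters, got {value!r}"
            )
        entries[position] = residues
    missing = sorted(set(range(1, expected + 1)) - set(entries))
    if missing:
        raise MatrixConfigError(f"[{section}]: missing positions {missing}")
    positions = tuple(entries[i] for i in range(1, expected + 1))
    return MotifMatrix(motif_index, flavour, positions, allow_motif2_r=allow_motif2_r)


def load_custom_matrices(source: str | None = None) -> MatrixSet:
    """Build a :class:`MatrixSet` from a configuration file or text.

    ``source`` may be a path, raw configuration text, or ``None`` — in which
    case the built-in narrow/extended set is returned unchanged.  The
    configuration must define all six motifs at the built-in lengths;
    errors name the offending motif.
    """
    if source is None:
        return builtin_matrix_set()
    parser = configparser.ConfigParser()
    text = source
    if "\n" not in source and "[" not in source:
        with open(source, "r", encoding="utf-8") as handle:
            text = handle.read()
    try:
        parser.read_file(io.StringIO(text))
    except configparser.Error as exc:
        raise MatrixConfigError(f"unparsable matrix configuration: {exc}") from exc

    allow_r = False
    if parser.has_section("options"):
        allow_r = parser.getboolean("options", "allow_motif2_r", fallback=False)

    primary = []
    for k in range(1, 7):
        section = f"motif {k}"
        if not parser.has_section(section):
            raise MatrixConfigError(f"configuration is missing section [{section}]")
        primary.append(_parse_section(parser, section, k, "custom", allow_r))

    relaxed_sections = [f"motif {k} relaxed" for k in range(1, 7)]
    present = [s for s in relaxed_sections if parser.has_section(s)]
    relaxed = None
    if present:
        if len(present) != 6:
            raise MatrixConfigError(
                "relaxed tier must define all six motifs; "
                f"missing {sorted(set(relaxed_sections) - set(present))}"
            )
        relaxed = tuple(
            _parse_section(parser, f"motif {k} relaxed", k, "custom", allow_r)
            for k in range(1, 7)
        )

    known = {"options", *(f"motif {k}" for k in range(1, 7)), *relaxed_sections}
    unknown = [s for s in parser.sections() if s not in known]
    if unknown:
        raise MatrixConfigError(f"unknown configuration sections: {unknown}")
    return MatrixSet(tuple(primary), relaxed)


def format_matrices(matrices: Iterable[MotifMatrix]) -> str:
    """Human-readable rendering, one line per motif position."""
    lines = []
    for matrix in matrices:
        lines.append(f"motif {matrix.motif_index} ({matrix.flavour})")
        for i, residues in enumerate(matrix.positions, start=1):
            lines.append(f"  {i}: {''.join(sorted(residues))}")
    return "\n".join(lines)
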