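"""Labelled synthetic proteomes for exercising the ALPH screen.

Positives are assembled motif by motif: one residue is drawn per window
position from the chosen matrix flavour, motifs are joined by background
spacers whose lengths follow the family's conserved spacing distributions
(the 1→2 gap concentrated on 28-30 with mode 29, 2→3 on 26, 3→4 on 55-64,
4→5 broad, 5→6 on 19), and termini are padded to the family's median
N-/C-terminal extension sizes.  Decoys are positives perturbed to violate
exactly one property of the screen: a PPP-like arginine at motif-2
position 6, a spacing outside its bounds, one motif deleted, a terminal
truncation, or pure background.

Background residues are drawn uniformly from the 20 standard amino acids
and rejection-resampled until no window overlapping background matches any
motif matrix of any flavour, so the planted truth is exactly the set of
motif occurrences available to the screen and labels are clean by
construction.  All randomness flows from the single seed in the spec;
identical seeds give byte-identical output.

The generator emulates the screen's assumptions, not real proteins: spacer
composition is uniform rather than biased, motif residues are drawn
independently per position, and no evolutionary divergence or homology
structure is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .motif_model import (
    MOTIF_LENGTHS,
    DEFAULT_DISTANCE_BOUNDS,
    builtin_matrices,
    matches_at,
    occurrence_starts,
)

__all__ = [
    "DistanceModel",
    "SyntheticSpec",
    "SyntheticTruth",
    "SyntheticRecord",
    "SyntheticSpecError",
    "generate",
    "perturb_to_missing",
    "truth_frame",
    "write_corpus",
    "DECOY_CLASSES",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA20_CODES = np.frombuffer(AA20.encode("ascii"), dtype=np.uint8)

DECOY_CLASSES = (
    "ppp_like_R6",
    "distance_violation",
    "one_missing",
    "terminal_truncation",
    "random_background",
)


class SyntheticSpecError(ValueError):
    """Raised when a synthetic spec would plant illegal positives."""


@dataclass(frozen=True)
class DistanceModel:
    """A mixture of uniform integer bins: ``(weight, lo, hi)`` per bin."""

    bins: tuple

    def __post_init__(self) -> None:
        total = sum(w for w, _, _ in self.bins)
        if not np.isclose(total, 1.0):
            raise SyntheticSpecError(f"bin weights sum to {total}, expected 1")
        for w, lo, hi in self.bins:
            if w < 0 or lo > hi:
                raise SyntheticSpecError(f"malformed bin {(w, lo, hi)}")

    @property
    def support(self) -> tuple[int, int]:
        return min(lo for _, lo, _ in self.bins), max(hi for _, _, hi in self.bins)

    def sample(self, rng: np.random.Generator) -> int:
        weights = np.array([w for w, _, _ in self.bins])
        index = rng.choice(len(self.bins), p=weights / weights.sum())
        _, lo, hi = self.bins[index]
        return int(rng.integers(lo, hi + 1))

    def probability_at(self, value: int) -> float:
        """Exact mixture probability of one integer value (for recovery
        tests)."""
        p = 0.0
        for w, lo, hi in self.bins:
            if lo <= value <= hi:
                p += w / (hi - lo + 1)
        return p

    def probability_in(self, lo: int, hi: int) -> float:
        return sum(self.probability_at(v) for v in range(lo, hi + 1))


# Defaults concentrate each conserved spacing on its family mode: the 1→2
# gap on 28-30 (mode 29), 2→3 on 26 (almost all of the rest within 25-33),
# 3→4 on 55-64, 4→5 broad, and 5→6 on 19.
_D12_DEFAULT = DistanceModel(
    ((0.72, 29, 29), (0.1085, 28, 28), (0.1085, 30, 30), (0.0315, 14, 27), (0.0315, 31, 150))
)
_D23_DEFAULT = DistanceModel(
    ((0.83, 26, 26), (0.075, 25, 25), (0.075, 27, 33), (0.02, 34, 80))
)
_D34_DEFAULT = DistanceModel(((0.94, 55, 64), (0.03, 40, 54), (0.03, 65, 120)))
_D45_DEFAULT = DistanceModel(((1.0, 30, 120),))
_D56_DEFAULT = DistanceModel(((0.925, 19, 19), (0.0375, 17, 18), (0.0375, 20, 40)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic corpus.

    Terminus lengths are drawn from rounded log-normals with the family's
    median N-terminus (87 residues) and C-terminus (26 residues);
    ``extended_call_rate`` is the fraction of positives carrying exactly one
    extended-matrix motif (never two, matching the rarity of extended usage
    in real screens); ``multi_isoform_rate`` is the fraction of
    ALPH-positive organisms carrying a second isoform.
    """

    n_positive: int = 100
    n_decoy_per_class: int = 0
    decoy_classes: tuple = DECOY_CLASSES
    d12: DistanceModel = _D12_DEFAULT
    d23: DistanceModel = _D23_DEFAULT
    d34: DistanceModel = _D34_DEFAULT
    d45: DistanceModel = _D45_DEFAULT
    d56: DistanceModel = _D56_DEFAULT
    n_term_median: float = 87.0
    c_term_median: float = 26.0
    term_sigma: float = 0.6
    extended_call_rate: float = 0.113
    multi_isoform_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, model in (((1, 2), self.d12), ((2, 3), self.d23), ((5, 6), self.d56)):
            lo_bound, hi_bound = DEFAULT_DISTANCE_BOUNDS[pair]
            lo, hi = model.support
            if lo < lo_bound or hi > hi_bound:
                raise SyntheticSpecError(
                    f"distance model for motif pair {pair} has support [{lo},{hi}] "
                    f"outside the legal bounds [{lo_bound},{hi_bound}]"
                )
        unknown = set(self.decoy_classes) - set(DECOY_CLASSES)
        if unknown:
            raise SyntheticSpecError(f"unknown decoy classes: {sorted(unknown)}")
        if not 0.0 <= self.extended_call_rate <= 1.0:
            raise SyntheticSpecError("extended_call_rate must be a probability")

    @property
    def distance_models(self) -> dict:
        return {"d12": self.d12, "d23": self.d23, "d34": self.d34,
                "d45": self.d45, "d56": self.d56}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated protein.

    ``spans`` are 1-based inclusive (start, end) per motif, ``None`` where a
    motif was deleted or truncated away.
    """

    record_id: str
    label: str  # "alph" or a decoy class
    organism: str
    spans: tuple  # six entries of (start, end) or None
    flavours: tuple  # six entries of "narrow"/"extended" or None
    distances: tuple | None  # d12..d56 gaps as planted, None for background
    n_term_len: int | None
    c_term_len: int | None
    missing_index: int | None = None
    truncated_side: str | None = None
    violated_pair: tuple | None = None


@dataclass(frozen=True)
class SyntheticRecord:
    truth: SyntheticTruth
    sequence: str


# ---------------------------------------------------------------------------
# Low-level assembly


def _background(rng: np.random.Generator, n: int) -> np.ndarray:
    return _AA20_CODES[rng.integers(0, len(_AA20_CODES), size=n)]


def _sample_terminus(rng: np.random.Generator, median: float, sigma: float) -> int:
    return int(round(rng.lognormal(mean=np.log(median), sigma=sigma)))


_NARROW_CHOICES = {
    m.motif_index: [sorted(m.allowed(i)) for i in range(m.length)]
    for m in builtin_matrices("narrow")
}
_EXT_ONLY_CHOICES = {
    ext.motif_index: [
        sorted(ext.allowed(i) - nar.allowed(i)) for i in range(ext.length)
    ]
    for nar, ext in zip(builtin_matrices("narrow"), builtin_matrices("extended"))
}


def _motif_string(
    rng: np.random.Generator, motif_index: int, extended: bool
) -> str:
    """Sample a window from the narrow matrix, or (``extended``) a window
    matching only the extended matrix: one position uses a residue outside
    the narrow set (possibly the unknown token X)."""
    residues = [
        choices[int(rng.integers(len(choices)))]
        for choices in _NARROW_CHOICES[motif_index]
    ]
    if extended:
        position = int(rng.integers(MOTIF_LENGTHS[motif_index]))
        pool = _EXT_ONLY_CHOICES[motif_index][position]
        residues[position] = pool[int(rng.integers(len(pool)))]
    return "".join(residues)


_EXTENDED_MATRICES = builtin_matrices("extended")


def _clean_background(
    arr: np.ndarray,
    spans: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    max_iter: int = 500,
) -> np.ndarray:
    """Resample background residues until no motif matrix (extended flavour,
    which subsumes narrow) matches a window that is not fully inside a
    planted span.  ``spans`` are 0-based half-open."""
    protected = np.zeros(arr.size, dtype=bool)
    for start, end in spans:
        protected[start:end] = True
    for _ in range(max_iter):
        offending: list[tuple[int, int]] = []
        for matrix in _EXTENDED_MATRICES:
            length = matrix.length
            for start in occurrence_starts(arr, matrix):
                start = int(start)
                inside = any(
                    start >= s and start + length <= e for s, e in spans
                )
                if not inside:
                    offending.append((start, start + length))
        if not offending:
            return arr
        for start, end in offending:
            window = np.arange(start, end)
            free = window[~protected[window]]
            arr[free] = _background(rng, free.size)
    raise RuntimeError("background cleaning did not converge; ambiguous fixture")


@dataclass
class _Planted:
    """Intermediate assembly state for one positive-like protein."""

    arr: np.ndarray
    spans: list  # 0-based half-open per motif
    flavours: list
    distances: tuple
    n_term: int
    c_term: int


def _assemble_positive(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    motif_strings: dict[int, str] | None = None,
    distances: tuple | None = None,
) -> _Planted:
    if distances is None:
        distances = tuple(
            spec.distance_models[name].sample(rng)
            for name in ("d12", "d23", "d34", "d45", "d56")
        )
    extended_motif = None
    flavours = ["narrow"] * 6
    if rng.random() < spec.extended_call_rate:
        extended_motif = int(rng.integers(1, 7))
        flavours[extended_motif - 1] = "extended"
    strings = {}
    for k in range(1, 7):
        if motif_strings is not None and k in motif_strings:
            strings[k] = motif_strings[k]
        else:
            strings[k] = _motif_string(rng, k, extended=k == extended_motif)
    # The sampled terminus lengths are the *annotated* N-/C-terminal
    # extensions, i.e. the residues outside the catalytic domain.  The
    # domain absorbs 6 residues upstream of motif 1 and 8 downstream of
    # motif 6, so the planted padding adds those on top.
    n_term = _sample_terminus(rng, spec.n_term_median, spec.term_sigma)
    c_term = _sample_terminus(rng, spec.c_term_median, spec.term_sigma)
    pad_n = n_term + 6
    pad_c = c_term + 8

    segments: list[np.ndarray] = [_background(rng, pad_n)]
    spans: list[tuple[int, int]] = []
    cursor = pad_n
    for k in range(1, 7):
        encoded = np.frombuffer(strings[k].encode("ascii"), dtype=np.uint8).copy()
        segments.append(encoded)
        spans.append((cursor, cursor + encoded.size))
        cursor += encoded.size
        if k < 6:
            gap = distances[k - 1]
            segments.append(_background(rng, gap))
            cursor += gap
    segments.append(_background(rng, pad_c))
    arr = np.concatenate(segments)
    arr = _clean_background(arr, spans, rng)
    return _Planted(arr, spans, flavours, distances, n_term, c_term)


def _to_sequence(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _truth_from_planted(
    record_id: str, label: str, organism: str, planted: _Planted, **extra
) -> SyntheticTruth:
    spans_1based = tuple((s + 1, e) for s, e in planted.spans)
    return SyntheticTruth(
        record_id=record_id,
        label=label,
        organism=organism,
        spans=spans_1based,
        flavours=tuple(planted.flavours),
        distances=planted.distances,
        n_term_len=planted.n_term,
        c_term_len=planted.c_term,
        **extra,
    )


# ---------------------------------------------------------------------------
# Decoy construction

_VIOLATION_RANGES = {
    (1, 2): ((3, 13), (151, 200)),
    (2, 3): ((5, 24), (81, 130)),
    (5, 6): ((5, 16), (41, 80)),
}


def _make_distance_violation(rng: np.random.Generator, spec: SyntheticSpec) -> _Planted:
    pairs = tuple(_VIOLATION_RANGES)
    pair = pairs[int(rng.integers(len(pairs)))]
    low_side = bool(rng.integers(2))
    lo, hi = _VIOLATION_RANGES[pair][0 if low_side else 1]
    bad_value = int(rng.integers(lo, hi + 1))
    distances = list(
        spec.distance_models[name].sample(rng)
        for name in ("d12", "d23", "d34", "d45", "d56")
    )
    index = {(1, 2): 0, (2, 3): 1, (5, 6): 4}[pair]
    distances[index] = bad_value
    planted = _assemble_positive(rng, spec, distances=tuple(distances))
    planted.violated_pair = pair  # type: ignore[attr-defined]
    return planted


def _make_ppp_like(rng: np.random.Generator, spec: SyntheticSpec) -> _Planted:
    motif2 = list(_motif_string(rng, 2, extended=False))
    motif2[5] = "R"  # the PPP-family GDxxDRG arginine the screen rejects
    return _assemble_positive(rng, spec, motif_strings={2: "".join(motif2)})


def _delete_motif(
    planted: _Planted, motif_index: int, rng: np.random.Generator
) -> _Planted:
    """Replace one planted motif span by clean background."""
    start, end = planted.spans[motif_index - 1]
    remaining = [s for i, s in enumerate(planted.spans) if i != motif_index - 1]
    arr = planted.arr.copy()
    arr[start:end] = _background(rng, end - start)
    arr = _clean_background(arr, remaining, rng)
    spans = list(planted.spans)
    spans[motif_index - 1] = None
    flavours = list(planted.flavours)
    flavours[motif_index - 1] = None
    return _Planted(arr, spans, flavours, planted.distances, planted.n_term, planted.c_term)


def _truncate_terminal(planted: _Planted, side: str) -> _Planted:
    if side == "N":
        cut = planted.spans[0][1]  # drop everything through motif 1
        arr = planted.arr[cut:].copy()
        spans = [None] + [(s - cut, e - cut) for s, e in planted.spans[1:]]
        flavours = [None] + list(planted.flavours[1:])
        return _Planted(arr, spans, flavours, planted.distances, 0, planted.c_term)
    cut = planted.spans[5][0]  # drop motif 6 and the C terminus
    arr = planted.arr[:cut].copy()
    spans = list(planted.spans[:5]) + [None]
    flavours = list(planted.flavours[:5]) + [None]
    return _Planted(arr, spans, flavours, planted.distances, planted.n_term, 0)


def _spans_1based(spans) -> tuple:
    return tuple(None if s is None else (s[0] + 1, s[1]) for s in spans)


# ---------------------------------------------------------------------------
# Public API


def generate(spec: SyntheticSpec) -> list[SyntheticRecord]:
    """Generate the corpus described by ``spec``: positives first, then the
    decoy classes in their declared order.  Deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records: list[SyntheticRecord] = []

    # Organism assignment: a fraction of ALPH-positive organisms carries a
    # second isoform.
    organisms: list[str] = []
    org_index = 0
    while len(organisms) < spec.n_positive:
        org_index += 1
        name = f"org_{org_index:05d}"
        isoforms = 1
        if (spec.n_positive - len(organisms) >= 2
                and rng.random() < spec.multi_isoform_rate):
            isoforms = 2
        organisms.extend([name] * isoforms)

    for i in range(spec.n_positive):
        planted = _assemble_positive(rng, spec)
        record_id = f"ALPH_{i + 1:05d}"
        truth = _truth_from_planted(record_id, "alph", organisms[i], planted)
        records.append(SyntheticRecord(truth, _to_sequence(planted.arr)))

    for decoy_class in spec.decoy_classes:
        for i in range(spec.n_decoy_per_class):
            organism = f"decoy_{decoy_class}_{i + 1:05d}"
            record_id = f"DECOY_{decoy_class.upper()}_{i + 1:05d}"
            if decoy_class == "ppp_like_R6":
                planted = _make_ppp_like(rng, spec)
                truth = _truth_from_planted(record_id, decoy_class, organism, planted)
            elif decoy_class == "distance_violation":
                planted = _make_distance_violation(rng, spec)
                truth = _truth_from_planted(
                    record_id, decoy_class, organism, planted,
                    violated_pair=getattr(planted, "violated_pair", None),
                )
            elif decoy_class == "one_missing":
                base = _assemble_positive(rng, spec)
                missing = int(rng.integers(1, 7))
                planted = _delete_motif(base, missing, rng)
                truth = SyntheticTruth(
                    record_id, decoy_class, organism,
                    _spans_1based(planted.spans), tuple(planted.flavours),
                    planted.distances, planted.n_term, planted.c_term,
                    missing_index=missing,
                )
            elif decoy_class == "terminal_truncation":
                base = _assemble_positive(rng, spec)
                side = "N" if rng.integers(2) else "C"
                planted = _truncate_terminal(base, side)
                truth = SyntheticTruth(
                    record_id, decoy_class, organism,
                    _spans_1based(planted.spans), tuple(planted.flavours),
                    planted.distances, planted.n_term, planted.c_term,
                    missing_index=1 if side == "N" else 6,
                    truncated_side=side,
                )
            elif decoy_class == "random_background":
                length = (
                    _sample_terminus(rng, spec.n_term_median, spec.term_sigma)
                    + sum(MOTIF_LENGTHS.values())
                    + sum(
                        spec.distance_models[n].sample(rng)
                        for n in ("d12", "d23", "d34", "d45", "d56")
                    )
                    + _sample_terminus(rng, spec.c_term_median, spec.term_sigma)
                )
                arr = _clean_background(_background(rng, max(length, 30)), [], rng)
                truth = SyntheticTruth(
                    record_id, decoy_class, organism,
                    (None,) * 6, (None,) * 6, None, None, None,
                )
                records.append(SyntheticRecord(truth, _to_sequence(arr)))
                continue
            else:  # pragma: no cover - guarded by SyntheticSpec validation
                raise SyntheticSpecError(decoy_class)
            records.append(SyntheticRecord(truth, _to_sequence(planted.arr)))
    _verify_planted(records)
    return records


def _verify_planted(records: Sequence[SyntheticRecord]) -> None:
    """Self-audit: every recorded span must match its motif under the
    recorded flavour."""
    narrow = builtin_matrices("narrow")
    extended = builtin_matrices("extended")
    for record in records:
        truth = record.truth
        for k, (span, flavour) in enumerate(zip(truth.spans, truth.flavours), start=1):
            if span is None:
                continue
            window = record.sequence[span[0] - 1 : span[1]]
            if truth.label == "ppp_like_R6" and k == 2:
                if matches_at(window, narrow[1]) or matches_at(window, extended[1]):
                    raise RuntimeError(f"{truth.record_id}: decoy motif 2 matches")
                continue
            if flavour == "narrow":
                ok = matches_at(window, narrow[k - 1])
            else:
                ok = matches_at(window, extended[k - 1]) and not matches_at(
                    window, narrow[k - 1]
                )
            if not ok:
                raise RuntimeError(
                    f"{truth.record_id}: planted motif {k} span does not match "
                    f"its recorded flavour"
                )


def perturb_to_missing(
    record: SyntheticRecord, motif_index: int, seed: int
) -> SyntheticRecord:
    """Replace one planted motif of a positive by clean background.

    The replacement is rejection-sampled so the new window matches no
    flavour of any motif; an unconvergent replacement raises rather than
    emitting an ambiguous fixture.
    """
    if record.truth.label != "alph":
        raise ValueError("perturb_to_missing expects a planted positive")
    if motif_index not in MOTIF_LENGTHS:
        raise ValueError(f"missing motif index must be 1..6, got {motif_index}")
    rng = np.random.default_rng(seed)
    spans0 = [
        (s - 1, e) for s, e in record.truth.spans
    ]  # back to 0-based half-open
    planted = _Planted(
        np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8).copy(),
        spans0,
        list(record.truth.flavours),
        record.truth.distances,
        record.truth.n_term_len,
        record.truth.c_term_len,
    )
    perturbed = _delete_motif(planted, motif_index, rng)
    truth = SyntheticTruth(
        record_id=record.truth.record_id,
        label="one_missing",
        organism=record.truth.organism,
        spans=_spans_1based(perturbed.spans),
        flavours=tuple(perturbed.flavours),
        distances=perturbed.distances,
        n_term_len=perturbed.n_term,
        c_term_len=perturbed.c_term,
        missing_index=motif_index,
    )
    return SyntheticRecord(truth, _to_sequence(perturbed.arr))


def truth_frame(records: Sequence[SyntheticRecord]) -> pd.DataFrame:
    """Flat truth table, one row per record."""
    rows = []
    for record in records:
        truth = record.truth
        row: dict = {
            "record_id": truth.record_id,
            "label": truth.label,
            "organism": truth.organism,
            "missing_index": truth.missing_index,
            "truncated_side": truth.truncated_side,
            "n_term_len": truth.n_term_len,
            "c_term_len": truth.c_term_len,
            "length": len(record.sequence),
        }
        for k in range(1, 7):
            span = truth.spans[k - 1]
            row[f"m{k}_start"] = span[0] if span else None
            row[f"m{k}_end"] = span[1] if span else None
            row[f"m{k}_flavour"] = truth.flavours[k - 1]
        for name, value in zip(
            ("d12", "d23", "d34", "d45", "d56"), truth.distances or (None,) * 5
        ):
            row[name] = value
        rows.append(row)
    return pd.DataFrame(rows)


def write_corpus(
    records: Sequence[SyntheticRecord], fasta_path, truth_path
) -> None:
    """Write the corpus as FASTA plus a truth TSV (byte-stable)."""
    fasta_path = Path(fasta_path)
    fasta_path.parent.mkdir(parents=True, exist_ok=True)
    with open(fasta_path, "w", encoding="utf-8") as handle:
        for record in records:
            handle.write(
                f">{record.truth.record_id} label={record.truth.label} "
                f"organism={record.truth.organism}\n"
            )
            seq = record.sequence
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")
    frame = truth_frame(records)
    truth_path = Path(truth_path)
    truth_path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(truth_path, sep="\t", index=False, lineterminator="\n")
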