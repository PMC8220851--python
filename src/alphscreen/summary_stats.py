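"""Corpus-level characterisation of a set of ALPH annotations.

Computes the family's descriptive statistics over a screened corpus:
per-group and overall presence/absence counts, the ALPH-isoform histogram
per organism, medians and IQRs of the N-terminus, catalytic domain and
C-terminus lengths, inter-motif distance histograms with fraction-in-range
statistics for the conserved spacings, extended-matrix usage, and
position-by-residue count matrices of the matched motif strings (a
plain-text export consumable by sequence-logo tools).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_model import MOTIF_LENGTHS
from .screener import AlphCall

__all__ = [
    "DEFAULT_DISTANCE_RANGES",
    "GroupSummary",
    "CorpusSummary",
    "IsoformHistogram",
    "summarise",
    "motif_count_matrix",
    "write_count_matrix",
    "isoform_histogram",
]

logger = logging.getLogger("alphscreen")

DISTANCE_NAMES = ("d12", "d23", "d34", "d45", "d56")

#: Highlighted windows for the fraction-in-range statistics of each
#: conserved spacing (residue gaps between consecutive motifs).
DEFAULT_DISTANCE_RANGES: dict[str, tuple[tuple[int, int], ...]] = {
    "d12": ((28, 30), (29, 29)),
    "d23": ((26, 26), (25, 33)),
    "d34": ((55, 64),),
    "d56": ((19, 19),),
}

UNASSIGNED_GROUP = "unassigned"


@dataclass
class IsoformHistogram:
    """Distribution of ALPH counts per organism."""

    counts: dict  # isoform count -> number of organisms
    n_organisms: int
    n_positive: int

    @property
    def multi_isoform_fraction(self) -> float:
        """Fraction of ALPH-positive organisms with more than one isoform."""
        if not self.n_positive:
            return 0.0
        multi = sum(n for count, n in self.counts.items() if count > 1)
        return multi / self.n_positive


@dataclass
class GroupSummary:
    """Summary statistics for one phylogenetic group (or the whole corpus)."""

    n_organisms_screened: int
    n_organisms_with_alph: int
    n_alph_proteins: int
    isoforms: IsoformHistogram
    length_stats: dict  # segment -> {median, q1, q3}
    distance_histograms: dict  # distance name -> {value: count}
    distance_fractions: dict  # "d12_in_28_30" -> fraction
    extended_motif_fraction: float
    extended_call_fraction: float


@dataclass
class CorpusSummary:
    """Overall and per-group summaries plus the convention metadata."""

    overall: GroupSummary
    per_group: dict = field(default_factory=dict)
    distance_convention: str = "gap"

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-group view of the headline numbers."""
        rows = []
        for name, group in [("overall", self.overall), *sorted(self.per_group.items())]:
            row = {
                "group": name,
                "organisms_screened": group.n_organisms_screened,
                "organisms_with_alph": group.n_organisms_with_alph,
                "alph_proteins": group.n_alph_proteins,
                "multi_isoform_fraction": round(group.isoforms.multi_isoform_fraction, 4),
                "extended_motif_fraction": round(group.extended_motif_fraction, 4),
                "extended_call_fraction": round(group.extended_call_fraction, 4),
            }
            for segment, stats in group.length_stats.items():
                row[f"{segment}_median"] = stats["median"]
            for key, value in group.distance_fractions.items():
                row[key] = round(value, 4)
            rows.append(row)
        return pd.DataFrame(rows)


def _quartiles(values: Sequence[float]) -> dict:
    if len(values) == 0:
        return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    arr = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(arr)),
        "q1": float(np.percentile(arr, 25)),
        "q3": float(np.percentile(arr, 75)),
    }


def isoform_histogram(counts_by_organism: Mapping[str, int]) -> IsoformHistogram:
    """Histogram of ALPH isoform counts per organism (zero counts allowed
    and reported)."""
    histogram: dict[int, int] = {}
    for count in counts_by_organism.values():
        histogram[count] = histogram.get(count, 0) + 1
    positive = sum(1 for c in counts_by_organism.values() if c > 0)
    return IsoformHistogram(
        counts=dict(sorted(histogram.items())),
        n_organisms=len(counts_by_organism),
        n_positive=positive,
    )


def _group_stats(
    annotations: pd.DataFrame,
    organisms: Sequence[str],
    distance_ranges: Mapping[str, tuple],
) -> GroupSummary:
    counts_by_organism = {org: 0 for org in organisms}
    for org in annotations["organism"]:
        counts_by_organism[org] = counts_by_organism.get(org, 0) + 1
    isoforms = isoform_histogram(counts_by_organism)

    length_stats = {
        "n_term_len": _quartiles(annotations["n_term_len"].tolist()),
        "cat_domain_len": _quartiles(annotations["cat_domain_len"].tolist()),
        "c_term_len": _quartiles(annotations["c_term_len"].tolist()),
    }

    histograms: dict[str, dict] = {}
    fractions: dict[str, float] = {}
    n = len(annotations)
    for name in DISTANCE_NAMES:
        values = annotations[name].astype(int)
        histograms[name] = {
            int(v): int(c) for v, c in values.value_counts().sort_index().items()
        }
        for lo, hi in distance_ranges.get(name, ()):
            key = f"{name}_in_{lo}_{hi}" if lo != hi else f"{name}_eq_{lo}"
            fractions[key] = float(((values >= lo) & (values <= hi)).mean()) if n else 0.0

    extended = annotations["extended_count"].astype(int)
    return GroupSummary(
        n_organisms_screened=len(counts_by_organism),
        n_organisms_with_alph=isoforms.n_positive,
        n_alph_proteins=n,
        isoforms=isoforms,
        length_stats=length_stats,
        distance_histograms=histograms,
        distance_fractions=fractions,
        extended_motif_fraction=float(extended.sum()) / (6 * n) if n else 0.0,
        extended_call_fraction=float((extended > 0).mean()) if n else 0.0,
    )


def summarise(
    annotations: pd.DataFrame,
    group_map: Mapping[str, str] | None = None,
    organisms_screened: Sequence[str] | None = None,
    distance_ranges: Mapping[str, tuple] | None = None,
    distance_convention: str = "gap",
) -> CorpusSummary:
    """Summarise an annotation table (see
    :func:`alphscreen.proteome_io.annotations_to_frame`).

    ``organisms_screened`` lists every organism in the screen, including
    ALPH-negative ones, so presence/absence fractions are meaningful; when
    omitted, only organisms appearing in the annotations are counted.
    Organisms absent from ``group_map`` fall into an ``unassigned`` group
    with a warning.  Medians are the standard order statistic (mean of the
    central pair for even n).
    """
    if len(annotations) == 0:
        raise ValueError("summarise needs at least one annotation row")
    annotations = annotations.copy()
    if "organism" not in annotations or annotations["organism"].isna().all():
        annotations["organism"] = annotations["protein_id"]
    else:
        annotations["organism"] = annotations["organism"].fillna(
            annotations["protein_id"]
        )
    ranges = dict(DEFAULT_DISTANCE_RANGES)
    if distance_ranges is not None:
        ranges.update(distance_ranges)
    if organisms_screened is None:
        organisms_screened = sorted(set(annotations["organism"]))

    overall = _group_stats(annotations, organisms_screened, ranges)

    per_group: dict[str, GroupSummary] = {}
    if group_map is not None:
        unassigned = sorted(
            {org for org in annotations["organism"] if org not in group_map}
        )
        if unassigned:
            logger.warning(
                "%d organisms absent from the group map; counted as %r",
                len(unassigned),
                UNASSIGNED_GROUP,
            )

        def group_of(org: str) -> str:
            return group_map.get(org, UNASSIGNED_GROUP)

        groups = sorted({group_of(org) for org in organisms_screened}
                        | {group_of(org) for org in annotations["organism"]})
        for group in groups:
            member_orgs = [o for o in organisms_screened if group_of(o) == group]
            sub = annotations[annotations["organism"].map(group_of) == group]
            extra = [o for o in sub["organism"] if o not in set(member_orgs)]
            per_group[group] = _group_stats(sub, member_orgs + sorted(set(extra)), ranges)

    return CorpusSummary(
        overall=overall,
        per_group=per_group,
        distance_convention=distance_convention,
    )


AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY") + ("X",)


def motif_count_matrix(calls: Iterable[AlphCall], motif_index: int) -> pd.DataFrame:
    """Position × residue counts of the matched strings of one motif.

    Rows are 1-based window positions, columns the 20 standard residues
    plus ``X``; every column sum equals the number of calls, so the matrix
    feeds directly into count-matrix-based logo tools.
    """
    if motif_index not in MOTIF_LENGTHS:
        raise ValueError(f"motif index must be 1..6, got {motif_index}")
    length = MOTIF_LENGTHS[motif_index]
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, length + 1, name="position"), columns=list(AMINO_ACIDS)
    )
    n = 0
    for call in calls:
        matched = call.hits[motif_index - 1].matched
        for position, residue in enumerate(matched, start=1):
            if residue not in counts.columns:
                counts[residue] = 0
            counts.loc[position, residue] += 1
        n += 1
    if n == 0:
        raise ValueError("motif_count_matrix needs at least one call")
    return counts


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    """Plain-text ``position<TAB>residue counts`` export."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts.to_csv(path, sep="\t", lineterminator="\n")
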