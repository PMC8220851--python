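"""Domain architecture derived from an ALPH call.

The catalytic domain of an ALPH is defined as the region from six residues
upstream of motif 1 to eight residues downstream of motif 6, clipped to the
sequence; everything before it is the N-terminal extension and everything
after it the C-terminal extension.  All reported coordinates are 1-based
inclusive (internal computation is 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .screener import AlphCall

__all__ = [
    "CAT_DOMAIN_UPSTREAM",
    "CAT_DOMAIN_DOWNSTREAM",
    "AlphAnnotation",
    "annotate",
    "extract_catalytic_domain",
    "catalytic_domain_record",
]

#: Residues included upstream of motif 1 / downstream of motif 6.
CAT_DOMAIN_UPSTREAM = 6
CAT_DOMAIN_DOWNSTREAM = 8


@dataclass(frozen=True)
class AlphAnnotation:
    """Derived domain architecture of one ALPH protein.

    ``cat_domain_start``/``cat_domain_end`` are 1-based inclusive; the three
    segment lengths always sum to ``protein_length``.
    """

    protein_id: str
    protein_length: int
    n_term_len: int
    cat_domain_start: int
    cat_domain_end: int
    c_term_len: int
    distances: tuple[int, int, int, int, int]
    extended_count: int

    def __post_init__(self) -> None:
        cat_len = self.cat_domain_end - self.cat_domain_start + 1
        if self.n_term_len + cat_len + self.c_term_len != self.protein_length:
            raise ValueError(
                f"{self.protein_id}: segment lengths do not conserve protein length"
            )
        if not 1 <= self.cat_domain_start <= self.cat_domain_end <= self.protein_length:
            raise ValueError(f"{self.protein_id}: catalytic-domain span out of range")

    @property
    def cat_domain_len(self) -> int:
        return self.cat_domain_end - self.cat_domain_start + 1


def annotate(call: AlphCall, protein_length: int) -> AlphAnnotation:
    """Domain boundaries for a call: motif-1 start − 6 … motif-6 end + 8,
    clipped to the sequence.  Idempotent and length-conserving."""
    if protein_length < call.hits[-1].end:
        raise ValueError(
            f"{call.protein_id}: protein length {protein_length} shorter than "
            f"last motif end {call.hits[-1].end}"
        )
    start0 = max(0, call.hits[0].start - CAT_DOMAIN_UPSTREAM)
    end0 = min(protein_length, call.hits[-1].end + CAT_DOMAIN_DOWNSTREAM)
    return AlphAnnotation(
        protein_id=call.protein_id,
        protein_length=protein_length,
        n_term_len=start0,
        cat_domain_start=start0 + 1,
        cat_domain_end=end0,
        c_term_len=protein_length - end0,
        distances=call.distances,
        extended_count=call.extended_count,
    )


def extract_catalytic_domain(call: AlphCall, sequence: str) -> str:
    """The catalytic-domain subsequence for a call."""
    annotation = annotate(call, len(sequence))
    return sequence[annotation.cat_domain_start - 1 : annotation.cat_domain_end]


def catalytic_domain_record(call: AlphCall, sequence: str) -> SeqRecord:
    """FASTA record of the catalytic domain, for downstream alignment/tree
    tools."""
    annotation = annotate(call, len(sequence))
    domain = extract_catalytic_domain(call, sequence)
    return SeqRecord(
        Seq(domain),
        id=call.protein_id,
        description=(
            f"catalytic_domain {annotation.cat_domain_start}-{annotation.cat_domain_end}"
        ),
    )
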