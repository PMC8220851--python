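# Methods

## The screening model

ApaH-like phosphatases (ALPHs) are diagnosed purely by sequence: six short
motifs — the four phosphoprotein-phosphatase (PPP) signatures GDxHG,
GDxxDRG-like, GNHE and HGG (motifs 1–4) plus two ALPH-specific C-terminal
motifs (5 and 6) — occurring in order with conserved spacings. Each motif is
a window of per-position allowed-residue sets; matching is strict set
membership, not probabilistic scoring. Two built-in flavours exist:

* **narrow** — the strict sets used in the primary screening pass:
  `[G, D, VILT, HQ, G]`, `[G, DN, LMIFVT, EIVTLAC, NSATFGVQIDHM, KQN,
  GASHT]`, `[G, N, HNWQ, ED]`, `[H, AG, G]`, `[VIT, IVYFLAMT, FY, G, H]`,
  `[LVIMT, DE, STG, GASRN]` for motifs 1–6 (lengths 5, 7, 4, 3, 5, 4);
* **extended** — a relaxed superset at every position that additionally
  admits the unknown-residue token `X`/`x`. A protein may use at most
  `extended_budget = 2` motifs that match only the extended matrix.

Two hard rules sit on top of set membership:

1. **Arginine exclusion.** ALPHs replace the arginine of the PPP GDxxDRG
   motif by lysine; `R` at position 6 of motif 2 would re-admit the closely
   related ApaH/RLPH/SLP phosphatases and is rejected in every flavour.
   The exclusion is enforced inside the matcher itself, so a custom matrix
   listing `R` there is silently stripped unless it sets an explicit
   `allow_motif2_r` override.
2. **Distance bounds.** The spacings between motifs 1→2, 2→3 and 5→6 are
   restricted to 14–150, 25–80 and 17–40 residues; 3→4 and 4→5 are
   unconstrained (they are poorly conserved in the family).

### Distance convention

Whether an inter-motif distance is the gap (residues strictly between the
motifs) or start-to-start is genuinely ambiguous in the family literature.
We default to **gap length** — domain-architecture figures mark distances
between motif boxes, and a 29-residue spacer then reads as distance 29 —
and expose `DistanceConstraints(convention="start_to_start")` as a switch
so results can be recomputed under either reading. All distance statistics
carry the active convention in their metadata.

## Assignment search

Candidate occurrences of every motif are found by a vectorised window scan
(per-position boolean membership tables over the byte-encoded sequence).
A hit is labelled *narrow* when the narrow matrix matches and *extended*
only when solely the extended matrix matches. The screen then searches for
one occurrence per motif, in order, non-overlapping, within the distance
bounds, using at most the extended budget:

* depth-first over motifs in order, candidates in ascending start order,
  pruning a level as soon as a bounded consecutive spacing exceeds its
  upper limit;
* the allowed extended count is escalated 0, 1, … budget, and the first
  assignment found is returned. This yields the assignment with the
  fewest extended motifs, ties broken by the lexicographically smallest
  start tuple (leftmost) — the tie-break the family's screen leaves
  unspecified, fixed here deterministically.

Motif non-overlap is enforced (the printed spacings are all large relative
to the motif lengths, so this costs nothing on real proteins) and one call
is reported per protein; an opt-in `multi_domain` flag rescans the sequence
after the call and notes additional candidate ALPH domains (tandem-domain
proteins exist, e.g. in some fungi) without changing the call itself.

The search is exact: on every corpus we generate, its result equals
exhaustive enumeration over all 6-tuples of occurrences (checked in the
acceptance suite on 500 planted plus 500 random sequences up to ~300 aa).

## Audit modes

* **One-motif-missing scan.** For a chosen motif *k*, the remaining five
  motifs must admit a valid ordered assignment with every bound touching
  *k* waived, while the full six-motif screen is negative. This supports
  matrix curation (which motif is the screen losing?) and flags candidate
  truncated ALPHs: a missing motif 1 or 6 marks an N- or C-terminal
  truncation, typically a sequencing or annotation artefact.
* The missing scan deliberately does not attempt start-codon rescue;
  it only surfaces candidates for manual inspection.

## Domain annotation

The catalytic domain spans from 6 residues upstream of motif 1 to 8
residues downstream of motif 6, clipped to the sequence; the N- and
C-terminal extensions are the residues outside that span. The three
segment lengths always sum to the protein length (an invariant asserted on
every annotation). Reported coordinates are 1-based inclusive; internal
computation is 0-based half-open.

## Corpus summaries

`summarise` computes, overall and per user-supplied phylogenetic group:
organisms screened and with ≥1 ALPH, the isoform-count histogram and the
fraction of positive organisms with >1 isoform, median/IQR of the three
segment lengths, full distance histograms plus fraction-in-range
statistics for the conserved windows (d12 in 28–30 and exactly 29, d23
exactly 26 and in 25–33, d34 in 55–64, d56 exactly 19), and
extended-matrix usage (fraction of motifs; fraction of proteins). Medians
are the standard order statistic. Group mapping is user data, not
hard-coded taxonomy; organisms absent from the map fall into an
`unassigned` group with a warning. Fractions are reported at full
precision with a rounded 1-decimal view in the flat table.

`motif_count_matrix` tallies residues per window position across the
matched strings of one motif and exports a `position<TAB>residue counts`
text matrix for sequence-logo tools; each position's counts sum to the
number of calls.

## Synthetic corpora

The generator emulates the screen's assumptions so every other module is
testable without downloading proteomes:

* **Positives** sample one residue per motif position from the narrow sets
  (or, for a protein's single extended motif, one position from the
  extended-only residues, possibly `X`), join motifs with background
  spacers drawn from the spacing distributions above, and pad termini so
  the *annotated* extensions follow log-normals with medians 87 (N) and 26
  (C) residues, σ = 0.6. The default per-protein extended-matrix rate is
  0.113 with at most one extended motif (extended usage is rare in real
  screens and never reaches two per protein), and 25 % of ALPH-positive
  organisms carry a second isoform. Spacing defaults place 93.7 % of d12
  in 28–30 (72 % exactly 29), 83 % of d23 at 26 (98 % within 25–33), 94 %
  of d34 in 55–64, and 92.5 % of d56 at 19, with the remaining mass spread
  over the legal bounds; d45 is broad (uniform 30–120).
* **Decoys** violate exactly one property each: `ppp_like_R6` (arginine at
  motif-2 position 6), `distance_violation` (one constrained spacing
  outside its bounds), `one_missing` (one motif replaced by background),
  `terminal_truncation` (sequence cut to remove motif 1 or 6), and
  `random_background`.
* **Clean labels by rejection sampling.** Background residues are uniform
  over the 20 standard amino acids and resampled until no motif matrix (in
  extended flavour, which subsumes narrow) matches any window overlapping
  background. Windows fully inside a planted span of another motif are
  permitted — ordering and non-overlap make them unusable in any
  alternative assignment — so the screen's optimum provably coincides
  with the planted truth. The resampling loop is bounded (500 rounds) and
  raises rather than emit an ambiguous fixture; every generated corpus is
  additionally self-audited against the recorded spans and flavours.

Because spacers are uniform-random and rejection-cleaned, passing tests
demonstrate correctness of the screen's logic, not robustness to
homologous near-motifs or compositionally biased real proteomes; the
published corpus numbers require the pinned proteome releases and are out
of desk-scale reach (see `scripts/replicate_full_corpus.py`).

## Numerical and interface choices

* Sequences are uppercased on ingest; `*`, gaps, `B/Z/U/O` and other
  non-standard codes never match any position. Lower-case `x` folds into
  `X`, which matches only where a matrix set contains `X` (the extended
  flavour, or a custom matrix that lists it).
* Custom matrices use an INI-style text format (`[motif k]` sections, one
  `position = residues` line each, optional `[motif k relaxed]` tier and
  an `[options] allow_motif2_r` switch); all six motifs must be defined at
  the built-in lengths, and errors name the offending motif.
* Duplicate FASTA ids get stable `__dupN` suffixes with a warning;
  malformed FASTA (sequence before header, header without sequence) is a
  hard error with a line number.
* TSV outputs have fixed column orders and LF line endings; identical
  inputs give byte-identical files.
* CLI exit codes: 0 success (including zero hits), 1 usage error, 2 data
  error; a failing command removes the outputs it had already written and
  every command writes a `manifest.json` echoing its resolved options.

## Problem sizes

The test suite validates oracle equivalence on 500 planted + 500 random
sequences, planted-truth recovery on 1 000 positives + 1 250 decoys
(precision = recall = 1.0, spans and flavours exact), and parameter
recovery on a 10 000-protein corpus within three binomial standard errors.
`scripts/acceptance.py` regenerates a 5 000-positive / 1 500-decoy corpus
from a user seed and recomputes all headline quantities from scratch.

## Known limitations

* Set-membership matrices carry no position weighting; a PSSM would rank
  borderline windows but is deliberately out of scope.
* The screen counts proteins, not domains; tandem ALPH domains are only
  noted, not called separately.
* Localisation prediction, BLAST-based controls, phylogeny and the
  iterative manual matrix training that produced the built-in sets are out
  of scope; the matrices are taken as fixed inputs.
* The distance convention affects the printed spacing statistics; compare
  across conventions via the exposed switch before matching numbers from
  other sources.
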