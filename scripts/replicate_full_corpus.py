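#!/usr/bin/env python
"""Full-corpus replication driver.

Screens a directory of reference-proteome FASTA files (one file per
organism, plain or gzipped) and reports the corpus headline numbers: how
many organisms carry at least one ALPH, the total ALPH count, and the
Fig-2-style distance/size statistics.  Proteomes are not downloaded here;
fetch the UniProt reference proteomes (release 2019_02) and the TriTrypDB
Kinetoplastida proteomes (February 2019) to reproduce the published
corpus, or point the script at any proteome collection.

Usage:
    python scripts/replicate_full_corpus.py PROTEOME_DIR --out OUT_DIR \
        [--group-map groups.tsv]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from alphscreen.annotator import annotate
from alphscreen.proteome_io import (
    annotations_to_frame,
    outcomes_to_frame,
    read_group_map,
    read_proteome,
    write_table,
)
from alphscreen.screener import screen_protein
from alphscreen.summary_stats import isoform_histogram, summarise


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("proteome_dir", type=Path)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--group-map", type=Path, default=None)
    parser.add_argument("--extended-budget", type=int, default=2)
    args = parser.parse_args()

    fastas = sorted(
        p for p in args.proteome_dir.iterdir()
        if p.suffix in {".fasta", ".fa", ".gz"} or p.name.endswith(".fasta.gz")
    )
    if not fastas:
        raise SystemExit(f"no FASTA files found in {args.proteome_dir}")

    outcomes = []
    annotations = []
    organisms: dict[str, str] = {}
    counts_by_organism: dict[str, int] = {}
    for fasta in fastas:
        # One proteome file == one organism; the file stem is the fallback
        # label when headers carry no OS=/organism= field.
        label = fasta.name.split(".")[0]
        counts_by_organism.setdefault(label, 0)
        for record in read_proteome(fasta):
            outcome = screen_protein(
                record.record_id,
                record.sequence,
                extended_budget=args.extended_budget,
            )
            outcomes.append(outcome)
            if outcome.status == "alph":
                annotations.append(annotate(outcome.call, len(record.sequence)))
                organisms[record.record_id] = label
                counts_by_organism[label] += 1
        print(f"{fasta.name}: {counts_by_organism[label]} ALPH proteins")

    args.out.mkdir(parents=True, exist_ok=True)
    write_table(outcomes_to_frame(outcomes), args.out / "outcomes.tsv")
    frame = annotations_to_frame(annotations, organisms)
    write_table(frame, args.out / "annotations.tsv")

    histogram = isoform_histogram(counts_by_organism)
    headline = {
        "organisms_screened": histogram.n_organisms,
        "organisms_with_alph": histogram.n_positive,
        "alph_proteins": len(annotations),
        "multi_isoform_fraction": round(histogram.multi_isoform_fraction, 4),
    }
    if annotations:
        group_map = read_group_map(args.group_map) if args.group_map else None
        summary = summarise(
            frame,
            group_map=group_map,
            organisms_screened=sorted(counts_by_organism),
        )
        write_table(summary.to_frame(), args.out / "summary.tsv")
        headline["distance_fractions"] = {
            k: round(v, 4) for k, v in summary.overall.distance_fractions.items()
        }
    (args.out / "headline.json").write_text(json.dumps(headline, indent=2) + "\n")
    print(json.dumps(headline, indent=2))


if __name__ == "__main__":
    main()
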