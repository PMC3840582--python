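"""Cascade annotation and conserved miRNA family classification.

Runs the first-match annotation cascade (rRNA/tRNA/sn/sno/scRNA ->
repeats -> exons; native tier at <=1 edit, relative tier at <=2), then
classifies the unannotated tags against known mature miRNAs (native pass
<=1 non-seed edit, other-plant pass <=3) and applies the 15-RPM abundance
filter to families not described in close relatives.  Writes
results/03_annotation_ledger.tsv and 03_families.tsv, and the remaining
unannotated/exon tag lists for the downstream steps.
"""

import dataclasses

import pandas as pd

from _paths import RESULTS, SCRATCH, SIM
from bolmir.core import TagTable, read_fasta
from bolmir.homology import (
    RefSet,
    annotate_cascade,
    classify_conserved,
    filter_families,
    parse_mature_header,
)


def load_refsets():
    refsets = []
    for fa in sorted(SIM.glob("ref_*.fasta")):
        _, category, tier = fa.stem.split("_")
        refsets.append(RefSet(category=category, sequences=read_fasta(fa), native=tier == "native"))
    refsets.sort(key=lambda r: (["rRNA", "tRNA", "snRNA", "snoRNA", "scRNA", "repeat"].index(r.category), not r.native))
    refsets.append(RefSet(category="exon", sequences=read_fasta(SIM / "transcripts.fasta"), native=True))
    return refsets


def main() -> None:
    table = TagTable.from_tsv(SCRATCH / "tag_table.tsv")
    records, ledger = annotate_cascade(table, load_refsets())
    ledger.to_csv(RESULTS / "03_annotation_ledger.tsv", sep="\t", index=False)
    unannot = [s for s, r in records.items() if r.category == "unannotated"]
    exon = [s for s, r in records.items() if r.category == "exon"]
    print(f"cascade: {len(table.tags)} tags -> {len(unannot)} unannotated, {len(exon)} exon-derived")

    matures = [parse_mature_header(h, s) for h, s in read_fasta(SIM / "mature_mirnas.fasta").items()]
    brass = set((SIM / "brassicaceae_families.txt").read_text().split())
    assignments = classify_conserved(
        unannot, [m for m in matures if m.native], [m for m in matures if not m.native]
    )
    kept, dropped = filter_families(assignments, table, brass)
    pd.DataFrame(
        [{**dataclasses.asdict(f), "kept": True} for f in kept]
        + [{**dataclasses.asdict(f), "kept": False} for f in dropped]
    ).to_csv(RESULTS / "03_families.tsv", sep="\t", index=False)
    print(f"conserved: {len(assignments)} tags in {len(kept)} kept families, {len(dropped)} dropped")
    stars = sum(1 for a in assignments if a.is_star)
    print(f"  including {stars} miRNA* tags")

    assigned = {a.tag_seq for a in assignments if a.family in {f.family for f in kept}}
    (SCRATCH / "unannotated_tags.txt").write_text("\n".join(s for s in unannot if s not in assigned))
    (SCRATCH / "exon_tags.txt").write_text("\n".join(exon))
    pd.DataFrame(
        [
            {"tag": a.tag_seq, "family": a.family, "source": a.source_mirna,
             "is_star": a.is_star, "edits": a.evidence.edits}
            for a in assignments
        ]
    ).to_csv(SCRATCH / "conserved_assignments.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
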