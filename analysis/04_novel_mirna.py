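"""Novel miRNA prediction from the unannotated tags.

Maps the remaining unannotated tags exactly onto the genomic contigs,
excises +/-250/50-nt windows around each hit, folds them, applies the
structural rules (MFE <= -18 kcal/mol, >= 16 duplex pairs, bulge and
asymmetry <= 4 nt, mature on one arm) and the arm-dominance curation.
As a negative control the same tags are mapped onto a dinucleotide-
shuffled genome, which must yield no accepted hairpin.  Writes
results/04_novel_mirnas.tsv and 04_novel_mirnas.gff3.
"""

import numpy as np
import pandas as pd

from _paths import RESULTS, SCRATCH, SEED, SIM
from bolmir.core import TagTable, read_fasta, rna
from bolmir.novel import (
    dominance_filter,
    evaluate_hairpin,
    excise_candidates,
    map_tags,
    to_gff3,
)
from bolmir.simulate import dinucleotide_shuffle


def predict(tags, genome, tag_counts):
    hits = map_tags(tags, genome, max_mismatch=0)
    accepted, seen = [], set()
    for hit in hits:
        for cand in excise_candidates(hit, rna(genome[hit.ref_id])):
            key = (cand.ref_id, cand.strand, cand.precursor_start, cand.mature_span)
            if key in seen:
                continue
            seen.add(key)
            if evaluate_hairpin(cand)[0]:
                accepted.append(cand)
    return dominance_filter(accepted, hits, tag_counts), hits


def main() -> None:
    table = TagTable.from_tsv(SCRATCH / "tag_table.tsv")
    tag_counts = {t.seq: t.total() for t in table.tags}
    tags = (SCRATCH / "unannotated_tags.txt").read_text().split()
    genome = read_fasta(SIM / "genome.fasta")

    novel, hits = predict(tags, genome, tag_counts)
    rows = [
        {"name": f"novel_{i + 1}", "mature_seq": c.mature_seq, "ref_id": c.ref_id,
         "arm": c.arm, "mfe": c.mfe, "duplex_pairs": c.duplex_pairs,
         "max_bulge": c.max_bulge, "asymmetry": c.asymmetry,
         "dominance": round(c.dominance, 3), "count": tag_counts.get(c.mature_seq, 0),
         "precursor_seq": c.precursor_seq, "structure": c.structure}
        for i, c in enumerate(novel)
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "04_novel_mirnas.tsv", sep="\t", index=False)
    (RESULTS / "04_novel_mirnas.gff3").write_text(to_gff3(novel))
    print(f"{len({h.tag_seq for h in hits})} tags mapped; {len(novel)} hairpins accepted")
    for r in rows[:5]:
        print(f"  {r['name']} {r['mature_seq']} ({r['arm']} arm, mfe {r['mfe']:.1f}, "
              f"dominance {r['dominance']})")

    rng = np.random.default_rng(SEED + 1000)
    shuffled = {k: dinucleotide_shuffle(v, rng) for k, v in genome.items()}
    null, _ = predict(tags, shuffled, tag_counts)
    print(f"dinucleotide-shuffled genome control: {len(null)} accepted (expect 0)")


if __name__ == "__main__":
    main()
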