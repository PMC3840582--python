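"""Target prediction for the discovered miRNAs and GO enrichment.

Aligns every kept conserved miRNA and accepted novel mature against the
transcript set (+5 canonical / +2 G:U, 4x seed scaling; accept at score
>= 130, duplex energy <= -17 kcal/mol, clean seed), then tests the target
gene set for GO term overrepresentation (term-for-term, Bonferroni).
Writes results/06_targets.tsv and 06_go_enrichment.tsv.
"""

import dataclasses

import pandas as pd

from _paths import RESULTS, SCRATCH, SIM
from bolmir.core import read_fasta
from bolmir.enrichment import read_annotation_tsv, term_for_term
from bolmir.targets import find_targets, format_alignment


def main() -> None:
    assignments = pd.read_csv(SCRATCH / "conserved_assignments.tsv", sep="\t")
    novel = pd.read_csv(RESULTS / "04_novel_mirnas.tsv", sep="\t")
    mirnas = {
        row["source"]: row["tag"]
        for _, row in assignments.iterrows()
        if not row["is_star"]
    }
    for _, row in novel.iterrows():
        mirnas[row["name"]] = row["mature_seq"]
    transcripts = read_fasta(SIM / "transcripts.fasta")

    hits = find_targets(mirnas, transcripts)
    pd.DataFrame(
        [
            {"mirna": h.mirna_id, "target": h.target_id, "start": h.target_span[0],
             "end": h.target_span[1], "score": h.score, "mfe": h.duplex_mfe,
             "rank": h.rank, "pairs": h.pair_string}
            for h in hits
        ]
    ).to_csv(RESULTS / "06_targets.tsv", sep="\t", index=False)
    print(f"{len(hits)} target sites accepted for {len(mirnas)} miRNAs")
    if hits:
        print(format_alignment(hits[0]))

    amap = read_annotation_tsv(SIM / "go_annotations.tsv")
    population = sorted(set(transcripts) | amap.genes())
    study = sorted({h.target_id for h in hits})
    results = term_for_term(study, population, amap)
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        RESULTS / "06_go_enrichment.tsv", sep="\t", index=False
    )
    for r in results:
        flag = " *" if r.p_adj <= 0.05 else ""
        print(f"  {r.term}: {r.study_count}/{r.study_size} vs {r.pop_count}/{r.pop_size} "
              f"p_adj={r.p_adj:.3g}{flag}")


if __name__ == "__main__":
    main()
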