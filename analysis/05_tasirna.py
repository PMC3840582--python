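"""Phased tasiRNA locus detection.

Feeds the unannotated tags together with the exon-derived tags (TAS
transcripts are protein-coding-like, so their fragments annotate as exon)
into the 21-nt phasing scan: windows of 11 cycles, hypergeometric tail
per register, loci at p <= 1e-3, abundance floor of 4 reads per position.
Known-TAS homology (<=1 edit) names the loci that match provided
tasiRNAs.  Writes results/05_tas_loci.tsv.
"""

import pandas as pd

from _paths import RESULTS, SCRATCH, SIM
from bolmir.core import TagTable, read_fasta, rna
from bolmir.novel import map_tags
from bolmir.tasi import WORDING_NOTE, call_tas_loci, match_known_tas, scan_phasing


def main() -> None:
    print(f"note: {WORDING_NOTE}")
    table = TagTable.from_tsv(SCRATCH / "tag_table.tsv")
    tag_counts = {t.seq: t.total() for t in table.tags}
    tags = (SCRATCH / "unannotated_tags.txt").read_text().split()
    tags += (SCRATCH / "exon_tags.txt").read_text().split()
    tags = [t for t in tags if len(t) == 21]
    genome = {k: rna(v) for k, v in read_fasta(SIM / "genome.fasta").items()}

    hits = map_tags(tags, genome, max_mismatch=0)
    pileups = {}
    for h in hits:
        if h.strand != "+":
            continue
        pileups.setdefault(h.ref_id, {})
        pileups[h.ref_id][h.start] = pileups[h.ref_id].get(h.start, 0) + tag_counts.get(h.tag_seq, 0)

    loci = []
    for rid in sorted(pileups):
        windows = scan_phasing(pileups[rid], len(genome[rid]), rid)
        loci.extend(call_tas_loci(windows, pileups[rid], genome[rid]))

    known = match_known_tas(tags, read_fasta(SIM / "known_tas.fasta"))
    for locus in loci:
        for tag in locus.member_tags:
            if tag in known:
                locus.known_tas_match = known[tag]

    pd.DataFrame(
        [
            {"ref_id": l.ref_id, "start": l.start, "end": l.end, "p_value": l.p_value,
             "n_tasirnas": len(l.member_tags), "known_tas_match": l.known_tas_match}
            for l in loci
        ]
    ).to_csv(RESULTS / "05_tas_loci.tsv", sep="\t", index=False)
    n_tasi = sum(len(l.member_tags) for l in loci)
    print(f"{len(loci)} phased loci called ({n_tasi} tasiRNAs)")
    for l in loci:
        extra = f", matches {l.known_tas_match}" if l.known_tas_match else ""
        print(f"  {l.ref_id}:{l.start}-{l.end} p={l.p_value:.2e}{extra}")


if __name__ == "__main__":
    main()
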