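"""Clean the raw libraries, collapse to unique tags, normalize to RPM.

Applies the pipeline's read-cleaning rules (N bases, Q10/Q13 counts, 3'
adapter presence, 18-nt minimum insert, 5'-adapter and poly-A exclusion),
collapses survivors into unique tags with per-library counts and
reads-per-million normalization, and summarizes the insert length
distribution.  Writes results/02_qc_report.tsv, 02_length_distribution.tsv
and the tag table to scratch/analysis/tag_table.tsv.
"""

import pandas as pd

from _paths import RESULTS, SCRATCH, SIM
from bolmir.core import collapse_tags, length_distribution, normalize_counts, read_fastq
from bolmir.qc import qc_filter
from bolmir.simulate import SimConfig

ADAPTER3 = SimConfig().adapter3
ADAPTER5 = SimConfig().adapter5


def main() -> None:
    clean = {}
    rows = []
    for fq in sorted(SIM.glob("lib*.fastq")):
        lib = fq.stem
        inserts, rep = qc_filter(read_fastq(fq), ADAPTER3, ADAPTER5)
        clean[lib] = inserts
        rows.append({"library": lib, **rep.to_dict()})
        print(f"{lib}: {rep.clean_reads}/{rep.input_reads} reads clean "
              f"({100 * rep.clean_reads / rep.input_reads:.1f}%)")
    pd.DataFrame(rows).to_csv(RESULTS / "02_qc_report.tsv", sep="\t", index=False)

    table = normalize_counts(collapse_tags(clean))
    table.to_tsv(SCRATCH / "tag_table.tsv")
    print(f"collapsed to {len(table.tags)} unique tags")

    dist = length_distribution(table, weighted=True)
    pd.DataFrame([{"length": k, "fraction": v} for k, v in dist.items()]).to_csv(
        RESULTS / "02_length_distribution.tsv", sep="\t", index=False
    )
    mode = max(dist, key=dist.get)
    print(f"modal insert length {mode} nt ({100 * dist[mode]:.1f}% of clean reads)")


if __name__ == "__main__":
    main()
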