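"""bolmir: small-RNA sequencing analysis of Brassica oleracea leaf libraries.

Read QC, unique-tag collapsing, cascading annotation against ncRNA/repeat/
exon references, conserved miRNA family classification, novel hairpin
discovery, phased tasiRNA detection, complementarity-based target
prediction and GO term enrichment — with a synthetic-data generator that
plants every class of molecule with known ground truth.
"""

__version__ = "0.1.0"

from importlib import resources as _resources

import pandas as _pd


def load_northern_panel() -> "_pd.DataFrame":
    """The packaged northern-blot validation panel (13 miRNAs).

    Columns: miRNA name, sequence (four novel candidates in the DNA
    alphabet, conserved miRNAs in RNA), printed sequence length and the
    mean normalized read count supporting each molecule.
    """
    with _resources.files("bolmir").joinpath("data/northern_panel.tsv").open() as fh:
        return _pd.read_csv(fh, sep="\t")
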