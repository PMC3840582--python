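"""Shared locations for the numbered analysis scripts.

Bulky intermediates (FASTQ libraries, reference FASTAs) live under
``scratch/analysis``; the tables each step reports live under ``results``.
Every script seeds from SEED so the chain is reproducible end to end.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
SIM = SCRATCH / "sim"
RESULTS = ROOT / "results"

SEED = 1
READS_PER_LIBRARY = 50_000
N_LIBRARIES = 3

RESULTS.mkdir(parents=True, exist_ok=True)
SCRATCH.mkdir(parents=True, exist_ok=True)
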