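"""Shared domain types and tag-level bookkeeping for the small-RNA pipeline.

Everything downstream of the sequencer operates on *unique tags*: distinct
insert sequences with per-library read counts.  This module holds the tag
container, FASTQ/FASTA input, RPM normalization and the length-distribution
summaries used for library QC plots.

Sequences are stored in the RNA alphabet: T is normalized to U on input so
that DNA-alphabet references (e.g. genomic contigs) and RNA-alphabet mature
miRNAs collapse onto the same tag space.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "SmallRNARead",
    "UniqueTag",
    "TagTable",
    "PipelineConfig",
    "AnnotationRecord",
    "CATEGORIES",
    "rna",
    "dna",
    "revcomp",
    "read_fastq",
    "read_fasta",
    "write_fasta",
    "collapse_tags",
    "normalize_counts",
    "length_distribution",
]

#: annotation categories in cascade priority order (first match wins);
#: conserved_miRNA / miRNA_star / novel_miRNA / tasiRNA are assigned by the
#: dedicated stages, `unannotated` is the fall-through.
CATEGORIES = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "scRNA",
    "repeat",
    "exon",
    "conserved_miRNA",
    "miRNA_star",
    "novel_miRNA",
    "tasiRNA",
    "unannotated",
)

_RNA_TABLE = str.maketrans("Tt", "Uu")
_DNA_TABLE = str.maketrans("Uu", "Tt")
_COMP_RNA = str.maketrans("ACGUN", "UGCAN")


def rna(seq: str) -> str:
    """Uppercase RNA-alphabet form of *seq* (T -> U)."""
    return seq.upper().translate(_RNA_TABLE)


def dna(seq: str) -> str:
    """Uppercase DNA-alphabet form of *seq* (U -> T)."""
    return seq.upper().translate(_DNA_TABLE)


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return rna(seq).translate(_COMP_RNA)[::-1]


class FastqParseError(ValueError):
    """Raised on a malformed FASTQ record; carries the record index."""


@dataclass(frozen=True)
class SmallRNARead:
    """A raw sequencer read: id, bases and per-base Phred scores."""

    read_id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"empty read {self.read_id!r}")
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} "
                f"!= quality length {len(self.qual)}"
            )


@dataclass
class UniqueTag:
    """A distinct insert sequence with per-library raw and normalized counts."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)
    norm: dict[str, float] = field(default_factory=dict)
    mean_norm: float = 0.0

    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TagTable:
    """Unique tags of one experiment plus the per-library clean-read totals.

    ``library_totals`` are the denominators for RPM normalization and for the
    per-category percentages of the annotation ledger.
    """

    library_ids: list[str]
    tags: list[UniqueTag]
    library_totals: dict[str, int]

    def __post_init__(self) -> None:
        seqs = [t.seq for t in self.tags]
        if len(seqs) != len(set(seqs)):
            raise ValueError("tag sequences must be pairwise distinct")

    def by_seq(self) -> dict[str, UniqueTag]:
        return {t.seq: t for t in self.tags}

    def subset(self, seqs: Iterable[str]) -> "TagTable":
        """New table restricted to *seqs*; totals are kept (denominators)."""
        wanted = set(seqs)
        return TagTable(
            library_ids=list(self.library_ids),
            tags=[t for t in self.tags if t.seq in wanted],
            library_totals=dict(self.library_totals),
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for t in self.tags:
            row = {"seq": t.seq, "length": len(t.seq)}
            for lib in self.library_ids:
                row[f"count_{lib}"] = t.counts.get(lib, 0)
            for lib in self.library_ids:
                row[f"norm_{lib}"] = t.norm.get(lib, 0.0)
            row["mean_norm"] = t.mean_norm
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write("#totals\t" + "\t".join(f"{l}={self.library_totals[l]}" for l in self.library_ids) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagTable":
        import pandas as pd

        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#totals\t"):
                raise ValueError("tag table TSV missing #totals header")
            totals = {
                kv.split("=")[0]: int(kv.split("=")[1]) for kv in header.split("\t")[1:]
            }
            df = pd.read_csv(fh, sep="\t")
        libs = list(totals)
        tags = []
        for _, row in df.iterrows():
            tags.append(
                UniqueTag(
                    seq=row["seq"],
                    counts={l: int(row[f"count_{l}"]) for l in libs if row[f"count_{l}"] > 0},
                    norm={l: float(row[f"norm_{l}"]) for l in libs},
                    mean_norm=float(row["mean_norm"]),
                )
            )
        return cls(library_ids=libs, tags=tags, library_totals=totals)


@dataclass
class PipelineConfig:
    """Every numeric knob of the pipeline, with their standard defaults.

    Units: energies in kcal/mol, lengths in nucleotides, abundances in reads
    (raw) or reads-per-million (normalized).  Seed coordinates are 1-based
    inclusive positions from the 5' end of the small RNA.
    """

    # read QC
    max_bases_below_q10: int = 4
    max_bases_below_q13: int = 6
    min_read_len: int = 18
    # annotation cascade (edit budgets for the ncRNA/repeat/exon passes)
    max_edits_ncrna_native: int = 1
    max_edits_ncrna_relative: int = 2  # "less than three" mismatches/gaps
    # conserved miRNA homology
    seed_start: int = 2
    seed_end: int = 8
    max_edits_conserved_native: int = 1
    max_edits_conserved_other: int = 3
    max_coverage_diff: int = 2
    min_family_mean_norm: float = 15.0
    # genome/contig mapping
    mapping_seed_len: int = 8
    mapping_max_mismatch: int = 1
    # hairpin precursor evaluation
    precursor_mfe_max: float = -18.0
    min_duplex_pairs: int = 16
    max_bulge: int = 4
    max_asymmetry: int = 4
    # novel miRNA curation
    dominance_min: float = 0.5
    max_5p_heterogeneity: int = 2
    window_upstream: int = 250
    window_downstream: int = 50
    # tasiRNA phasing
    phase_len: int = 21
    phase_cycles: int = 11
    min_phase_abundance: int = 4
    tas_p_threshold: float = 1e-3
    max_edits_known_tas: int = 1
    # target prediction
    match_score: float = 5.0
    wobble_score: float = 2.0
    mismatch_score: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    target_score_min: float = 130.0
    target_mfe_max: float = -17.0
    top_n_targets_small: int = 10
    top_n_targets_large: int = 20
    top_n_switch: int = 50
    # GO enrichment
    enrich_p_threshold: float = 0.05
    # normalization scale (reads per million by default)
    norm_scale: float = 1e6

    def __post_init__(self) -> None:
        if not self.seed_start < self.seed_end:
            raise ValueError("seed_start must be < seed_end")
        if self.precursor_mfe_max >= 0 or self.target_mfe_max >= 0:
            raise ValueError("free-energy thresholds must be negative")
        for name in (
            "max_bases_below_q10",
            "max_bases_below_q13",
            "min_read_len",
            "max_edits_ncrna_native",
            "max_edits_ncrna_relative",
            "max_edits_conserved_native",
            "max_edits_conserved_other",
            "max_coverage_diff",
            "mapping_seed_len",
            "mapping_max_mismatch",
            "min_duplex_pairs",
            "max_bulge",
            "max_asymmetry",
            "phase_len",
            "min_phase_abundance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AnnotationRecord:
    """The category the cascade assigned to one tag, with its evidence."""

    tag_seq: str
    category: str
    reference_id: str = ""
    mismatches: int = 0
    gaps: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "unannotated") != (self.reference_id == ""):
            raise ValueError("unannotated records must have no reference id")


# ---------------------------------------------------------------------------
# sequence I/O


def read_fastq(path: str | Path) -> Iterator[SmallRNARead]:
    """Stream FASTQ records as :class:`SmallRNARead`.

    Only the plain 4-line dialect with Phred+33 qualities is accepted.
    Malformed records raise :class:`FastqParseError` naming the record index.
    """
    path = Path(path)
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if not header.startswith("@"):
                raise FastqParseError(f"record {idx}: header does not start with '@'")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or not qual:
                raise FastqParseError(f"record {idx}: truncated record")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {idx}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            scores = tuple(ord(c) - 33 for c in qual)
            if any(s < 0 for s in scores):
                raise FastqParseError(f"record {idx}: quality below Phred+33 range")
            yield SmallRNARead(header[1:].split()[0], seq.upper(), scores)
            idx += 1


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered mapping of full header id to uppercase sequence."""
    return {rec.description: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str] | Sequence[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# tag collapsing and normalization


def collapse_tags(reads_per_library: Mapping[str, Iterable[SmallRNARead | str]]) -> TagTable:
    """Collapse QC-passed inserts into unique tags with per-library counts.

    Accepts either :class:`SmallRNARead` objects or bare insert strings.
    T/U are identified (tags stored in the RNA alphabet), so a DNA-alphabet
    and an RNA-alphabet spelling of the same insert count as one tag.
    """
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    library_ids = list(reads_per_library)
    for lib, reads in reads_per_library.items():
        n = 0
        for r in reads:
            seq = rna(r.seq if isinstance(r, SmallRNARead) else r)
            counts.setdefault(seq, {}).setdefault(lib, 0)
            counts[seq][lib] += 1
            n += 1
        totals[lib] = n
    tags = [UniqueTag(seq=s, counts=c) for s, c in counts.items()]
    return TagTable(library_ids=library_ids, tags=tags, library_totals=totals)


def normalize_counts(table: TagTable, cfg: PipelineConfig | None = None) -> TagTable:
    """Library-scaling normalization: norm = count / library_total * scale.

    The default scale of 1e6 gives reads-per-million of clean reads, the
    standard instance of library scaling; ``mean_norm`` is the arithmetic
    mean over *all* configured libraries, zeros included.
    """
    cfg = cfg or PipelineConfig()
    libs = table.library_ids
    for lib in libs:
        if table.library_totals.get(lib, 0) <= 0:
            raise ValueError(f"library {lib!r} has zero total clean reads")
    for tag in table.tags:
        tag.norm = {
            lib: tag.counts.get(lib, 0) / table.library_totals[lib] * cfg.norm_scale
            for lib in libs
        }
        tag.mean_norm = sum(tag.norm.values()) / len(libs) if libs else 0.0
    return table


def length_distribution(table: TagTable, weighted: bool = False) -> dict[int, float]:
    """Fraction of tags (or of reads, if *weighted*) at each insert length."""
    if not table.tags:
        raise ValueError("empty tag table")
    acc: dict[int, float] = {}
    for t in table.tags:
        w = t.total() if weighted else 1
        acc[len(t.seq)] = acc.get(len(t.seq), 0) + w
    total = sum(acc.values())
    return {length: v / total for length, v in sorted(acc.items())}
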