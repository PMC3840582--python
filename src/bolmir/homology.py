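"""Edit-bounded homology matching and the two-pass annotation cascade.

The classic workflow for this problem is a heuristic BlastN search with
small edit allowances over 18-26 nt queries; at those sizes an exhaustive
edit-bounded alignment (edlib, banded Myers bit-vector) is strictly more
sensitive and fully deterministic, so it replaces the heuristic search here.  E-values are therefore not modeled —
the edit budget *is* the acceptance rule.

Two reference tiers mirror the study design: "native" sets (the organism's
own sequences, tight budget) and "relative" sets (close relatives, looser
budget).  Conserved-miRNA classification additionally protects the seed
region (positions 2-8 from the tag 5' end): any edit falling there
disqualifies the match, and tag/reference lengths may differ by at most
two nucleotides.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .core import CATEGORIES, AnnotationRecord, PipelineConfig, TagTable, rna

__all__ = [
    "AlignmentResult",
    "FamilyAssignment",
    "FamilySummary",
    "RefSet",
    "MatureRef",
    "parse_mature_header",
    "align_tag",
    "annotate_cascade",
    "classify_conserved",
    "filter_families",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Best end-to-end placement of a tag inside a reference sequence."""

    ref_id: str
    mismatches: int
    gaps: int
    seed_violations: int
    len_diff: int
    aligned_tag: str
    aligned_ref: str

    @property
    def edits(self) -> int:
        return self.mismatches + self.gaps


@dataclass(frozen=True)
class FamilyAssignment:
    tag_seq: str
    family: str
    source_mirna: str
    is_star: bool
    evidence: AlignmentResult


@dataclass
class FamilySummary:
    family: str
    n_members: int
    mean_norm_total: float
    brassicaceae_described: bool


@dataclass
class RefSet:
    """One labeled reference tier of the cascade."""

    category: str
    sequences: Mapping[str, str]
    native: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown refset label {self.category!r}")


@dataclass(frozen=True)
class MatureRef:
    """A mature miRNA reference with its family and strand labels."""

    ref_id: str
    seq: str
    family: str
    star: bool
    native: bool


def parse_mature_header(header: str, seq: str) -> MatureRef:
    """Parse ``id|family=MIR169|star=0|native=1`` structured FASTA headers."""
    parts = header.split("|")
    fields = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
    return MatureRef(
        ref_id=parts[0],
        seq=rna(seq),
        family=fields.get("family", parts[0]),
        star=fields.get("star", "0") == "1",
        native=fields.get("native", "1") == "1",
    )


# ---------------------------------------------------------------------------
# edit-bounded alignment


def align_tag(
    tag: str,
    ref: str,
    max_edits: int,
    protect_seed: bool = False,
    cfg: PipelineConfig | None = None,
    ref_id: str = "",
) -> AlignmentResult | None:
    """Minimum-edit infix alignment of *tag* against *ref*, or None.

    The tag is fully consumed; the reference location is free (infix
    semantics).  Returns None when the edit distance exceeds *max_edits*,
    or — with *protect_seed* — when any edit falls in tag positions
    seed_start..seed_end (1-based from the 5' end) or the tag/reference
    length difference exceeds ``max_coverage_diff``.

    Gap columns in the tag (reference base unmatched) are charged to the
    following tag position for the seed test.
    """
    cfg = cfg or PipelineConfig()
    if not tag:
        raise ValueError("empty tag")
    tag = rna(tag)
    ref = rna(ref)
    len_diff = abs(len(tag) - len(ref))
    if protect_seed and len_diff > cfg.max_coverage_diff:
        return None
    res = edlib.align(tag, ref, mode="HW", task="path", k=max_edits)
    if res["editDistance"] < 0:
        return None
    nice = edlib.getNiceAlignment(res, tag, ref)
    q, t = nice["query_aligned"], nice["target_aligned"]
    mismatches = gaps = seed_violations = 0
    tag_pos = 0  # 1-based position of the last consumed tag base
    for qc, tc in zip(q, t):
        if qc != "-":
            tag_pos += 1
        if qc == tc:
            continue
        if qc == "-" or tc == "-":
            gaps += 1
            pos = tag_pos + 1 if qc == "-" else tag_pos
        else:
            mismatches += 1
            pos = tag_pos
        if cfg.seed_start <= pos <= cfg.seed_end:
            seed_violations += 1
    if protect_seed and seed_violations > 0:
        return None
    return AlignmentResult(
        ref_id=ref_id,
        mismatches=mismatches,
        gaps=gaps,
        seed_violations=seed_violations,
        len_diff=len_diff,
        aligned_tag=q,
        aligned_ref=t,
    )


def _best_match(
    tag: str,
    refs: Mapping[str, str],
    max_edits: int,
    protect_seed: bool,
    cfg: PipelineConfig,
) -> AlignmentResult | None:
    """Best reference for a tag: fewest edits, then fewest seed-adjacent
    edits, then lexicographically smallest reference id (determinism)."""
    best: AlignmentResult | None = None
    for ref_id in sorted(refs):
        aln = align_tag(tag, refs[ref_id], max_edits, protect_seed, cfg, ref_id=ref_id)
        if aln is None:
            continue
        key = (aln.edits, aln.seed_violations, aln.ref_id)
        if best is None or key < (best.edits, best.seed_violations, best.ref_id):
            best = aln
        if best.edits == 0:
            break  # sorted ids: first zero-edit hit is the tie-break winner
    return best


# ---------------------------------------------------------------------------
# annotation cascade


def annotate_cascade(
    table: TagTable,
    refsets: Sequence[RefSet],
    cfg: PipelineConfig | None = None,
) -> tuple[dict[str, AnnotationRecord], pd.DataFrame]:
    """Assign each tag the category of the FIRST reference tier it matches.

    Native tiers use ``max_edits_ncrna_native`` (one mismatch/gap), relative
    tiers ``max_edits_ncrna_relative`` (fewer than three).  Returns the
    per-tag records plus a per-category ledger: unique tags, count-weighted
    totals and percentages of clean reads per library.
    """
    cfg = cfg or PipelineConfig()
    records: dict[str, AnnotationRecord] = {}
    for tag in table.tags:
        rec: AnnotationRecord | None = None
        for refset in refsets:
            max_edits = (
                cfg.max_edits_ncrna_native if refset.native else cfg.max_edits_ncrna_relative
            )
            aln = _best_match(tag.seq, refset.sequences, max_edits, False, cfg)
            if aln is not None:
                rec = AnnotationRecord(
                    tag_seq=tag.seq,
                    category=refset.category,
                    reference_id=aln.ref_id,
                    mismatches=aln.mismatches,
                    gaps=aln.gaps,
                )
                break
        records[tag.seq] = rec or AnnotationRecord(tag_seq=tag.seq, category="unannotated")
    return records, cascade_ledger(table, records)


def cascade_ledger(table: TagTable, records: Mapping[str, AnnotationRecord]) -> pd.DataFrame:
    """Per-category unique/total tallies and percentages of clean reads."""
    libs = table.library_ids
    cats = [c for c in CATEGORIES if any(r.category == c for r in records.values())]
    rows = []
    for cat in ["clean_reads"] + cats:
        row: dict[str, object] = {"category": cat}
        for lib in libs:
            if cat == "clean_reads":
                uniq = sum(1 for t in table.tags if t.counts.get(lib, 0) > 0)
                total = table.library_totals[lib]
            else:
                members = [
                    t for t in table.tags if records[t.seq].category == cat and t.counts.get(lib, 0) > 0
                ]
                uniq = len(members)
                total = sum(t.counts.get(lib, 0) for t in members)
            row[f"unique_{lib}"] = uniq
            row[f"total_{lib}"] = total
            denom = table.library_totals[lib]
            row[f"pct_{lib}"] = 100.0 * total / denom if denom else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conserved miRNA classification


def classify_conserved(
    tags: Iterable[str],
    native_mirnas: Sequence[MatureRef],
    other_plant_mirnas: Sequence[MatureRef],
    cfg: PipelineConfig | None = None,
) -> list[FamilyAssignment]:
    """Two-pass homology classification of unannotated tags.

    Native pass first (<=1 edit outside the seed, length within 2 nt); tags
    assigned there are excluded from the other-plant pass (<=3 edits outside
    the seed, same length rule).  Star references yield ``is_star=True``.
    """
    cfg = cfg or PipelineConfig()
    passes = [
        (native_mirnas, cfg.max_edits_conserved_native),
        (other_plant_mirnas, cfg.max_edits_conserved_other),
    ]
    assignments: list[FamilyAssignment] = []
    remaining = [rna(t) for t in tags]
    for refs, max_edits in passes:
        by_id = {r.ref_id: r.seq for r in refs}
        meta = {r.ref_id: r for r in refs}
        unmatched: list[str] = []
        for tag in remaining:
            aln = _best_match(tag, by_id, max_edits, True, cfg)
            if aln is None:
                unmatched.append(tag)
                continue
            ref = meta[aln.ref_id]
            assignments.append(
                FamilyAssignment(
                    tag_seq=tag,
                    family=ref.family,
                    source_mirna=ref.ref_id,
                    is_star=ref.star,
                    evidence=aln,
                )
            )
        remaining = unmatched
    return assignments


def filter_families(
    assignments: Sequence[FamilyAssignment],
    table: TagTable,
    brassicaceae_families: set[str],
    cfg: PipelineConfig | None = None,
) -> tuple[list[FamilySummary], list[FamilySummary]]:
    """Abundance filter on families not described in close relatives.

    A family is dropped iff it is not Brassicaceae-described AND the mean
    over libraries of its members' summed normalized counts is below
    ``min_family_mean_norm`` (15 RPM).  Star members do not count toward
    the abundance sum.
    """
    cfg = cfg or PipelineConfig()
    by_seq = table.by_seq()
    libs = table.library_ids
    families: dict[str, list[FamilyAssignment]] = {}
    for a in assignments:
        families.setdefault(a.family, []).append(a)
    kept: list[FamilySummary] = []
    dropped: list[FamilySummary] = []
    for family in sorted(families):
        members = families[family]
        per_lib = []
        for lib in libs:
            s = sum(
                by_seq[a.tag_seq].norm.get(lib, 0.0)
                for a in members
                if not a.is_star and a.tag_seq in by_seq
            )
            per_lib.append(s)
        mean_norm_total = sum(per_lib) / len(libs) if libs else 0.0
        summary = FamilySummary(
            family=family,
            n_members=len({a.tag_seq for a in members}),
            mean_norm_total=mean_norm_total,
            brassicaceae_described=family in brassicaceae_families,
        )
        if not summary.brassicaceae_described and mean_norm_total < cfg.min_family_mean_norm:
            dropped.append(summary)
        else:
            kept.append(summary)
    return kept, dropped
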