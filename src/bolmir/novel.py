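"""Novel miRNA prediction from unannotated tags.

Unannotated tags are mapped to genomic references (exact in contig mode,
one substitution in genome mode, via 8-nt exact seeds), candidate hairpin
precursors are excised around each hit and folded with the ViennaRNA
minimum-free-energy algorithm, and candidates are accepted when they meet
the classic structural rules:

* precursor MFE at or below -18 kcal/mol,
* at least 16 base pairs in the miRNA:miRNA* duplex,
* no bulge longer than 4 nt in the duplex,
* miRNA/miRNA* asymmetry of at most 4 nt,
* mature sequence confined to one arm (no overlap with the terminal loop).

A final curation step keeps only candidates whose mature tag dominates the
read pileup of its precursor (>=50% of mapped reads, 5' ends within 2 nt),
standing in for the manual single-dominant-product check of community
miRNA annotation criteria.
"""

from __future__ import annotations

import functools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import RNA

from .core import PipelineConfig, dna, revcomp, rna

__all__ = [
    "GenomicHit",
    "HairpinCandidate",
    "map_tags",
    "fold",
    "excise_candidates",
    "evaluate_hairpin",
    "dominance_filter",
]

_VALID = set("ACGUN")


@dataclass(frozen=True)
class GenomicHit:
    """One placement of a tag on a reference (0-based, half-open)."""

    ref_id: str
    start: int
    end: int
    strand: str
    edits: int
    tag_seq: str = ""


@dataclass
class HairpinCandidate:
    """An excised, folded precursor with its duplex statistics."""

    precursor_seq: str
    structure: str
    mfe: float
    mature_span: tuple[int, int]
    star_span: tuple[int, int] | None
    duplex_pairs: int
    max_bulge: int
    asymmetry: int
    arm: str
    dominance: float = 0.0
    ref_id: str = ""
    precursor_start: int = 0
    strand: str = "+"
    mature_seq: str = ""


# ---------------------------------------------------------------------------
# mapping


def _build_seed_index(ref: str, seed_len: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(ref) - seed_len + 1):
        index.setdefault(ref[i : i + seed_len], []).append(i)
    return index


@functools.lru_cache(maxsize=8)
def _cached_index(ref: str, seed_len: int) -> dict[str, list[int]]:
    return _build_seed_index(ref, seed_len)


def map_tags(
    tags: Iterable[str],
    references: Mapping[str, str],
    cfg: PipelineConfig | None = None,
    max_mismatch: int | None = None,
) -> list[GenomicHit]:
    """All substitution-only placements of each tag on both strands.

    Seed-and-extend with exact seeds of ``mapping_seed_len`` (8 nt): for a
    budget of *m* mismatches the tag is cut into m+1 blocks and at least one
    block of length >= 8 must match exactly (pigeonhole), so seeding the
    first and last 8-mer is exhaustive for m <= 1.  Contig mode is
    ``max_mismatch=0``, genome mode ``max_mismatch=1`` (the default from
    the config).  Reverse-strand hits are reported in forward coordinates.
    """
    cfg = cfg or PipelineConfig()
    m = cfg.mapping_max_mismatch if max_mismatch is None else max_mismatch
    if m > 1:
        raise ValueError("seed scheme supports at most one mismatch")
    seed_len = cfg.mapping_seed_len
    hits: list[GenomicHit] = []
    refs = {rid: rna(seq) for rid, seq in references.items()}
    for rid in sorted(refs):
        fwd = refs[rid]
        n = len(fwd)
        index = _cached_index(fwd, seed_len)
        for tag in tags:
            tag = rna(tag)
            L = len(tag)
            if L < seed_len or L > n:
                continue
            for strand in "+-":
                q = tag if strand == "+" else revcomp(tag)
                starts: set[int] = set()
                # anchor the 5'-most and 3'-most seed (covers <=1 mismatch)
                for off in {0, L - seed_len}:
                    for pos in index.get(q[off : off + seed_len], ()):
                        starts.add(pos - off)
                for s in sorted(starts):
                    if s < 0 or s + L > n:
                        continue
                    mism = sum(1 for a, b in zip(q, fwd[s : s + L]) if a != b)
                    if mism <= m:
                        hits.append(
                            GenomicHit(
                                ref_id=rid, start=s, end=s + L, strand=strand,
                                edits=mism, tag_seq=tag,
                            )
                        )
    return hits


# ---------------------------------------------------------------------------
# folding


@functools.lru_cache(maxsize=100_000)
def fold(seq: str) -> tuple[str, float]:
    """Minimum-free-energy secondary structure (dot-bracket, kcal/mol).

    Thin deterministic wrapper over the ViennaRNA MFE fold with its default
    (Turner 2004) parameter set; no pseudoknots.  Results are cached — the
    pipeline folds the same excision window once per locus, not per tag.
    """
    s = rna(seq)
    if set(s) - _VALID:
        raise ValueError(f"invalid characters in sequence: {sorted(set(s) - _VALID)}")
    structure, mfe = RNA.fold(s)
    return structure, float(mfe)


# ---------------------------------------------------------------------------
# excision and duplex statistics


def _duplex_stats(
    structure: str, mature: tuple[int, int]
) -> tuple[int, int, int, tuple[int, int] | None, str] | None:
    """Compute (duplex_pairs, max_bulge, asymmetry, star_span, arm).

    Returns None when the mature span overlaps the terminal loop (its
    pairing partners interleave with itself) or is entirely unpaired.
    """
    pt = RNA.ptable(structure)  # 1-based; pt[i] = partner of i, 0 if unpaired
    ms, me = mature
    partners = [pt[i + 1] - 1 for i in range(ms, me) if pt[i + 1] > 0]
    duplex_pairs = len(partners)
    if not partners:
        return None
    lo, hi = min(partners), max(partners)
    # arm assignment: all partners strictly on one side of the mature span
    if lo >= me:
        arm = "5p"
    elif hi < ms:
        arm = "3p"
    else:
        return None  # mature pairs with itself -> sits in the terminal loop
    # star span: pairing partner region with the canonical 2-nt 3' overhang
    if arm == "5p":
        star = (max(0, lo - 2), hi + 1)
    else:
        star = (lo, min(len(structure), hi + 1 + 2))
    # bulges: runs of unpaired bases interior to the duplex on either strand
    def runs(a: int, b: int) -> list[int]:
        out, cur = [], 0
        for i in range(a, b):
            if pt[i + 1] == 0:
                cur += 1
            elif cur:
                out.append(cur)
                cur = 0
        if cur:
            out.append(cur)
        return out

    mat_runs = runs(ms, me)
    star_runs = runs(lo, hi + 1)
    max_bulge = max(mat_runs + star_runs, default=0)
    asymmetry = abs(sum(mat_runs) - sum(star_runs))
    return duplex_pairs, max_bulge, asymmetry, star, arm


def excise_candidates(
    hit: GenomicHit,
    reference_seq: str,
    cfg: PipelineConfig | None = None,
) -> list[HairpinCandidate]:
    """Fold the two asymmetric windows around a hit into candidates.

    Windows of [start-250, end+50) and [start-50, end+250), clipped to the
    reference, cover a mature tag on either precursor arm.  Candidates
    whose mature span sits in the terminal loop, or whose window clips
    below 40 nt, are skipped.  Reverse-strand hits are excised from the
    reverse complement.
    """
    cfg = cfg or PipelineConfig()
    ref = rna(reference_seq)
    n = len(ref)
    out: list[HairpinCandidate] = []
    windows = [
        (hit.start - cfg.window_upstream, hit.end + cfg.window_downstream),
        (hit.start - cfg.window_downstream, hit.end + cfg.window_upstream),
    ]
    seen: set[tuple[int, int]] = set()
    for a, b in windows:
        a, b = max(0, a), min(n, b)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        if b - a < 40:
            continue
        window = ref[a:b]
        mature = (hit.start - a, hit.end - a)
        if hit.strand == "-":
            window = revcomp(window)
            mature = (b - hit.end, b - hit.start)
        structure, mfe = fold(window)
        stats = _duplex_stats(structure, mature)
        if stats is None:
            continue
        duplex_pairs, max_bulge, asymmetry, star, arm = stats
        out.append(
            HairpinCandidate(
                precursor_seq=window,
                structure=structure,
                mfe=mfe,
                mature_span=mature,
                star_span=star,
                duplex_pairs=duplex_pairs,
                max_bulge=max_bulge,
                asymmetry=asymmetry,
                arm=arm,
                ref_id=hit.ref_id,
                precursor_start=a,
                strand=hit.strand,
                mature_seq=hit.tag_seq or window[mature[0] : mature[1]],
            )
        )
    return out


def evaluate_hairpin(
    c: HairpinCandidate, cfg: PipelineConfig | None = None
) -> tuple[bool, list[str]]:
    """Apply the structural acceptance rules; return (accept, reasons)."""
    cfg = cfg or PipelineConfig()
    reasons: list[str] = []
    if c.mfe > cfg.precursor_mfe_max:
        reasons.append("mfe")
    if c.duplex_pairs < cfg.min_duplex_pairs:
        reasons.append("duplex_pairs")
    if c.max_bulge > cfg.max_bulge:
        reasons.append("max_bulge")
    if c.asymmetry > cfg.max_asymmetry:
        reasons.append("asymmetry")
    if c.arm not in ("5p", "3p"):
        reasons.append("arm")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# dominance curation


def dominance_filter(
    candidates: Sequence[HairpinCandidate],
    hits: Sequence[GenomicHit],
    tag_counts: Mapping[str, int],
    cfg: PipelineConfig | None = None,
) -> list[HairpinCandidate]:
    """Keep candidates whose mature tag clearly dominates its precursor.

    Dominance: reads of the mature tag (and of tags sharing its 5' end
    within ``max_5p_heterogeneity`` nt on the same arm) must make up at
    least ``dominance_min`` of all reads mapped inside the precursor
    window.  Overlapping surviving precursors on the same strand collapse
    to the highest-dominance one (ties: leftmost).
    """
    cfg = cfg or PipelineConfig()
    kept: list[HairpinCandidate] = []
    for c in candidates:
        a = c.precursor_start
        b = a + len(c.precursor_seq)
        inside = [
            h
            for h in hits
            if h.ref_id == c.ref_id and h.strand == c.strand and h.start >= a and h.end <= b
        ]
        total = sum(tag_counts.get(h.tag_seq, 1) for h in inside)
        if total == 0:
            continue
        # 5' end of the mature tag in reference coordinates
        if c.strand == "+":
            anchor = a + c.mature_span[0]
            five_prime = lambda h: h.start  # noqa: E731
        else:
            anchor = b - c.mature_span[0] - 1
            five_prime = lambda h: h.end - 1  # noqa: E731
        supporting = [
            h for h in inside if abs(five_prime(h) - anchor) <= cfg.max_5p_heterogeneity
        ]
        support = sum(tag_counts.get(h.tag_seq, 1) for h in supporting)
        c.dominance = support / total
        if c.dominance >= cfg.dominance_min:
            kept.append(c)
    # collapse overlapping precursor loci (a perfect inverted repeat is
    # called from both strands; it is one physical locus)
    kept.sort(key=lambda c: (c.ref_id, c.precursor_start, c.strand))
    final: list[HairpinCandidate] = []
    for c in kept:
        merged = False
        for i, f in enumerate(final):
            if (
                f.ref_id == c.ref_id
                and c.precursor_start < f.precursor_start + len(f.precursor_seq)
                and f.precursor_start < c.precursor_start + len(c.precursor_seq)
            ):
                if c.dominance > f.dominance:
                    final[i] = c
                merged = True
                break
        if not merged:
            final.append(c)
    return final


def to_gff3(candidates: Sequence[HairpinCandidate]) -> str:
    """GFF3 of precursor loci (1-based inclusive, per the GFF3 standard)."""
    lines = ["##gff-version 3"]
    for i, c in enumerate(candidates, 1):
        start = c.precursor_start + 1
        end = c.precursor_start + len(c.precursor_seq)
        lines.append(
            "\t".join(
                [
                    c.ref_id,
                    "bolmir",
                    "miRNA_primary_transcript",
                    str(start),
                    str(end),
                    f"{c.mfe:.1f}",
                    c.strand,
                    ".",
                    f"ID=novel{i};arm={c.arm};dominance={c.dominance:.3f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
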