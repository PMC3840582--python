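"""miRanda-style miRNA target prediction.

Plant miRNAs act through extensive complementarity to their mRNA targets,
so prediction is a complementarity alignment: the miRNA is aligned
antiparallel against each transcript and columns are scored +5 for a
canonical pair (A:U, G:C), +2 for a G:U wobble, -3 for a mismatch, -9/-4
for gap open/extend, with every column at miRNA positions 2-8 (the seed)
multiplied by 4.  A site is reported when the alignment score reaches 130,
the nearest-neighbor hybridization energy of the duplex is at or below
-17 kcal/mol, and the seed contains no gap and no non-canonical pair
(G:U counts as non-canonical inside the seed while still scoring +2
outside it).

Without the 5' scaling the 130 threshold would exceed the maximum
attainable score of a perfect 21-mer (105), so the scaling is required for
the scheme's thresholds to be mutually consistent.

Alignment display convention: ``aligned_mirna`` reads 5'->3', and
``aligned_target`` is the site written 3'->5' so that aligned columns are
base-paired partners; ``pair_string`` uses '|' (canonical), ':' (wobble),
'.' (mismatch) and '-' (gap), as in the conventional duplex figures.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import RNA

from .core import PipelineConfig, rna

__all__ = [
    "TargetAlignment",
    "TargetHit",
    "score_duplex_alignment",
    "rescore_pair_string",
    "duplex_energy",
    "find_targets",
    "format_alignment",
]

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
_VALID = set("ACGU")


@dataclass(frozen=True)
class TargetAlignment:
    mirna_id: str
    target_id: str
    target_span: tuple[int, int]
    aligned_mirna: str
    aligned_target: str
    pair_string: str
    score: float
    duplex_mfe: float
    seed_ok: bool


@dataclass(frozen=True)
class TargetHit(TargetAlignment):
    rank: int = 0


def _col_symbol(m: str, t: str) -> str:
    if m == "-" or t == "-":
        return "-"
    if (m, t) in _CANONICAL:
        return "|"
    if (m, t) in _WOBBLE:
        return ":"
    return "."


def _col_score(sym: str, prev_sym: str, cfg: PipelineConfig) -> float:
    if sym == "|":
        return cfg.match_score
    if sym == ":":
        return cfg.wobble_score
    if sym == ".":
        return cfg.mismatch_score
    return cfg.gap_extend if prev_sym == "-" else cfg.gap_open


def rescore_pair_string(
    aligned_mirna: str, pair_string: str, cfg: PipelineConfig | None = None
) -> float:
    """Recompute the alignment score from the stored columns (audit path)."""
    cfg = cfg or PipelineConfig()
    score = 0.0
    pos = 0  # 1-based miRNA position of the last consumed base
    prev = ""
    for mc, sym in zip(aligned_mirna, pair_string):
        if mc != "-":
            pos += 1
        col = _col_score(sym, prev, cfg)
        # a gap in the miRNA is charged to the following miRNA position
        eff_pos = pos + 1 if mc == "-" else pos
        if cfg.seed_start <= eff_pos <= cfg.seed_end:
            col *= cfg.seed_scale
        score += col
        prev = sym
    return score


def score_duplex_alignment(
    mirna: str,
    site: str,
    cfg: PipelineConfig | None = None,
    prealigned: bool = False,
) -> tuple[float, str]:
    """Score the miRNA:site duplex; return (score, pair_string).

    With ``prealigned=True`` both arguments are gapped column strings
    (miRNA 5'->3', site 3'->5') and are scored as given.  Otherwise a
    banded local complementarity alignment is computed and the best
    scoring placement returned.  Empty overlap scores 0 with an empty
    pair string.
    """
    cfg = cfg or PipelineConfig()
    if prealigned:
        syms = "".join(_col_symbol(m, t) for m, t in zip(mirna, site))
        return rescore_pair_string(mirna, syms, cfg), syms
    m = rna(mirna)
    s = rna(site)
    if (set(m) | set(s)) - _VALID:
        raise ValueError("invalid alphabet in miRNA or site")
    if not m or not s:
        return 0.0, ""
    aln = _align_site(m, s[::-1], cfg)
    if aln is None:
        return 0.0, ""
    score, m_aln, t_aln, _span = aln
    syms = "".join(_col_symbol(a, b) for a, b in zip(m_aln, t_aln))
    return score, syms


def _align_site(
    m: str, t_rev: str, cfg: PipelineConfig
) -> tuple[float, str, str, tuple[int, int]] | None:
    """Banded global-in-miRNA / local-in-site DP.

    *t_rev* is the site written 3'->5' so that miRNA position i pairs with
    column i.  The band (+/-3 around the diagonal) admits short bulges on
    either strand; the miRNA is fully consumed, the site end-trimmed.
    Returns (score, gapped miRNA, gapped site-3'->5', (lo, hi) span of the
    consumed t_rev interval).
    """
    band = 3
    n, k = len(m), len(t_rev)
    NEG = -1e9
    # dp[i][j]: best score aligning m[:i] with t_rev[:j]; band |i-j|<=band
    dp = np.full((n + 1, k + 1), NEG)
    back = np.zeros((n + 1, k + 1), dtype=np.int8)  # 0 diag, 1 up(gap in site), 2 left(gap in miRNA)
    dp[0, : band + 1] = 0.0  # free start within the band
    for i in range(1, n + 1):
        scale = cfg.seed_scale if cfg.seed_start <= i <= cfg.seed_end else 1.0
        lo = max(0, i - band)
        hi = min(k, i + band)
        for j in range(lo, hi + 1):
            best = NEG
            op = 0
            if j >= 1 and dp[i - 1, j - 1] > NEG / 2:
                sym = _col_symbol(m[i - 1], t_rev[j - 1])
                sc = dp[i - 1, j - 1] + _col_score(sym, "", cfg) * scale
                if sc > best:
                    best, op = sc, 0
            if dp[i - 1, j] > NEG / 2:  # miRNA base vs gap in site
                prev_gap = back[i - 1, j] == 1
                g = cfg.gap_extend if prev_gap else cfg.gap_open
                sc = dp[i - 1, j] + g * scale
                if sc > best:
                    best, op = sc, 1
            if j >= 1 and dp[i, j - 1] > NEG / 2:  # site base vs gap in miRNA
                prev_gap = back[i, j - 1] == 2
                g = cfg.gap_extend if prev_gap else cfg.gap_open
                gscale = cfg.seed_scale if cfg.seed_start <= i + 1 <= cfg.seed_end else 1.0
                sc = dp[i, j - 1] + g * gscale
                if sc > best:
                    best, op = sc, 2
            dp[i, j] = best
            back[i, j] = op
    # free end in the site row
    j_end = int(np.argmax(dp[n, :]))
    if dp[n, j_end] <= NEG / 2:
        return None
    m_aln: list[str] = []
    t_aln: list[str] = []
    i, j = n, j_end
    while i > 0:
        op = back[i, j]
        if op == 0:
            m_aln.append(m[i - 1])
            t_aln.append(t_rev[j - 1])
            i, j = i - 1, j - 1
        elif op == 1:
            m_aln.append(m[i - 1])
            t_aln.append("-")
            i -= 1
        else:
            m_aln.append("-")
            t_aln.append(t_rev[j - 1])
            j -= 1
    j_start = j
    return float(dp[n, j_end]), "".join(reversed(m_aln)), "".join(reversed(t_aln)), (j_start, j_end)


def _seed_ok(aligned_mirna: str, pair_string: str, cfg: PipelineConfig) -> bool:
    """No gap and no non-canonical column within miRNA seed positions."""
    pos = 0
    for mc, sym in zip(aligned_mirna, pair_string):
        if mc != "-":
            pos += 1
            if cfg.seed_start <= pos <= cfg.seed_end and sym != "|":
                return False
        else:
            # gap in the miRNA, charged to the following miRNA position
            if cfg.seed_start <= pos + 1 <= cfg.seed_end:
                return False
    return True


def duplex_energy(mirna: str, site: str) -> float:
    """Hybridization free energy (kcal/mol) of the RNA:RNA duplex.

    Nearest-neighbor duplex fold (ViennaRNA RNAduplex); deterministic for
    a fixed parameter set.
    """
    m, s = rna(mirna), rna(site)
    if not m or not s:
        raise ValueError("empty sequence")
    if (set(m) | set(s)) - _VALID:
        raise ValueError("invalid alphabet")
    return float(RNA.duplexfold(m, s).energy)


def find_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cfg: PipelineConfig | None = None,
) -> list[TargetHit]:
    """All accepted, non-overlapping sites per (miRNA, transcript).

    Candidate anchors are located by an ungapped complementarity scan
    (every offset, numpy); anchors above half the score threshold are
    refined with the banded DP, checked against the three rules
    (score >= 130, duplex energy <= -17 kcal/mol, clean seed) and pruned
    to non-overlapping sites.  Hits are sorted per miRNA by descending
    score then ascending energy, and truncated to the top 10 (or top 20
    when a miRNA has more than ``top_n_switch`` raw hits).
    """
    cfg = cfg or PipelineConfig()
    enc = {"A": 0, "C": 1, "G": 2, "U": 3}
    # pairwise column scores for the ungapped prescan
    pair = np.full((4, 4), cfg.mismatch_score)
    for (a, b) in _CANONICAL:
        pair[enc[a], enc[b]] = cfg.match_score
    for (a, b) in _WOBBLE:
        pair[enc[a], enc[b]] = cfg.wobble_score
    raw_hits: dict[str, list[TargetAlignment]] = {mid: [] for mid in mirnas}
    for mid in sorted(mirnas):
        m = rna(mirnas[mid])
        if not (18 <= len(m) <= 26):
            raise ValueError(f"miRNA {mid} length {len(m)} outside 18-26 nt")
        L = len(m)
        mv = np.array([enc[c] for c in m])
        scale = np.where(
            (np.arange(1, L + 1) >= cfg.seed_start) & (np.arange(1, L + 1) <= cfg.seed_end),
            cfg.seed_scale,
            1.0,
        )
        for tid in sorted(transcripts):
            t = rna(transcripts[tid])
            if len(t) < L or set(t) - _VALID:
                continue
            tv = np.array([enc[c] for c in t])
            # ungapped antiparallel scan: miRNA pos i pairs site pos (off+L-1-i)
            n_off = len(t) - L + 1
            windows = np.lib.stride_tricks.sliding_window_view(tv, L)[:, ::-1]
            scores = (pair[mv[None, :], windows] * scale[None, :]).sum(axis=1)
            anchors = np.nonzero(scores >= cfg.target_score_min / 2)[0]
            sites: list[TargetAlignment] = []
            for off in anchors:
                a = max(0, off - 3)
                b = min(len(t), off + L + 3)
                site = t[a:b]
                aln = _align_site(m, site[::-1], cfg)
                if aln is None:
                    continue
                score, m_aln, t_aln, (jlo, jhi) = aln
                if score < cfg.target_score_min:
                    continue
                syms = "".join(_col_symbol(x, y) for x, y in zip(m_aln, t_aln))
                seed = _seed_ok(m_aln, syms, cfg)
                if not seed:
                    continue
                # consumed site interval in transcript coordinates
                span = (a + (len(site) - jhi), a + (len(site) - jlo))
                site_seq = t[span[0] : span[1]]
                mfe = duplex_energy(m, site_seq)
                if mfe > cfg.target_mfe_max:
                    continue
                sites.append(
                    TargetAlignment(
                        mirna_id=mid, target_id=tid, target_span=span,
                        aligned_mirna=m_aln, aligned_target=t_aln,
                        pair_string=syms, score=score, duplex_mfe=mfe,
                        seed_ok=seed,
                    )
                )
            # prune overlapping sites: best score first
            sites.sort(key=lambda s: (-s.score, s.duplex_mfe, s.target_span))
            chosen: list[TargetAlignment] = []
            for s in sites:
                if all(
                    s.target_span[1] <= c.target_span[0] or s.target_span[0] >= c.target_span[1]
                    for c in chosen
                ):
                    chosen.append(s)
            raw_hits[mid].extend(chosen)
    out: list[TargetHit] = []
    for mid in sorted(raw_hits):
        hits = sorted(raw_hits[mid], key=lambda s: (-s.score, s.duplex_mfe, s.target_id, s.target_span))
        top_n = cfg.top_n_targets_large if len(hits) > cfg.top_n_switch else cfg.top_n_targets_small
        for rank, h in enumerate(hits[:top_n], 1):
            out.append(TargetHit(**{**h.__dict__, "rank": rank}))
    return out


def format_alignment(hit: TargetAlignment) -> str:
    """Human-readable duplex block in the conventional figure style."""
    return (
        f"{hit.mirna_id} vs {hit.target_id} [{hit.target_span[0]}..{hit.target_span[1]}) "
        f"score={hit.score:.1f} mfe={hit.duplex_mfe:.1f}\n"
        f"  miRNA  5' {hit.aligned_mirna} 3'\n"
        f"            {hit.pair_string}\n"
        f"  target 3' {hit.aligned_target} 5'\n"
    )
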