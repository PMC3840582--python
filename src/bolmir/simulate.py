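"""Synthetic small-RNA libraries with known ground truth.

The generator emulates the study design the pipeline was built for: three
deeply sequenced leaf libraries whose reads are drawn from

* conserved miRNA families (mature and star strands, references split into
  a native tier and an other-plant tier),
* novel miRNA hairpins planted in genomic contigs (perfect 21-bp stem,
  >=8 nt loop, mature on one arm),
* 21-nt phased TAS loci (8 consecutive in-register positions),
* ncRNA/repeat contaminant fragments, and
* mRNA degradation fragments of simulated transcripts,

with a log-normal abundance skew (a few dominant species over a long
tail), a 3' sequencing adapter appended to every insert, substitution
errors, and a labeled fraction of QC-negative reads (N bases, low
quality, short inserts, 5'-adapter contamination, poly-A, missing 3'
adapter).  Every read id carries its truth label, and ``expected_category``
maps each planted insert to the category the pipeline should assign.

Planted species are guaranteed a small minimum read count per library —
the pipeline discovers *expressed* molecules, so simulated expression is
never zero — and each phased TAS position is guaranteed at least the
phasing abundance threshold so the loci are detectable by construction.
All randomness flows from one integer seed through a single PCG64 stream;
identical configs produce byte-identical output files.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .core import PipelineConfig, SmallRNARead, dna, revcomp, rna, write_fasta
from .enrichment import AnnotationMap
from .homology import MatureRef, RefSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ReferenceBundle",
    "simulate_references",
    "simulate_libraries",
    "write_simulation",
]

_ALPHA = np.array(list("ACGU"))

# QC-negative classes, in the proportion they are injected
_NEG_CLASSES = ("n", "q10", "q13", "short", "adapter5", "polya", "noadapter")


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment."""

    rng_seed: int = 0
    n_libraries: int = 3
    reads_per_library: int = 50_000
    n_conserved_families: int = 20
    n_novel_hairpins: int = 10
    n_tas_loci: int = 3
    n_contaminant_refs: int = 12
    n_transcripts: int = 30
    abundance_shape: float = 1.5  # log-normal sigma of species weights
    error_rate: float = 0.001  # per-base substitution rate
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    genome_contig_len: int = 1200
    fraction_star: float = 0.3  # planted star weight relative to its mature
    read_length: int = 36
    qc_negative_fraction: float = 0.05
    tas_positions: int = 8  # consecutive phased positions per locus
    min_planted_reads: int = 5  # per mature species per library
    min_tas_reads: int = 5  # per phased position per library

    def __post_init__(self) -> None:
        for name in (
            "n_libraries", "reads_per_library", "n_conserved_families",
            "n_novel_hairpins", "n_tas_loci", "n_contaminant_refs",
            "n_transcripts",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_libraries >= 1 and self.reads_per_library < 1:
            raise ValueError("reads_per_library must be >= 1")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0 <= self.fraction_star <= 1):
            raise ValueError("fraction_star must be in [0, 1]")


@dataclass
class Species:
    """One planted read species (an insert sequence with a weight)."""

    species_id: str
    seq: str
    category: str
    weight: float
    guaranteed: int = 0  # minimum reads per library


@dataclass
class GroundTruth:
    planted_mirnas: list[tuple[str, str, str, str]] = field(default_factory=list)
    planted_tas: list[tuple[str, int, list[int]]] = field(default_factory=list)
    planted_contaminants: list[tuple[str, str]] = field(default_factory=list)
    planted_fragments: list[str] = field(default_factory=list)
    expected_category: dict[str, str] = field(default_factory=dict)
    species: list[Species] = field(default_factory=list)
    target_sites: list[tuple[str, str, int]] = field(default_factory=list)

    def planted_families(self) -> set[str]:
        return {fam for fam, *_ in self.planted_mirnas if not fam.startswith("novel")}


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    refsets: list[RefSet]
    mirna_native: list[MatureRef]
    mirna_other: list[MatureRef]
    transcripts: dict[str, str]
    known_tas: dict[str, str]
    brassicaceae_families: set[str]
    go: AnnotationMap


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPHA[rng.integers(0, 4, n)])


def _matches_any(tag: str, refs: Sequence[str], max_edits: int) -> bool:
    for ref in refs:
        mode = "HW" if len(ref) > len(tag) + 2 else "NW"
        if edlib.align(tag, ref, mode=mode, k=max_edits)["editDistance"] >= 0:
            return True
    return False


def simulate_references(cfg: SimConfig) -> tuple[dict[str, str], ReferenceBundle, GroundTruth]:
    """Build genome contigs, reference sets and the ground truth.

    Returns ``(genome, bundle, truth)``; the genome mapping is also part of
    the bundle.  Deterministic for a fixed ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    truth = GroundTruth()
    avoid: list[str] = []  # sequences a fresh planted small RNA must not resemble

    def fresh_tag(n: int, min_dist: int = 4) -> str:
        for _ in range(200):
            t = _rand_seq(rng, n)
            if t not in truth.expected_category and not _matches_any(t, avoid, min_dist):
                return t
        raise RuntimeError("could not draw a dissimilar sequence; shrink the design")

    def add_species(species_id: str, seq: str, category: str, weight: float, guaranteed: int = 0) -> None:
        if seq in truth.expected_category:
            return
        truth.expected_category[seq] = category
        truth.species.append(Species(species_id, seq, category, weight, guaranteed))

    weights = rng.lognormal(mean=0.0, sigma=cfg.abundance_shape, size=4096)
    w_iter = iter(weights)

    # --- contaminant references (ncRNA + repeat, native and relative tiers)
    ncrna_cats = ["rRNA", "tRNA", "snRNA", "snoRNA", "scRNA", "repeat"]
    native_refs: dict[str, dict[str, str]] = {c: {} for c in ncrna_cats}
    relative_refs: dict[str, dict[str, str]] = {c: {} for c in ncrna_cats}
    for i in range(cfg.n_contaminant_refs):
        cat = ncrna_cats[i % len(ncrna_cats)]
        tier = native_refs if (i // len(ncrna_cats)) % 2 == 0 else relative_refs
        ref_id = f"{cat}_{i}"
        seq = _rand_seq(rng, int(rng.integers(120, 400)))
        tier[cat][ref_id] = seq
        avoid.append(seq)
        truth.planted_contaminants.append((cat, ref_id))
        # two read species per reference: fragments of the reference
        for j in range(2):
            L = int(rng.integers(19, 28))
            start = int(rng.integers(0, len(seq) - L))
            frag = seq[start : start + L]
            if frag not in truth.expected_category:
                add_species(f"{ref_id}_frag{j}", frag, cat, next(w_iter))

    # --- conserved miRNA families
    n_native = cfg.n_conserved_families // 2
    mirna_native: list[MatureRef] = []
    mirna_other: list[MatureRef] = []
    brassicaceae: set[str] = set()
    for f in range(cfg.n_conserved_families):
        family = f"MIR{900 + f}"
        native = f < n_native
        if rng.random() < 0.7:
            brassicaceae.add(family)
        n_members = int(rng.integers(1, 4))
        founder = fresh_tag(21)
        for m in range(n_members):
            mature = founder
            if m > 0:
                # family members differ by 1-2 substitutions outside the seed
                mature = list(founder)
                for _ in range(int(rng.integers(1, 3))):
                    pos = int(rng.choice([0] + list(range(8, 21))))
                    mature[pos] = str(rng.choice([c for c in "ACGU" if c != mature[pos]]))
                mature = "".join(mature)
                if mature in truth.expected_category:
                    continue
            ref_id = f"{family.lower()}{chr(97 + m)}"
            ref = MatureRef(ref_id=ref_id, seq=mature, family=family, star=False, native=native)
            (mirna_native if native else mirna_other).append(ref)
            w = next(w_iter)
            add_species(ref_id, mature, "conserved_miRNA", w, guaranteed=cfg.min_planted_reads)
            truth.planted_mirnas.append((family, mature, "", ""))
            avoid.append(mature)
            if rng.random() < cfg.fraction_star:
                star = revcomp(mature)
                star_id = f"{ref_id}*"
                sref = MatureRef(ref_id=star_id, seq=star, family=family, star=True, native=native)
                (mirna_native if native else mirna_other).append(sref)
                add_species(star_id, star, "miRNA_star", w * 0.1, guaranteed=1)
                avoid.append(star)

    # --- genome contigs with novel hairpins; each planted precursor is
    # verified in genomic context (excised, folded, evaluated) so that the
    # simulated loci are genuine hairpins, and redrawn otherwise
    from .novel import GenomicHit, evaluate_hairpin, excise_candidates

    genome: dict[str, str] = {}
    for h in range(cfg.n_novel_hairpins):
        contig_id = f"contig_mir{h}"
        arm = "5p" if h % 2 == 0 else "3p"
        for _ in range(50):
            mature = fresh_tag(21)
            star = revcomp(mature)
            loop = _rand_seq(rng, 12)
            precursor = mature + loop + star if arm == "5p" else star + loop + mature
            flank = (cfg.genome_contig_len - len(precursor)) // 2
            if flank < 0:
                raise ValueError("genome_contig_len shorter than a precursor")
            contig = _rand_seq(rng, flank) + precursor + _rand_seq(
                rng, cfg.genome_contig_len - flank - len(precursor)
            )
            i = contig.find(mature)
            hit = GenomicHit(contig_id, i, i + 21, "+", 0, mature)
            if any(evaluate_hairpin(c)[0] for c in excise_candidates(hit, contig)):
                break
        else:
            raise RuntimeError("could not plant a folding hairpin")
        genome[contig_id] = contig
        locus = f"{contig_id}:{flank}-{flank + len(precursor)}"
        truth.planted_mirnas.append((f"novel{h}", mature, star, locus))
        w = next(w_iter)
        add_species(f"novel{h}", mature, "novel_miRNA", w, guaranteed=cfg.min_planted_reads)
        add_species(f"novel{h}*", star, "unannotated", w * 0.1, guaranteed=1)
        avoid.extend([mature, star])

    # --- genome contigs with phased TAS loci
    known_tas: dict[str, str] = {}
    for t in range(cfg.n_tas_loci):
        contig_id = f"contig_tas{t}"
        span = 21 * cfg.tas_positions
        for _ in range(100):
            contig = _rand_seq(rng, cfg.genome_contig_len)
            t0 = int(rng.integers(50, cfg.genome_contig_len - span - 50))
            tags = [contig[t0 + 21 * i : t0 + 21 * i + 21] for i in range(cfg.tas_positions)]
            if not any(_matches_any(x, avoid, 4) or x in truth.expected_category for x in tags):
                break
        else:
            raise RuntimeError("could not place a TAS locus")
        genome[contig_id] = contig
        positions = [t0 + 21 * i for i in range(cfg.tas_positions)]
        truth.planted_tas.append((contig_id, t0, positions))
        for i, x in enumerate(tags):
            add_species(
                f"tas{t}_D{i + 1}", x, "tasiRNA", next(w_iter), guaranteed=cfg.min_tas_reads
            )
            avoid.append(x)
        if t == 0 and cfg.tas_positions >= 7:
            # one planted locus mirrors a known TAS3 D7(+) tasiRNA
            known_tas["TAS3a_D7(+)"] = tags[6]

    # --- transcripts with planted target sites and degradation fragments
    transcripts: dict[str, str] = {}
    matures_for_targets = [s for s in truth.species if s.category in ("conserved_miRNA", "novel_miRNA")]
    go_map = AnnotationMap(
        parents={
            "GO:BP": set(),
            "GO:stress": {"GO:BP"},
            "GO:metabolism": {"GO:BP"},
            "GO:transport": {"GO:BP"},
            "GO:development": {"GO:BP"},
        }
    )
    leaf_terms = ["GO:stress", "GO:metabolism", "GO:transport", "GO:development"]
    for g in range(cfg.n_transcripts):
        tid = f"transcript_{g}"
        seq = _rand_seq(rng, int(rng.integers(400, 800)))
        if matures_for_targets and g < min(8, len(matures_for_targets)):
            # plant a perfect complementary site for one miRNA
            sp = matures_for_targets[g]
            site = revcomp(sp.seq)
            pos = int(rng.integers(50, len(seq) - len(site) - 50))
            seq = seq[:pos] + site + seq[pos + len(site):]
            truth.target_sites.append((sp.species_id, tid, pos))
            go_map.term_to_genes.setdefault("GO:stress", set()).add(tid)
        else:
            term = leaf_terms[int(rng.integers(0, len(leaf_terms)))]
            go_map.term_to_genes.setdefault(term, set()).add(tid)
        transcripts[tid] = seq
        truth.planted_fragments.append(tid)
        for j in range(2):
            L = int(rng.integers(19, 28))
            start = int(rng.integers(0, len(seq) - L))
            frag = seq[start : start + L]
            if frag not in truth.expected_category and not _matches_any(frag, avoid, 3):
                add_species(f"{tid}_frag{j}", frag, "exon", next(w_iter))

    refsets = (
        [RefSet(category=c, sequences=native_refs[c], native=True) for c in ncrna_cats if native_refs[c]]
        + [RefSet(category=c, sequences=relative_refs[c], native=False) for c in ncrna_cats if relative_refs[c]]
        + [RefSet(category="exon", sequences=transcripts, native=True)]
    )
    bundle = ReferenceBundle(
        genome=genome,
        refsets=refsets,
        mirna_native=mirna_native,
        mirna_other=mirna_other,
        transcripts=transcripts,
        known_tas=known_tas,
        brassicaceae_families=brassicaceae,
        go=go_map,
    )
    for fam, mature, _star, _locus in truth.planted_mirnas:
        assert mature in truth.expected_category
    return genome, bundle, truth


# ---------------------------------------------------------------------------
# read sampling


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    for i in range(len(arr)):
        if rng.random() < rate:
            arr[i] = str(rng.choice([c for c in "ACGU" if c != arr[i]]))
    return "".join(arr)


def _high_qual(rng: np.random.Generator, n: int) -> tuple[int, ...]:
    return tuple(int(q) for q in rng.integers(35, 41, n))


def simulate_libraries(
    cfg: SimConfig, truth: GroundTruth
) -> dict[str, list[SmallRNARead]]:
    """Sample ``reads_per_library`` reads per library from the planted species.

    Species counts follow a multinomial over the log-normal weights after
    the per-species guaranteed minima are allocated; a configurable
    fraction of reads is replaced by labeled QC-negative classes.  Read
    ids are ``<lib>_<i>_<label>`` with label ``ok:<species>`` or
    ``neg:<class>``.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    adapter3 = rna(cfg.adapter3)
    adapter5 = rna(cfg.adapter5)
    libraries: dict[str, list[SmallRNARead]] = {}
    species = truth.species
    w = np.array([s.weight for s in species]) if species else np.array([])

    def make_read(lib: str, i: int, label: str, insert: str, qual_mode: str = "high") -> SmallRNARead:
        full = (insert + adapter3)[: cfg.read_length]
        qual = list(_high_qual(rng, len(full)))
        seq = list(full)
        if qual_mode == "n":
            seq[int(rng.integers(0, len(seq)))] = "N"
        elif qual_mode == "q10":
            for p in rng.choice(len(seq), 5, replace=False):
                qual[p] = int(rng.integers(2, 10))
        elif qual_mode == "q13":
            for p in rng.choice(len(seq), 7, replace=False):
                qual[p] = int(rng.integers(10, 13))
        return SmallRNARead(f"{lib}_{i}_{label}", "".join(seq), tuple(qual))

    for lib_idx in range(cfg.n_libraries):
        lib = f"lib{lib_idx + 1}"
        reads: list[SmallRNARead] = []
        n_total = cfg.reads_per_library
        n_neg = int(round(cfg.qc_negative_fraction * n_total))
        # guaranteed planted counts first
        alloc = np.array([s.guaranteed for s in species], dtype=int)
        n_guaranteed = int(alloc.sum())
        n_free = n_total - n_neg - n_guaranteed
        if n_free < 0:
            raise ValueError("reads_per_library too small for the guarantees")
        if species and n_free > 0:
            alloc = alloc + rng.multinomial(n_free, w / w.sum())
        i = 0
        for s, count in zip(species, alloc):
            for j in range(count):
                # the guaranteed floor is emitted verbatim (expressed copies);
                # sequencing errors apply to the sampled remainder
                insert = s.seq if j < s.guaranteed else _mutate(rng, s.seq, cfg.error_rate)
                reads.append(make_read(lib, i, f"ok:{s.species_id}", insert))
                i += 1
        for j in range(n_neg):
            neg = _NEG_CLASSES[j % len(_NEG_CLASSES)]
            insert = _rand_seq(rng, 22)
            if neg in ("n", "q10", "q13"):
                reads.append(make_read(lib, i, f"neg:{neg}", insert, qual_mode=neg))
            elif neg == "short":
                reads.append(make_read(lib, i, "neg:short", _rand_seq(rng, int(rng.integers(10, 18)))))
            elif neg == "adapter5":
                reads.append(make_read(lib, i, "neg:adapter5", adapter5[:8] + _rand_seq(rng, 13)))
            elif neg == "polya":
                reads.append(make_read(lib, i, "neg:polya", "A" * 22))
            else:  # missing 3' adapter
                while True:
                    raw = _rand_seq(rng, cfg.read_length)
                    from .qc import find_adapter3

                    if find_adapter3(raw, adapter3) < 0:
                        break
                reads.append(
                    SmallRNARead(f"{lib}_{i}_neg:noadapter", raw, _high_qual(rng, cfg.read_length))
                )
            i += 1
        order = rng.permutation(len(reads))
        libraries[lib] = [reads[k] for k in order]
    return libraries


# ---------------------------------------------------------------------------
# writers


def write_fastq(path: str | Path, reads: Sequence[SmallRNARead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.read_id}\n{dna(r.seq)}\n+\n{qual}\n")


def write_simulation(
    outdir: str | Path,
    cfg: SimConfig,
    bundle: ReferenceBundle,
    truth: GroundTruth,
    libraries: Mapping[str, Sequence[SmallRNARead]],
) -> Path:
    """Write FASTQ libraries, reference FASTAs, a GFF3 of planted loci and
    a TSV manifest of expected categories.  Returns the output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for lib, reads in libraries.items():
        write_fastq(out / f"{lib}.fastq", reads)
    write_fasta(out / "genome.fasta", {k: dna(v) for k, v in bundle.genome.items()})
    write_fasta(out / "transcripts.fasta", {k: dna(v) for k, v in bundle.transcripts.items()})
    for refset in bundle.refsets:
        if refset.category == "exon":
            continue
        tier = "native" if refset.native else "relative"
        write_fasta(
            out / f"ref_{refset.category}_{tier}.fasta",
            {k: dna(v) for k, v in refset.sequences.items()},
        )
    mature = {
        f"{r.ref_id}|family={r.family}|star={int(r.star)}|native={int(r.native)}": dna(r.seq)
        for r in bundle.mirna_native + bundle.mirna_other
    }
    write_fasta(out / "mature_mirnas.fasta", mature)
    if bundle.known_tas:
        write_fasta(out / "known_tas.fasta", {k: dna(v) for k, v in bundle.known_tas.items()})
    with open(out / "planted_loci.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for fam, mat, star, locus in truth.planted_mirnas:
            if not locus:
                continue
            contig, span = locus.split(":")
            a, b = span.split("-")
            fh.write(
                f"{contig}\tbolmir_sim\tmiRNA_primary_transcript\t{int(a) + 1}\t{b}\t.\t+\t.\tID={fam}\n"
            )
        for contig, start, positions in truth.planted_tas:
            fh.write(
                f"{contig}\tbolmir_sim\tTAS_locus\t{start + 1}\t{positions[-1] + 21}\t.\t+\t.\t"
                f"ID={contig};positions={len(positions)}\n"
            )
    with open(out / "expected_categories.tsv", "w") as fh:
        fh.write("tag\tcategory\n")
        for tag, cat in sorted(truth.expected_category.items()):
            fh.write(f"{tag}\t{cat}\n")
    (out / "brassicaceae_families.txt").write_text(
        "\n".join(sorted(bundle.brassicaceae_families)) + "\n"
    )
    with open(out / "go_annotations.tsv", "w") as fh:
        for term in sorted(bundle.go.term_to_genes):
            for gene in sorted(bundle.go.term_to_genes[term]):
                fh.write(f"{gene}\t{term}\n")
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Altschul-Erickson style: shuffle the outgoing edge lists of the
    dinucleotide transition multigraph, retrying until the Eulerian walk
    consumes every edge.
    """
    s = rna(seq)
    if len(s) < 3:
        return s
    for _ in range(100):
        edges: dict[str, list[str]] = {}
        for a, b in zip(s, s[1:]):
            edges.setdefault(a, []).append(b)
        for a in edges:
            edges[a] = [edges[a][i] for i in rng.permutation(len(edges[a]))]
        walk = [s[0]]
        node = s[0]
        ok = True
        for _ in range(len(s) - 1):
            nxt = edges.get(node)
            if not nxt:
                ok = False
                break
            node = nxt.pop()
            walk.append(node)
        if ok:
            return "".join(walk)
    return s  # pathological composition; give back the original
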