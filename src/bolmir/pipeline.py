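"""End-to-end orchestration: simulate -> QC -> annotate -> discover -> report.

``run_all`` drives every stage off a single YAML config and writes all
tabular outputs plus a JSON run manifest mirroring the classic clean-read
accounting table (per-category unique/total counts and percentages).
Stage order follows the classic discovery workflow: cleaned reads are collapsed
and normalized, annotated by the cascade (ncRNA -> repeat -> exon, native
then relative tiers), classified against known miRNAs, and the remaining
unannotated tags feed novel-miRNA prediction; the tasiRNA scan receives
the unannotated tags together with the exon-derived tags, and target
prediction/GO enrichment close the run.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .core import (
    PipelineConfig,
    TagTable,
    collapse_tags,
    length_distribution,
    normalize_counts,
    read_fasta,
    read_fastq,
    rna,
)
from .enrichment import AnnotationMap, read_annotation_tsv, read_obo, term_for_term
from .homology import (
    MatureRef,
    RefSet,
    annotate_cascade,
    classify_conserved,
    filter_families,
    parse_mature_header,
)
from .novel import (
    dominance_filter,
    evaluate_hairpin,
    excise_candidates,
    map_tags,
    to_gff3,
)
from .qc import qc_filter
from .simulate import (
    SimConfig,
    simulate_libraries,
    simulate_references,
    write_simulation,
)
from .tasi import WORDING_NOTE, call_tas_loci, match_known_tas, scan_phasing

__all__ = ["run_all", "report", "load_config", "PipelineResult"]

_KNOWN_SECTIONS = {"outdir", "seed", "simulate", "inputs", "pipeline", "adapters"}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate the YAML run config (schema errors before compute)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(cfg)


def validate_config(cfg: dict[str, Any]) -> dict[str, Any]:
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    if "outdir" not in cfg:
        raise ValueError("config must set 'outdir'")
    if "simulate" not in cfg:
        inputs = cfg.get("inputs")
        if not inputs:
            raise ValueError("config needs a 'simulate' section or explicit 'inputs'")
        for key in ("fastq", "genome", "mature_mirnas", "transcripts"):
            if key not in inputs:
                raise ValueError(f"inputs section missing {key!r}")
            paths = inputs[key] if isinstance(inputs[key], list) else [inputs[key]]
            for p in paths:
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    for key in cfg.get("simulate") or {}:
        if key not in sim_fields:
            raise ValueError(f"unknown simulate option {key!r}")
    pipe_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in cfg.get("pipeline") or {}:
        if key not in pipe_fields:
            raise ValueError(f"unknown pipeline option {key!r}")
    return cfg


@dataclasses.dataclass
class PipelineResult:
    outdir: Path
    manifest: dict[str, Any]
    table: TagTable
    records: dict[str, Any]
    assignments: list
    kept_families: list
    novel: list
    tas_loci: list
    target_hits: list
    enrichment: list


def _stage(manifest: dict[str, Any], name: str, **counts: Any) -> None:
    manifest["stages"].append({"stage": name, **counts})


def run_all(config: dict[str, Any] | str | Path, quiet: bool = True) -> PipelineResult:
    """Execute the full pipeline; returns the in-memory results.

    *config* is a path to a YAML file or an already-loaded dict.  All
    randomness derives from ``config['seed']``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    t0 = time.time()
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    pcfg = PipelineConfig(**(config.get("pipeline") or {}))
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "inputs"},
        "stages": [],
        "notes": [WORDING_NOTE],
    }

    def log(msg: str) -> None:
        if not quiet:
            print(f"[bolmir] {msg}")

    # ---- stage 0: inputs (simulated or from disk)
    if "simulate" in config:
        scfg = SimConfig(rng_seed=seed, **{k: v for k, v in (config["simulate"] or {}).items() if k != "rng_seed"})
        genome, bundle, truth = simulate_references(scfg)
        libraries = simulate_libraries(scfg, truth)
        simdir = write_simulation(outdir / "sim", scfg, bundle, truth, libraries)
        log(f"simulated {len(libraries)} libraries into {simdir}")
        adapter3, adapter5 = scfg.adapter3, scfg.adapter5
        reads_per_library = {lib: iter(reads) for lib, reads in libraries.items()}
        go_map = bundle.go
        brass = bundle.brassicaceae_families
        _stage(manifest, "simulate", libraries=len(libraries), species=len(truth.species))
    else:
        inputs = config["inputs"]
        adapters = config.get("adapters") or {}
        adapter3 = adapters.get("adapter3", "TGGAATTCTCGGGTGCCAAGG")
        adapter5 = adapters.get("adapter5", "GTTCAGAGTTCTACAGTCCGACGATC")
        genome = read_fasta(inputs["genome"])
        matures = [parse_mature_header(h, s) for h, s in read_fasta(inputs["mature_mirnas"]).items()]
        transcripts = read_fasta(inputs["transcripts"])
        refsets = []
        for entry in inputs.get("refsets", []):
            refsets.append(
                RefSet(
                    category=entry["category"],
                    sequences=read_fasta(entry["path"]),
                    native=bool(entry.get("native", True)),
                )
            )
        refsets.append(RefSet(category="exon", sequences=transcripts, native=True))
        bundle = _LoadedBundle(
            genome=genome,
            refsets=refsets,
            mirna_native=[m for m in matures if m.native],
            mirna_other=[m for m in matures if not m.native],
            transcripts=transcripts,
            known_tas=read_fasta(inputs["known_tas"]) if inputs.get("known_tas") else {},
        )
        truth = None
        go_map = (
            read_annotation_tsv(inputs["go_annotations"]) if inputs.get("go_annotations") else AnnotationMap()
        )
        if inputs.get("go_obo"):
            go_map.parents = read_obo(inputs["go_obo"])
        brass = set(inputs.get("brassicaceae_families", []))
        fastqs = inputs["fastq"] if isinstance(inputs["fastq"], list) else [inputs["fastq"]]
        reads_per_library = {Path(p).stem: read_fastq(p) for p in fastqs}

    # ---- stage 1: QC
    clean: dict[str, list[str]] = {}
    qc_rows = []
    for lib, reads in reads_per_library.items():
        inserts, rep = qc_filter(reads, adapter3, adapter5, pcfg)
        clean[lib] = inserts
        qc_rows.append({"library": lib, **rep.to_dict()})
        log(f"{lib}: {rep.clean_reads}/{rep.input_reads} clean reads")
    pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    _stage(manifest, "qc", **{r["library"]: r["clean_reads"] for r in qc_rows})

    # ---- stage 2: collapse + normalize + length distribution
    table = normalize_counts(collapse_tags(clean), pcfg)
    lengths = length_distribution(table, weighted=True)
    pd.DataFrame(
        [{"length": k, "fraction": v} for k, v in lengths.items()]
    ).to_csv(outdir / "length_distribution.tsv", sep="\t", index=False)
    _stage(manifest, "collapse", unique_tags=len(table.tags))
    log(f"collapsed to {len(table.tags)} unique tags")

    # ---- stage 3: annotation cascade
    records, ledger = annotate_cascade(table, bundle.refsets, pcfg)
    ledger.to_csv(outdir / "annotation_ledger.tsv", sep="\t", index=False)
    manifest["ledger"] = ledger.to_dict(orient="records")
    unannot = [s for s, r in records.items() if r.category == "unannotated"]
    _stage(manifest, "cascade", unannotated=len(unannot))
    log(f"cascade left {len(unannot)} unannotated tags")

    # ---- stage 4: conserved miRNA classification + family filter
    assignments = classify_conserved(unannot, bundle.mirna_native, bundle.mirna_other, pcfg)
    kept, dropped = filter_families(assignments, table, brass, pcfg)
    fam_rows = [
        {**dataclasses.asdict(f), "kept": f in kept} for f in kept + dropped
    ]
    pd.DataFrame(fam_rows).to_csv(outdir / "families.tsv", sep="\t", index=False)
    kept_families = {f.family for f in kept}
    assigned = {a.tag_seq for a in assignments if a.family in kept_families}
    conserved_mirnas = {
        a.source_mirna: a.tag_seq for a in assignments if a.family in kept_families and not a.is_star
    }
    _stage(
        manifest, "conserved",
        assignments=len(assignments), families_kept=len(kept), families_dropped=len(dropped),
    )
    log(f"{len(assignments)} tags in {len(kept)} kept families ({len(dropped)} dropped)")

    # ---- stage 5: novel miRNA prediction (contig mode: exact mapping)
    remaining = [s for s in unannot if s not in assigned]
    hits = map_tags(remaining, bundle.genome, pcfg, max_mismatch=0)
    tag_counts = {t.seq: t.total() for t in table.tags}
    genome_seqs = {k: rna(v) for k, v in bundle.genome.items()}
    accepted = []
    seen_candidates = set()
    for hit in hits:
        for cand in excise_candidates(hit, genome_seqs[hit.ref_id], pcfg):
            key = (cand.ref_id, cand.strand, cand.precursor_start, cand.mature_span)
            if key in seen_candidates:
                continue
            seen_candidates.add(key)
            ok, _reasons = evaluate_hairpin(cand, pcfg)
            if ok:
                accepted.append(cand)
    novel = dominance_filter(accepted, hits, tag_counts, pcfg)
    novel_rows = [
        {
            "name": f"novel_{i + 1}",
            "mature_seq": c.mature_seq,
            "precursor_seq": c.precursor_seq,
            "structure": c.structure,
            "mfe": c.mfe,
            "arm": c.arm,
            "dominance": round(c.dominance, 4),
            "ref_id": c.ref_id,
            "count": tag_counts.get(c.mature_seq, 0),
        }
        for i, c in enumerate(novel)
    ]
    pd.DataFrame(novel_rows).to_csv(outdir / "novel_mirnas.tsv", sep="\t", index=False)
    (outdir / "novel_mirnas.gff3").write_text(to_gff3(novel))
    _stage(manifest, "novel", mapped_tags=len({h.tag_seq for h in hits}), accepted=len(novel))
    log(f"novel prediction: {len(novel)} accepted hairpins")

    # ---- stage 6: tasiRNA scan (unannotated + exon tags, 21-nt only)
    exon_tags = [s for s, r in records.items() if r.category == "exon"]
    tasi_input = [s for s in remaining + exon_tags if len(s) == pcfg.phase_len]
    tasi_hits = map_tags(tasi_input, bundle.genome, pcfg, max_mismatch=0)
    pileups: dict[str, dict[int, int]] = {}
    for h in tasi_hits:
        if h.strand != "+":
            continue
        pileups.setdefault(h.ref_id, {})
        pileups[h.ref_id][h.start] = pileups[h.ref_id].get(h.start, 0) + tag_counts.get(h.tag_seq, 0)
    tas_loci = []
    for rid in sorted(pileups):
        windows = scan_phasing(pileups[rid], len(genome_seqs[rid]), rid, pcfg)
        tas_loci.extend(call_tas_loci(windows, pileups[rid], genome_seqs[rid], pcfg))
    known = match_known_tas(remaining, bundle.known_tas, pcfg) if bundle.known_tas else {}
    for locus in tas_loci:
        for tag in locus.member_tags:
            if tag in known:
                locus.known_tas_match = known[tag]
    tas_rows = [
        {
            "ref_id": l.ref_id, "start": l.start, "end": l.end, "strand": l.strand,
            "p_value": l.p_value, "n_tasirnas": len(l.member_tags),
            "known_tas_match": l.known_tas_match,
        }
        for l in tas_loci
    ]
    pd.DataFrame(tas_rows).to_csv(outdir / "tas_loci.tsv", sep="\t", index=False)
    _stage(
        manifest, "tasirna",
        loci=len(tas_loci), tasirnas=sum(len(l.member_tags) for l in tas_loci),
        known_matches=len(known),
    )
    log(f"tasiRNA: {len(tas_loci)} loci; {WORDING_NOTE}")

    # ---- stage 7: target prediction
    mirna_set = dict(conserved_mirnas)
    for i, c in enumerate(novel):
        mirna_set[f"novel_{i + 1}"] = c.mature_seq
    from .targets import find_targets

    target_hits = find_targets(mirna_set, bundle.transcripts, pcfg)
    pd.DataFrame(
        [
            {
                "mirna": h.mirna_id, "target": h.target_id,
                "start": h.target_span[0], "end": h.target_span[1],
                "score": h.score, "mfe": h.duplex_mfe, "rank": h.rank,
                "aligned_mirna": h.aligned_mirna, "aligned_target": h.aligned_target,
                "pairs": h.pair_string,
            }
            for h in target_hits
        ]
    ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
    _stage(manifest, "targets", mirnas=len(mirna_set), hits=len(target_hits))
    log(f"targets: {len(target_hits)} accepted sites for {len(mirna_set)} miRNAs")

    # ---- stage 8: GO enrichment of target genes
    population = sorted(go_map.genes() | set(bundle.transcripts))
    study = sorted({h.target_id for h in target_hits})
    enrichment = term_for_term(study, population, go_map, pcfg) if study else []
    pd.DataFrame([dataclasses.asdict(r) for r in enrichment]).to_csv(
        outdir / "go_enrichment.tsv", sep="\t", index=False
    )
    _stage(
        manifest, "enrichment",
        terms_tested=len(enrichment),
        significant=sum(r.p_adj <= pcfg.enrich_p_threshold for r in enrichment),
    )

    manifest["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "report.md").write_text(report(manifest))
    return PipelineResult(
        outdir=outdir, manifest=manifest, table=table, records=records,
        assignments=assignments, kept_families=kept, novel=novel,
        tas_loci=tas_loci, target_hits=target_hits, enrichment=enrichment,
    )


@dataclasses.dataclass
class _LoadedBundle:
    genome: dict
    refsets: list
    mirna_native: list
    mirna_other: list
    transcripts: dict
    known_tas: dict


def report(manifest: dict[str, Any]) -> str:
    """Render the run manifest as a markdown summary."""
    lines = [
        "# Small RNA pipeline run summary",
        "",
        f"pipeline version {manifest.get('version', '?')}, seed {manifest.get('seed')}",
        "",
        "## Clean-read annotation ledger",
        "",
    ]
    ledger = manifest.get("ledger") or []
    if ledger:
        cols = list(ledger[0])
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for row in ledger:
            lines.append(
                "| "
                + " | ".join(
                    f"{row[c]:.2f}" if isinstance(row[c], float) else str(row[c]) for c in cols
                )
                + " |"
            )
    else:
        lines.append("(no annotation ledger; cascade stage produced zero categories)")
    lines += ["", "## Stage counts", ""]
    for stage in manifest.get("stages", []):
        rest = ", ".join(f"{k}={v}" for k, v in stage.items() if k != "stage")
        lines.append(f"- **{stage['stage']}**: {rest if rest else '(no counts)'}")
    for note in manifest.get("notes", []):
        lines += ["", f"_Note: {note}_"]
    return "\n".join(lines) + "\n"
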