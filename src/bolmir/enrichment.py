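"""Term-for-term GO overrepresentation with Bonferroni correction.

Each term with at least one study gene is tested with the hypergeometric
upper tail P(X >= study_count) against the annotation universe; raw
p-values are Bonferroni-multiplied by the number of terms actually tested
(terms with no study gene neither get a p-value nor inflate the factor,
matching the behavior of the standard term-for-term implementations).
Annotations are propagated up the ontology first (true-path rule).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import PipelineConfig
from .stats import hypergeom_tail

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "read_annotation_tsv",
    "read_obo",
    "propagate_annotations",
    "term_for_term",
]


@dataclass
class AnnotationMap:
    """Direct gene annotations plus an optional is-a parent relation."""

    term_to_genes: dict[str, set[str]] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.term_to_genes.values():
            out |= gs
        return out

    def check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p in self.parents.get(t, ()):
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"ontology cycle through {t!r} -> {p!r}")
                if s == 0:
                    visit(p)
            state[t] = 2

        for t in list(self.parents):
            if state.get(t, 0) == 0:
                visit(t)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    study_count: int
    study_size: int
    pop_count: int
    pop_size: int
    p_raw: float
    p_adj: float

    @property
    def significant(self) -> bool:
        return self.p_adj <= PipelineConfig().enrich_p_threshold


def read_annotation_tsv(path: str | Path) -> AnnotationMap:
    """Tab-separated ``gene<TAB>term`` (one pair per line, '#' comments)."""
    amap = AnnotationMap()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene, term = line.split("\t")[:2]
        amap.term_to_genes.setdefault(term, set()).add(gene)
    return amap


def read_obo(path: str | Path) -> dict[str, set[str]]:
    """is-a parent relation from an OBO ontology file."""
    import obonet

    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return parents


def propagate_annotations(amap: AnnotationMap) -> AnnotationMap:
    """Annotate every gene to all ancestors of its terms (idempotent)."""
    amap.check_acyclic()
    out = AnnotationMap(
        term_to_genes={t: set(g) for t, g in amap.term_to_genes.items()},
        parents={t: set(p) for t, p in amap.parents.items()},
    )
    ancestors: dict[str, set[str]] = {}

    def anc(t: str) -> set[str]:
        if t not in ancestors:
            acc: set[str] = set()
            for p in out.parents.get(t, ()):
                acc.add(p)
                acc |= anc(p)
            ancestors[t] = acc
        return ancestors[t]

    for term, genes in list(amap.term_to_genes.items()):
        for a in anc(term):
            out.term_to_genes.setdefault(a, set()).update(genes)
    return out


def term_for_term(
    study: Iterable[str],
    population: Iterable[str],
    amap: AnnotationMap,
    cfg: PipelineConfig | None = None,
    propagate: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation test of *study* within *population*.

    Returns one result per term with at least one study gene, sorted by
    adjusted then raw p-value.  Raises when the study is not a subset of
    the population.
    """
    cfg = cfg or PipelineConfig()
    study_set = set(study)
    pop_set = set(population)
    if not study_set <= pop_set:
        raise ValueError("study genes must be a subset of the population")
    annotated = propagate_annotations(amap) if propagate else amap
    N = len(pop_set)
    n = len(study_set)
    tested: list[tuple[str, int, int]] = []
    for term in sorted(annotated.term_to_genes):
        pop_count = len(annotated.term_to_genes[term] & pop_set)
        study_count = len(annotated.term_to_genes[term] & study_set)
        if study_count >= 1:
            tested.append((term, study_count, pop_count))
    m = len(tested)
    results = []
    for term, k, K in tested:
        p_raw = hypergeom_tail(k, N, K, n)
        results.append(
            EnrichmentResult(
                term=term, study_count=k, study_size=n,
                pop_count=K, pop_size=N,
                p_raw=p_raw, p_adj=min(1.0, p_raw * m),
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
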