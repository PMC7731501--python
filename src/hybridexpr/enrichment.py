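"""Topology-aware GO enrichment (elim-KS) and redundancy reduction.

Terms are tested with a one-sided two-sample Kolmogorov-Smirnov test of
the scores (DE or association p-values; smaller = more interesting) of a
term's genes against all other scored genes.  The elim variant walks the
DAG from the deepest terms upward: when a term tests below the
elimination cutoff, its genes are removed from the retained gene sets of
all its ancestors before those are tested, so a parent is only called
enriched if it carries signal beyond its significant descendants.

Redundancy among significant terms is reduced with Lin semantic
similarity, sim(t1, t2) = 2 IC(MICA) / (IC(t1) + IC(t2)) where IC is the
information content -log(n_t / n_root) from the propagated annotation
corpus and MICA the common ancestor with maximal IC.  A greedy sweep in
ascending p order keeps a term iff its similarity to every kept term
stays at or below the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ks_2samp


@dataclass
class GODag:
    """Acyclic single-rooted is_a hierarchy; edges point child -> parent."""

    graph: nx.DiGraph
    root: str = field(init=False)
    depths: dict[str, int] = field(init=False)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO graph contains a cycle")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {roots}")
        self.root = roots[0]
        # depth = longest path from the root, via topological order
        depths = {self.root: 0}
        for term in reversed(list(nx.topological_sort(g))):
            if term == self.root:
                continue
            parents = list(g.successors(term))
            if not parents:
                raise ValueError(f"non-root term {term!r} has no parent")
            depths[term] = 1 + max(depths[p] for p in parents)
        self.depths = depths

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        names: Mapping[str, str] | None = None,
    ) -> "GODag":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(graph=g, names=dict(names or {}))

    @classmethod
    def from_obo(cls, path: str) -> "GODag":
        import obonet

        raw = obonet.read_obo(path)
        g = nx.DiGraph()
        names = {}
        for term, data in raw.nodes(data=True):
            g.add_node(term)
            if "name" in data:
                names[term] = data["name"]
        for child, parent, key in raw.edges(keys=True):
            if key == "is_a":
                g.add_edge(child, parent)
        return cls(graph=g, names=names)

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """Proper ancestors of ``term`` (excluding itself)."""
        return nx.descendants(self.graph, term)


@dataclass
class AnnotationSet:
    """Direct and true-path-propagated gene annotations with term IC."""

    direct: dict[str, set[str]]  # gene -> terms
    term_genes: dict[str, set[str]]  # term -> genes after propagation
    ic: dict[str, float]  # defined only for terms with >= 1 gene
    n_genes: int


def propagate_annotations(
    dag: GODag, direct: Mapping[str, Iterable[str]]
) -> AnnotationSet:
    """Apply the true-path rule and compute information content.

    Every gene annotated to a term is annotated to all the term's
    ancestors; IC(t) = -log(n_t / n_root) over the propagated corpus.
    Terms with no annotations have undefined IC and are absent from
    ``ic``.
    """
    term_genes: dict[str, set[str]] = {t: set() for t in dag.terms}
    direct_clean: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        tset = set(terms)
        for t in tset:
            if t not in term_genes:
                raise ValueError(f"unknown term id {t!r} for gene {gene!r}")
            term_genes[t].add(gene)
            for anc in dag.ancestors(t):
                term_genes[anc].add(gene)
        direct_clean[gene] = tset
    n_root = len(term_genes[dag.root])
    ic = {
        t: -math.log(len(genes) / n_root)
        for t, genes in term_genes.items()
        if genes and n_root > 0
    }
    return AnnotationSet(
        direct=direct_clean, term_genes=term_genes, ic=ic, n_genes=n_root
    )


def _ks_p(term_scores: np.ndarray, other_scores: np.ndarray) -> float:
    """One-sided KS p: are the term's scores stochastically smaller?"""
    if other_scores.size == 0 or term_scores.size == 0:
        return 1.0
    # alternative="greater": the term ECDF dominates, i.e. smaller scores
    return float(ks_2samp(term_scores, other_scores, alternative="greater").pvalue)


def elim_ks(
    scores: Mapping[str, float],
    ann: AnnotationSet,
    dag: GODag,
    elim_cutoff: float = 0.01,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Classic and elim KS enrichment over all terms.

    ``scores`` maps genes to p-value-like scores in [0, 1]; the score
    universe defines the background.  Terms whose retained gene set drops
    below ``min_genes`` are skipped (p = NaN).  Returns a DataFrame with
    columns term, name, depth, n_annotated, n_retained, classic_p,
    elim_p sorted by elim_p.
    """
    if not scores:
        raise ValueError("empty score list")
    bad = [g for g, s in scores.items() if not (0.0 <= s <= 1.0)]
    if bad:
        raise ValueError(f"scores outside [0, 1] for genes: {bad[:5]}")
    universe = set(scores)
    score_of = {g: float(scores[g]) for g in universe}

    retained = {
        t: set(g for g in ann.term_genes[t] if g in universe) for t in dag.terms
    }
    annotated = {t: frozenset(retained[t]) for t in dag.terms}

    order = sorted(dag.terms, key=lambda t: (-dag.depths[t], t))
    rows = []
    for term in order:
        full = annotated[term]
        classic_p = np.nan
        if len(full) >= min_genes:
            in_s = np.array([score_of[g] for g in full])
            out_s = np.array([score_of[g] for g in universe - full])
            classic_p = _ks_p(in_s, out_s)
        kept = retained[term]
        elim_p = np.nan
        if len(kept) >= min_genes:
            in_s = np.array([score_of[g] for g in kept])
            out_s = np.array([score_of[g] for g in universe - kept])
            elim_p = _ks_p(in_s, out_s)
            if elim_p < elim_cutoff:
                removed = set(kept)
                for anc in dag.ancestors(term):
                    retained[anc] -= removed
        rows.append(
            {
                "term": term,
                "name": dag.names.get(term, ""),
                "depth": dag.depths[term],
                "n_annotated": len(full),
                "n_retained": len(kept),
                "classic_p": classic_p,
                "elim_p": elim_p,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["elim_p", "term"], na_position="last")
        .reset_index(drop=True)
    )


def lin_similarity(t1: str, t2: str, ann: AnnotationSet, dag: GODag) -> float:
    """Lin semantic similarity via the maximum-IC common ancestor."""
    for t in (t1, t2):
        if t not in ann.ic:
            raise ValueError(f"term {t!r} has no annotations, IC undefined")
    common = (dag.ancestors(t1) | {t1}) & (dag.ancestors(t2) | {t2})
    mica_ic = max((ann.ic[t] for t in common if t in ann.ic), default=0.0)
    denom = ann.ic[t1] + ann.ic[t2]
    if denom == 0.0:
        return 1.0  # both terms carry no information: fully redundant
    return 2.0 * mica_ic / denom


def reduce_redundancy(
    result: pd.DataFrame,
    ann: AnnotationSet,
    dag: GODag,
    sim_threshold: float = 0.5,
    p_column: str = "elim_p",
) -> pd.DataFrame:
    """Flag representative terms among significant ones.

    Greedy sweep in ascending p order (ties broken by larger IC, then
    term id): a term is representative iff its Lin similarity to every
    previously kept term is <= ``sim_threshold``.
    """
    df = result.copy()
    ordered = sorted(
        df.itertuples(index=True),
        key=lambda r: (
            getattr(r, p_column),
            -ann.ic.get(r.term, float("-inf")),
            r.term,
        ),
    )
    kept: list[str] = []
    flags = pd.Series(False, index=df.index)
    for row in ordered:
        p = getattr(row, p_column)
        if not np.isfinite(p):
            continue
        if all(
            lin_similarity(row.term, k, ann, dag) <= sim_threshold for k in kept
        ):
            kept.append(row.term)
            flags.at[row.Index] = True
    df["representative"] = flags
    return df
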