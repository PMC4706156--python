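"""GO functional-annotation clustering and DAG-decorrelated gene-set enrichment.

Two complementary views of a disease-associated gene list:

* DAVID-style clustering — per-term EASE p-values (hypergeometric tail with the
  overlap reduced by one), Cohen's kappa agreement between term memberships over
  the gene list, fuzzy heuristic grouping of similar terms, and a cluster
  enrichment score ES = -log10(geometric mean of member term p-values), with
  ES >= 1.3 (mean p <= 0.05) highlighted.

* Ranked gene-set enrichment — genes scored by their best gene-based p-value,
  each GO term tested by a one-sided two-sample Kolmogorov-Smirnov test
  (members stochastically smaller), optionally decorrelated over the is_a DAG by
  the elim or weight01 heuristics so that ancestors are not re-credited for
  signal already explained by a significant descendant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .errors import GraphError

NAMESPACES = ("BP", "CC", "MF")


class GoGraph:
    """GO subset: is_a DAG (edges child -> parent) plus term -> gene annotation,
    propagated so every term also carries its descendants' genes."""

    def __init__(self, graph: nx.DiGraph, annotation: dict[str, frozenset],
                 namespace: dict[str, str]):
        self.graph = graph
        self.annotation = annotation
        self.namespace = namespace

    @classmethod
    def from_records(cls, annotations, edges) -> "GoGraph":
        g = nx.DiGraph()
        direct: dict[str, set] = {}
        namespace: dict[str, str] = {}
        for term, ns, gene in annotations:
            direct.setdefault(term, set()).add(gene)
            if term in namespace and namespace[term] != ns:
                raise GraphError(f"term {term} annotated under two namespaces")
            namespace[term] = ns
            g.add_node(term)
        for child, parent in edges:
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise GraphError(f"is_a edges contain a cycle: {cyc}")
        # propagate annotations child -> parent (parent superset of children)
        prop = {t: set(direct.get(t, set())) for t in g.nodes}
        for term in nx.topological_sort(g):  # children before parents
            for parent in g.successors(term):
                prop.setdefault(parent, set()).update(prop.get(term, set()))
        for t in prop:
            if t not in namespace:
                # inherit namespace from any child
                for c in nx.ancestors(g, t):
                    if c in namespace:
                        namespace[t] = namespace[c]
                        break
        annotation = {t: frozenset(s) for t, s in prop.items()}
        return cls(g, annotation, namespace)

    @property
    def terms(self) -> list[str]:
        return sorted(self.annotation)

    def genes(self) -> frozenset:
        out: set = set()
        for s in self.annotation.values():
            out |= s
        return frozenset(out)

    def ancestors(self, term: str) -> set[str]:
        """Strict ancestors (more general terms reachable via is_a)."""
        return nx.descendants(self.graph, term)


def ease_p(k: int, n: int, big_k: int, big_n: int, modified: bool = True) -> float:
    """Term enrichment p for a gene list: hypergeometric upper tail of drawing
    ``k`` of term ``big_k`` in a list of ``n`` from a universe of ``big_n``.
    ``modified=True`` (EASE) discounts one overlapping gene: P(X >= k - 1)."""
    if not (0 <= k <= min(n, big_k) and n <= big_n and big_k <= big_n):
        raise ValueError(f"impossible contingency: k={k}, n={n}, K={big_k}, N={big_n}")
    if k == 0:
        return 1.0
    shift = 1 if modified else 0
    return float(scipy.stats.hypergeom.sf(k - shift - 1, big_n, big_k, n))


def kappa_pair(genes_a: set, genes_b: set, gene_list) -> float:
    """Cohen's kappa of two term memberships over the gene list; defined as 0
    when expected agreement is 1 (both memberships constant)."""
    genes = list(gene_list)
    t = len(genes)
    if t == 0:
        raise ValueError("empty gene list")
    in_a = np.array([g in genes_a for g in genes])
    in_b = np.array([g in genes_b for g in genes])
    obs = float((in_a == in_b).mean())
    pa, pb = in_a.mean(), in_b.mean()
    exp = pa * pb + (1 - pa) * (1 - pb)
    if exp >= 1.0 - 1e-12:
        return 0.0
    return float((obs - exp) / (1.0 - exp))


def cluster_es(member_pvalues) -> float:
    """Enrichment score: -log10 of the geometric mean of member term p-values."""
    p = np.asarray(list(member_pvalues), dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-np.mean(np.log10(p)))


def es_to_p(es: float) -> float:
    """Geometric-mean p corresponding to an enrichment score (10**-ES)."""
    return float(10.0 ** (-es))


@dataclass
class Cluster:
    terms: list[str]
    es: float
    highlighted: bool


@dataclass
class ClusterReport:
    clusters: list[Cluster] = field(default_factory=list)
    unclustered: list[str] = field(default_factory=list)


def fuzzy_cluster(
    term_members: dict[str, set],
    term_pvalues: dict[str, float],
    gene_list,
    kappa_threshold: float = 0.85,
    seed_membership: int = 3,
    merge_overlap: float = 0.5,
    es_highlight: float = 1.3,
) -> ClusterReport:
    """Fuzzy heuristic grouping of functionally similar terms.

    A term seeds a group when its kappa >= threshold neighbourhood reaches
    ``seed_membership`` members with majority pairwise agreement; seed groups
    sharing >= ``merge_overlap`` of their smaller member set are merged
    iteratively in deterministic (term id) order. Cluster ES comes from the
    member terms' p-values; ES >= ``es_highlight`` marks the cluster.
    """
    terms = sorted(term_members)
    genes = sorted(set(gene_list))
    kap = {}
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            kap[(a, b)] = kap[(b, a)] = kappa_pair(term_members[a], term_members[b], genes)

    seeds: list[set[str]] = []
    for t in terms:
        group = {t} | {u for u in terms if u != t and kap[(t, u)] >= kappa_threshold}
        if len(group) < seed_membership:
            continue
        members = sorted(group)
        pairs = [(a, b) for i, a in enumerate(members) for b in members[i + 1:]]
        agree = sum(1 for a, b in pairs if kap[(a, b)] >= kappa_threshold)
        if pairs and agree / len(pairs) > 0.5:
            seeds.append(group)

    merged = True
    while merged:
        merged = False
        seeds.sort(key=lambda s: sorted(s))
        for i in range(len(seeds)):
            for j in range(i + 1, len(seeds)):
                inter = len(seeds[i] & seeds[j])
                if inter and inter / min(len(seeds[i]), len(seeds[j])) >= merge_overlap:
                    seeds[i] = seeds[i] | seeds[j]
                    del seeds[j]
                    merged = True
                    break
            if merged:
                break

    clustered: set[str] = set()
    report = ClusterReport()
    for group in seeds:
        members = sorted(group)
        es = cluster_es([term_pvalues[t] for t in members])
        report.clusters.append(Cluster(members, es, es >= es_highlight))
        clustered |= group
    report.clusters.sort(key=lambda c: -c.es)
    report.unclustered = [t for t in terms if t not in clustered]
    return report


def gene_score(method_pvalues: dict[str, float]) -> float:
    """Gene score for ranked enrichment: the minimum available gene-based
    p-value; raises when every method is missing."""
    vals = [v for v in method_pvalues.values() if v is not None and np.isfinite(v)]
    if not vals:
        raise ValueError("no gene-based p-value available")
    return float(min(vals))


def gene_scores(gene_results: pd.DataFrame) -> pd.Series:
    """Per-gene minimum p over methods from a long gene-results table
    (columns gene, method, p_raw); genes with no finite p are dropped."""
    ok = gene_results.dropna(subset=["p_raw"])
    return ok.groupby("gene")["p_raw"].min()


def ks_term_p(
    scores: pd.Series, member_genes: set, min_genes: int = 8
) -> float | None:
    """One-sided two-sample KS test that member scores are stochastically
    smaller than non-member scores; exact distribution when both groups are
    small (<= 25), asymptotic otherwise. Returns None for excluded terms
    (fewer than ``min_genes`` scored members, or no complement)."""
    members = scores.index.isin(member_genes)
    m_scores = scores[members].to_numpy()
    o_scores = scores[~members].to_numpy()
    if m_scores.size < min_genes or o_scores.size == 0:
        return None
    method = "exact" if max(m_scores.size, o_scores.size) <= 25 else "asymp"
    res = scipy.stats.ks_2samp(m_scores, o_scores, alternative="greater", method=method)
    return float(res.pvalue)


def _weighted_ks_p(scores: pd.Series, member_weights: dict[str, float],
                   min_genes: int = 8) -> float | None:
    """One-sided KS with weighted member contributions (weight01 path).

    The member ECDF weights each gene by its residual claim; the p-value uses
    the one-sided asymptotic tail with the weighted effective sample size
    (sum w)^2 / sum w^2. Genes at weight zero drop to the complement.
    """
    w = {g: wt for g, wt in member_weights.items() if wt > 0 and g in scores.index}
    if len(w) < min_genes:
        return None
    members = np.array(sorted(w))
    o_mask = ~scores.index.isin(members)
    others = scores[o_mask].to_numpy()
    if others.size == 0:
        return None
    ms = scores[members].to_numpy()
    wts = np.array([w[g] for g in members])
    order = np.argsort(ms, kind="stable")
    ms, wts = ms[order], wts[order]
    others = np.sort(others)
    grid = np.unique(np.concatenate([ms, others]))
    f_m = np.cumsum(wts)[np.searchsorted(ms, grid, side="right") - 1]
    f_m = np.where(np.searchsorted(ms, grid, side="right") > 0, f_m, 0.0) / wts.sum()
    f_o = np.searchsorted(others, grid, side="right") / others.size
    d_plus = float(np.max(f_m - f_o))
    n1 = wts.sum() ** 2 / np.sum(wts**2)
    n2 = others.size
    n_eff = n1 * n2 / (n1 + n2)
    return float(min(1.0, math.exp(-2.0 * n_eff * d_plus**2)))


def decorrelate_run(
    go: GoGraph,
    scores: pd.Series,
    algorithm: str = "weight01",
    elim_cutoff: float = 0.01,
    min_genes: int = 8,
    namespace: str | None = None,
) -> pd.DataFrame:
    """Per-term enrichment p-values with optional DAG decorrelation.

    classic: plain per-term KS. elim: terms are processed leaves first; once a
    term's p drops below ``elim_cutoff`` its genes are removed from all its
    ancestors before those are tested. weight01: elim's removal plus weight-style
    down-weighting — genes claimed by a more significant child keep only the
    weight (-log10 p_parent) / (-log10 p_child), capped at 1, in the ancestor's
    membership. Deterministic given inputs.
    """
    if algorithm not in {"classic", "elim", "weight01"}:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    terms = [t for t in go.terms
             if namespace is None or go.namespace.get(t) == namespace]
    term_set = set(terms)
    topo = [t for t in nx.topological_sort(go.graph) if t in term_set]
    topo += [t for t in terms if t not in set(topo)]  # isolated annotation-only terms

    classic_p: dict[str, float | None] = {}
    if algorithm in {"classic", "weight01"}:
        for t in terms:
            classic_p[t] = ks_term_p(scores, go.annotation.get(t, frozenset()), min_genes)
    if algorithm == "classic":
        result = classic_p
    elif algorithm == "elim":
        removed: dict[str, set] = {t: set() for t in terms}
        result = {}
        for t in topo:
            genes = set(go.annotation.get(t, frozenset())) - removed[t]
            p = ks_term_p(scores, genes, min_genes)
            result[t] = p
            if p is not None and p < elim_cutoff:
                for anc in go.ancestors(t):
                    if anc in removed:
                        removed[anc] |= set(go.annotation.get(t, frozenset()))
    else:  # weight01
        weights: dict[str, dict[str, float]] = {
            t: {g: 1.0 for g in go.annotation.get(t, frozenset())} for t in terms
        }
        result = {}
        for t in topo:
            wt = weights[t]
            if all(w == 1.0 for w in wt.values()):
                p = ks_term_p(scores, set(wt), min_genes)
            else:
                p = _weighted_ks_p(scores, wt, min_genes)
            result[t] = p
            if p is None:
                continue
            for anc in go.ancestors(t):
                if anc not in weights:
                    continue
                p_anc = classic_p.get(anc)
                if p < elim_cutoff:
                    factor = 0.0
                elif p_anc is not None and p < p_anc:
                    factor = min(1.0, math.log10(p_anc) / math.log10(p))
                else:
                    continue
                for g in go.annotation.get(t, frozenset()):
                    if g in weights[anc]:
                        weights[anc][g] *= factor

    rows = [
        {"term": t, "namespace": go.namespace.get(t, ""),
         "n_genes": len(go.annotation.get(t, frozenset())), "p": result.get(t)}
        for t in terms
    ]
    return pd.DataFrame(rows, columns=["term", "namespace", "n_genes", "p"])


def group_terms(term_table: pd.DataFrame,
                cutoffs: tuple[float, float, float] = (0.001, 0.005, 0.01)) -> pd.DataFrame:
    """Label significant terms into report groups: group 1 p < cutoffs[0],
    group 2 cutoffs[0] <= p < cutoffs[1], group 3 cutoffs[1] <= p < cutoffs[2]."""
    df = term_table.copy()
    c1, c2, c3 = cutoffs

    def grp(p):
        if p is None or not np.isfinite(p) or p >= c3:
            return 0
        if p < c1:
            return 1
        if p < c2:
            return 2
        return 3

    df["group"] = df["p"].map(grp)
    return df
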