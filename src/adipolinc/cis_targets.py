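"""Neighbor discovery (<100 kb), correlation-based target prediction, network export.

A protein-coding gene is a potential target gene (PTG) of a lincRNA gene when
their expression profiles are Pearson-correlated at raw p < 0.05 (the
classical rule; a BH option exists for principled use), and a DEPTG when the
coding gene is additionally differentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval
from .diffexpr import bh_adjust


@dataclass(frozen=True)
class GeneLocus:
    """A gene's union span over its transcripts, tagged lincrna or coding."""

    gene_id: str
    interval: GenomicInterval
    category: str  # lincrna | coding


@dataclass
class TargetEdge:
    lincrna_gene: str
    coding_gene: str
    r: float
    p: float
    n: int
    is_neighbor: bool = False
    is_ptg: bool = False
    is_deptg: bool = False

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"


def find_neighbors(
    lincrna_loci: Iterable[GeneLocus],
    coding_loci: Iterable[GeneLocus],
    window: int = 100_000,
) -> list[tuple[str, str, int]]:
    """All (lincRNA, coding, gap) pairs on the same chromosome with gap < window.

    Gap is max(0, max(starts) - min(ends)); overlapping loci have gap 0.
    Strand is ignored.
    """
    out = []
    coding_by_chrom: dict[str, list[GeneLocus]] = {}
    for c in coding_loci:
        coding_by_chrom.setdefault(c.interval.chrom, []).append(c)
    for l in lincrna_loci:
        for c in coding_by_chrom.get(l.interval.chrom, []):
            gap = l.interval.gap(c.interval)
            if gap < window:
                out.append((l.gene_id, c.gene_id, gap))
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the exact t-transform.

    t = r * sqrt(n-2) / sqrt(1-r^2), with n-2 degrees of freedom.
    |r| = 1 returns p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def predict_targets(
    lincrna_expr: pd.DataFrame,
    coding_expr: pd.DataFrame,
    de_coding_ids: Iterable[str],
    alpha: float = 0.05,
    neighbors: Iterable[tuple[str, str, int]] | None = None,
    adjust: bool = False,
) -> list[TargetEdge]:
    """Test every lincRNA x coding pair; flag PTGs (p < alpha) and DEPTGs.

    Both expression matrices must share an identical sample ordering.
    ``adjust=True`` applies BH to the pairwise p-values before the PTG call.
    """
    if list(lincrna_expr.columns) != list(coding_expr.columns):
        raise ValueError("lincRNA and coding matrices must share sample order")
    n = lincrna_expr.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    de_set = set(de_coding_ids)
    neighbor_set = (
        {(a, b) for a, b, _ in neighbors} if neighbors is not None else set()
    )

    lm = lincrna_expr.values.astype(float)
    cm = coding_expr.values.astype(float)
    lz = lm - lm.mean(axis=1, keepdims=True)
    cz = cm - cm.mean(axis=1, keepdims=True)
    lsd = np.sqrt((lz**2).sum(axis=1))
    csd = np.sqrt((cz**2).sum(axis=1))
    if (lsd == 0).any() or (csd == 0).any():
        bad = list(lincrna_expr.index[lsd == 0]) + list(coding_expr.index[csd == 0])
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    rmat = np.clip((lz @ cz.T) / np.outer(lsd, csd), -1.0, 1.0)

    edges = []
    pvals = []
    for i, lg in enumerate(lincrna_expr.index):
        for j, cg in enumerate(coding_expr.index):
            r = float(rmat[i, j])
            p = pearson_pvalue(r, n)
            pvals.append(p)
            edges.append(
                TargetEdge(
                    lincrna_gene=lg,
                    coding_gene=cg,
                    r=r,
                    p=p,
                    n=n,
                    is_neighbor=(lg, cg) in neighbor_set,
                )
            )
    effective_p = bh_adjust(np.asarray(pvals)) if adjust else np.asarray(pvals)
    for e, p in zip(edges, effective_p):
        e.is_ptg = bool(p < alpha)
        e.is_deptg = e.is_ptg and e.coding_gene in de_set
    return edges


def build_network(
    edges: Iterable[TargetEdge], restrict: str = "deptg_only"
) -> nx.Graph:
    """Bipartite lincRNA-coding co-expression graph from passing edges."""
    if restrict not in {"deptg_only", "all"}:
        raise ValueError("restrict must be 'deptg_only' or 'all'")
    g = nx.Graph()
    for e in edges:
        if restrict == "deptg_only" and not e.is_deptg:
            continue
        if restrict == "all" and not e.is_ptg:
            continue
        g.add_node(e.lincrna_gene, bipartite="lincrna")
        g.add_node(e.coding_gene, bipartite="coding")
        g.add_edge(e.lincrna_gene, e.coding_gene, r=e.r, p=e.p, sign=e.sign)
    return g


def edges_to_frame(edges: Iterable[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lincrna_gene": e.lincrna_gene,
                "coding_gene": e.coding_gene,
                "r": e.r,
                "p": e.p,
                "n": e.n,
                "is_neighbor": e.is_neighbor,
                "is_ptg": e.is_ptg,
                "is_deptg": e.is_deptg,
                "sign": e.sign,
            }
            for e in edges
        ]
    )
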