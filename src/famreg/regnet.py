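"""Motif-gated coexpression network inference.

An edge regulator->target exists iff the target's promoter carries the
regulator family's binding site AND the Pearson correlation of their
expression profiles passes the threshold (|r| >= threshold, inclusive on
both sides by default). Correlation is computed on raw FPKM.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from .genome_io import ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.90


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Standard Pearson correlation; raises on constant profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 conditions for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("constant profile: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def edge_sign(r: float) -> str:
    return "activation" if r >= 0 else "repression"


def build_network(
    expr: ExpressionMatrix,
    regulator_motifs: dict[str, str],
    motif_targets: dict[str, set[str]],
    threshold: float = DEFAULT_THRESHOLD,
    inclusive: bool = True,
    node_groups: dict[str, str] | None = None,
    tissue_of_max: dict[str, str] | None = None,
) -> nx.DiGraph:
    """Assemble the evidence-gated regulatory network.

    Parameters
    ----------
    regulator_motifs
        regulator gene id -> binding-site pattern of its family.
    motif_targets
        pattern -> set of genes whose promoter carries that pattern
        (from the promoter scan).
    threshold, inclusive
        |r| >= threshold keeps an edge when inclusive, |r| > threshold
        otherwise. Sign follows the sign of r.

    Self-edges are never emitted; candidate pairs with a constant profile
    are skipped with a log entry.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    known = set(expr.gene_ids)
    for reg in regulator_motifs:
        if reg not in known:
            raise KeyError(f"regulator {reg} absent from expression matrix")
    g = nx.DiGraph()
    passes = (lambda a: a >= threshold) if inclusive else (lambda a: a > threshold)
    for reg in sorted(regulator_motifs):
        pattern = regulator_motifs[reg]
        targets = motif_targets.get(pattern, set())
        x = expr.profile(reg)
        for target in sorted(targets):
            if target == reg or target not in known:
                continue
            y = expr.profile(target)
            try:
                r = pcc(x, y)
            except ZeroDivisionError:
                log.warning(
                    "skipping %s->%s: constant expression profile", reg, target
                )
                continue
            if passes(abs(r)):
                g.add_edge(reg, target, r=r, sign=edge_sign(r))
    groups = node_groups or {}
    tmax = tissue_of_max or {}
    for node in g.nodes:
        g.nodes[node]["group"] = groups.get(node, "target")
        if node in tmax:
            g.nodes[node]["tissue_max"] = tmax[node]
    return g


def rank_hubs(network: nx.DiGraph) -> list[tuple[str, int]]:
    """Nodes by total degree descending; ties broken by gene id."""
    return sorted(
        ((node, d) for node, d in network.degree()),
        key=lambda item: (-item[1], item[0]),
    )


def tissue_max(expr: ExpressionMatrix) -> dict[str, tuple[str, bool]]:
    """Argmax condition per gene (first condition wins ties).

    Returns gene -> (condition, all_zero_flag); all-zero genes are
    reported with the flag set rather than dropped.
    """
    if not expr.gene_ids:
        raise ValueError("empty expression matrix")
    out = {}
    conditions = expr.condition_ids
    for gene in expr.gene_ids:
        profile = expr.profile(gene)
        all_zero = bool((profile == 0).all())
        out[gene] = (conditions[int(np.argmax(profile))], all_zero)
    return out
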