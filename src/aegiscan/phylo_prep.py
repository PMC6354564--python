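"""Marker filtering for phylogeny and a distance-based species tree.

Filtering mirrors the standard SNP-phylogeny pipeline defaults: a marker is
dropped when it is monomorphic, has minor allele frequency below 0.1 (the
boundary value 0.1 itself is kept — the rule is strictly "< 0.1"), or is
missing in 10% or more of the samples (the boundary is removed).  MAF is
computed on called alleles pooled across all samples.  Each removed marker
is charged to exactly one rule, in the priority order monomorphic → MAF →
missingness.

Tree building here is neighbor joining on a precomputed distance matrix,
rooted on a designated outgroup; maximum-likelihood inference and bootstrap
support belong to external pipelines fed via the hapmap writer.  Ties in
the NJ Q-criterion are broken lexicographically on the joined pair's
labels, so the topology is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .genotype_io import CallMatrix, NOCALL
from .ordination import DistanceMatrix

__all__ = ["FilterParams", "FilterReport", "TreeResult",
           "filter_markers", "neighbor_joining_tree"]


@dataclass(frozen=True)
class FilterParams:
    maf_min: float = 0.1
    max_missing: float = 0.1
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 1) or not (0 <= self.max_missing <= 1):
            raise ValueError("filter fractions must lie in [0, 1]")


@dataclass
class FilterReport:
    """Per-rule removal tallies; each marker is charged to one rule only."""

    n_in: int
    n_out: int
    removed_monomorphic: int
    removed_maf: int
    removed_missing: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rule": ["monomorphic", "maf", "missing"],
            "removed": [self.removed_monomorphic, self.removed_maf,
                        self.removed_missing],
        })


def filter_markers(matrix: CallMatrix, params: FilterParams = FilterParams()
                   ) -> tuple[CallMatrix, FilterReport]:
    """Drop low-information markers; returns the kept matrix and a report."""
    if matrix.n_samples < 2:
        raise ValueError("marker filtering needs at least 2 samples")
    calls = matrix.calls
    called = calls != NOCALL
    n_called = called.sum(axis=1)
    # integer ratio, so a marker missing in exactly 10% of samples compares
    # equal to a 0.1 threshold
    missing_frac = (matrix.n_samples - n_called) / matrix.n_samples

    lo = np.where(called, calls, 3).min(axis=1)
    hi = np.where(called, calls, -2).max(axis=1)
    monomorphic = ~((n_called >= 2) & (hi > lo))

    dosage = np.where(called, calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, dosage / np.maximum(2 * n_called, 1),
                        0.0)
    maf = np.minimum(freq, 1 - freq)

    fail_mono = monomorphic if params.drop_monomorphic else np.zeros(
        matrix.n_markers, dtype=bool)
    fail_maf = maf < params.maf_min
    fail_miss = missing_frac >= params.max_missing

    charged_mono = fail_mono
    charged_maf = fail_maf & ~charged_mono
    charged_miss = fail_miss & ~charged_mono & ~charged_maf
    drop = charged_mono | charged_maf | charged_miss
    if drop.all():
        raise ValueError("all markers removed by filtering")
    kept = matrix.subset_markers(~drop)
    report = FilterReport(
        n_in=matrix.n_markers, n_out=kept.n_markers,
        removed_monomorphic=int(charged_mono.sum()),
        removed_maf=int(charged_maf.sum()),
        removed_missing=int(charged_miss.sum()))
    return kept, report


@dataclass
class TreeResult:
    """A rooted tree in newick text plus the outgroup used to root it."""

    newick: str
    outgroup: str

    def tree(self) -> TreeNode:
        return TreeNode.read([self.newick])

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree().tips()}


def neighbor_joining_tree(dist: DistanceMatrix, outgroup: str) -> TreeResult:
    """Neighbor joining on a distance matrix, rooted on ``outgroup``.

    Canonical Q-criterion agglomeration; equal Q values are resolved in
    favour of the lexicographically smallest joined pair, so repeated runs
    give an identical topology.
    """
    labels = list(dist.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    if outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} is not a sample")

    d = {frozenset((a, b)): float(dist.values[i, j])
         for i, a in enumerate(labels) for j, b in enumerate(labels) if i < j}
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name)
                                  for name in labels}
    # sort keys: lexicographic on the original pair of labels under each node
    sort_key = {name: (name,) for name in labels}
    active = list(labels)

    while len(active) > 2:
        n = len(active)
        r = {a: sum(d[frozenset((a, b))] for b in active if b != a)
             for a in active}
        best = None
        for ia in range(n):
            for ib in range(ia + 1, n):
                a, b = active[ia], active[ib]
                q = (n - 2) * d[frozenset((a, b))] - r[a] - r[b]
                tie = tuple(sorted((sort_key[a], sort_key[b])))
                if best is None or (q, tie) < best[:2]:
                    best = (q, tie, a, b)
        _, _, a, b = best
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        # clamp tiny negative branch lengths from noisy distances
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = TreeNode()
        ca, cb = nodes.pop(a), nodes.pop(b)
        ca.length, cb.length = la, lb
        parent.extend([ca, cb])
        new = f"__internal_{len(active)}_{a}"
        nodes[new] = parent
        sort_key[new] = min(sort_key[a], sort_key[b])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new, c))] = 0.5 * (d[frozenset((a, c))]
                                            + d[frozenset((b, c))] - dab)
        active = [c for c in active if c not in (a, b)] + [new]

    a, b = active
    ca, cb = nodes[a], nodes[b]
    dab = d[frozenset((a, b))]
    ca.length = cb.length = dab / 2
    root = TreeNode()
    root.extend([ca, cb])

    rooted = root.root_by_outgroup([outgroup], branch_attrs=[])
    newick = str(rooted).strip()
    return TreeResult(newick=newick, outgroup=outgroup)
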