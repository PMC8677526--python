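"""Posterior summaries: MCC trees, lineage-through-time curves, and
branch-length comparisons between posteriors.

Clade identity follows the extant-taxon rule: a node is the root of the
subtree containing all of, and only, a given set of *extant* taxa; fossil
taxa never enter clade keys.  This makes supports and node ages comparable
between analyses that resolve fossil placements differently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import AGE_TOL, TimeTree, parse_tree
from .validation import hpd_interval


def _as_trees(samples):
    out = []
    for t in samples:
        out.append(parse_tree(t) if isinstance(t, str) else t)
    return out


def _extant_clades(tree):
    """{node id: frozenset of extant taxa below}, bottom-up."""
    clades = {}
    for node in tree.postorder():
        acc = set()
        if node.is_sample and node.age <= AGE_TOL:
            acc.add(node.label)
        for c in node.children:
            acc |= clades[id(c)]
        clades[id(node)] = frozenset(acc)
    return clades


# ---------------------------------------------------------------------------
# MCC tree
# ---------------------------------------------------------------------------

def mcc_tree(samples) -> TimeTree:
    """Maximum clade credibility tree of a posterior sample.

    Returns the sampled tree maximizing the product of its clades'
    posterior frequencies, annotated per node (``meta``) with the clade
    support and the mean age of the clade among the samples containing it.
    """
    trees = _as_trees(samples)
    if not trees:
        raise ValueError("empty tree sample")
    n = len(trees)

    counts = {}
    age_sums = {}
    per_tree_keys = []
    for tree in trees:
        clades = _extant_clades(tree)
        keys = []
        for node in tree.preorder():
            key = clades[id(node)]
            if len(key) < 2 or len(node.children) < 2:
                continue
            keys.append(key)
            counts[key] = counts.get(key, 0) + 1
            age_sums[key] = age_sums.get(key, 0.0) + node.age
        per_tree_keys.append(keys)

    best_i = 0
    best_score = -math.inf
    for i, keys in enumerate(per_tree_keys):
        score = sum(math.log(counts[k] / n) for k in keys)
        if score > best_score:
            best_score = score
            best_i = i

    mcc = trees[best_i].copy()
    clades = _extant_clades(mcc)
    for node in mcc.preorder():
        key = clades[id(node)]
        if len(key) < 2 or len(node.children) < 2:
            continue
        c = counts[key]
        node.meta = {"posterior": c / n,
                     "age_mean": age_sums[key] / c}
    return mcc


# ---------------------------------------------------------------------------
# lineages through time
# ---------------------------------------------------------------------------

@dataclass
class LTTCurve:
    """Per-grid-point posterior mean lineage count with 95% HPD bounds."""
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    counts: np.ndarray = field(repr=False, default=None)  # trees x steps

    def to_frame(self):
        return pd.DataFrame({"time_Ma": self.grid, "mean": self.mean,
                             "hpd_lower": self.lower,
                             "hpd_upper": self.upper})


def ltt_curve(samples, n_steps: int = 1024, t_min: float = 0.0,
              t_max: float = None, level: float = 0.95) -> LTTCurve:
    """Lineage counts through time, including extinct and fossil lineages.

    Counts, per sampled tree, the branches alive at each of ``n_steps``
    evenly spaced times in [t_min, t_max] (the root-to-origin stem counts
    when the tree carries an origin age); the posterior mean and HPD
    interval are taken per grid point across trees.
    """
    trees = _as_trees(samples)
    if not trees:
        raise ValueError("empty tree sample")
    if t_max is None:
        t_max = max((t.origin_age or t.root.age) for t in trees)
    if t_max <= t_min:
        raise ValueError("t_max must exceed t_min")
    grid = np.linspace(t_min, t_max, n_steps)
    counts = np.zeros((len(trees), n_steps))
    for k, tree in enumerate(trees):
        lo = []
        hi = []
        for node in tree.preorder():
            if node.parent is not None:
                lo.append(node.age)
                hi.append(node.parent.age)
            else:
                top = tree.origin_age if tree.origin_age is not None \
                    else node.age
                lo.append(node.age)
                hi.append(top)
        lo = np.asarray(lo)
        hi = np.asarray(hi)
        counts[k] = ((lo[None, :] <= grid[:, None])
                     & (grid[:, None] < hi[None, :])).sum(axis=1)
        # the present itself: extant tips sit exactly at t = 0
        at_zero = grid <= AGE_TOL
        if at_zero.any():
            counts[k][at_zero] = np.maximum(
                counts[k][at_zero],
                sum(1 for n_ in tree.leaves() if n_.age <= AGE_TOL))
    mean = counts.mean(axis=0)
    lower = np.empty(n_steps)
    upper = np.empty(n_steps)
    for j in range(n_steps):
        lower[j], upper[j] = hpd_interval(counts[:, j], level)
    return LTTCurve(grid, mean, lower, upper, counts)


# ---------------------------------------------------------------------------
# branch-length comparison
# ---------------------------------------------------------------------------

def branch_length_comparison(samples_a, samples_b,
                             threshold: float = 0.005) -> pd.DataFrame:
    """Compare branch lengths between two posteriors.

    A branch is identified by its (child clade, parent clade) pair of
    extant-taxon sets and is *compared* only when both nodes are present
    in at least ``threshold`` of the trees in BOTH posteriors; other
    branches are flagged below-threshold.  The difference column is
    ``mean_b - mean_a``.
    """
    trees_a = _as_trees(samples_a)
    trees_b = _as_trees(samples_b)
    taxa_a = {l for t in trees_a for l in t.taxa}
    taxa_b = {l for t in trees_b for l in t.taxa}
    if not (taxa_a & taxa_b):
        raise ValueError("posteriors share no taxa")

    def tally(trees):
        count = {}
        length_sum = {}
        for tree in trees:
            clades = _extant_clades(tree)
            for node in tree.preorder():
                if node.parent is None:
                    continue
                ck = clades[id(node)]
                pk = clades[id(node.parent)]
                if not ck:
                    continue
                key = (ck, pk)
                count[key] = count.get(key, 0) + 1
                length_sum[key] = (length_sum.get(key, 0.0)
                                   + node.parent.age - node.age)
        return count, length_sum

    ca, sa = tally(trees_a)
    cb, sb = tally(trees_b)
    na, nb = len(trees_a), len(trees_b)
    rows = []
    for key in sorted(set(ca) | set(cb),
                      key=lambda k: (sorted(k[0]), sorted(k[1]))):
        fa = ca.get(key, 0) / na
        fb = cb.get(key, 0) / nb
        ok = fa >= threshold and fb >= threshold
        row = {"child_clade": ",".join(sorted(key[0])),
               "parent_clade": ",".join(sorted(key[1])),
               "freq_a": fa, "freq_b": fb, "compared": ok}
        if ok:
            ma = sa[key] / ca[key]
            mb = sb[key] / cb[key]
            row.update(mean_a=ma, mean_b=mb, difference=mb - ma)
        else:
            row.update(mean_a=np.nan, mean_b=np.nan, difference=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
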