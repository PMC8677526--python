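"""Generative counterparts of the model densities.

Every density in the package has a matched simulator here: forward
birth-death-fossilization simulation of species trees (optionally
conditioned on the number of sampled extant taxa by rejection), coalescent
simulation of gene trees within a species tree, and character simulation
on any time tree.  Simulation code shares only the tree data model with
the inference code; tests compare the two directions distributionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chars import MkModel, SubstModel
from .fbd import FBDParams
from .msc import MSCConfig
from .trees import TaxonMap, TimeTree, TimeTreeNode


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Configuration of one simulation replicate."""
    fbd: FBDParams = None
    n_extant: int = 8
    n_loci: int = 2
    samples_per_species: int = 2
    seq_length: int = 300
    subst_model: SubstModel = field(default_factory=SubstModel)
    msc: MSCConfig = None
    n_morph: int = 50
    morph_model: MkModel = field(default_factory=MkModel)
    seed: int = 1


# ---------------------------------------------------------------------------
# FBD species trees
# ---------------------------------------------------------------------------

def simulate_fbd_tree(params: FBDParams, n_extant: int, rng,
                      max_attempts: int = 100_000) -> TimeTree:
    """Forward FBD simulation conditioned on the sampled extant count.

    Runs the birth-death-fossilization process forward from the origin,
    thins extant tips by rho, prunes unsampled lineages, and rejects until
    exactly ``n_extant`` sampled extant tips remain.  Fossils on lineages
    with sampled descendants become sampled ancestors; others are fossil
    tips (decided by the pruning, not by an extra random choice).
    """
    params.validate()
    if params.origin_age is None:
        raise ValueError("simulation requires an origin age")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    for _ in range(max_attempts):
        tree = _simulate_fbd_once(params, rng)
        if tree is not None and len(tree.extant_tips()) == n_extant:
            return tree
    raise SimulationError(
        f"no tree with {n_extant} sampled extant tips in "
        f"{max_attempts} attempts")


def _simulate_fbd_once(params: FBDParams, rng) -> TimeTree | None:
    lam, mu, psi, rho = params.lambda_, params.mu, params.psi, params.rho
    x0 = params.origin_age
    total = lam + mu + psi

    # forward time from the origin; age = x0 - t
    anchor = TimeTreeNode(age=x0)    # placeholder above the origin lineage
    stub = TimeTreeNode(age=-1.0)
    anchor.add_child(stub)
    active = [stub]  # leaf stubs of currently alive lineages
    nodecap = 20000
    t = 0.0
    while active:
        n_act = len(active)
        t += rng.exponential(1.0 / (n_act * total))
        if t >= x0:
            break
        i = rng.integers(n_act)
        node = active[i]
        u = rng.random() * total
        age = x0 - t
        if u < lam:
            # speciation
            parent = TimeTreeNode(age=age)
            _replace(node, parent)
            c1 = TimeTreeNode(age=-1.0)
            c2 = TimeTreeNode(age=-1.0)
            parent.add_child(c1)
            parent.add_child(c2)
            active[i] = c1
            active.append(c2)
            nodecap -= 1
            if nodecap <= 0:
                return None  # runaway tree; treat as rejected
        elif u < lam + mu:
            # extinction: unsampled tip at this age
            node.age = age
            node.label = ""
            active.pop(i)
        else:
            # fossil sampling event: degree-2 marker, lineage continues
            marker = TimeTreeNode(age=age, is_sample=True, label="F?")
            _replace(node, marker)
            marker.add_child(node)
    # survivors reach the present
    for node in active:
        node.age = 0.0
        if rng.random() < rho:
            node.is_sample = True
            node.label = "T?"

    root = anchor.children[0]
    root.parent = None
    pruned = _prune_unsampled(root)
    if pruned is None:
        return None
    pruned.parent = None
    _label_samples(pruned)
    return TimeTree(pruned, origin_age=x0)


def _replace(node, replacement):
    """Splice ``replacement`` into ``node``'s position in the growing tree."""
    parent = node.parent
    parent.children[parent.children.index(node)] = replacement
    replacement.parent = parent
    node.parent = None


def _prune_unsampled(node):
    kept = []
    for c in list(node.children):
        r = _prune_unsampled(c)
        if r is not None:
            kept.append(r)
    node.children = kept
    for c in kept:
        c.parent = node
    if node.is_sample:
        return node           # fossil marker (SA or tip) or sampled extant
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return node


def _label_samples(root):
    fossils = []
    extant = []
    stack = [root]
    while stack:
        n = stack.pop()
        if n.is_sample:
            (extant if n.age == 0.0 else fossils).append(n)
        stack.extend(n.children)
    fossils.sort(key=lambda n: n.age)
    for i, n in enumerate(extant):  # deterministic traversal order
        n.label = f"T{i + 1}"
    for i, n in enumerate(fossils):
        n.label = f"F{i + 1}"


# ---------------------------------------------------------------------------
# MSC gene trees
# ---------------------------------------------------------------------------

def simulate_gene_trees(species: TimeTree, msc: MSCConfig,
                        samples_per_species: int, n_loci: int, rng,
                        taxon_map: TaxonMap | None = None):
    """Coalescent gene trees within a species tree (explicit sizes).

    Molecular samples are drawn from extant species only; tips are labeled
    ``<species>_<i>``.  Returns (gene_trees, taxon_map).
    """
    msc.validate()
    if msc.mode != "explicit":
        raise ValueError("simulation requires explicit population sizes")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mapping = {}
    for sp in species.extant_tips():
        for i in range(samples_per_species):
            mapping[f"{sp.label}_{i + 1}"] = (sp.label, str(i + 1))
    tmap = taxon_map or TaxonMap(mapping)
    trees = [_simulate_one_gene_tree(species, msc, tmap, rng)
             for _ in range(n_loci)]
    return trees, tmap


def _simulate_one_gene_tree(species, msc, tmap, rng):
    # lineages per species node, processed in species-node age order
    by_species = {}
    for tip_label, (sp, _) in tmap.mapping.items():
        by_species.setdefault(sp, []).append(
            TimeTreeNode(label=tip_label, age=0.0, is_sample=True))

    sp_nodes = sorted(species.postorder(), key=lambda n: n.age)
    lineages_at = {}   # species node id -> lineages entering its branch

    for s in sp_nodes:
        lineages = lineages_at.pop(id(s), [])
        if s.is_leaf:
            lineages = by_species.get(s.label, [])
        else:
            for c in s.children:
                lineages.extend(lineages_at.pop(("out", id(c)), []))
        top = s.parent.age if s.parent is not None else np.inf
        ne_c = msc.ploidy * msc.pop_sizes[s.branch_index]
        t = s.age
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / 2.0 / ne_c
            t = t + rng.exponential(1.0 / rate)
            if t >= top:
                break
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            parent = TimeTreeNode(age=t, children=[a, b])
            lineages = [l for idx, l in enumerate(lineages)
                        if idx not in (i, j)]
            lineages.append(parent)
        lineages_at[("out", id(s))] = lineages

    final = lineages_at[("out", id(species.root))]
    assert len(final) == 1
    root = final[0]
    root.parent = None
    return TimeTree(root)


# ---------------------------------------------------------------------------
# characters
# ---------------------------------------------------------------------------

def simulate_characters(tree: TimeTree, model, length: int, rng):
    """Simulate an alignment (SubstModel) or morphological matrix (MkModel).

    The root state is drawn from the stationary frequencies and evolved
    down every branch with the model's transition probabilities; sampled
    ancestors emit their state at their age (morphology).  Returns
    taxon -> sequence string for nucleotides, taxon -> state list for
    morphology (sampled nodes only).
    """
    from .chars import DNA_STATES, transition_probs

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ns = model.nstates
    pi = model.stationary()
    rates, rweights = model.rate_categories()
    cat = rng.choice(len(rates), size=length, p=rweights)
    site_rate = rates[cat]

    states = {id(tree.root): rng.choice(ns, size=length, p=pi)}
    out = {}
    if tree.root.is_sample:
        out[tree.root.label] = states[id(tree.root)]
    for node in tree.preorder():
        for child in node.children:
            dur = node.age - child.age
            cur = states[id(node)]
            if dur <= 0:
                nxt = cur.copy()
            else:
                nxt = np.empty(length, dtype=np.int64)
                for r in np.unique(site_rate):
                    mask = site_rate == r
                    p = transition_probs(model, dur * r)
                    cum = p.cumsum(axis=1)
                    u = rng.random(mask.sum())
                    nxt[mask] = (
                        u[:, None] > cum[cur[mask]]).sum(axis=1)
            states[id(child)] = nxt
            if child.is_sample:
                out[child.label] = nxt
    if isinstance(model, MkModel):
        return {t: [int(s) for s in v] for t, v in out.items()}
    return {t: "".join(DNA_STATES[s] for s in v) for t, v in out.items()}
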