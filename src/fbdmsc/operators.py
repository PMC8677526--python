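"""Metropolis-Hastings proposal operators.

Each operator's ``propose(state, rng)`` mutates the state in place and
returns a :class:`Proposal` carrying the log Hastings ratio (including any
Jacobian), the set of dirtied posterior components, the loci whose
coalescent embedding must be re-derived, and an ``undo`` callable for
rejection.  ``None`` means "not applicable in this state" (counted, not an
error); a proposal with ``log_hr = -inf`` is rejected without evaluation.

Conventions: scalar scale moves are symmetric random walks in log space
(``log HR = log s`` per scaled dimension); node-age moves are uniform
within bounds that the move itself does not alter (``log HR = 0``); the
sampled-ancestor jump is the reversible-jump pair *fossil tip <->
sampled ancestor* whose only continuous proposal is the attachment age,
drawn uniformly on (fossil age, parent age), giving
``log HR = -/+ log(parent age - fossil age)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .trees import TimeTreeNode

NEG_INF = float("-inf")


@dataclass
class Proposal:
    log_hr: float
    dirty: tuple
    loci: tuple = ()
    undo: callable = None


class Operator:
    name = "operator"
    tuning = 1.0
    tunable = False   # whether burn-in auto-tuning may adjust ``tuning``
    needs_gene_trees = False

    def propose(self, state, rng):  # pragma: no cover - interface
        raise NotImplementedError


def _seq_comps(state):
    return tuple(f"seq:{i}" for i in range(len(state.loci)))


def _all_loci(state):
    return tuple(range(len(state.gene_trees)))


# ---------------------------------------------------------------------------
# scalar moves
# ---------------------------------------------------------------------------

class ScaleParam(Operator):
    """Multiplicative random walk on one scalar parameter."""

    tunable = True

    def __init__(self, param, dirty, tuning=1.0, loci=()):
        self.param = param
        self.dirty = tuple(dirty) + ("prior",)
        self.tuning = tuning
        self.loci = tuple(loci)
        self.name = f"scale({param})"

    def propose(self, state, rng):
        old = state.params[self.param]
        s = math.exp(self.tuning * (rng.random() - 0.5))
        state.params[self.param] = old * s

        def undo():
            state.params[self.param] = old

        return Proposal(math.log(s), self.dirty, self.loci, undo)


class UniformParam(Operator):
    """Uniform sliding-window move (for bounded parameters like turnover)."""

    tunable = True

    def __init__(self, param, dirty, tuning=0.1, loci=()):
        self.param = param
        self.dirty = tuple(dirty) + ("prior",)
        self.tuning = tuning
        self.loci = tuple(loci)
        self.name = f"slide({param})"

    def propose(self, state, rng):
        old = state.params[self.param]
        state.params[self.param] = old + self.tuning * (rng.random() - 0.5)

        def undo():
            state.params[self.param] = old

        return Proposal(0.0, self.dirty, self.loci, undo)


class PopSizeScale(Operator):
    """Composite-model-space move: scales one entry of the full-capacity
    population-size vector; inactive entries only feel their prior."""

    name = "scale(pop_size)"
    tunable = True

    def __init__(self, tuning=1.5):
        self.tuning = tuning

    def propose(self, state, rng):
        if state.pop_sizes is None:
            return None
        i = int(rng.integers(len(state.pop_sizes)))
        old = state.pop_sizes[i]
        s = math.exp(self.tuning * (rng.random() - 0.5))
        state.pop_sizes[i] = old * s

        def undo():
            state.pop_sizes[i] = old

        return Proposal(math.log(s), ("msc", "prior"), (), undo)


class UpDownClockGenes(Operator):
    """Joint scaler for the clock/gene-height correlation.

    Multiplies the molecular clock rate by ``s`` and contracts the gene
    coalescences in the species root branch toward the root age by ``1/s``
    (``a' = t_root + (a - t_root)/s``).  Only root-branch events move, so
    no species-divergence constraint can be violated; the moved set is
    determined by the unchanged root age, making the proposal
    self-inverse.  log HR = (1 - n_moved) log s.
    """

    needs_gene_trees = True

    name = "updown(clock,genes)"
    tunable = True

    def __init__(self, tuning=0.4):
        self.tuning = tuning

    def propose(self, state, rng):
        if "clock_rate" not in state.params or not state.gene_trees:
            return None
        s = math.exp(self.tuning * (rng.random() - 0.5))
        t_root = state.species.root.age
        old_clock = state.params["clock_rate"]
        moved = []
        for g in state.gene_trees:
            for n in g.node_list():
                if n.children and n.age > t_root:
                    moved.append((n, n.age))
        state.params["clock_rate"] = old_clock * s
        inv = 1.0 / s
        for n, a in moved:
            n.age = t_root + (a - t_root) * inv

        def undo():
            state.params["clock_rate"] = old_clock
            for n, a in moved:
                n.age = a

        dirty = ("msc", "prior") + _seq_comps(state)
        return Proposal((1 - len(moved)) * math.log(s), dirty,
                        _all_loci(state), undo)


class UpDownTimes(Operator):
    """Global time-stretch: scales the origin age, species bifurcation
    ages and gene-tree internal ages by ``s`` and both clock rates by
    ``1/s``.  Fossil tip and sampled-ancestor ages are data and stay
    fixed; proposals that violate their ordering constraints are rejected.
    log HR = (d_up - d_down) log s."""

    name = "updown(times,rates)"
    tunable = True

    def __init__(self, tuning=0.2):
        self.tuning = tuning

    def propose(self, state, rng):
        s = math.exp(self.tuning * (rng.random() - 0.5))
        ages = []
        for n in state.species.node_list():
            if len(n.children) == 2:
                ages.append((n, n.age))
        for g in state.gene_trees:
            for n in g.node_list():
                if n.children:
                    ages.append((n, n.age))
        rates = []
        for p in ("clock_rate", "morph_clock"):
            if p in state.params:
                rates.append((p, state.params[p]))
        d_up = len(ages)
        old_origin = state.params.get("origin_age")
        if old_origin is not None:
            d_up += 1
            state.params["origin_age"] = old_origin * s
        for n, a in ages:
            n.age = a * s
        for p, v in rates:
            state.params[p] = v / s

        def undo():
            if old_origin is not None:
                state.params["origin_age"] = old_origin
            for n, a in ages:
                n.age = a
            for p, v in rates:
                state.params[p] = v

        # fossil/SA ordering can break when shrinking or stretching
        for n, _ in ages:
            if n.parent is not None and n.age >= n.parent.age:
                undo()
                return Proposal(NEG_INF, (), (), lambda: None)
            for c in n.children:
                if c.age >= n.age:
                    undo()
                    return Proposal(NEG_INF, (), (), lambda: None)

        dirty = ("fbd", "msc", "mk", "prior") + _seq_comps(state)
        return Proposal((d_up - len(rates)) * math.log(s), dirty,
                        _all_loci(state), undo)


# ---------------------------------------------------------------------------
# node-age moves
# ---------------------------------------------------------------------------

def _internal_bifurcations(tree, include_root=True):
    out = []
    for n in tree.node_list():
        if len(n.children) == 2 and (include_root or n.parent is not None):
            out.append(n)
    return out


def _age_bounds(node, origin_age):
    lower = max(c.age for c in node.children)
    if node.parent is not None:
        upper = node.parent.age
    elif origin_age is not None:
        upper = origin_age
    else:
        upper = None
    return lower, upper


class GeneNodeAge(Operator):
    """Uniform age move on a non-root internal gene-tree node."""

    needs_gene_trees = True

    name = "gene-node-age"

    def propose(self, state, rng):
        if not state.gene_trees:
            return None
        i = int(rng.integers(len(state.gene_trees)))
        tree = state.gene_trees[i]
        nodes = _internal_bifurcations(tree, include_root=False)
        if not nodes:
            return None
        node = nodes[int(rng.integers(len(nodes)))]
        lower, upper = _age_bounds(node, None)
        old = node.age
        node.age = lower + rng.random() * (upper - lower)

        def undo():
            node.age = old

        return Proposal(0.0, (f"seq:{i}", "msc"), (i,), undo)


class GeneRootTranslate(Operator):
    """Symmetric translation of a gene-tree root age."""

    needs_gene_trees = True

    name = "gene-root-age"
    tunable = True

    def __init__(self, tuning=0.5):
        self.tuning = tuning

    def propose(self, state, rng):
        if not state.gene_trees:
            return None
        i = int(rng.integers(len(state.gene_trees)))
        root = state.gene_trees[i].root
        delta = self.tuning * (rng.random() - 0.5)
        old = root.age
        new = old + delta
        if root.children and new <= max(c.age for c in root.children):
            return Proposal(NEG_INF, (), (), lambda: None)
        root.age = new

        def undo():
            root.age = old

        return Proposal(0.0, (f"seq:{i}", "msc"), (i,), undo)


class GeneTreeScale(Operator):
    """Scales all internal ages of one gene tree (log HR = d log s)."""

    needs_gene_trees = True

    name = "gene-tree-scale"
    tunable = True

    def __init__(self, tuning=0.5):
        self.tuning = tuning

    def propose(self, state, rng):
        if not state.gene_trees:
            return None
        i = int(rng.integers(len(state.gene_trees)))
        tree = state.gene_trees[i]
        internals = [n for n in tree.node_list() if n.children]
        s = math.exp(self.tuning * (rng.random() - 0.5))
        olds = [n.age for n in internals]
        for n in internals:
            n.age *= s
        if s < 1.0:
            for n in internals:  # a tip may now be older than its parent
                for c in n.children:
                    if c.age >= n.age:
                        for m, a in zip(internals, olds):
                            m.age = a
                        return Proposal(NEG_INF, (), (), lambda: None)

        def undo():
            for m, a in zip(internals, olds):
                m.age = a

        return Proposal(len(internals) * math.log(s),
                        (f"seq:{i}", "msc"), (i,), undo)


class SpeciesNodeAge(Operator):
    """Uniform age move on a species-tree bifurcation (root bounded above
    by the origin)."""

    name = "species-node-age"

    def propose(self, state, rng):
        nodes = _internal_bifurcations(state.species, include_root=True)
        if not nodes:
            return None
        node = nodes[int(rng.integers(len(nodes)))]
        lower, upper = _age_bounds(node, state.params.get("origin_age"))
        if upper is None or upper <= lower:
            return None
        old = node.age
        node.age = lower + rng.random() * (upper - lower)

        def undo():
            node.age = old

        dirty = ("fbd", "msc", "mk") if state.mode == "fbd-msc" \
            else ("fbd", "mk") + _seq_comps(state)
        return Proposal(0.0, dirty, _all_loci(state), undo)


# ---------------------------------------------------------------------------
# topology moves
# ---------------------------------------------------------------------------

def _is_ancestor(a, b):
    """True if a is an ancestor of b."""
    while b is not None:
        if b is a:
            return True
        b = b.parent
    return False


class WideExchange(Operator):
    """Swap two subtrees (uniformly chosen node pair; invalid pairs are
    rejected, keeping the proposal symmetric)."""

    def __init__(self, target="species"):
        self.target = target
        self.name = f"wide-exchange({target})"
        self.needs_gene_trees = target == "gene"

    def propose(self, state, rng):
        if self.target == "species":
            tree = state.species
            locus = None
        else:
            if not state.gene_trees:
                return None
            locus = int(rng.integers(len(state.gene_trees)))
            tree = state.gene_trees[locus]
        nodes = [n for n in tree.node_list() if n.parent is not None]
        if len(nodes) < 2:
            return None
        i, j = rng.integers(len(nodes)), rng.integers(len(nodes))
        ni, nj = nodes[int(i)], nodes[int(j)]
        if ni is nj or ni.parent is nj.parent:
            return Proposal(NEG_INF, (), (), lambda: None)
        if _is_ancestor(ni, nj) or _is_ancestor(nj, ni):
            return Proposal(NEG_INF, (), (), lambda: None)
        pi, pj = ni.parent, nj.parent
        if pi.age <= nj.age or pj.age <= ni.age:
            return Proposal(NEG_INF, (), (), lambda: None)
        ii = pi.children.index(ni)
        jj = pj.children.index(nj)
        pi.children[ii], pj.children[jj] = nj, ni
        ni.parent, nj.parent = pj, pi
        old_version = tree.bump_version()

        def undo():
            pi.children[ii], pj.children[jj] = ni, nj
            ni.parent, nj.parent = pi, pj
            tree.version = old_version

        if self.target == "species":
            dirty = ("fbd", "msc", "mk") if state.mode == "fbd-msc" \
                else ("fbd", "mk") + _seq_comps(state)
            return Proposal(0.0, dirty, _all_loci(state), undo)
        return Proposal(0.0, (f"seq:{locus}", "msc"), (locus,), undo)


class NarrowExchange(Operator):
    """Swap an uncle with a nephew (local topology move, high acceptance).

    Picks a non-root internal bifurcation ``c`` with a bifurcating parent;
    swaps ``c``'s sibling with one of ``c``'s children.  Selection counts
    are invariant under the swap, so log HR = 0.
    """

    def __init__(self, target="species"):
        self.target = target
        self.name = f"narrow-exchange({target})"
        self.needs_gene_trees = target == "gene"

    def propose(self, state, rng):
        if self.target == "species":
            tree = state.species
            locus = None
        else:
            if not state.gene_trees:
                return None
            locus = int(rng.integers(len(state.gene_trees)))
            tree = state.gene_trees[locus]
        cands = [n for n in tree.node_list()
                 if len(n.children) == 2 and n.parent is not None
                 and len(n.parent.children) == 2]
        if not cands:
            return None
        c = cands[int(rng.integers(len(cands)))]
        p = c.parent
        s = p.children[0] if p.children[1] is c else p.children[1]
        x = c.children[int(rng.integers(2))]
        if c.age <= s.age:
            return Proposal(NEG_INF, (), (), lambda: None)
        si = p.children.index(s)
        xi = c.children.index(x)
        p.children[si], c.children[xi] = x, s
        x.parent, s.parent = p, c
        old_version = tree.bump_version()

        def undo():
            p.children[si], c.children[xi] = s, x
            x.parent, s.parent = c, p
            tree.version = old_version

        if self.target == "species":
            dirty = ("fbd", "msc", "mk") if state.mode == "fbd-msc" \
                else ("fbd", "mk") + _seq_comps(state)
            return Proposal(0.0, dirty, _all_loci(state), undo)
        return Proposal(0.0, (f"seq:{locus}", "msc"), (locus,), undo)


class FossilReattach(Operator):
    """Subtree-prune-regraft for a fossil tip.

    Detaches the fossil (with its attachment node) from the species tree,
    picks a backbone edge uniformly among those reaching above the fossil
    age, and reattaches at a uniform age within the eligible span.  The
    backbone is identical in the two states, so the only Hastings term is
    the ratio of the two eligible spans.
    """

    name = "fossil-reattach"

    def propose(self, state, rng):
        tree = state.species
        fossils = [n for n in tree.node_list()
                   if n.is_sample and n.age > 1e-9 and not n.children
                   and n.parent is not None and len(n.parent.children) == 2]
        if not fossils:
            return None
        origin = state.params.get("origin_age")
        if origin is None:
            return None
        f = fossils[int(rng.integers(len(fossils)))]
        p = f.parent
        s = p.children[0] if p.children[1] is f else p.children[1]
        gp = p.parent

        # detach: splice s into p's place
        if gp is None:
            tree.root = s
            s.parent = None
        else:
            gp.children[gp.children.index(p)] = s
            s.parent = gp

        # eligible backbone edges: top of edge must clear the fossil age
        # (live traversal: the tree is mid-mutation here, caches are stale)
        targets = []
        for m in tree.preorder():
            top = m.parent.age if m.parent is not None else origin
            if top > f.age:
                targets.append((m, top))
        # reverse-move span: s's edge in the backbone
        s_top = s.parent.age if s.parent is not None else origin
        rev_span = s_top - max(f.age, s.age)

        m, top = targets[int(rng.integers(len(targets)))]
        lo = max(f.age, m.age)
        u = lo + rng.random() * (top - lo)
        old_p_age = p.age
        mp = m.parent
        p.age = u
        p.children = [m, f]
        m.parent = p
        f.parent = p
        if mp is None:
            tree.root = p
            p.parent = None
        else:
            mp.children[mp.children.index(m)] = p
            p.parent = mp
        old_version = tree.bump_version()

        def undo():
            # remove p from m's position
            if mp is None:
                tree.root = m
                m.parent = None
            else:
                mp.children[mp.children.index(p)] = m
                m.parent = mp
            # put p back above s at its original age
            p.age = old_p_age
            p.children = [s, f]
            s.parent = p
            f.parent = p
            if gp is None:
                tree.root = p
                p.parent = None
            else:
                gp.children[gp.children.index(s)] = p
                p.parent = gp
            tree.version = old_version

        # detailed balance for edge-uniform + height-uniform proposals:
        # HR = span(target edge) / span(source edge)
        log_hr = math.log(top - lo) - math.log(rev_span)
        dirty = ("fbd", "msc", "mk") if state.mode == "fbd-msc" \
            else ("fbd", "mk") + _seq_comps(state)
        return Proposal(log_hr, dirty, _all_loci(state), undo)


class SampledAncestorJump(Operator):
    """Reversible-jump conversion between a fossil tip and a sampled
    ancestor (node count changes by exactly one).

    tip -> SA: the fossil's parent bifurcation is removed and the fossil
    becomes a degree-2 sampled node at its own age on the sibling's edge
    (valid only when the sibling is younger than the fossil).
    SA -> tip: a new bifurcation is created on the former host edge at an
    age drawn uniformly on (fossil age, upper), where upper is the parent
    age (or the origin for the root edge).
    """

    name = "sa-jump"

    def propose(self, state, rng):
        tree = state.species
        fossils = [n for n in tree.node_list() if n.is_sample
                   and n.age > 1e-9]
        if not fossils:
            return None
        f = fossils[int(rng.integers(len(fossils)))]
        if f.is_sampled_ancestor:
            return self._sa_to_tip(state, tree, f, rng)
        return self._tip_to_sa(state, tree, f, rng)

    def _upper_age(self, state, node):
        if node.parent is not None:
            return node.parent.age
        return state.params.get("origin_age")

    def _tip_to_sa(self, state, tree, f, rng):
        p = f.parent
        if p is None or len(p.children) != 2:
            return None
        sib = [c for c in p.children if c is not f][0]
        if sib.age >= f.age:
            return Proposal(NEG_INF, (), (), lambda: None)
        upper = self._upper_age(state, p)
        if upper is None:
            return None
        gp = p.parent
        # splice: remove p; f becomes degree-2 node above sib
        old_children = list(f.children)
        f.children = [sib]
        sib.parent = f
        if gp is None:
            tree.root = f
            f.parent = None
        else:
            gp.children[gp.children.index(p)] = f
            f.parent = gp
        removed = p
        old_version = tree.bump_version()

        def undo():
            f.children = old_children
            sib.parent = removed
            if gp is None:
                tree.root = removed
                removed.parent = None
            else:
                gp.children[gp.children.index(f)] = removed
                removed.parent = gp
            f.parent = removed
            tree.version = old_version

        log_hr = -math.log(upper - f.age)
        return self._proposal(state, log_hr, undo)

    def _sa_to_tip(self, state, tree, f, rng):
        child = f.children[0]
        gp = f.parent
        upper = self._upper_age(state, f)
        if upper is None or upper <= f.age:
            return None
        attach_age = f.age + rng.random() * (upper - f.age)
        bi = state.allocate_branch_index()
        p = TimeTreeNode(age=attach_age, branch_index=bi)
        f.children = []
        p.add_child(child)
        p.add_child(f)
        if gp is None:
            tree.root = p
            p.parent = None
        else:
            gp.children[gp.children.index(f)] = p
            p.parent = gp
        f.parent = p
        old_version = tree.bump_version()

        def undo():
            f.children = [child]
            child.parent = f
            if gp is None:
                tree.root = f
                f.parent = None
            else:
                gp.children[gp.children.index(p)] = f
                f.parent = gp
            tree.version = old_version

        log_hr = math.log(upper - f.age)
        return self._proposal(state, log_hr, undo)

    def _proposal(self, state, log_hr, undo):
        dirty = ("fbd", "msc", "mk") if state.mode == "fbd-msc" \
            else ("fbd", "mk") + _seq_comps(state)
        return Proposal(log_hr, dirty, _all_loci(state), undo)


# ---------------------------------------------------------------------------
# coordinated species/gene moves
# ---------------------------------------------------------------------------

class CoordinatedNodeAge(Operator):
    """Species node-age move that carries gene-tree coalescences along.

    The species node age is redrawn uniformly in its bounds (L, U) -- for
    the root, U is the origin age -- and every gene-node age inside (L, U)
    is remapped by the monotone piecewise-linear map (L, t, U) ->
    (L, t', U).  The map is globally monotone, so gene trees always remain
    valid; because L and U do not change under the move, the proposal is
    exactly self-inverse, with log-Jacobian
    n_below*log((t'-L)/(t-L)) + n_above*log((U-t')/(U-t)).
    """

    name = "coordinated-node-age"

    def propose(self, state, rng):
        nodes = _internal_bifurcations(state.species, include_root=True)
        if not nodes:
            return None
        node = nodes[int(rng.integers(len(nodes)))]
        return self._internal_move(state, node, rng)

    def _dirty(self, state):
        return (("fbd", "msc", "mk") + _seq_comps(state),
                _all_loci(state))

    def _internal_move(self, state, node, rng):
        lower, upper = _age_bounds(node, state.params.get("origin_age"))
        if upper is None or upper <= lower:
            return None
        old = node.age
        new = lower + rng.random() * (upper - lower)
        below = []
        above = []
        for g in state.gene_trees:
            for n in g.node_list():
                if n.children and lower < n.age < upper:
                    (below if n.age <= old else above).append((n, n.age))
        s_below = (new - lower) / (old - lower)
        s_above = (upper - new) / (upper - old)
        for n, a in below:
            n.age = lower + (a - lower) * s_below
        for n, a in above:
            n.age = upper - (upper - a) * s_above
        node.age = new

        def undo():
            node.age = old
            for n, a in below + above:
                n.age = a

        log_j = (len(below) * math.log(s_below)
                 + len(above) * math.log(s_above))
        dirty, loci = self._dirty(state)
        return Proposal(log_j, dirty, loci, undo)


# ---------------------------------------------------------------------------
# validation-harness move
# ---------------------------------------------------------------------------

class FossilAgeMove(Operator):
    """Uniformly redraws one fossil sample age within its local bounds.

    Only used by the prior-validation harness, where fossil ages are
    marginalized to compare MCMC against unconditioned forward simulation;
    in data analyses tip ages are data and this operator is not scheduled.
    """

    name = "fossil-age"

    def propose(self, state, rng):
        tree = state.species
        fossils = [n for n in tree.node_list() if n.is_sample
                   and n.age > 1e-9]
        if not fossils:
            return None
        f = fossils[int(rng.integers(len(fossils)))]
        lower = f.children[0].age if f.children else 0.0
        upper = (f.parent.age if f.parent is not None
                 else state.params.get("origin_age"))
        if upper is None or upper <= lower:
            return None
        old = f.age
        f.age = lower + rng.random() * (upper - lower)

        def undo():
            f.age = old

        dirty = ("fbd", "msc", "mk") if state.mode == "fbd-msc" \
            else ("fbd", "mk") + _seq_comps(state)
        return Proposal(0.0, dirty, _all_loci(state), undo)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class OperatorSchedule:
    """Weighted operator battery with accept/reject bookkeeping."""
    operators: list = field(default_factory=list)
    weights: list = field(default_factory=list)

    def add(self, op, weight):
        if weight <= 0:
            raise ValueError("operator weights must be > 0")
        self.operators.append(op)
        self.weights.append(float(weight))
        return self

    def finalize(self):
        total = sum(self.weights)
        cum = []
        acc = 0.0
        for w in self.weights:
            acc += w / total
            cum.append(acc)
        self._cum = cum
        self.counts = {op.name: [0, 0, 0] for op in self.operators}
        # [accepted, rejected, not-applicable]
        self._tune_stats = {op.name: [0, 0] for op in self.operators}
        return self

    def choose(self, rng):
        from bisect import bisect_left
        i = bisect_left(self._cum, rng.random())
        return self.operators[min(i, len(self.operators) - 1)]

    def record(self, op, outcome, tune=False, target=0.3):
        """Outcome 0 = accepted, 1 = rejected, 2 = not applicable.

        With ``tune`` (burn-in only), scale-type operators adjust their
        tuning toward the target acceptance every 40 decided proposals;
        tuning is frozen afterwards.
        """
        self.counts[op.name][outcome] += 1
        if tune and op.tunable and outcome in (0, 1):
            st = self._tune_stats[op.name]
            st[0] += (outcome == 0)
            st[1] += 1
            if st[1] >= 40:
                rate = st[0] / st[1]
                factor = math.exp(1.5 * (rate - target))
                op.tuning = min(max(op.tuning * factor, 1e-3), 10.0)
                st[0] = st[1] = 0

    def summary(self):
        rows = []
        for op in self.operators:
            acc, rej, na = self.counts[op.name]
            tot = acc + rej
            rows.append({"operator": op.name, "accepted": acc,
                         "rejected": rej, "not_applicable": na,
                         "acceptance": acc / tot if tot else float("nan")})
        return rows
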