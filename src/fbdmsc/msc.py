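"""Multispecies coalescent density of gene trees inside a species tree.

Gene-tree lineages are traced backwards in time through the branches of a
(possibly non-ultrametric, sampled-ancestor) species tree.  Within a branch
carrying ``k`` lineages and constant effective population size ``N_e``, each
pair coalesces at rate ``1/(ploidy * N_e)``, giving a total rate
``k(k-1)/(2 * ploidy * N_e)`` and an event density ``1/(ploidy * N_e)`` per
realized coalescence.

Two modes are supported:

* **explicit** -- one ``N_e`` per species branch (keyed by ``branch_index``);
* **integrated** -- branch sizes are marginalized analytically under an
  inverse-gamma prior with fixed shape ``alpha`` and estimated mean, using
  the conjugacy of the inverse gamma with the coalescent exponential rates.
  With ``n_b`` coalescences and weighted interval sum
  ``A_b = sum_i binom(k_i, 2) dt_i`` in branch ``b`` (pooled over loci), the
  per-branch marginal is
  ``Gamma(alpha + n_b)/Gamma(alpha) * B^alpha / (B + A_b)^(alpha + n_b)``
  with ``B = ploidy * mean * (alpha - 1)``.

Sampled-ancestor nodes split a species branch into two segments, each with
its own size (or its own marginalization unit); gene lineages pass through
them without any event.  The root branch population extends indefinitely
into the past, so all residual lineages coalesce there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trees import AGE_TOL, TaxonMap, TimeTree

NEG_INF = float("-inf")


@dataclass
class MSCConfig:
    """mode "explicit": per-branch sizes in ``pop_sizes`` (branch_index ->
    N_e); mode "integrated": inverse-gamma shape ``ig_shape`` (> 1, fixed)
    and mean ``ig_mean`` (estimated).  ``ploidy`` scales N_e into the
    coalescent rate (2 = diploid autosomal)."""
    mode: str = "integrated"
    pop_sizes: dict[int, float] = field(default_factory=dict)
    ig_shape: float = 3.0
    ig_mean: float = 1.0
    ploidy: float = 2.0

    def validate(self):
        if self.mode not in ("explicit", "integrated"):
            raise ValueError(f"unknown MSC mode {self.mode!r}")
        if self.mode == "integrated" and self.ig_shape <= 1:
            raise ValueError("ig_shape must be > 1 (mean must exist)")
        if self.mode == "integrated" and self.ig_mean <= 0:
            raise ValueError("ig_mean must be > 0")
        if self.mode == "explicit":
            for b, ne in self.pop_sizes.items():
                if ne <= 0:
                    raise ValueError(f"pop size for branch {b} must be > 0")


@dataclass
class BranchCoalescentRecord:
    """Sufficient statistics of the coalescent within one species branch."""
    branch_index: int
    start_age: float          # younger end of the branch
    end_age: float            # older end (math.inf for the root branch)
    lineages_in: int          # entering at the younger end
    event_ages: list[float] = field(default_factory=list)

    @property
    def lineages_out(self):
        return self.lineages_in - len(self.event_ages)

    def stats(self):
        """(n_events, A) with A = sum over intervals of C(k,2) * dt."""
        k = self.lineages_in
        a = 0.0
        t = self.start_age
        for e in sorted(self.event_ages):
            a += k * (k - 1) / 2.0 * (e - t)
            t = e
            k -= 1
        if math.isfinite(self.end_age) and k >= 2:
            a += k * (k - 1) / 2.0 * (self.end_age - t)
        return len(self.event_ages), a


class IncompatibleError(Exception):
    """Gene tree incompatible with the species tree (density -inf)."""


def assign_lineages(species: TimeTree, gene: TimeTree, taxon_map: TaxonMap
                    ) -> list[BranchCoalescentRecord]:
    """Tile the gene-tree lineage history by species-tree branches.

    Returns one record per species branch (including fossil-only branches,
    which carry zero lineages).  Raises :class:`IncompatibleError` when a
    gene coalescence predates the species divergence it must postdate; the
    caller converts this to a ``-inf`` density.
    """
    # species nodes in postorder; branch above node `s` spans
    # [s.age, s.parent.age) (root: to +inf).
    sp_nodes = list(species.postorder())
    records = {}
    for s in sp_nodes:
        top = s.parent.age if s.parent is not None else math.inf
        records[id(s)] = BranchCoalescentRecord(
            branch_index=s.branch_index, start_age=s.age, end_age=top,
            lineages_in=0)

    tips_by_species = {}
    for g in gene.leaves():
        sp = taxon_map.species_of(g.label)
        tips_by_species.setdefault(sp, []).append(g)
    sp_tip_nodes = {n.label: n for n in species.preorder() if n.is_sample}
    for sp in tips_by_species:
        if sp not in sp_tip_nodes:
            raise ValueError(f"gene tips map to species {sp!r} "
                             "absent from the species tree")

    # species branch containing age t on the lineage upward from node s
    def climb(s, t):
        while s.parent is not None and t >= s.parent.age - AGE_TOL:
            s = s.parent
        return s

    # assign each gene node to a species branch, bottom-up by age
    gene_nodes = sorted(gene.postorder(), key=lambda n: n.age)
    gspecies = {}
    for g in gene_nodes:
        if g.is_leaf:
            s = sp_tip_nodes[taxon_map.species_of(g.label)]
            if g.age < s.age - AGE_TOL:
                raise IncompatibleError(
                    f"gene tip {g.label} younger than its species sample")
            gspecies[id(g)] = climb(s, g.age)
        else:
            homes = [climb(gspecies[id(c)], g.age) for c in g.children]
            first = homes[0]
            for h in homes[1:]:
                if h is not first:
                    raise IncompatibleError(
                        "gene coalescence predates species divergence")
            gspecies[id(g)] = first
            records[id(first)].event_ages.append(g.age)

    # lineage counts: walk each gene edge through the species branches it
    # crosses, incrementing lineages_in at every branch it is present in at
    # the branch's younger end.  An edge created by a coalescence strictly
    # inside a branch does not enter at its bottom; it is accounted for by
    # the event decrementing k there.
    for g in gene_nodes:
        s = gspecies[id(g)]
        t_hi = math.inf if g.parent is None else g.parent.age
        rec = records[id(s)]
        if g.age <= rec.start_age + AGE_TOL:
            rec.lineages_in += 1
        while s.parent is not None and t_hi > s.parent.age + AGE_TOL:
            s = s.parent
            records[id(s)].lineages_in += 1
    return [records[id(s)] for s in sp_nodes]


def embed_stats(species: TimeTree, gene: TimeTree, tip_species: dict
                ) -> dict:
    """Fast embedding: per-branch coalescent statistics without record
    objects (the MCMC hot path; ``assign_lineages`` is the reference
    implementation and the two agree exactly).

    tip_species : dict id(gene tip node) -> species sample node.
    Returns {branch_index: (n_events, A)}; raises IncompatibleError.
    """
    entry = {}
    events = {}
    gsp = {}
    touched = {}
    for g in gene.postorder():   # children always precede parents
        a = g.age
        if not g.children:
            s = tip_species[id(g)]
            if a < s.age - AGE_TOL:
                raise IncompatibleError("gene tip younger than its sample")
        else:
            c1, c2 = g.children
            s = gsp[id(c1)]
            while s.parent is not None and a >= s.parent.age - AGE_TOL:
                s = s.parent
            s2 = gsp[id(c2)]
            while s2.parent is not None and a >= s2.parent.age - AGE_TOL:
                s2 = s2.parent
            if s is not s2:
                raise IncompatibleError(
                    "gene coalescence predates species divergence")
            i = id(s)
            touched[i] = s
            if i in events:
                events[i].append(a)
            else:
                events[i] = [a]
        while s.parent is not None and a >= s.parent.age - AGE_TOL:
            s = s.parent
        gsp[id(g)] = s
        # walk the edge above g through the species branches it enters
        i = id(s)
        touched[i] = s
        if a <= s.age + AGE_TOL:
            entry[i] = entry.get(i, 0) + 1
        t_hi = math.inf if g.parent is None else g.parent.age
        while s.parent is not None and t_hi > s.parent.age + AGE_TOL:
            s = s.parent
            i = id(s)
            touched[i] = s
            entry[i] = entry.get(i, 0) + 1
    out = {}
    for i, s in touched.items():
        k = entry.get(i, 0)
        evs = events.get(i)
        top = s.parent.age if s.parent is not None else math.inf
        a = 0.0
        t = s.age
        nev = 0
        if evs:
            evs.sort()
            for e in evs:
                a += k * (k - 1) * 0.5 * (e - t)
                t = e
                k -= 1
                nev += 1
        if math.isfinite(top) and k >= 2:
            a += k * (k - 1) * 0.5 * (top - t)
        if nev or a != 0.0:
            out[s.branch_index] = (nev, a)
    return out


def _embed_kernel_py(g_c1, g_c2, g_parent, g_age, g_tipsp,
                     s_parent, s_age, n_ev, a_out, tol):
    """Array embedding (compiled below): returns 0 on success, 1 when the
    gene tree is incompatible with the species tree.

    Gene nodes are in postorder; ``n_ev`` and ``a_out`` are per-species-
    node outputs (event counts and weighted interval sums).
    """
    ng = g_age.shape[0]
    ns = s_age.shape[0]
    gsp = np.empty(ng, dtype=np.int64)
    entry = np.zeros(ns, dtype=np.int64)
    ev_branch = np.empty(ng, dtype=np.int64)
    ev_age = np.empty(ng, dtype=np.float64)
    nev_tot = 0
    for gi in range(ng):
        a = g_age[gi]
        if g_c1[gi] < 0:
            s = g_tipsp[gi]
            if a < s_age[s] - tol:
                return 1
        else:
            s = gsp[g_c1[gi]]
            while s_parent[s] >= 0 and a >= s_age[s_parent[s]] - tol:
                s = s_parent[s]
            s2 = gsp[g_c2[gi]]
            while s_parent[s2] >= 0 and a >= s_age[s_parent[s2]] - tol:
                s2 = s_parent[s2]
            if s != s2:
                return 1
            ev_branch[nev_tot] = s
            ev_age[nev_tot] = a
            nev_tot += 1
        while s_parent[s] >= 0 and a >= s_age[s_parent[s]] - tol:
            s = s_parent[s]
        gsp[gi] = s
        if a <= s_age[s] + tol:
            entry[s] += 1
        if g_parent[gi] >= 0:
            t_hi = g_age[g_parent[gi]]
        else:
            t_hi = np.inf
        while s_parent[s] >= 0 and t_hi > s_age[s_parent[s]] + tol:
            s = s_parent[s]
            entry[s] += 1
    # per-branch interval sums
    buf = np.empty(nev_tot, dtype=np.float64)
    for s in range(ns):
        k = entry[s]
        m = 0
        for e in range(nev_tot):
            if ev_branch[e] == s:
                buf[m] = ev_age[e]
                m += 1
        if k == 0 and m == 0:
            n_ev[s] = 0
            a_out[s] = 0.0
            continue
        # insertion sort of the (few) events in this branch
        for i in range(1, m):
            v = buf[i]
            j = i - 1
            while j >= 0 and buf[j] > v:
                buf[j + 1] = buf[j]
                j -= 1
            buf[j + 1] = v
        acc = 0.0
        t = s_age[s]
        for i in range(m):
            acc += k * (k - 1) * 0.5 * (buf[i] - t)
            t = buf[i]
            k -= 1
        if s_parent[s] >= 0 and k >= 2:
            acc += k * (k - 1) * 0.5 * (s_age[s_parent[s]] - t)
        n_ev[s] = m
        a_out[s] = acc
    return 0


try:
    from numba import njit as _njit
    _embed_kernel = _njit(cache=False)(_embed_kernel_py)
except ImportError:  # pragma: no cover
    _embed_kernel = _embed_kernel_py


def fbd_kernel_py(kind, age, lam, mu, psi, rho, log2lam, c1, c2, tol):
    """Array FBD log-density core (compiled below): kind 0=extant tip,
    1=fossil tip, 2=sampled ancestor, 3=bifurcation (root handled by the
    caller's conditioning terms)."""
    om = 1.0 - c2
    op = 1.0 + c2
    logp = 0.0
    n_extant = 0
    for i in range(kind.shape[0]):
        k = kind[i]
        if k == 3:
            t = age[i]
            denom = np.exp(-c1 * t) * om + op
            if denom <= 0.0:
                return 1, 0.0
            logp += log2lam + np.log(4.0) - c1 * t - 2.0 * np.log(denom)
        elif k == 2:
            if psi == 0.0:
                return 1, 0.0
            logp += np.log(psi)
        elif k == 1:
            if psi == 0.0:
                return 1, 0.0
            t = age[i]
            e = np.exp(-c1 * t)
            denom = e * om + op
            if denom <= 0.0:
                return 1, 0.0
            frac = (e * om - op) / denom
            pz = (lam + mu + psi + c1 * frac) / (2.0 * lam)
            if pz <= 0.0:
                return 1, 0.0
            logp += (np.log(psi) + np.log(pz)
                     - (np.log(4.0) - c1 * t - 2.0 * np.log(denom)))
        else:
            n_extant += 1
    logp += n_extant * np.log(rho)
    return 0, logp


try:
    fbd_kernel = _njit(cache=False)(fbd_kernel_py)
except NameError:  # pragma: no cover
    fbd_kernel = fbd_kernel_py


def embed_stats_arrays(g_c1, g_c2, g_parent, g_age, g_tipsp,
                       s_parent, s_age):
    """Kernel wrapper: returns (n_events, A) arrays over species nodes or
    None when incompatible."""
    ns = s_age.shape[0]
    n_ev = np.zeros(ns, dtype=np.int64)
    a_out = np.zeros(ns, dtype=np.float64)
    bad = _embed_kernel(g_c1, g_c2, g_parent, g_age, g_tipsp,
                        s_parent, s_age, n_ev, a_out, AGE_TOL)
    if bad:
        return None
    return n_ev, a_out


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def branch_stats(records):
    """Per-branch sufficient statistics {branch_index: (n_events, A)}."""
    return {r.branch_index: r.stats() for r in records}


def msc_log_density_explicit(records, config: MSCConfig) -> float:
    """Sum of standard coalescent interval log-densities over branches."""
    config.validate()
    if config.mode != "explicit":
        raise ValueError("explicit mode required")
    logp = 0.0
    for rec in records:
        n, a = rec.stats()
        if n == 0 and a == 0.0:
            continue
        try:
            ne = config.pop_sizes[rec.branch_index]
        except KeyError:
            raise KeyError(
                f"no population size for branch {rec.branch_index}")
        nc = config.ploidy * ne
        logp += -n * math.log(nc) - a / nc
    return logp


def msc_log_density_integrated(all_records, config: MSCConfig) -> float:
    """Marginal log-density with branch N_e integrated out analytically.

    ``all_records`` holds the record lists of every locus; the integration
    couples loci because each branch's size is shared across loci.
    """
    config.validate()
    if config.mode != "integrated":
        raise ValueError("integrated mode required")
    pooled = {}
    for records in all_records:
        for rec in records:
            n, a = rec.stats()
            if n == 0 and a == 0.0:
                continue
            pn, pa = pooled.get(rec.branch_index, (0, 0.0))
            pooled[rec.branch_index] = (pn + n, pa + a)
    return integrated_from_stats(pooled.values(), config)


def integrated_from_stats(stats, config: MSCConfig) -> float:
    """Integrated MSC log-density from pooled (n_events, A) per branch."""
    alpha = config.ig_shape
    beta = config.ig_mean * (alpha - 1.0)
    b_scaled = config.ploidy * beta
    log_b = math.log(b_scaled)
    logp = 0.0
    for n, a in stats:
        if n == 0 and a == 0.0:
            continue
        logp += (math.lgamma(alpha + n) - math.lgamma(alpha)
                 + alpha * log_b - (alpha + n) * math.log(b_scaled + a))
    return logp
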