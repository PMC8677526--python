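"""MCMC model state: trees, parameters and cached component densities.

The joint posterior factorizes into components that are cached and
selectively recomputed:

* ``seq:i`` -- phylogenetic likelihood of locus *i* on its gene tree
  (or on the species tree in concatenation mode);
* ``msc``   -- multispecies-coalescent density of all gene trees
  (absent in concatenation mode);
* ``mk``    -- Mk likelihood of the morphological matrix on the species tree;
* ``fbd``   -- FBD prior density of the species tree;
* ``prior`` -- scalar-parameter (and population-size-vector) priors.

Operators report which components they dirty; the engine recomputes only
those and can restore the previous values on rejection.  A periodic
full-recomputation check guards cache coherence.
"""

from __future__ import annotations

import math

import numpy as np

from .chars import MkModel, pruning_log_likelihood
from .fbd import FBDParams, _c1_c2, log_q, p0_hat
from .msc import embed_stats_arrays, fbd_kernel
from .trees import TaxonMap, TimeTree

NEG_INF = float("-inf")


class ModelState:
    """Everything the sampler needs, with cached component log-densities."""

    def __init__(self, species: TimeTree, params: dict, priors: dict,
                 gene_trees=None, taxon_map: TaxonMap | None = None,
                 loci=None, subst_models=None,
                 morph_partitions=None, morph_clock_param="morph_clock",
                 msc_mode="integrated", ig_shape=3.0, ploidy=2.0,
                 pop_sizes=None, pop_size_prior=None,
                 fbd_condition="origin", fbd_survival=True,
                 mode="fbd-msc", mk_correction="none"):
        self.species = species
        self.gene_trees = gene_trees or []
        self.taxon_map = taxon_map
        self.loci = loci or []                # CompressedPartition per locus
        self.subst_models = subst_models or []
        self.morph_partitions = morph_partitions or []  # [(k, partition)]
        self.morph_clock_param = morph_clock_param
        self.params = dict(params)
        self.priors = dict(priors)
        self.msc_mode = msc_mode
        self.ig_shape = ig_shape
        self.ploidy = ploidy
        self.pop_sizes = (np.asarray(pop_sizes, dtype=float)
                          if pop_sizes is not None else None)
        self.pop_size_prior = pop_size_prior
        self.fbd_condition = fbd_condition
        self.fbd_survival = fbd_survival
        self.mode = mode
        self.mk_correction = mk_correction

        if mode not in ("fbd-msc", "fbd-concat"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "fbd-concat" and self.gene_trees:
            raise ValueError("concatenation mode has no gene trees")
        if taxon_map is not None:
            taxon_map.validate(species)

        self.locus_stats = [None] * len(self.gene_trees)  # br idx -> (n, A)
        self.logp = {}
        self.next_branch_index = 1 + max(
            (n.branch_index for n in species.preorder()), default=0)
        # hot-path caches: gene tip -> species sample node per locus, and
        # persistent Mk models (their eigensystems are clock-independent)
        sample_by_label = {n.label: n for n in species.preorder()
                           if n.is_sample}
        self._tip_species = []
        for gt in self.gene_trees:
            m = {}
            for tip in gt.leaves():
                sp_name = self.taxon_map.species_of(tip.label)
                m[id(tip)] = sample_by_label[sp_name]
            self._tip_species.append(m)
        self._mk_models = {
            k: MkModel(k=k, correction=self.mk_correction)
            for k, _ in self.morph_partitions}
        self._sp_cache = None
        self._gene_cache = [None] * len(self.gene_trees)
        self._validate_data_taxa()
        self.recompute_all()

    # -- array-native tree views for the coalescent kernel ------------------
    def _species_arrays(self):
        sp = self.species
        cache = self._sp_cache
        if cache is None or cache[0] != sp.version:
            nodes = list(sp.postorder())
            index = {id(n): i for i, n in enumerate(nodes)}
            parent = np.array(
                [index[id(n.parent)] if n.parent is not None else -1
                 for n in nodes], dtype=np.int64)
            branch = np.array([n.branch_index for n in nodes],
                              dtype=np.int64)
            # node kind for the FBD kernel: 0 extant tip, 1 fossil tip,
            # 2 sampled ancestor, 3 bifurcation
            kind = np.empty(len(nodes), dtype=np.int64)
            for i, n in enumerate(nodes):
                nc = len(n.children)
                if nc == 2:
                    kind[i] = 3
                elif nc == 1:
                    kind[i] = 2
                else:
                    kind[i] = 1 if n.age > 1e-6 else 0
            age = np.empty(len(nodes))
            cache = (sp.version, nodes, index, parent, branch, age, kind)
            self._sp_cache = cache
        _, nodes, index, parent, branch, age, kind = cache
        for i, n in enumerate(nodes):
            age[i] = n.age
        return nodes, index, parent, branch, age

    def _gene_arrays(self, i, sp_index):
        gt = self.gene_trees[i]
        cache = self._gene_cache[i]
        if cache is None or cache[0] != gt.version:
            nodes = list(gt.postorder())
            gidx = {id(n): k for k, n in enumerate(nodes)}
            n = len(nodes)
            c1 = np.full(n, -1, dtype=np.int64)
            c2 = np.full(n, -1, dtype=np.int64)
            parent = np.full(n, -1, dtype=np.int64)
            tipsp = np.full(n, -1, dtype=np.int64)
            tip_map = self._tip_species[i]
            for k, node in enumerate(nodes):
                if node.children:
                    c1[k] = gidx[id(node.children[0])]
                    if len(node.children) > 1:
                        c2[k] = gidx[id(node.children[1])]
                else:
                    tipsp[k] = sp_index[id(tip_map[id(node)])]
                if node.parent is not None:
                    parent[k] = gidx[id(node.parent)]
            age = np.empty(n)
            cache = [gt.version, self.species.version, nodes, c1, c2,
                     parent, tipsp, age]
            self._gene_cache[i] = cache
        elif cache[1] != self.species.version:
            # species structure changed: only the tip -> species-row map
            # needs refreshing
            nodes, tipsp = cache[2], cache[6]
            tip_map = self._tip_species[i]
            for k, node in enumerate(nodes):
                if not node.children:
                    tipsp[k] = sp_index[id(tip_map[id(node)])]
            cache[1] = self.species.version
        _, _, nodes, c1, c2, parent, tipsp, age = cache
        for k, node in enumerate(nodes):
            age[k] = node.age
        return c1, c2, parent, age, tipsp

    def _validate_data_taxa(self):
        if self.mode == "fbd-concat":
            taxa = self.species.taxa
            for part in self.loci:
                for t in part.taxa:
                    if t not in taxa:
                        raise ValueError(f"data taxon {t!r} not in tree")
        else:
            for i, part in enumerate(self.loci):
                taxa = self.gene_trees[i].taxa
                for t in part.taxa:
                    if t not in taxa:
                        raise ValueError(f"data taxon {t!r} not in tree")
        sp_taxa = self.species.taxa
        for _, part in self.morph_partitions:
            for t in part.taxa:
                if t not in sp_taxa:
                    raise ValueError(f"morphology taxon {t!r} not in tree")

    # -- component list ----------------------------------------------------
    def components(self):
        comps = ["fbd", "prior"]
        if self.morph_partitions:
            comps.append("mk")
        if self.mode == "fbd-msc":
            comps.append("msc")
        for i in range(len(self.loci)):
            comps.append(f"seq:{i}")
        return comps

    def posterior_log_density(self):
        total = 0.0
        for v in self.logp.values():
            if v == NEG_INF:
                return NEG_INF
            total += v
        return total

    # -- FBD ---------------------------------------------------------------
    def fbd_params(self):
        p = self.params
        lam = p["lambda"]
        mu = p["turnover"] * lam if "turnover" in p else p["mu"]
        return FBDParams(lambda_=lam, mu=mu, psi=p["psi"],
                         rho=p.get("rho", 1.0),
                         origin_age=p.get("origin_age"))

    # -- recomputation -----------------------------------------------------
    def compute(self, comp, stale_loci=None):
        if comp == "fbd":
            return self._compute_fbd()
        if comp == "prior":
            total = 0.0
            for name, prior in self.priors.items():
                total += prior.log_pdf(self.params[name])
                if total == NEG_INF:
                    return NEG_INF
            if self.pop_sizes is not None and self.pop_size_prior is not None:
                for v in self.pop_sizes:
                    total += self.pop_size_prior.log_pdf(v)
            return total
        if comp == "mk":
            clock = self.params.get(self.morph_clock_param, 1.0)
            total = 0.0
            for k, part in self.morph_partitions:
                pm = self._mk_models[k]
                pm.clock_rate = clock
                total += pruning_log_likelihood(self.species, part, pm,
                                                check_taxa=False)
            return total
        if comp == "msc":
            return self._compute_msc(stale_loci)
        if comp.startswith("seq:"):
            i = int(comp[4:])
            model = self.subst_models[i]
            if f"kappa:{i}" in self.params:
                model.kappa = self.params[f"kappa:{i}"]
            if "clock_rate" in self.params:
                model.clock_rate = self.params["clock_rate"]
            tree = (self.species if self.mode == "fbd-concat"
                    else self.gene_trees[i])
            return pruning_log_likelihood(tree, self.loci[i], model,
                                          check_taxa=False)
        raise KeyError(comp)

    def _compute_fbd(self):
        """FBD log-density via the array kernel (the tree-walking
        ``fbd_log_density`` is the reference; both paths are compared by
        the coherence checks and the test suite)."""
        p = self.fbd_params()
        try:
            p.validate()
        except ValueError:
            return NEG_INF
        lam, mu, psi, rho = p.lambda_, p.mu, p.psi, p.rho
        nodes, _, _, _, age = self._species_arrays()
        kind = self._sp_cache[6]
        c1, c2 = _c1_c2(lam, mu, psi, rho)
        bad, logp = fbd_kernel(kind, age, lam, mu, psi, rho,
                               math.log(2.0 * lam), c1, c2, 1e-6)
        if bad:
            return NEG_INF
        root = self.species.root
        if self.fbd_condition == "origin":
            x0 = p.origin_age
            if x0 is None:
                x0 = self.species.origin_age
            if x0 is None:
                return NEG_INF
            if x0 <= root.age:
                return NEG_INF
            logp += log_q(x0, lam, mu, psi, rho)
            if self.fbd_survival:
                surv = 1.0 - p0_hat(x0, lam, mu, rho)
                if surv <= 0.0:
                    return NEG_INF
                logp -= math.log(surv)
        else:
            if len(root.children) != 2:
                return NEG_INF
            # the kernel counted the root bifurcation; root conditioning
            # replaces its 2*lam*q factor with q(root)^2
            logp -= (math.log(2.0 * lam)
                     + log_q(root.age, lam, mu, psi, rho))
            logp += 2.0 * log_q(root.age, lam, mu, psi, rho)
            if self.fbd_survival:
                surv = 1.0 - p0_hat(root.age, lam, mu, rho)
                if surv <= 0.0:
                    return NEG_INF
                logp -= 2.0 * math.log(surv)
        return logp

    def _compute_msc(self, stale_loci):
        if not self.gene_trees:
            return 0.0
        sp_version = self.species.version
        if stale_loci is None:
            stale_loci = range(len(self.gene_trees))
        nodes, sidx, s_parent, s_branch, s_age = self._species_arrays()
        stale = set(stale_loci)
        for i in range(len(self.gene_trees)):
            st = self.locus_stats[i]
            if i in stale or st is None or (st is not False
                                            and st[0] != sp_version):
                res = embed_stats_arrays(
                    *self._gene_arrays(i, sidx), s_parent, s_age)
                self.locus_stats[i] = (False if res is None
                                       else (sp_version, res[0], res[1]))
        if any(st is False for st in self.locus_stats):
            return NEG_INF
        n_tot = self.locus_stats[0][1].copy()
        a_tot = self.locus_stats[0][2].copy()
        for st in self.locus_stats[1:]:
            n_tot += st[1]
            a_tot += st[2]
        mask = (n_tot > 0) | (a_tot > 0.0)
        if not mask.any():
            return 0.0
        n = n_tot[mask]
        a = a_tot[mask]
        if self.msc_mode == "integrated":
            from scipy.special import gammaln
            alpha = self.ig_shape
            b_scaled = (self.ploidy * self.params["pop_mean"]
                        * (alpha - 1.0))
            return float(
                (gammaln(alpha + n) - gammaln(alpha)
                 + alpha * math.log(b_scaled)
                 - (alpha + n) * np.log(b_scaled + a)).sum())
        # explicit, composite model space: only branches in the current
        # topology contribute
        nc = self.ploidy * self.pop_sizes[s_branch[mask]]
        return float((-n * np.log(nc) - a / nc).sum())

    def recompute(self, comps, stale_loci=None):
        logp = self.logp
        for c in comps:
            if c == "msc":
                logp[c] = self._compute_msc(stale_loci)
            else:
                logp[c] = self.compute(c)

    def recompute_all(self):
        self.locus_stats[:] = [None] * len(self.gene_trees)
        for c in self.components():
            self.logp[c] = self.compute(c)

    def coherence_check(self, tol=1e-6):
        """Fresh recomputation of every component vs the cached values."""
        cached = dict(self.logp)
        self.species._flat.clear()
        for g in self.gene_trees:
            g._flat.clear()
        self.recompute_all()
        bad = {}
        for c, v in self.logp.items():
            old = cached[c]
            if old == v:
                continue
            if not (math.isfinite(old) and math.isfinite(v)
                    and abs(old - v) <= tol):
                bad[c] = (old, v)
        return bad

    # -- branch index allocation (composite model space) -------------------
    def allocate_branch_index(self):
        used = {n.branch_index for n in self.species.preorder()}
        idx = 0
        while idx in used:
            idx += 1
        if self.pop_sizes is not None and idx >= len(self.pop_sizes):
            raise RuntimeError("population-size capacity exceeded")
        return idx

    # -- summaries for the trace -------------------------------------------
    def trace_row(self):
        row = {}
        lik = 0.0
        pri = 0.0
        for c, v in self.logp.items():
            if c.startswith("seq:") or c == "mk":
                lik += v
            else:
                pri += v
        row["posterior"] = self.posterior_log_density()
        row["likelihood"] = lik
        row["prior"] = pri
        for c, v in self.logp.items():
            row[c] = v
        for k, v in self.params.items():
            row[k] = v
        row["species_root_age"] = self.species.root.age
        row["sa_count"] = len(self.species.sampled_ancestors())
        for i, g in enumerate(self.gene_trees):
            row[f"gene_height:{i}"] = g.root.age
        if (self.pop_sizes is not None):
            for b in sorted(n.branch_index
                            for n in self.species.preorder()):
                row[f"pop_size:{b}"] = self.pop_sizes[b]
        return row
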