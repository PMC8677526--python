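"""Correctness program: coverage study, topology probabilities, quadrature.

Three tiers, mirroring how sampled-ancestor tree samplers are usually
validated:

1. **analytic/simulated topology probabilities** -- prior-only MCMC class
   frequencies for tiny sample configurations against large direct
   forward-simulation references;
2. **node-age quadrature** -- the posterior CDF of the single free node age
   of a two-taxon model against adaptive numerical integration of the
   unnormalized density;
3. **well-calibrated coverage** -- parameters drawn from priors, data
   simulated under the full model, inference run with the same priors;
   about 95% of 95%-HPD intervals must contain the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chars import CompressedPartition, SubstModel
from .fbd import FBDParams, fbd_log_density
from .mcmc import effective_sample_size, run_mcmc
from .msc import MSCConfig
from .operators import (CoordinatedNodeAge, FossilAgeMove, FossilReattach,
                        GeneNodeAge, GeneRootTranslate, GeneTreeScale,
                        NarrowExchange, OperatorSchedule,
                        SampledAncestorJump, ScaleParam, SpeciesNodeAge,
                        UniformParam, UpDownClockGenes, UpDownTimes,
                        WideExchange)
from .priors import Fixed, LogNormal, Uniform
from .simulate import (SimulationError, _simulate_fbd_once,
                       simulate_characters, simulate_fbd_tree,
                       simulate_gene_trees)
from .state import ModelState
from .trees import TimeTree, TimeTreeNode, parse_tree


# ---------------------------------------------------------------------------
# HPD intervals
# ---------------------------------------------------------------------------

def hpd_interval(samples, level: float = 0.95):
    """Shortest contiguous interval containing ``ceil(level * n)`` of the
    sorted samples (the common trace-tool estimator)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    k = int(math.ceil(level * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


# ---------------------------------------------------------------------------
# coverage study
# ---------------------------------------------------------------------------

@dataclass
class CoverageReport:
    """Per-parameter coverage of the nominal-level HPD intervals."""
    level: float = 0.95
    n_replicates: int = 0
    excluded: list = field(default_factory=list)   # (replicate, reason)
    hits: dict = field(default_factory=dict)       # param -> [bool]
    records: dict = field(default_factory=dict)    # param -> [(truth, mean,
                                                   #            lo, hi)]
    skipped: dict = field(default_factory=dict)    # param -> [reason]

    def add(self, param, truth, samples):
        lo, hi = hpd_interval(samples, self.level)
        hit = lo <= truth <= hi
        self.hits.setdefault(param, []).append(bool(hit))
        self.records.setdefault(param, []).append(
            (float(truth), float(np.mean(samples)), lo, hi))
        return hit

    def skip(self, param, reason):
        self.skipped.setdefault(param, []).append(reason)

    def coverage(self):
        return {p: float(np.mean(h)) for p, h in self.hits.items()}

    def trials(self):
        return {p: len(h) for p, h in self.hits.items()}

    def summary_frame(self):
        import pandas as pd
        rows = []
        for p, h in self.hits.items():
            n = len(h)
            lo, hi = binomial_acceptance_region(n, self.level)
            rows.append({"parameter": p, "n": n, "hits": int(np.sum(h)),
                         "coverage": float(np.mean(h)),
                         "accept_lo": lo / n, "accept_hi": hi / n,
                         "ok": lo <= int(np.sum(h)) <= hi})
        return pd.DataFrame(rows)


def binomial_acceptance_region(n, p=0.95, alpha=0.01):
    """Central exact-binomial acceptance region [k_lo, k_hi] for hit counts
    under nominal coverage ``p``."""
    from scipy.stats import binom
    k_lo = int(binom.ppf(alpha / 2, n, p))
    # make the region honest: shrink/grow to exact central mass
    while k_lo > 0 and binom.cdf(k_lo - 1, n, p) > alpha / 2:
        k_lo -= 1
    k_hi = int(binom.ppf(1 - alpha / 2, n, p))
    while k_hi < n and binom.sf(k_hi, n, p) > alpha / 2:
        k_hi += 1
    return k_lo, k_hi


def default_study_priors():
    """Priors of the reduced well-calibrated study.

    Rates are per Ma, population sizes in units of Ma (N_e times generation
    time); values chosen to give species trees of a handful of Ma with a
    few fossils, moderate incomplete lineage sorting and informative but
    unsaturated sequences.
    """
    return {
        "lambda": LogNormal(math.log(0.8), 0.4),
        "turnover": Uniform(0.0, 0.9),
        "psi": LogNormal(math.log(0.3), 0.6),
        "origin_age": Uniform(3.0, 6.0),
        "pop_mean": LogNormal(math.log(0.05), 0.5),
        "clock_rate": LogNormal(math.log(0.15), 0.3),
        "morph_clock": LogNormal(math.log(0.12), 0.5),
        "kappa": LogNormal(math.log(2.5), 0.5),
    }


@dataclass
class StudyConfig:
    """Reduced-scale well-calibrated study conditions."""
    n_extant: int = 8
    n_loci: int = 2
    seq_length: int = 300
    samples_per_species: int = 1   # one sequence per species per locus
    n_morph: int = 50
    rho: float = 1.0
    ig_shape: float = 3.0
    ploidy: float = 2.0
    chain_length: int = 200_000
    sample_count: int = 1000
    burn_in_samples: int = 100
    ess_min: float = 20.0        # replicate-level failsafe (posterior trace)
    trial_ess_min: float = 100.0  # per-parameter convergence gate
    priors: dict = field(default_factory=default_study_priors)
    max_draw_attempts: int = 40_000


def _draw_conditioned_replicate(cfg: StudyConfig, rng):
    """Draw parameters and a species tree jointly, conditioned on the
    extant count.

    Parameters are REDRAWN from their priors on every rejection, so the
    accepted joint is p(theta, tree | n_extant), whose normalizer does not
    depend on theta -- inference with the unconditioned prior therefore
    remains exactly calibrated.
    """
    for _ in range(cfg.max_draw_attempts):
        truth = {k: p.sample(rng) for k, p in cfg.priors.items()}
        fbd = FBDParams(lambda_=truth["lambda"],
                        mu=truth["turnover"] * truth["lambda"],
                        psi=truth["psi"], rho=cfg.rho,
                        origin_age=truth["origin_age"])
        tree = _simulate_fbd_once(fbd, rng)
        if tree is not None and len(tree.extant_tips()) == cfg.n_extant:
            return truth, tree
    raise SimulationError("could not satisfy the extant-count condition")


def simulate_replicate(cfg: StudyConfig, rng):
    """Simulate one full data set under the joint model.

    Returns (truth dict, species tree, gene trees, taxon map, alignments,
    morphology dict).  ``truth`` additionally records the realized species
    root age and gene-tree heights.
    """
    truth, species = _draw_conditioned_replicate(cfg, rng)
    beta = truth["pop_mean"] * (cfg.ig_shape - 1.0)
    pop = {n.branch_index: beta / rng.gamma(cfg.ig_shape)
           for n in species.preorder()}
    msc = MSCConfig(mode="explicit", pop_sizes=pop, ploidy=cfg.ploidy)
    gene_trees, tmap = simulate_gene_trees(
        species, msc, cfg.samples_per_species, cfg.n_loci, rng)
    truth["kappas"] = [cfg.priors["kappa"].sample(rng)
                       for _ in range(cfg.n_loci)]
    truth["kappas"][0] = truth.pop("kappa")  # first draw already made
    alignments = []
    for i, gt in enumerate(gene_trees):
        model = SubstModel(family="HKY", kappa=truth["kappas"][i],
                           clock_rate=truth["clock_rate"])
        alignments.append(simulate_characters(gt, model, cfg.seq_length,
                                              rng))
    from .chars import MkModel
    mk = MkModel(k=2, clock_rate=truth["morph_clock"])
    morph = simulate_characters(species, mk, cfg.n_morph, rng)
    truth["species_root_age"] = species.root.age
    truth["gene_heights"] = [g.root.age for g in gene_trees]
    return truth, species, gene_trees, tmap, alignments, morph


def build_inference_state(cfg: StudyConfig, truth, species, gene_trees,
                          tmap, alignments, morph):
    """Inference state with the study priors, initialized at the simulated
    (prior-drawn) state, i.e. already in stationarity."""
    params = {
        "lambda": truth["lambda"], "turnover": truth["turnover"],
        "psi": truth["psi"], "origin_age": truth["origin_age"],
        "pop_mean": truth["pop_mean"], "clock_rate": truth["clock_rate"],
        "morph_clock": truth["morph_clock"], "rho": cfg.rho,
    }
    priors = {k: cfg.priors[k] for k in
              ("lambda", "turnover", "psi", "origin_age", "pop_mean",
               "clock_rate", "morph_clock")}
    priors["rho"] = Fixed(cfg.rho)
    models = []
    for i in range(cfg.n_loci):
        params[f"kappa:{i}"] = truth["kappas"][i]
        priors[f"kappa:{i}"] = cfg.priors["kappa"]
        models.append(SubstModel(family="HKY", kappa=truth["kappas"][i],
                                 clock_rate=truth["clock_rate"]))
    loci = [CompressedPartition.from_alignment(a) for a in alignments]
    morph_parts = [(2, CompressedPartition.from_morphology(morph, 2))]
    # Survival conditioning must stay OFF here: the replicate simulator
    # conditions on the extant count by redrawing theta jointly, which is
    # exactly calibrated against the UNCONDITIONED origin density; the
    # survival factor 1/(1 - p0_hat(x0; lambda, mu)) is theta-dependent
    # and would tilt the birth/death-parameter posteriors.
    return ModelState(
        species=species, params=params, priors=priors,
        gene_trees=gene_trees, taxon_map=tmap,
        loci=loci, subst_models=models,
        morph_partitions=morph_parts,
        msc_mode="integrated", ig_shape=cfg.ig_shape, ploidy=cfg.ploidy,
        fbd_condition="origin", fbd_survival=False,
        mode="fbd-msc")


def standard_schedule(state, include_fossil_age=False):
    """Default operator battery for joint FBD-MSC inference.

    Tree-operator weights scale with the number of dimensions they act on
    (nodes, fossils), so fossil-rich or larger trees receive
    proportionally more tree moves per state.
    """
    # dimension-proportional weights, capped so that fossil-rich
    # replicates keep a bounded per-state cost
    n_sp = min(max(len([n for n in state.species.preorder()
                        if len(n.children) == 2]), 1), 16)
    n_fossil = min(len(state.species.fossil_samples()), 8)
    n_gene = min(sum(len([n for n in g.preorder() if n.children])
                     for g in state.gene_trees), 24)

    s = OperatorSchedule()
    tunings = {"clock_rate": 0.5, "morph_clock": 1.0}
    for p in ("lambda", "psi", "pop_mean", "clock_rate", "morph_clock"):
        if p in state.params and not isinstance(state.priors.get(p), Fixed):
            weight = 3 if p == "clock_rate" else 1.5
            s.add(ScaleParam(p, _dirty_for(state, p),
                             tuning=tunings.get(p, 1.0)), weight)
    if "turnover" in state.params and not isinstance(
            state.priors.get("turnover"), Fixed):
        s.add(UniformParam("turnover", ("fbd",), tuning=0.3), 1.5)
    if "origin_age" in state.params and not isinstance(
            state.priors.get("origin_age"), Fixed):
        s.add(ScaleParam("origin_age", ("fbd",), tuning=0.2), 1)
    for i in range(len(state.loci)):
        if f"kappa:{i}" in state.params:
            s.add(ScaleParam(f"kappa:{i}", (f"seq:{i}",), tuning=0.5), 1)
    s.add(SpeciesNodeAge(), 0.9 * n_sp)
    s.add(WideExchange("species"), 0.3 * n_sp)
    s.add(NarrowExchange("species"), 0.4 * n_sp)
    if n_fossil:
        s.add(SampledAncestorJump(), 0.8 * n_fossil)
        s.add(FossilReattach(), 1.0 * n_fossil)
    if include_fossil_age and n_fossil:
        s.add(FossilAgeMove(), 1.0 * n_fossil)
    if state.gene_trees:
        s.add(GeneNodeAge(), 0.9 * n_gene)
        s.add(GeneRootTranslate(), 2)
        s.add(GeneTreeScale(tuning=0.15), 2)
        s.add(WideExchange("gene"), 0.25 * n_gene)
        s.add(NarrowExchange("gene"), 0.35 * n_gene)
        s.add(CoordinatedNodeAge(), 0.8 * n_sp)
        if "clock_rate" in state.params and not isinstance(
                state.priors.get("clock_rate"), Fixed):
            s.add(UpDownClockGenes(tuning=0.4), 3)
            s.add(UpDownTimes(tuning=0.4), 5)
    return s.finalize()


def _dirty_for(state, param):
    if param in ("lambda", "psi"):
        return ("fbd",)
    if param == "pop_mean":
        return ("msc",)
    if param == "clock_rate":
        return tuple(f"seq:{i}" for i in range(len(state.loci)))
    if param == "morph_clock":
        return ("mk",)
    return ("fbd",)


def well_calibrated_study(cfg: StudyConfig, n_replicates: int, seed: int
                          ) -> CoverageReport:
    """Simulate-infer-check loop.

    Coverage is a property of converged chains, so each (replicate,
    parameter) trial is counted only when that parameter's trace reaches
    ``trial_ess_min`` effective samples (an unconverged trace yields an
    anti-conservative interval and would test Monte-Carlo error rather
    than model correctness); skipped trials are logged per parameter.
    Replicates whose posterior trace falls below the ``ess_min`` failsafe
    are excluded outright.
    """
    master = np.random.default_rng(seed)
    report = CoverageReport(level=0.95)
    scalar_params = ("lambda", "turnover", "psi", "origin_age", "pop_mean",
                     "clock_rate", "morph_clock")

    def add_gated(param, truth_value, trace, rep):
        ess = effective_sample_size(trace)
        if ess < cfg.trial_ess_min:
            report.skip(param, f"rep {rep}: ESS {ess:.0f}")
        else:
            report.add(param, truth_value, trace)

    for rep in range(n_replicates):
        rep_seed = int(master.integers(2 ** 31 - 1))
        rng = np.random.default_rng(rep_seed)
        truth, species, gene_trees, tmap, aligns, morph = \
            simulate_replicate(cfg, rng)
        state = build_inference_state(cfg, truth, species, gene_trees,
                                      tmap, aligns, morph)
        sched = standard_schedule(state)
        res = run_mcmc(state, sched, cfg.chain_length, cfg.sample_count,
                       seed=rep_seed, check_every=0, log_trees=False)
        df = res.frame.iloc[cfg.burn_in_samples:]
        ess = effective_sample_size(df["posterior"].values)
        if ess < cfg.ess_min:
            report.excluded.append((rep, f"posterior ESS {ess:.0f} < "
                                    f"{cfg.ess_min:.0f}"))
            continue
        report.n_replicates += 1
        for p in scalar_params:
            add_gated(p, truth[p], df[p].values, rep)
        for i in range(cfg.n_loci):
            add_gated("kappa", truth["kappas"][i],
                      df[f"kappa:{i}"].values, rep)
            add_gated("gene_tree_height", truth["gene_heights"][i],
                      df[f"gene_height:{i}"].values, rep)
        add_gated("species_root_age", truth["species_root_age"],
                  df["species_root_age"].values, rep)
    return report


# ---------------------------------------------------------------------------
# topology probabilities (prior-sampling equivalence)
# ---------------------------------------------------------------------------

def classify_sa_config(tree: TimeTree) -> str:
    """Shape class of a small sampled-ancestor configuration.

    Classes: ``sa-tip`` (fossil is an SA on a terminal extant lineage),
    ``sa-stem`` (SA above more than one extant taxon), ``tip-cherry``
    (fossil tip sister to one extant taxon), ``tip-out`` (fossil tip
    outside more than one extant taxon).
    """
    from .trees import AGE_TOL

    def extant_below(node):
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_sample and n.age <= AGE_TOL:
                out.add(n.label)
            stack.extend(n.children)
        return out

    sas = tree.sampled_ancestors()
    if sas:
        ext = extant_below(sas[0].children[0])
        return "sa-tip" if len(ext) == 1 else "sa-stem"
    fossil = [n for n in tree.leaves() if n.age > AGE_TOL][0]
    if fossil.parent is None:
        return "tip-out"
    sib = [c for c in fossil.parent.children if c is not fossil][0]
    ext = extant_below(sib)
    return "tip-cherry" if len(ext) == 1 else "tip-out"


def _initial_config_tree(n_extant, n_fossil, origin_age):
    """Deterministic valid starting tree for a tiny sample configuration."""
    tips = [TimeTreeNode(label=f"T{i+1}", age=0.0, is_sample=True)
            for i in range(n_extant)]
    h = 0.55 * origin_age
    node = tips[0]
    age = h / max(n_extant - 1, 1)
    for i, t in enumerate(tips[1:], start=1):
        node = TimeTreeNode(age=age * i, children=[node, t])
    for j in range(n_fossil):
        f = TimeTreeNode(label=f"F{j+1}", age=0.6 * origin_age
                         + 0.1 * j * origin_age, is_sample=True)
        node = TimeTreeNode(age=0.65 * origin_age + 0.1 * j * origin_age
                            + 0.05 * origin_age, children=[node, f])
    return TimeTree(node, origin_age=origin_age)


def topology_probability_check(params: FBDParams, n_extant: int,
                               n_fossil: int, seed: int,
                               n_direct: int = 1_000_000,
                               chain_length: int = 2_000_000,
                               sample_count: int = 20_000):
    """Prior-only MCMC class frequencies vs direct forward simulation.

    The MCMC conditions on the sample counts with free fossil ages
    (marginalizing them), matching the direct-simulation conditional.
    Returns a table of per-class frequencies with Monte-Carlo standard
    errors from both routes.
    """
    import pandas as pd
    rng = np.random.default_rng(seed)
    sim_counts = {}
    matched = 0
    for _ in range(n_direct):
        t = _simulate_fbd_once(params, rng)
        if t is None:
            continue
        if (len(t.extant_tips()) == n_extant
                and len(t.fossil_samples()) == n_fossil):
            matched += 1
            c = classify_sa_config(t)
            sim_counts[c] = sim_counts.get(c, 0) + 1

    sp = _initial_config_tree(n_extant, n_fossil, params.origin_age)
    p = {"lambda": params.lambda_, "mu": params.mu, "psi": params.psi,
         "rho": params.rho, "origin_age": params.origin_age}
    state = ModelState(sp, p, {k: Fixed(v) for k, v in p.items()},
                       mode="fbd-msc", fbd_survival=False)
    sched = (OperatorSchedule()
             .add(SpeciesNodeAge(), 3)
             .add(WideExchange("species"), 3)
             .add(SampledAncestorJump(), 2)
             .add(FossilReattach(), 2)
             .add(FossilAgeMove(), 2)).finalize()
    res = run_mcmc(state, sched, chain_length, sample_count,
                   seed=seed + 1, log_trees=True)
    classes = [classify_sa_config(parse_tree(nwk))
               for nwk in res.species_trees]

    rows = []
    for c in sorted(set(sim_counts) | set(classes)):
        ps = sim_counts.get(c, 0) / matched if matched else float("nan")
        se_s = math.sqrt(ps * (1 - ps) / matched) if matched else float(
            "nan")
        ind = np.array([1.0 if x == c else 0.0 for x in classes])
        pm = float(ind.mean())
        ess = effective_sample_size(ind)
        se_m = math.sqrt(max(pm * (1 - pm), 1e-12) / ess)
        se = math.hypot(se_s, se_m)
        rows.append({"class": c, "direct": ps, "direct_se": se_s,
                     "mcmc": pm, "mcmc_se": se_m,
                     "z": (pm - ps) / se if se > 0 else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# node-age quadrature check
# ---------------------------------------------------------------------------

def node_age_quadrature_check(params: FBDParams, seed: int,
                              seq_length: int = 100,
                              clock_rate: float = 0.5,
                              chain_length: int = 200_000,
                              sample_count: int = 4096) -> float:
    """Two-taxon toy: sup-norm discrepancy between the MCMC posterior CDF
    of the single free node age and adaptive quadrature of the
    unnormalized density.

    The model is the FBD prior times a JC likelihood on the two-taxon
    species tree (concatenation form), so the check exercises prior,
    likelihood and the node-age operator together.
    """
    from scipy.integrate import quad

    rng = np.random.default_rng(seed)
    x0 = params.origin_age
    true_age = 0.4 * x0
    a = TimeTreeNode(label="T1", age=0.0, is_sample=True)
    b = TimeTreeNode(label="T2", age=0.0, is_sample=True)
    root = TimeTreeNode(age=true_age, children=[a, b])
    species = TimeTree(root, origin_age=x0)
    model = SubstModel(family="JC", clock_rate=clock_rate)
    aln = simulate_characters(species, model, seq_length, rng)
    locus = CompressedPartition.from_alignment(aln)

    p = {"lambda": params.lambda_, "mu": params.mu, "psi": params.psi,
         "rho": params.rho, "origin_age": x0}
    state = ModelState(species, p, {k: Fixed(v) for k, v in p.items()},
                       loci=[locus], subst_models=[model],
                       mode="fbd-concat", fbd_survival=False)

    from .chars import pruning_log_likelihood

    def log_post(age):
        if not 0 < age < x0:
            return float("-inf")
        t = TimeTree(TimeTreeNode(
            age=age,
            children=[TimeTreeNode(label="T1", age=0.0, is_sample=True),
                      TimeTreeNode(label="T2", age=0.0, is_sample=True)]),
            origin_age=x0)
        lp = fbd_log_density(t, params, condition="origin", survival=False)
        return lp + pruning_log_likelihood(t, locus, model)

    # reference value to stabilize the exponentials
    ref = log_post(true_age)
    dens = lambda u: math.exp(log_post(u) - ref)
    z, zerr = quad(dens, 0.0, x0, limit=400)
    if not np.isfinite(z) or z <= 0 or zerr > 1e-6 * z:
        raise RuntimeError("quadrature did not converge")

    sched = OperatorSchedule().add(SpeciesNodeAge(), 1).finalize()
    res = run_mcmc(state, sched, chain_length, sample_count,
                   seed=seed + 1, log_trees=False)
    ages = np.sort(res.frame["species_root_age"].values)

    # sup-norm of |empirical CDF - quadrature CDF| at the sample points
    disc = 0.0
    n = len(ages)
    cum = 0.0
    prev = 0.0
    for i, v in enumerate(ages):
        cum += quad(dens, prev, v, limit=200)[0]
        prev = v
        cdf = cum / z
        disc = max(disc, abs(cdf - i / n), abs(cdf - (i + 1) / n))
    return disc
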