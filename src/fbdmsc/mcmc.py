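"""Metropolis-Hastings chain runner, trace/tree logging, chain joining."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .operators import OperatorSchedule
from .trees import write_tree

NEG_INF = float("-inf")


class _CompCost(dict):
    def __missing__(self, key):      # seq:<i> and any future components
        return 4


_COMP_COST = _CompCost(prior=0, fbd=1, msc=2, mk=3)


class CacheCoherenceError(RuntimeError):
    pass


@dataclass
class TraceLog:
    """In-memory trace: one row per logged state, fixed column set."""
    rows: list = field(default_factory=list)

    def append(self, sample_index, row):
        self.rows.append({"Sample": sample_index, **row})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class McmcResult:
    trace: TraceLog
    species_trees: list          # newick strings
    gene_trees: list             # list per locus of newick strings
    schedule: OperatorSchedule
    seed: int

    @property
    def frame(self):
        return self.trace.to_frame()


def run_mcmc(state, schedule: OperatorSchedule, chain_length: int,
             sample_count: int, seed: int,
             check_every: int = 1000,
             log_trees: bool = True,
             tune_fraction: float = 0.1) -> McmcResult:
    """Run a Metropolis-Hastings chain over the joint model.

    ``sample_count`` evenly spaced samples are logged (the state after
    every ``chain_length // sample_count`` proposals).  Runs are
    deterministic given ``seed``.  Every ``check_every`` accepted moves the
    cached component densities are recomputed from scratch and compared to
    the incremental values; a mismatch names the last operator.  During
    the first ``tune_fraction`` of the chain, scale-type operators
    auto-tune toward a target acceptance rate and are frozen afterwards
    (treat that window as burn-in).
    """
    rng = np.random.default_rng(seed)
    if not hasattr(schedule, "_cum"):
        schedule.finalize()
    if chain_length < sample_count:
        raise ValueError("chain_length must be >= sample_count")
    if state.posterior_log_density() == NEG_INF:
        raise ValueError("initial state has zero posterior density")
    if state.mode == "fbd-concat":
        bad = [op.name for op in schedule.operators
               if getattr(op, "needs_gene_trees", False)]
        if bad:
            raise ValueError(
                "gene-tree operators are not part of the concatenation "
                f"model: {bad}")
    every = chain_length // sample_count

    trace = TraceLog()
    sp_log = []
    gt_log = [[] for _ in state.gene_trees]

    accepted = 0
    last_op = None
    tune_until = int(chain_length * tune_fraction)
    logp = state.logp
    locus_stats = state.locus_stats
    choose = schedule.choose
    record = schedule.record
    rng_random = rng.random
    log = math.log
    for step in range(1, chain_length + 1):
        tune = step <= tune_until
        op = choose(rng)
        prop = op.propose(state, rng)
        if prop is None:
            record(op, 2)
        elif prop.log_hr == NEG_INF:
            record(op, 1, tune=tune)
        else:
            dirty = sorted((c for c in prop.dirty if c in logp),
                           key=_COMP_COST.__getitem__)
            old_vals = {c: logp[c] for c in dirty}
            old_stats = {i: locus_stats[i] for i in prop.loci}
            # recompute cheap components first; stop at the first -inf so
            # expensive likelihoods are skipped for impossible proposals
            delta = 0.0
            for c in dirty:
                state.recompute((c,), stale_loci=prop.loci)
                nv, ov = logp[c], old_vals[c]
                if nv == NEG_INF:
                    delta = NEG_INF
                    break
                delta += nv - (ov if ov != NEG_INF else 0.0)
                if ov == NEG_INF:
                    delta = math.inf  # escaping an impossible state
            if delta == NEG_INF:
                accept = False
            elif delta == math.inf:
                accept = True
            else:
                accept = log(rng_random() + 1e-300) < delta + prop.log_hr
            if accept:
                record(op, 0, tune=tune)
                accepted += 1
                last_op = op.name
                if check_every and accepted % check_every == 0:
                    bad = state.coherence_check()
                    if bad:
                        raise CacheCoherenceError(
                            f"cache mismatch after operator {last_op}: "
                            f"{bad}")
            else:
                record(op, 1, tune=tune)
                prop.undo()
                logp.update(old_vals)
                for i, s in old_stats.items():
                    locus_stats[i] = s
        if step % every == 0 and len(trace.rows) < sample_count:
            trace.append(step, state.trace_row())
            if log_trees:
                sp_log.append(write_tree(state.species))
                for i, g in enumerate(state.gene_trees):
                    gt_log[i].append(write_tree(g))
    return McmcResult(trace, sp_log, gt_log, schedule, seed)


def join_chains(traces, tree_logs=None, burn_in_samples: int = 0,
                thin: int = 1):
    """Discard ``burn_in_samples`` leading samples per chain, concatenate,
    and keep every ``thin``-th sample.

    ``traces`` are DataFrames (or TraceLogs) with identical columns;
    ``tree_logs`` (optional) are per-chain lists subjected to the same
    selection.  Returns the pooled DataFrame (and pooled trees if given).
    """
    frames = [t.to_frame() if isinstance(t, TraceLog) else t
              for t in traces]
    cols = list(frames[0].columns)
    for f in frames[1:]:
        if list(f.columns) != cols:
            raise ValueError("chains have mismatched columns")
    kept = [f.iloc[burn_in_samples:] for f in frames]
    pooled = pd.concat(kept, ignore_index=True)
    pooled = pooled.iloc[thin - 1::thin].reset_index(drop=True)
    if tree_logs is None:
        return pooled
    trees = []
    for log in tree_logs:
        trees.extend(log[burn_in_samples:])
    trees = trees[thin - 1::thin]
    return pooled, trees


def effective_sample_size(x) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf = acf / acf[0]
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))
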