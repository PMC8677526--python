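"""Felsenstein-pruning likelihoods for sequences and morphology.

Sequence evolution uses the reversible GTR family (JC, HKY, GTR) with the
rate matrix normalized to one expected substitution per site per unit of
``clock_rate * time``; morphology uses the Mk model (k states, uniform
stationary frequencies), optionally with the variable-characters-only
ascertainment correction.

Sampled-ancestor nodes carry observed morphological states as internal
constraints: a degree-2 sampled node behaves as a tip-with-child, its
partial likelihood multiplied elementwise by the observed-state indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .trees import TimeTree

NEG_INF = float("-inf")

_UNIT_CATS = (np.ones(1), np.ones(1))

DNA_STATES = "ACGT"
# IUPAC ambiguity codes -> compatible states (gaps and N fully missing)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT",
}


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class SubstModel:
    """GTR-family nucleotide model.

    family : "JC" | "HKY" | "GTR"
    kappa : transition/transversion rate ratio (HKY)
    rates : 6 exchangeabilities in order AC, AG, AT, CG, CT, GT (GTR)
    freqs : stationary frequencies (A, C, G, T), sum to 1
    clock_rate : substitutions / site / Ma
    gamma_shape, gamma_ncat : optional discrete-gamma rate heterogeneity
    """
    family: str = "JC"
    kappa: float = 2.0
    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    clock_rate: float = 1.0
    gamma_shape: float | None = None
    gamma_ncat: int = 4

    def __post_init__(self):
        self._cache_key = None
        self._eig = None
        self._pi_cache = None

    @property
    def nstates(self):
        return 4

    def rate_matrix(self):
        pi = np.asarray(self.freqs, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")
        if np.any(pi <= 0):
            raise ValueError("frequencies must be positive")
        if self.family == "JC":
            ex = np.ones(6)
            pi = np.full(4, 0.25)
        elif self.family == "HKY":
            k = self.kappa
            ex = np.array([1.0, k, 1.0, 1.0, k, 1.0])
        elif self.family == "GTR":
            ex = np.asarray(self.rates, dtype=float)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        q = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(ex, idx):
            q[i, j] = r * pi[j]
            q[j, i] = r * pi[i]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalize: mean rate  -sum_i pi_i q_ii  == 1
        mean_rate = -(pi * np.diag(q)).sum()
        return q / mean_rate, pi

    def eigensystem(self):
        key = (self.family, self.kappa, tuple(self.rates), tuple(self.freqs))
        if self._cache_key != key:
            q, pi = self.rate_matrix()
            self._eig = _reversible_eig(q, pi)
            self._cache_key = key
        return self._eig

    def stationary(self):
        if self._pi_cache is None:
            if self.family == "JC":
                self._pi_cache = np.full(4, 0.25)
            else:
                self._pi_cache = np.ascontiguousarray(
                    np.asarray(self.freqs, dtype=float))
        return self._pi_cache

    def rate_categories(self):
        """(rates, weights) of the discrete-gamma mixture (or (1,), (1,))."""
        if self.gamma_shape is None:
            return _UNIT_CATS
        from scipy.stats import gamma as gamma_dist
        n = self.gamma_ncat
        a = self.gamma_shape
        # category means between quantile boundaries (mean-normalized)
        qs = gamma_dist.ppf((np.arange(n) + 0.5) / n, a, scale=1.0 / a)
        qs = qs / qs.mean()
        return qs, np.full(n, 1.0 / n)


@dataclass
class MkModel:
    """Lewis Mk model: k states, uniform frequencies.

    correction : "none" | "variable-only" (ascertainment for matrices in
        which constant characters are unscorable).
    """
    k: int = 2
    clock_rate: float = 1.0
    correction: str = "none"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("Mk needs k >= 2")
        if self.correction not in ("none", "variable-only"):
            raise ValueError(f"unknown correction {self.correction!r}")
        self._eig = None
        self._pi_cache = None

    @property
    def nstates(self):
        return self.k

    def rate_matrix(self):
        k = self.k
        q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(q, -1.0)
        return q, np.full(k, 1.0 / k)

    def eigensystem(self):
        if self._eig is None:
            q, pi = self.rate_matrix()
            self._eig = _reversible_eig(q, pi)
        return self._eig

    def stationary(self):
        if self._pi_cache is None:
            self._pi_cache = np.full(self.k, 1.0 / self.k)
        return self._pi_cache

    def rate_categories(self):
        return _UNIT_CATS


def _reversible_eig(q, pi):
    """Real eigensystem of a reversible rate matrix via symmetrization."""
    d = np.sqrt(pi)
    sym = (q * d[:, None]) / d[None, :]
    sym = (sym + sym.T) / 2.0
    evals, vecs = np.linalg.eigh(sym)
    umat = vecs / d[:, None]
    uinv = vecs.T * d[None, :]
    return (np.ascontiguousarray(evals), np.ascontiguousarray(umat),
            np.ascontiguousarray(uinv))


def transition_probs(model, duration: float) -> np.ndarray:
    """Stochastic matrix P(duration) for a SubstModel or MkModel.

    ``duration`` is in Ma; the clock rate converts it to expected
    substitutions.  Rows sum to 1; duration 0 gives the identity.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    evals, umat, uinv = model.eigensystem()
    t = duration * model.clock_rate
    p = (umat * np.exp(evals * t)) @ uinv
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

class CompressedPartition:
    """Pattern-compressed character partition ready for the kernel.

    taxa : ordered taxon names with data rows
    partials : float64[ntaxa, npat, nstates] (ambiguity -> multi-one rows)
    weights : pattern multiplicities
    """

    def __init__(self, taxa, partials, weights, nstates):
        self.taxa = list(taxa)
        self.row = {t: i for i, t in enumerate(self.taxa)}
        self.partials = np.ascontiguousarray(partials, dtype=np.float64)
        self.weights = np.ascontiguousarray(weights, dtype=np.float64)
        self.nstates = nstates

    @property
    def nsites(self):
        return int(self.weights.sum())

    @classmethod
    def from_alignment(cls, alignment: dict[str, str]):
        """Compress a nucleotide alignment (taxon -> IUPAC string)."""
        taxa = sorted(alignment)
        lens = {len(alignment[t]) for t in taxa}
        if len(lens) != 1:
            raise ValueError("sequences must have equal length")
        nsites = lens.pop()
        cols = {}
        order = []
        for s in range(nsites):
            col = tuple(alignment[t][s].upper() for t in taxa)
            if col not in cols:
                cols[col] = 0
                order.append(col)
            cols[col] += 1
        partials = np.zeros((len(taxa), len(order), 4))
        for p, col in enumerate(order):
            for i, ch in enumerate(col):
                try:
                    allowed = IUPAC[ch]
                except KeyError:
                    raise ValueError(f"unknown nucleotide code {ch!r}")
                for a in allowed:
                    partials[i, p, DNA_STATES.index(a)] = 1.0
        weights = np.array([cols[c] for c in order], dtype=float)
        return cls(taxa, partials, weights, 4)

    @classmethod
    def from_morphology(cls, matrix: dict[str, list], k: int):
        """Compress morphological characters sharing state count ``k``.

        States are ints in 0..k-1 or "?" for missing.
        """
        taxa = sorted(matrix)
        nch = len(matrix[taxa[0]])
        cols = {}
        order = []
        for s in range(nch):
            col = tuple(matrix[t][s] for t in taxa)
            if col not in cols:
                cols[col] = 0
                order.append(col)
            cols[col] += 1
        partials = np.zeros((len(taxa), len(order), k))
        for p, col in enumerate(order):
            for i, st in enumerate(col):
                if st == "?" or st is None:
                    partials[i, p, :] = 1.0
                else:
                    st = int(st)
                    if not 0 <= st < k:
                        raise ValueError(
                            f"state {st} out of range for k={k}")
                    partials[i, p, st] = 1.0
        weights = np.array([cols[c] for c in order], dtype=float)
        return cls(taxa, partials, weights, k)


@dataclass
class CharacterData:
    """Per-locus nucleotide alignments plus a morphological matrix."""
    alignments: list = field(default_factory=list)   # dicts taxon -> seq
    morph: dict = field(default_factory=dict)        # taxon -> state list
    morph_k: list = field(default_factory=list)      # per-character k

    def morph_partitions(self):
        """Split the matrix into per-k partitions (k -> taxon -> states)."""
        parts = {}
        for ci, k in enumerate(self.morph_k):
            parts.setdefault(k, []).append(ci)
        out = {}
        for k, cis in parts.items():
            out[k] = {t: [self.morph[t][ci] for ci in cis]
                      for t in self.morph}
        return out


# ---------------------------------------------------------------------------
# tree flattening
# ---------------------------------------------------------------------------

def flatten_tree(tree: TimeTree, partition: CompressedPartition,
                 clock_rate: float):
    """Postorder arrays for the kernel.

    Tips present in the partition point at their data row; tips absent from
    it get an all-ones (missing) row; sampled ancestors with data become
    tip-with-child constraints.  The structural arrays are cached on the
    tree and invalidated by its ``version`` counter; only branch lengths
    are rebuilt per call.
    """
    cache = tree._flat.get(id(partition))
    # the cache entry holds the partition itself: identity check guards
    # against id() reuse after garbage collection
    if (cache is not None and cache[0] == tree.version
            and cache[7] is partition):
        _, order, child1, child2, data_idx, nodes, partials, _ = cache
    else:
        nodes = list(tree.postorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        child1 = np.full(n, -1, dtype=np.int32)
        child2 = np.full(n, -1, dtype=np.int32)
        data_idx = np.full(n, -1, dtype=np.int32)
        order = np.arange(n, dtype=np.int32)
        missing_row = None
        partials = partition.partials
        for i, node in enumerate(nodes):
            if node.children:
                child1[i] = index[id(node.children[0])]
                if len(node.children) > 1:
                    child2[i] = index[id(node.children[1])]
            if node.is_sample:
                row = partition.row.get(node.label)
                if row is None:
                    if node.is_leaf:
                        if missing_row is None:
                            missing = np.ones(
                                (1, partials.shape[1], partials.shape[2]))
                            partials = np.concatenate([partials, missing])
                            missing_row = partials.shape[0] - 1
                        data_idx[i] = missing_row
                    # SA without data: no constraint
                else:
                    data_idx[i] = row
        tree._flat[id(partition)] = (tree.version, order, child1, child2,
                                     data_idx, nodes, partials, partition)
    nn = len(nodes)
    blen = np.empty(nn, dtype=np.float64)
    for i in range(nn):
        node = nodes[i]
        if node.parent is not None:
            d = (node.parent.age - node.age) * clock_rate
            blen[i] = d if d > 0.0 else 0.0
        else:
            blen[i] = 0.0
    return order, child1, child2, data_idx, blen, partials


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _site_logliks(tree, partition, model, check_taxa=True):
    """Per-pattern log-likelihoods, mixed over rate categories."""
    if check_taxa:
        tree_taxa = tree.taxa
        for taxon in partition.taxa:
            if taxon not in tree_taxa:
                raise ValueError(
                    f"taxon {taxon!r} in data absent from tree")
    evals, umat, uinv = model.eigensystem()
    freqs = np.ascontiguousarray(model.stationary())
    rates, rweights = model.rate_categories()
    order, c1, c2, didx, blen, partials = flatten_tree(
        tree, partition, model.clock_rate)
    per_cat = []
    for r in rates:
        site_lik, log_scale = _kernels.prune_site_likelihoods(
            order, c1, c2, didx, blen * r, evals, umat, uinv,
            partials, freqs)
        per_cat.append(np.log(np.maximum(site_lik, 1e-300)) + log_scale)
    per_cat = np.asarray(per_cat)
    m = per_cat.max(axis=0)
    mixed = m + np.log(
        (rweights[:, None] * np.exp(per_cat - m[None, :])).sum(axis=0))
    return mixed


def pruning_log_likelihood(tree: TimeTree, data, model,
                           check_taxa=True) -> float:
    """Phylogenetic log-likelihood of one partition on one tree.

    ``data`` is a CompressedPartition, a taxon->sequence dict (nucleotide)
    or a taxon->state-list dict (morphology, with an MkModel).
    """
    partition = _as_partition(data, model)
    if model.rate_categories()[0].shape[0] == 1 and not (
            isinstance(model, MkModel)
            and model.correction == "variable-only"):
        # fast path: single rate category, no correction
        if check_taxa:
            tree_taxa = tree.taxa
            for taxon in partition.taxa:
                if taxon not in tree_taxa:
                    raise ValueError(
                        f"taxon {taxon!r} in data absent from tree")
        evals, umat, uinv = model.eigensystem()
        order, c1, c2, didx, blen, partials = flatten_tree(
            tree, partition, model.clock_rate)
        return float(_kernels.prune_loglik(
            order, c1, c2, didx, blen, evals, umat, uinv, partials,
            model.stationary(), partition.weights))
    mixed = _site_logliks(tree, partition, model, check_taxa=check_taxa)
    logl = float((partition.weights * mixed).sum())
    if isinstance(model, MkModel) and model.correction == "variable-only":
        logl -= partition.nsites * _log_one_minus_pconst(tree, model)
    return logl


def _as_partition(data, model):
    if isinstance(data, CompressedPartition):
        return data
    if isinstance(model, MkModel):
        return CompressedPartition.from_morphology(data, model.k)
    return CompressedPartition.from_alignment(data)


def _log_one_minus_pconst(tree, model):
    """log(1 - P(constant pattern)) for the variable-only correction."""
    k = model.k
    taxa = sorted(tree.taxa)
    partials = np.zeros((len(taxa), k, k))
    for s in range(k):
        partials[:, s, s] = 1.0
    const = CompressedPartition(taxa, partials, np.ones(k), k)
    logliks = _site_logliks(tree, const, model)
    pconst = float(np.exp(logliks).sum())
    if pconst >= 1.0:
        return NEG_INF
    return math.log1p(-pconst)


def mk_log_likelihood(species: TimeTree, data: CharacterData,
                      model: MkModel) -> float:
    """Mk log-likelihood of the morphological matrix, characters
    partitioned by state count (each partition uses its own k)."""
    total = 0.0
    for k, matrix in data.morph_partitions().items():
        part_model = MkModel(k=k, clock_rate=model.clock_rate,
                             correction=model.correction)
        total += pruning_log_likelihood(species, matrix, part_model)
    return total


def concatenated_log_likelihood(species: TimeTree, loci, models) -> float:
    """Sum of per-locus likelihoods evaluated directly on the species tree
    (the defining change of the concatenation variant)."""
    if not isinstance(models, (list, tuple)):
        models = [models] * len(loci)
    return sum(pruning_log_likelihood(species, locus, model)
               for locus, model in zip(loci, models))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_fasta(text: str) -> dict[str, str]:
    import dendropy
    mat = dendropy.DnaCharacterMatrix.get(data=text, schema="fasta")
    return {t.label.split()[0]: str(mat[t]).replace(" ", "")
            for t in mat.taxon_namespace}


def write_fasta(seqs: dict[str, str]) -> str:
    return "".join(f">{t}\n{s}\n" for t, s in sorted(seqs.items()))


def read_nexus_dna(text: str) -> dict[str, str]:
    import dendropy
    mat = dendropy.DnaCharacterMatrix.get(data=text, schema="nexus")
    return {t.label: str(mat[t]).replace(" ", "")
            for t in mat.taxon_namespace}


def read_nexus_morphology(text: str):
    """NEXUS standard-datatype matrix -> (taxon -> states, per-char k).

    Missing entries are "?"; the per-character state count is the number of
    distinct observed states (minimum 2).
    """
    import dendropy
    mat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    matrix = {}
    for t in mat.taxon_namespace:
        states = []
        for cell in mat[t]:
            sym = str(cell.symbol)
            states.append("?" if sym in "?-" else int(sym))
        matrix[t.label] = states
    nch = len(next(iter(matrix.values())))
    ks = []
    for ci in range(nch):
        observed = {row[ci] for row in matrix.values() if row[ci] != "?"}
        ks.append(max(2, (max(observed) + 1) if observed else 2))
    return matrix, ks


def write_nexus_morphology(matrix: dict, ks: list) -> str:
    taxa = sorted(matrix)
    nch = len(ks)
    maxsym = max(ks)
    symbols = "".join(str(i) for i in range(maxsym))
    lines = ["#NEXUS", "", "Begin data;",
             f"    Dimensions ntax={len(taxa)} nchar={nch};",
             f'    Format datatype=standard symbols="{symbols}" missing=?;',
             "    Matrix"]
    width = max(len(t) for t in taxa) + 2
    for t in taxa:
        row = "".join("?" if s == "?" else str(s) for s in matrix[t])
        lines.append(f"        {t:<{width}}{row}")
    lines += ["    ;", "End;", ""]
    return "\n".join(lines)
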