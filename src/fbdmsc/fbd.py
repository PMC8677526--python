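"""Fossilized birth-death (FBD) tree prior with sampled ancestors.

The FBD process runs forward from an origin time with constant speciation
rate ``lambda``, extinction rate ``mu``, fossil-sampling rate ``psi`` and
extant-sampling probability ``rho``.  The reconstructed (sampled) tree may
contain fossil tips and sampled-ancestor (degree-2 sampled) nodes.

The density implemented here is the standard sampled-ancestor FBD density
for labeled trees.  With

``c1 = sqrt((lambda - mu - psi)^2 + 4 lambda psi)``
``c2 = -(lambda - mu - 2 lambda rho - psi) / c1``
``q(t) = 4 e^{-c1 t} / (e^{-c1 t}(1-c2) + (1+c2))^2``
``p0(t)`` = probability of no sampled descendants for a lineage alive at t,

a labeled tree with origin age x0, bifurcation ages x_i, fossil-tip ages
y_i, k sampled ancestors and n extant samples has log-density

``log q(x0) + sum_i log(2 lambda q(x_i)) + sum_j log(psi p0(y_j)/q(y_j))
  + k log(psi) + n log(rho)``

optionally divided by the probability of at least one sampled extant
descendant (survival conditioning).  The per-bifurcation factor of 2 is the
orientation count of a labeled bifurcation; it is not constant across
sampled-ancestor configurations (converting a fossil tip to a sampled
ancestor removes a bifurcation) and is required for the prior to match
direct forward simulation.

All computation is in log space; impossible trees score ``-inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .trees import AGE_TOL, TimeTree

NEG_INF = float("-inf")


@dataclass
class FBDParams:
    """Canonical FBD parameterization.

    lambda_ : speciation rate (events / lineage / Ma), > 0
    mu      : extinction rate, >= 0
    psi     : fossil-sampling rate, >= 0
    rho     : extant-species sampling probability, (0, 1]
    origin_age : Ma, must exceed the root age of any tree scored
    """
    lambda_: float
    mu: float
    psi: float
    rho: float = 1.0
    origin_age: float | None = None

    def validate(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda must be > 0")
        if self.mu < 0 or self.psi < 0:
            raise ValueError("mu and psi must be >= 0")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")


@dataclass
class FBDReparam:
    """Diversification d = lambda - mu, turnover r = mu/lambda,
    fossil-sampling proportion s = psi/(mu + psi)."""
    d: float
    r: float
    s: float
    rho: float = 1.0
    origin_age: float | None = None


def fbd_transform(p):
    """Exact algebraic transform between FBDParams and FBDReparam."""
    if isinstance(p, FBDParams):
        lam, mu, psi = p.lambda_, p.mu, p.psi
        if mu + psi == 0:
            s = 0.0
        else:
            s = psi / (mu + psi)
        return FBDReparam(d=lam - mu, r=mu / lam, s=s,
                          rho=p.rho, origin_age=p.origin_age)
    if isinstance(p, FBDReparam):
        if p.r >= 1:
            raise ValueError("turnover r >= 1 requires infinite mu")
        if p.s >= 1:
            raise ValueError("fossil proportion s >= 1 requires infinite psi")
        if p.r < 0 or p.s < 0:
            raise ValueError("r and s must be >= 0")
        lam = p.d / (1 - p.r)
        mu = lam * p.r
        psi = mu * p.s / (1 - p.s) if p.s > 0 else 0.0
        return FBDParams(lambda_=lam, mu=mu, psi=psi,
                         rho=p.rho, origin_age=p.origin_age)
    raise TypeError(type(p))


# ---------------------------------------------------------------------------
# density helpers
# ---------------------------------------------------------------------------

def _c1_c2(lam, mu, psi, rho):
    c1 = math.sqrt((lam - mu - psi) ** 2 + 4.0 * lam * psi)
    if c1 == 0.0:
        c1 = 1e-300
    c2 = -(lam - mu - 2.0 * lam * rho - psi) / c1
    return c1, c2


def log_q(t, lam, mu, psi, rho):
    c1, c2 = _c1_c2(lam, mu, psi, rho)
    # q(t) = 4 e^{-c1 t} / (e^{-c1 t}(1 - c2) + (1 + c2))^2, stable in logs
    denom = math.exp(-c1 * t) * (1.0 - c2) + (1.0 + c2)
    if denom <= 0:
        return NEG_INF
    return math.log(4.0) - c1 * t - 2.0 * math.log(denom)


def p0(t, lam, mu, psi, rho):
    """P(no sampled descendants at all | lineage alive at age t)."""
    c1, c2 = _c1_c2(lam, mu, psi, rho)
    e = math.exp(-c1 * t)
    frac = (e * (1.0 - c2) - (1.0 + c2)) / (e * (1.0 - c2) + (1.0 + c2))
    return (lam + mu + psi + c1 * frac) / (2.0 * lam)


def p0_hat(t, lam, mu, rho):
    """P(no *extant* sampled descendants | lineage alive at age t).

    Fossil sampling does not remove lineages, so this is the plain
    birth-death expression with sampling fraction rho.
    """
    if abs(lam - mu) < 1e-12:
        # critical limit
        return 1.0 - rho / (1.0 + rho * lam * t)
    g = lam - mu
    e = math.exp(-g * t)
    return 1.0 - rho * g / (rho * lam + (lam * (1.0 - rho) - mu) * e)


# ---------------------------------------------------------------------------
# tree density
# ---------------------------------------------------------------------------

def fbd_log_density(tree: TimeTree, params: FBDParams,
                    condition: str = "origin",
                    survival: bool = True) -> float:
    """Log-density of a sampled-ancestor time tree under the FBD process.

    condition : "origin" (needs ``params.origin_age``; also taken from
        ``tree.origin_age``) or "root".
    survival : condition on at least one sampled extant descendant (of the
        origin lineage, or of both root children under root conditioning).
    """
    params.validate()
    lam, mu, psi, rho = params.lambda_, params.mu, params.psi, params.rho
    c1, c2 = _c1_c2(lam, mu, psi, rho)
    om_c2, op_c2 = 1.0 - c2, 1.0 + c2
    log4 = math.log(4.0)
    exp = math.exp
    log = math.log

    n_extant = 0
    logp = 0.0
    root = tree.root
    log_2lam = log(2.0 * lam)
    for node in tree.node_list():
        nc = len(node.children)
        if nc == 2:
            if node is root and condition == "root":
                continue  # handled below
            t = node.age
            denom = exp(-c1 * t) * om_c2 + op_c2
            if denom <= 0:
                return NEG_INF
            logp += log_2lam + log4 - c1 * t - 2.0 * log(denom)
        elif nc == 1:
            # sampled ancestor
            if psi == 0.0:
                return NEG_INF
            logp += log(psi)
        else:
            if node.age > AGE_TOL:
                # fossil tip
                if psi == 0.0:
                    return NEG_INF
                t = node.age
                e = exp(-c1 * t)
                denom = e * om_c2 + op_c2
                if denom <= 0:
                    return NEG_INF
                frac = (e * om_c2 - op_c2) / denom
                pz = (lam + mu + psi + c1 * frac) / (2.0 * lam)
                if pz <= 0.0:
                    return NEG_INF
                logp += (log(psi) + log(pz)
                         - (log4 - c1 * t - 2.0 * log(denom)))
            else:
                n_extant += 1
    logp += n_extant * math.log(rho)

    if condition == "origin":
        x0 = params.origin_age
        if x0 is None:
            x0 = tree.origin_age
        if x0 is None:
            raise ValueError("origin conditioning requires an origin age")
        if x0 <= root.age:
            return NEG_INF
        logp += log_q(x0, lam, mu, psi, rho)
        if survival:
            surv = 1.0 - p0_hat(x0, lam, mu, rho)
            if surv <= 0.0:
                return NEG_INF
            logp -= math.log(surv)
    elif condition == "root":
        if len(root.children) != 2:
            return NEG_INF
        logp += 2.0 * log_q(root.age, lam, mu, psi, rho)
        if survival:
            surv = 1.0 - p0_hat(root.age, lam, mu, rho)
            if surv <= 0.0:
                return NEG_INF
            logp -= 2.0 * math.log(surv)
    else:
        raise ValueError(f"unknown conditioning {condition!r}")
    return logp
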