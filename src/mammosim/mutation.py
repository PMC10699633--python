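"""Stochastic mutation dynamics.

Spontaneous mutations follow a Yule-Furry pure-birth process whose
count distribution from a single founder is geometric with parameter p.
The hopping probability is coupled to the local glucose level through
the ansatz p = exp[-(C1/theta_div)^2]: nutrient-poor niches mutate
faster.  Estrogen-receptor failure adds an independent route, giving
the per-cell acceptance probability

    Prm = p + beta_hat * (1 - p) * P(B),

where beta_hat is the local lineage segregation index.  Accepted events
advance the genotype by a tau-leap: an exponential leap interval tau,
one gene selected from a negative-binomial index stream, and an
increment determined by the product of a Poisson draw (mean
poisson_mean * tau) and a geometric draw, capped at one new mutation
per gene per leap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GENES, N_GENES


@dataclass
class MutationState:
    """Per-cell view of the tau-leaping state.

    ``x`` is the genotype (per-gene mutation counts); all propensities
    are 1, so a0 equals the number of genes.
    """

    x: np.ndarray
    p_hop: float
    a_j: np.ndarray = field(default_factory=lambda: np.ones(N_GENES))

    @property
    def a0(self) -> float:
        return float(self.a_j.sum())


def hopping_probability(C1_local, theta_div):
    """p = exp[-(C1/theta_div)^2] in (0, 1]."""
    C1 = np.asarray(C1_local, dtype=float)
    if (C1 < 0).any():
        raise ValueError("glucose concentration must be nonnegative")
    if theta_div <= 0:
        raise ValueError("theta_div must be positive")
    out = np.exp(-((C1 / theta_div) ** 2))
    return float(out) if np.isscalar(C1_local) else out


def yule_pmf(x, p):
    """Geometric law P(x) = p (1-p)^(x-1), x >= 1.

    This is the known solution of the Yule-Furry pure-birth master
    equation started from a single lineage; it sums to 1 over x >= 1
    and has mean 1/p.
    """
    x = np.asarray(x)
    if (x < 1).any():
        raise ValueError("the Yule-Furry count starts at x = 1")
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    out = p * (1.0 - p) ** (x - 1)
    return float(out) if out.ndim == 0 else out


def acceptance_probability(p, beta_hat, P_B):
    """Prm = p + beta_hat (1-p) P(B); the union of the glucose-gradient
    and estrogen-receptor-failure mutation routes.

    Reduces to p when estrogen gradients are negligible (P(B) = 0).
    """
    p_arr = np.asarray(p, dtype=float)
    b_arr = np.asarray(beta_hat, dtype=float)
    for name, a in (("p", p_arr), ("beta_hat", b_arr),
                    ("P_B", np.asarray(P_B, dtype=float))):
        if ((a < 0) | (a > 1)).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    out = p_arr + b_arr * (1.0 - p_arr) * P_B
    if np.isscalar(p) and np.isscalar(beta_hat):
        return float(out)
    return out


def sample_tau(a0, r):
    """Leap interval tau = ln(1/r)/a0 for a uniform draw r in (0, 1)."""
    r = np.asarray(r, dtype=float)
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    if ((r <= 0) | (r >= 1)).any():
        raise ValueError("r must lie strictly inside (0, 1)")
    out = np.log(1.0 / r) / a0
    return float(out) if out.ndim == 0 else out


def select_gene(p, rng, mode="negative_binomial", size=None):
    """Gene index stream for the tau-leap update.

    The negative-binomial mode maps the number of geometric(p) failures
    onto a gene index modulo the gene count (the distribution's
    parameterization is a modeling choice; a uniform stream is provided
    as the alternative).
    """
    if mode == "negative_binomial":
        draws = rng.geometric(np.clip(p, 1e-12, 1.0), size=size)
        return (draws - 1) % N_GENES
    if mode == "uniform":
        return rng.integers(N_GENES, size=size)
    raise ValueError(f"unknown gene selection mode {mode!r}")


def tau_leap_update(state: MutationState, poisson_mean, rng,
                    mode="negative_binomial") -> MutationState:
    """One tau-leap: select a gene, draw Poisson x geometric, increment.

    The per-gene increment per leap is capped at 1 (the update vector
    changes a gene's count by 0 or 1), so genotype counts never
    decrease and grow by at most one unit per gene per leap.
    """
    r = rng.uniform()
    while r <= 0.0:
        r = rng.uniform()
    tau = sample_tau(state.a0, r)
    j = int(select_gene(state.p_hop, rng, mode=mode))
    k = rng.poisson(poisson_mean * tau)
    z = rng.geometric(np.clip(state.p_hop, 1e-12, 1.0))
    x = state.x.copy()
    if k * z >= 1:
        x[j] += 1
    return MutationState(x=x, p_hop=state.p_hop, a_j=state.a_j.copy())


def mutation_sweep(cells, fields, beta_hat_cells, config, rng):
    """One per-cycle sweep over randomly ordered cancer cells.

    For each visited cell, the acceptance probability Prm combines the
    glucose hopping probability at the cell site with the cell's local
    segregation index; a uniform draw decides whether a tau-leap fires
    (``r < Prm`` under the conventional rule, ``r > Prm`` as printed in
    the source model).  Returns the indices of cells that leaped.

    Genotype changes are propagated to GRN thresholds by the caller
    (the thresholds respond to the segregation the new diversity
    creates, not to the raw counts).
    """
    n = len(cells.cells)
    if n == 0:
        return np.empty(0, dtype=int)
    order = rng.permutation(n)
    pos = cells.positions()
    C1 = fields.C1[tuple(pos.T)]
    p = hopping_probability(C1, config.theta_div)
    prm = acceptance_probability(p, np.asarray(beta_hat_cells), config.P_B)
    draws = rng.uniform(size=n)
    if config.mutation_rule == "conventional":
        fire = draws[order] < prm[order]
    else:                       # "as_printed"
        fire = draws[order] > prm[order]
    fired = order[fire]
    if len(fired) == 0:
        return fired
    # vectorized tau-leap over all fired cells (one leap each)
    m = len(fired)
    p_f = np.clip(p[fired], 1e-12, 1.0)
    r = np.clip(rng.uniform(size=m), 1e-300, 1.0 - 1e-16)
    taus = sample_tau(float(N_GENES), r)
    genes = select_gene(p_f, rng, mode=config.gene_selection, size=m)
    k = rng.poisson(config.poisson_mean * taus)
    z = rng.geometric(p_f)
    hit = (k * z) >= 1
    for i, j, h in zip(fired, genes, hit):
        if h:
            cells.cells[i].genotype[j] += 1
    return fired
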