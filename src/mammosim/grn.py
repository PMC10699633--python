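"""The 10-gene breast-cancer regulatory network.

Continuous kinetics per gene i:

    dx_i/dt = ag_i (y_i/eta_i - 1)(1 - x_i)
              + R(x_i) Ht(x_i)
              + sum_j s_ij x_i H(x_j)
              - mu_i x_i

where y_i is the microenvironmental input (normalized oxygen for TP53,
ATR, MDM2 and CDK2; the Michaelis-Menten estrogen saturation
C3/(C3+kappa_eps) for the rest), eta_i the activation-inhibition
threshold, R a saturating positive/negative self-feedback, H a Hill
interaction with half-saturation k = 1/2 for every gene, and s_ij the
sign of the regulatory edge j -> i.

The network topology and per-gene kinetic parameters are DATA, shipped
as a YAML config reconstructed from the constraints the model states
(the ATR/ATM/CHEK1/CDK2 kinase cluster acting on the cell cycle,
estrogen-responsive BRCA1/HER2, oxygen-associated TP53/AKT1/MDM2/P21,
and the MDM2-TP53, ATR-TP53, TP53-P21, HER2-TP53 feedback loops), with
parameter values drawn from the published value sets.  Everything is
user-overridable; no wiring is hard-coded here.

Attractors of the synchronous Boolean representation classify
phenotypes: the all-inhibited pattern and the TP53/ATM/CHEK1 pattern
are normal; the unique attractor over-expressing HER2, AKT1, P21 and
CDK2 is cancer; every other attractor is precancer.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import GENES, N_GENES

OXYGEN_GENES = ("TP53", "ATR", "MDM2", "CDK2")
CANCER_SIGNATURE = ("HER2", "AKT1", "P21", "CDK2")
NORMAL_PATTERNS = (
    frozenset(),                          # state a: all genes inhibited
    frozenset({"TP53", "ATM", "CHEK1"}),  # state c
)


# ---------------------------------------------------------------------------
# Elementary terms
# ---------------------------------------------------------------------------

def hill(x_j, beta_j, nu_j, gamma_j, k_j=0.5):
    """H = beta (nu x)^gamma / (k + (nu x)^gamma); in [0, beta)."""
    t = (nu_j * np.asarray(x_j, dtype=float)) ** gamma_j
    out = beta_j * t / (k_j + t)
    return float(out) if out.ndim == 0 else out


def feedback(x_i, lambda_g, delta_i, sign="positive"):
    """Saturating self-regulation: lg*x/(d+x) (pos) or lg*d/(d+x) (neg)."""
    x = np.asarray(x_i, dtype=float)
    if sign == "positive":
        out = lambda_g * x / (delta_i + x)
    elif sign == "negative":
        out = lambda_g * delta_i / (delta_i + x)
    else:
        raise ValueError(f"unknown feedback sign {sign!r}")
    return float(out) if out.ndim == 0 else out


def microenv_input(concentration, kappa_eps, agent="estrogen"):
    """Gene drive y: direct for oxygen, MM-saturated for estrogen."""
    c = np.asarray(concentration, dtype=float)
    if (c < 0).any():
        raise ValueError("concentration must be nonnegative")
    if agent == "oxygen":
        out = c
    elif agent == "estrogen":
        out = c / (c + kappa_eps)
    else:
        raise ValueError(f"unknown agent {agent!r}")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class GRNModel:
    """Topology plus per-gene kinetic and Boolean parameters."""

    genes: tuple = GENES
    alpha_g: np.ndarray = None           # agent interaction rate, +/-1
    mu: np.ndarray = None                # self-degradation
    lambda_g: np.ndarray = None          # self-activation
    delta: np.ndarray = None             # self-feedback threshold
    feedback_sign: tuple = None          # per-gene "positive"/"negative"
    fb_beta: np.ndarray = None           # self-feedback Hill strength
    fb_nu: np.ndarray = None
    fb_gamma: np.ndarray = None
    edge_sign: np.ndarray = None         # (target, source) in {-1, 0, +1}
    hill_beta: np.ndarray = None         # per-source-gene A-I strength
    hill_nu: np.ndarray = None
    hill_gamma: np.ndarray = None
    k: float = 0.5
    bool_threshold: np.ndarray = None
    input_agent: tuple = None            # per-gene "oxygen"/"estrogen"
    drive_cap: float = 1e3

    _default_cache = None

    # -- construction --------------------------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "GRNModel":
        genes = tuple(doc.get("genes", GENES))
        order = {g: i for i, g in enumerate(genes)}
        n = len(genes)
        per = doc["per_gene"]

        def arr(key, default=None):
            return np.array([per[g].get(key, default) for g in genes],
                            dtype=float)

        edge_sign = np.zeros((n, n))
        for e in doc["edges"]:
            s = +1.0 if e["sign"] in (1, "+", "activation") else -1.0
            edge_sign[order[e["target"]], order[e["source"]]] = s
        model = cls(
            genes=genes,
            alpha_g=arr("alpha_g"),
            mu=arr("mu", 0.2),
            lambda_g=arr("lambda_g", 0.4),
            delta=arr("delta"),
            feedback_sign=tuple(per[g]["feedback"] for g in genes),
            edge_sign=edge_sign,
            fb_beta=arr("fb_beta"),
            fb_nu=arr("fb_nu"),
            fb_gamma=arr("fb_gamma"),
            hill_beta=arr("hill_beta"),
            hill_nu=arr("hill_nu"),
            hill_gamma=arr("hill_gamma"),
            k=float(doc.get("k", 0.5)),
            bool_threshold=arr("bool_threshold", 0.5),
            input_agent=tuple(per[g]["input"] for g in genes),
            drive_cap=float(doc.get("drive_cap", 1e3)),
        )
        model.validate()
        return model

    def to_dict(self) -> dict:
        per = {}
        for i, g in enumerate(self.genes):
            per[g] = {
                "alpha_g": float(self.alpha_g[i]),
                "mu": float(self.mu[i]),
                "lambda_g": float(self.lambda_g[i]),
                "delta": float(self.delta[i]),
                "feedback": self.feedback_sign[i],
                "fb_beta": float(self.fb_beta[i]),
                "fb_nu": float(self.fb_nu[i]),
                "fb_gamma": float(self.fb_gamma[i]),
                "hill_beta": float(self.hill_beta[i]),
                "hill_nu": float(self.hill_nu[i]),
                "hill_gamma": float(self.hill_gamma[i]),
                "bool_threshold": float(self.bool_threshold[i]),
                "input": self.input_agent[i],
            }
        edges = []
        tgt, src = np.nonzero(self.edge_sign)
        for t, s in zip(tgt, src):
            edges.append({"source": self.genes[s], "target": self.genes[t],
                          "sign": int(self.edge_sign[t, s])})
        return {"genes": list(self.genes), "k": self.k,
                "drive_cap": self.drive_cap, "per_gene": per, "edges": edges}

    @classmethod
    def from_yaml(cls, path) -> "GRNModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def default(cls) -> "GRNModel":
        if cls._default_cache is None:
            ref = importlib.resources.files("mammosim.data") / "grn_default.yaml"
            cls._default_cache = cls.from_dict(yaml.safe_load(ref.read_text()))
        return cls._default_cache

    def validate(self) -> None:
        if self.k != 0.5:
            raise ValueError("the Hill half-saturation k is 1/2 for all genes")
        if not set(np.unique(self.alpha_g)) <= {-1.0, 1.0}:
            raise ValueError("alpha_g entries must be -1 or +1")
        indeg = (self.edge_sign != 0).sum(axis=1)
        # gamma is tied to the number of regulators of the source gene
        for i in range(len(self.genes)):
            if indeg[i] > 0 and self.hill_gamma[i] <= 0:
                raise ValueError("hill_gamma must be positive")

    def in_degree(self) -> np.ndarray:
        return (self.edge_sign != 0).sum(axis=1)

    def y_from_fields(self, C2_local, C3_local, kappa_eps):
        """Per-gene input vector from local oxygen/estrogen levels."""
        C2 = np.asarray(C2_local, dtype=float)
        C3 = np.asarray(C3_local, dtype=float)
        y = np.empty(np.broadcast(C2, C3).shape + (N_GENES,))
        for i, agent in enumerate(self.input_agent):
            y[..., i] = microenv_input(C2 if agent == "oxygen" else C3,
                                       kappa_eps, agent)
        return y


# ---------------------------------------------------------------------------
# Continuous dynamics
# ---------------------------------------------------------------------------

def grn_rhs(x, y, model: GRNModel, eta) -> np.ndarray:
    """Right-hand side of the kinetic system; batched over leading axes.

    The drive factor (y/eta - 1) is capped at +-drive_cap so the system
    stays finite when plasticity has driven a threshold to its clamp at
    zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    ratio = y / np.maximum(eta, 1e-12)
    drive = model.alpha_g * np.clip(ratio - 1.0, -model.drive_cap,
                                    model.drive_cap) * (1.0 - x)
    pos = getattr(model, "_fb_pos", None)
    if pos is None:
        pos = np.array([s == "positive" for s in model.feedback_sign])
        object.__setattr__(model, "_fb_pos", pos)
    R = np.where(pos, model.lambda_g * x / (model.delta + x),
                 model.lambda_g * model.delta / (model.delta + x))
    t = (model.fb_nu * x) ** model.fb_gamma
    Ht = model.fb_beta * t / (model.k + t)
    te = (model.hill_nu * x) ** model.hill_gamma
    H = model.hill_beta * te / (model.k + te)
    interactions = x * (H @ model.edge_sign.T)
    return drive + R * Ht + interactions - model.mu * x


@dataclass
class AttractorLabel:
    """Binarized expression pattern with its phenotype class."""

    pattern: tuple                 # per-gene 0/1 at threshold 0.5
    phenotype: str                 # normal / precancer / cancer
    converged: bool = True

    @property
    def expressed(self) -> frozenset:
        return frozenset(g for g, on in zip(GENES, self.pattern) if on)


def classify_pattern(pattern) -> str:
    """Attractor-to-phenotype map: a/c normal, the HER2-AKT1-P21-CDK2 state
    cancer, anything else precancer."""
    on = frozenset(g for g, v in zip(GENES, pattern) if v)
    if all(g in on for g in CANCER_SIGNATURE):
        return "cancer"
    if on in NORMAL_PATTERNS:
        return "normal"
    return "precancer"


def integrate_grn(x0, y, model: GRNModel, eta, t_max=400.0, dt=0.05,
                  tol=1e-7):
    """Clipped fixed-step RK4 to (near) steady state; batched.

    Returns (x_final, converged_mask).  States are confined to [0,1]
    (expression levels are fractions of the full gene state).
    """
    x0 = np.asarray(x0, dtype=float)
    lead = x0.shape[:-1]
    n_genes = x0.shape[-1]
    x = np.clip(x0, 0.0, 1.0).reshape(-1, n_genes).copy()
    y = np.broadcast_to(np.asarray(y, dtype=float), x0.shape) \
        .reshape(-1, n_genes).copy()
    ea = np.broadcast_to(np.asarray(eta, dtype=float), x0.shape) \
        .reshape(-1, n_genes).copy()
    steps = int(round(t_max / dt))
    check_every = 25
    converged = np.zeros(x.shape[0], dtype=bool)
    active = np.arange(x.shape[0])
    xa, ya = x[active], y[active]
    ea_a = ea[active]
    for s in range(steps):
        k1 = grn_rhs(xa, ya, model, ea_a)
        k2 = grn_rhs(np.clip(xa + 0.5 * dt * k1, 0, 1), ya, model, ea_a)
        k3 = grn_rhs(np.clip(xa + 0.5 * dt * k2, 0, 1), ya, model, ea_a)
        k4 = grn_rhs(np.clip(xa + dt * k3, 0, 1), ya, model, ea_a)
        xa = np.clip(xa + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, 1.0)
        if (s + 1) % check_every == 0 or s == steps - 1:
            rate = grn_rhs(xa, ya, model, ea_a)
            # clipped coordinates pinned at the boundary are stationary
            rate = np.where((xa <= 0) & (rate < 0), 0.0, rate)
            rate = np.where((xa >= 1) & (rate > 0), 0.0, rate)
            done = np.abs(rate).max(axis=-1) < tol
            x[active] = xa
            converged[active] = done
            if done.all():
                active = active[:0]
                break
            keep = ~done            # converged rows leave the batch
            active = active[keep]
            xa, ya, ea_a = xa[keep], ya[keep], ea_a[keep]
    if len(active):
        x[active] = xa
    return x.reshape(x0.shape), converged.reshape(lead)


def integrate_to_attractor(x0, y, model: GRNModel, eta=None, t_max=400.0,
                           tol=1e-7):
    """Settle one GRN into its attractor and label the phenotype."""
    if eta is None:
        eta = np.full(N_GENES, 0.5)
    x, converged = integrate_grn(x0, y, model, eta, t_max=t_max, tol=tol)
    pattern = tuple(int(v) for v in (x > 0.5))
    return AttractorLabel(pattern=pattern,
                          phenotype=classify_pattern(pattern),
                          converged=bool(np.all(converged))), x


# ---------------------------------------------------------------------------
# Boolean representation
# ---------------------------------------------------------------------------

def boolean_step(states: np.ndarray, model: GRNModel) -> np.ndarray:
    """Synchronous update: ON iff net signed input exceeds the threshold."""
    inp = states @ model.edge_sign.T
    return (inp > model.bool_threshold).astype(np.int8)


def boolean_attractors(model: GRNModel):
    """Exhaustively enumerate attractors of the synchronous Boolean GRN.

    Returns a list of dicts with keys ``states`` (tuple of bit-tuples,
    one per cycle state), ``basin`` (number of the 2^N states that flow
    there) and ``phenotype`` (the worst phenotype along the cycle:
    cancer > precancer > normal).
    """
    n = len(model.genes)
    total = 1 << n
    all_states = ((np.arange(total)[:, None] >> np.arange(n)) & 1).astype(np.int8)
    nxt_states = boolean_step(all_states, model)
    succ = (nxt_states << np.arange(n)).sum(axis=1)

    # peel non-cycle states: iterate the successor map n_states times
    reach = succ.copy()
    for _ in range(12):              # 2^10 states: 10 doublings suffice
        reach = reach[reach]
    on_cycle = np.zeros(total, dtype=bool)
    on_cycle[np.unique(reach)] = True

    seen = np.zeros(total, dtype=bool)
    attractors = []
    cycle_id = np.full(total, -1)
    for s in range(total):
        if not on_cycle[s] or seen[s]:
            continue
        cyc = [s]
        seen[s] = True
        t = succ[s]
        while t != s:
            cyc.append(t)
            seen[t] = True
            t = succ[t]
        for c in cyc:
            cycle_id[c] = len(attractors)
        attractors.append(cyc)

    basin_of = cycle_id[reach]
    out = []
    rank = {"normal": 0, "precancer": 1, "cancer": 2}
    for i, cyc in enumerate(attractors):
        patterns = tuple(tuple(int(b) for b in all_states[c]) for c in cyc)
        phen = max((classify_pattern(p) for p in patterns),
                   key=lambda ph: rank[ph])
        out.append({"states": patterns,
                    "basin": int((basin_of == i).sum()),
                    "phenotype": phen})
    return out


# ---------------------------------------------------------------------------
# Expression sweeps
# ---------------------------------------------------------------------------

def expression_sweep(model: GRNModel, eta0, n_points=101, t_max=400.0):
    """Steady-state expression of every gene versus the driving input.

    The normalized concentration (NC) of the driving agent is swept over
    [0, 1]; at each point the network is settled from the resting state
    with y_i = NC for every gene.  Returns (nc_grid, matrix) with shape
    (genes, n_points).
    """
    nc = np.linspace(0.0, 1.0, n_points)
    eta = np.broadcast_to(np.asarray(eta0, dtype=float),
                          (N_GENES,)).astype(float)
    y = np.repeat(nc[:, None], N_GENES, axis=1)
    x0 = np.zeros((n_points, N_GENES))
    x, _ = integrate_grn(x0, y, model, eta, t_max=t_max)
    return nc, x.T


def expression_onset(nc, expression, gene, level=0.5):
    """Smallest NC at which a gene's steady state exceeds ``level``.

    ``level=0.5`` is the expressed/inhibited binarization; ``level=0.9``
    is the full-expression criterion.  Returns NaN if never reached.
    """
    gi = GENES.index(gene) if isinstance(gene, str) else gene
    above = expression[gi] > level
    if not above.any():
        return float("nan")
    return float(nc[np.argmax(above)])
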