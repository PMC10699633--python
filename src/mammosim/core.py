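"""Core data types, configuration, seeding and lattice bookkeeping.

The tissue lives on a 2D square or 3D cubic lattice.  Three occupancy
variables are defined at every site: ``sigma_n`` (normal cell, binary),
``sigma_d`` (necrotic cell, binary) and ``sigma_c`` (number of piled
cancer/precancer cells, a nonnegative integer).  Glucose, oxygen and
estrogen are scalar lattice fields normalized to the capillary value 1;
the capillary is the boundary row/plane with the maximal last-axis index.

Coordinates are 0-based integer tuples everywhere.  "Top" (the capillary
side) means the maximal index along the last axis, in 2D and 3D alike.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml

#: Gene order used for genotype vectors, thresholds and GRN states.
GENES = ("TP53", "ATM", "HER2", "BRCA1", "AKT1",
         "ATR", "CHEK1", "MDM2", "CDK2", "P21")
N_GENES = len(GENES)

#: Named independent random streams spawned from the master seed.
STREAM_NAMES = ("init", "placement", "death", "mutation", "tauleap",
                "homogenize", "grn", "misc")


class RandomStreams:
    """One master seed spawning independent named PCG64 streams.

    Each subsystem (division placement, death draws, mutation draws,
    tau-leaping, homogenization block order) owns a stream, so its draws
    are reproducible in isolation from the others.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(STREAM_NAMES))
        self._rngs = {name: np.random.default_rng(child)
                      for name, child in zip(STREAM_NAMES, children)}

    def __getitem__(self, name: str) -> np.random.Generator:
        return self._rngs[name]

    def state_dict(self) -> dict:
        return {name: rng.bit_generator.state
                for name, rng in self._rngs.items()}

    def set_state_dict(self, state: dict) -> None:
        for name, st in state.items():
            self._rngs[name].bit_generator.state = st


@dataclass
class SimulationConfig:
    """All model parameters plus numerical controls and the seed.

    Transport/microenvironment parameters follow the dimensionless model:
    ``alpha[l]`` are per-site consumption rates and ``lam[l]`` supply
    (competition) rates for glucose (l=0), oxygen (l=1) and estrogen
    (l=2).  ``theta_d`` is the steepness of the hypoxic-death Gaussian,
    ``theta_div`` the steepness of the glucose-coupled hopping
    probability, ``kappa_eps`` the estrogen carrying-capacity constant,
    ``xi``/``chi`` the intrinsic/extrinsic plasticity susceptibilities,
    ``R_o`` the lineage neighborhood radius and ``P_B`` the
    estrogen-receptor failure probability.
    """

    dims: int = 2
    L: int = 100
    alpha: tuple = (8e-3, 8e-3, 8e-3)
    lam: tuple = (100.0, 50.0, 200.0)
    theta_d: float = 0.01
    theta_div: float = 0.3
    kappa_eps: float = 0.1
    xi: float = 0.5
    chi: float = 4.0
    R_o: int = 20
    P_B: float = 1.0
    poisson_mean: float = 1.0
    seed: int = 0
    max_cycles: int = 250
    block: int = 20
    mutation_rule: str = "as_printed"   # or "conventional"

    # --- numerical controls -------------------------------------------------
    eta0: float = 0.5              # initial activation-inhibition threshold
    eta_step_scale: float | None = None   # per-cycle plasticity step scale;
    # None: normalized so that sustained maximal pressure (xi eta0 + chi)
    # erodes a threshold from eta0 to 0 over one full cycle budget
    cycles_per_division: float = 2.8   # automaton cycles per seed division
                                       # (biological ~35 h vs ~12.5 h cycle)
    lv_init: tuple = (1.2, 1.0)    # initial cell-cycle phase (u, v)
    stop_fraction: float = 0.9     # tumor bounding-box stop criterion
    transport_tol: float = 1e-5
    transport_max_iter: int = 20000
    necrotic_replaceable: bool = False
    normal_cells_divide: bool = False
    death_pick: str = "lifo"       # which piled cell dies: "lifo"|"random"
    gene_selection: str = "negative_binomial"   # or "uniform"
    drive_cap: float = 1e3         # cap on y/eta - 1 when eta -> 0
    grn: object = None             # GRNModel; filled lazily with the default

    def __post_init__(self):
        self.alpha = tuple(float(a) for a in np.atleast_1d(self.alpha))
        self.lam = tuple(float(v) for v in np.atleast_1d(self.lam))
        if self.dims not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.dims}")
        if self.L < 2 * self.block:
            raise ValueError(
                f"L={self.L} too small to host the {self.block}-site "
                f"homogenization block grid (need L >= {2 * self.block})")
        if len(self.alpha) != 3 or len(self.lam) != 3:
            raise ValueError("alpha and lam must each have 3 entries")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("all consumption rates alpha must be > 0")
        if any(v < 0 for v in self.lam):
            raise ValueError("supply rates lam must be >= 0")
        if self.theta_d <= 0 or self.theta_div <= 0:
            raise ValueError("theta_d and theta_div must be > 0")
        if self.kappa_eps <= 0:
            raise ValueError("kappa_eps must be > 0")
        if not 0.0 <= self.P_B <= 1.0:
            raise ValueError("P_B must lie in [0, 1]")
        if self.R_o > self.L:
            raise ValueError("R_o cannot exceed the lattice size")
        if self.mutation_rule not in ("conventional", "as_printed"):
            raise ValueError(f"unknown mutation_rule {self.mutation_rule!r}")

    @property
    def shape(self) -> tuple:
        return (self.L,) * self.dims

    # Reference susceptibilities anchoring the plasticity step scale
    # (the phenotype-map conditions).  The scale must not depend on the
    # scanned xi/chi themselves, or susceptibility scans self-cancel.
    ETA_REF_XI = 0.5
    ETA_REF_CHI = 4.0

    # Per-cycle plasticity step scale.
    @property
    def eta_step(self) -> float:
        scale = self.eta_step_scale
        if scale is None:
            scale = self.eta0 / (self.ETA_REF_XI * self.eta0
                                 + self.ETA_REF_CHI)
        return scale / max(self.max_cycles, 1)

    def grn_model(self):
        if self.grn is None:
            from .grn import GRNModel
            self.grn = GRNModel.default()
        return self.grn

    # --- YAML round trip ----------------------------------------------------
    _YAML_KEYS = ("dims", "L", "alpha", "lambda", "theta_d", "theta_div",
                  "kappa_eps", "xi", "chi", "R_o", "P_B", "poisson_mean",
                  "seed", "max_cycles", "block", "mutation_rule", "eta0",
                  "eta_step_scale", "cycles_per_division", "lv_init",
                  "stop_fraction", "necrotic_replaceable",
                  "normal_cells_divide", "death_pick", "gene_selection")

    def to_yaml(self, path) -> None:
        doc = {}
        for key in self._YAML_KEYS:
            attr = "lam" if key == "lambda" else key
            val = getattr(self, attr)
            if isinstance(val, tuple):
                val = list(val)
            doc[key] = val
        grn = self.grn_model()
        doc["grn"] = grn.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        grn_doc = doc.pop("grn", None)
        if "lambda" in doc:
            doc["lam"] = doc.pop("lambda")
        for key in ("alpha", "lam", "lv_init"):
            if key in doc:
                doc[key] = tuple(doc[key])
        cfg = cls(**doc)
        if grn_doc is not None:
            from .grn import GRNModel
            cfg.grn = GRNModel.from_dict(grn_doc)
        return cfg


@dataclass
class CellGrid:
    """Per-site occupancy: sigma_n, sigma_d in {0,1}; sigma_c in N."""

    sigma_n: np.ndarray
    sigma_c: np.ndarray
    sigma_d: np.ndarray

    @classmethod
    def empty(cls, shape) -> "CellGrid":
        return cls(sigma_n=np.zeros(shape, dtype=np.int8),
                   sigma_c=np.zeros(shape, dtype=np.int32),
                   sigma_d=np.zeros(shape, dtype=np.int8))

    def validate(self) -> None:
        if (self.sigma_c < 0).any() or (self.sigma_n < 0).any() \
                or (self.sigma_d < 0).any():
            raise ValueError("occupancy fields must be nonnegative")
        if ((self.sigma_n + self.sigma_d) > 1).any():
            raise ValueError("sigma_n + sigma_d must be <= 1 at every site")
        if ((self.sigma_n == 1) & (self.sigma_c > 0)).any():
            raise ValueError("a site cannot hold a normal cell and cancer "
                             "cells simultaneously")


@dataclass(eq=False)
class CellRecord:
    """State of one precancer/cancer cell.

    ``genotype`` counts accumulated mutations per gene (monotone
    non-decreasing over the cell's lifetime), ``eta``/``eta0`` are the
    current and initial per-gene activation-inhibition thresholds,
    ``grn_state`` the continuous GRN expression vector, ``phase`` the
    Lotka-Volterra cell-cycle pair (u, v) and ``clock`` the fraction of
    the current division period already elapsed.
    """

    pos: tuple
    genotype: np.ndarray
    eta: np.ndarray
    eta0: np.ndarray
    grn_state: np.ndarray
    phase: tuple
    clock: float = 0.0
    phenotype: str = "cancer"

    def copy(self) -> "CellRecord":
        return CellRecord(pos=self.pos,
                          genotype=self.genotype.copy(),
                          eta=self.eta.copy(),
                          eta0=self.eta0.copy(),
                          grn_state=self.grn_state.copy(),
                          phase=tuple(self.phase),
                          clock=0.0,
                          phenotype=self.phenotype)


@dataclass
class Fields:
    """Glucose (C1), oxygen (C2) and estrogen (C3) lattice fields."""

    C1: np.ndarray
    C2: np.ndarray
    C3: np.ndarray

    def __getitem__(self, l: int) -> np.ndarray:
        return (self.C1, self.C2, self.C3)[l]

    def __setitem__(self, l: int, value: np.ndarray) -> None:
        setattr(self, ("C1", "C2", "C3")[l], value)

    @classmethod
    def ones(cls, shape) -> "Fields":
        return cls(*(np.ones(shape) for _ in range(3)))


class CellPopulation:
    """All living precancer/cancer cells, stacked per lattice site.

    Cells piled at one site form an ordered stack; by default the most
    recently added record dies first (the model does not resolve which
    piled cell dies, so the pick is configurable to uniform-random).
    """

    def __init__(self):
        self.cells: list[CellRecord] = []
        self._by_site: dict[tuple, list[CellRecord]] = {}

    def __len__(self):
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def add(self, cell: CellRecord) -> None:
        self.cells.append(cell)
        self._by_site.setdefault(cell.pos, []).append(cell)

    def at(self, pos: tuple) -> list:
        return self._by_site.get(tuple(pos), [])

    def remove_at(self, pos: tuple, rng=None, pick: str = "lifo") -> CellRecord:
        """Remove one piled cell at ``pos`` (LIFO by default).

        The record is flagged dead and dropped from the site stack;
        call :meth:`compact` after a death sweep to rebuild the flat
        cell list in one pass.
        """
        stack = self._by_site[tuple(pos)]
        if pick == "random" and rng is not None and len(stack) > 1:
            idx = int(rng.integers(len(stack)))
        else:
            idx = len(stack) - 1
        cell = stack.pop(idx)
        if not stack:
            del self._by_site[tuple(pos)]
        cell.dead = True
        return cell

    def compact(self) -> None:
        self.cells = [c for c in self.cells if not getattr(c, "dead", False)]

    def positions(self) -> np.ndarray:
        if not self.cells:
            return np.empty((0, 0), dtype=int)
        return np.array([c.pos for c in self.cells], dtype=int)


def neighbors(pos, config: SimulationConfig) -> list:
    """Von Neumann neighborhood of ``pos``, clipped at the boundaries.

    4 nearest neighbors in 2D, 6 in 3D; deterministic order (-/+ along
    each axis in turn).
    """
    pos = tuple(int(p) for p in pos)
    if len(pos) != config.dims:
        raise ValueError(f"position {pos} does not match dims={config.dims}")
    if any(not 0 <= p < config.L for p in pos):
        raise ValueError(f"position {pos} outside the lattice")
    out = []
    for axis in range(config.dims):
        for step in (-1, +1):
            q = pos[axis] + step
            if 0 <= q < config.L:
                out.append(pos[:axis] + (q,) + pos[axis + 1:])
    return out


def make_initial_state(config: SimulationConfig):
    """All-normal tissue with one cancer cell at the lattice center.

    The initial cancer cell carries a single TP53 mutation; fields start
    at the capillary value 1 everywhere (the transport solve relaxes
    them before the first cycle).
    """
    shape = config.shape
    grid = CellGrid.empty(shape)
    grid.sigma_n[...] = 1
    center = tuple(config.L // 2 for _ in range(config.dims))
    grid.sigma_n[center] = 0
    grid.sigma_c[center] = 1

    genotype = np.zeros(N_GENES, dtype=np.int64)
    genotype[GENES.index("TP53")] = 1
    eta0 = np.full(N_GENES, config.eta0, dtype=float)
    cell = CellRecord(pos=center, genotype=genotype,
                      eta=eta0.copy(), eta0=eta0.copy(),
                      grn_state=np.zeros(N_GENES),
                      phase=tuple(config.lv_init), clock=0.0,
                      phenotype="cancer")
    cells = CellPopulation()
    cells.add(cell)
    fields = Fields.ones(shape)
    return grid, cells, fields


# ---------------------------------------------------------------------------
# Snapshots
# ---------------------------------------------------------------------------

_CELL_SCALARS = ("clock",)


def save_snapshot(path, grid: CellGrid, cells: CellPopulation,
                  fields: Fields, streams: RandomStreams | None = None,
                  cycle: int = 0, extra: dict | None = None) -> None:
    """Write lattice, fields, per-cell tables and RNG state to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["cycle"] = cycle
        for name in ("sigma_n", "sigma_c", "sigma_d"):
            fh.create_dataset(name, data=getattr(grid, name))
        for l, name in enumerate(("C1", "C2", "C3")):
            fh.create_dataset(name, data=fields[l])
        n = len(cells)
        g = fh.create_group("cells")
        dims = grid.sigma_n.ndim
        g.create_dataset("pos", data=np.array(
            [c.pos for c in cells], dtype=np.int64).reshape(n, dims))
        for name in ("genotype", "eta", "eta0", "grn_state"):
            g.create_dataset(name, data=np.array(
                [getattr(c, name) for c in cells]).reshape(n, N_GENES))
        g.create_dataset("phase", data=np.array(
            [c.phase for c in cells], dtype=float).reshape(n, 2))
        g.create_dataset("clock", data=np.array(
            [c.clock for c in cells], dtype=float))
        g.create_dataset("phenotype", data=np.array(
            [c.phenotype for c in cells], dtype="S9"))
        # spatial mutation map: max total count over each site's pile
        mut_map = np.zeros(grid.sigma_n.shape, dtype=np.int64)
        for c in cells:
            total = int(c.genotype.sum())
            if total > mut_map[c.pos]:
                mut_map[c.pos] = total
        fh.create_dataset("mutation_map", data=mut_map)
        if streams is not None:
            fh.attrs["rng_state"] = json.dumps(streams.state_dict())
            fh.attrs["seed"] = streams.seed
        if extra:
            for key, val in extra.items():
                fh.attrs[key] = val


def load_snapshot(path, config: SimulationConfig | None = None):
    """Inverse of :func:`save_snapshot`.

    Returns ``(grid, cells, fields, streams, cycle)``; ``streams`` is
    None when the snapshot carries no RNG state.
    """
    with h5py.File(path, "r") as fh:
        grid = CellGrid(sigma_n=fh["sigma_n"][...],
                        sigma_c=fh["sigma_c"][...],
                        sigma_d=fh["sigma_d"][...])
        fields = Fields(fh["C1"][...], fh["C2"][...], fh["C3"][...])
        g = fh["cells"]
        cells = CellPopulation()
        n = g["clock"].shape[0]
        for i in range(n):
            cells.add(CellRecord(
                pos=tuple(int(v) for v in g["pos"][i]),
                genotype=g["genotype"][i].astype(np.int64),
                eta=g["eta"][i].astype(float),
                eta0=g["eta0"][i].astype(float),
                grn_state=g["grn_state"][i].astype(float),
                phase=tuple(float(v) for v in g["phase"][i]),
                clock=float(g["clock"][i]),
                phenotype=g["phenotype"][i].decode()))
        streams = None
        if "rng_state" in fh.attrs:
            streams = RandomStreams(int(fh.attrs.get("seed", 0)))
            streams.set_state_dict(json.loads(fh.attrs["rng_state"]))
        cycle = int(fh.attrs.get("cycle", 0))
    return grid, cells, fields, streams, cycle
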