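"""Lineage segregation and activation-threshold plasticity.

The segregation index of a cell averages, over all living neighbors
within Euclidean distance R_o, the product of a genetic activity term
(0 for an identical genotype, 1 otherwise) and a Michaelis-Menten
estrogen weight C3/(C3 + kappa_eps) evaluated at the neighbor position.
It ranges from 0 (a clonal neighborhood) toward 1 (complete lineage
segregation under saturating estrogen).

Cell plasticity erodes the per-gene activation-inhibition thresholds:
the intrinsic part is proportional to the initial threshold (rate xi),
the extrinsic (quorum-sensing) part to the local segregation index
(rate chi).  The update is applied once per simulation cycle with a
step scale s, clamped at zero from below.
"""

from __future__ import annotations

import numpy as np

from .core import CellGrid, CellPopulation, SimulationConfig


def genetic_activity(a_i: np.ndarray, a_j: np.ndarray) -> int:
    """0 if the two genotypes are identical, 1 otherwise."""
    a_i = np.asarray(a_i)
    a_j = np.asarray(a_j)
    if a_i.shape != a_j.shape:
        raise ValueError("genotype length mismatch")
    return int(not np.array_equal(a_i, a_j))


def michaelis_menten(C3, kappa_eps):
    return C3 / (C3 + kappa_eps)


def segregation_index(cell, neighbor_cells, C3_field: np.ndarray,
                      kappa_eps: float) -> float:
    """Segregation index of one cell from an explicit neighbor list.

    ``neighbor_cells`` are the living cells within R_o (piled cells at
    the same site included, the focal cell itself excluded); an
    isolated cell has no lineage signal and returns 0.
    """
    if not neighbor_cells:
        return 0.0
    total = 0.0
    for nb in neighbor_cells:
        g = genetic_activity(cell.genotype, nb.genotype)
        total += g * michaelis_menten(float(C3_field[tuple(nb.pos)]),
                                      kappa_eps)
    return total / len(neighbor_cells)


def update_thresholds(eta: np.ndarray, eta0: np.ndarray, beta_hat: float,
                      xi: float, chi: float, s: float = 1.0) -> np.ndarray:
    """One plasticity step: eta -> max(0, eta - s (xi eta0 + beta_hat chi)).

    The minimum threshold is zero (cells resist unbounded plasticity);
    with xi = chi = 0 the thresholds are left untouched.
    """
    if xi < 0 or chi < 0:
        raise ValueError("susceptibilities must be nonnegative")
    return np.maximum(0.0, eta - s * (xi * eta0 + beta_hat * chi))


# ---------------------------------------------------------------------------
# Lattice-wide computation
# ---------------------------------------------------------------------------

def _ball_offsets(R_o: int, dims: int) -> np.ndarray:
    rng = np.arange(-R_o, R_o + 1)
    grids = np.meshgrid(*([rng] * dims), indexing="ij")
    pts = np.stack([g.reshape(-1) for g in grids], axis=1)
    keep = (pts ** 2).sum(axis=1) <= R_o ** 2
    return pts[keep]


class _BallGather:
    """Sum a lattice field over the R_o-ball around many positions."""

    def __init__(self, shape, R_o):
        self.shape = shape
        self.R = int(R_o)
        self.offsets = _ball_offsets(self.R, len(shape))
        pad_shape = tuple(s + 2 * self.R for s in shape)
        strides = np.cumprod((1,) + pad_shape[::-1][:-1])[::-1]
        self._pad_shape = pad_shape
        self._lin_offsets = (self.offsets * strides).sum(axis=1)
        self._strides = strides

    def __call__(self, field: np.ndarray, positions: np.ndarray) -> np.ndarray:
        if positions.size == 0:
            return np.zeros(0)
        padded = np.zeros(self._pad_shape, dtype=float)
        interior = tuple(slice(self.R, self.R + s) for s in self.shape)
        padded[interior] = field
        flat = padded.reshape(-1)
        base = ((positions + self.R) * self._strides).sum(axis=1)
        out = np.empty(len(base))
        chunk = max(1, int(4e6) // len(self._lin_offsets))
        for lo in range(0, len(base), chunk):
            sel = base[lo:lo + chunk]
            out[lo:lo + chunk] = flat[
                sel[:, None] + self._lin_offsets[None, :]].sum(axis=1)
        return out


def _genotype_classes(cells: CellPopulation):
    classes: dict[bytes, list[int]] = {}
    for i, c in enumerate(cells.cells):
        classes.setdefault(c.genotype.tobytes(), []).append(i)
    return classes


def beta_for_cells(grid: CellGrid, cells: CellPopulation,
                   C3: np.ndarray, config: SimulationConfig,
                   gather: _BallGather | None = None) -> np.ndarray:
    """Segregation index of every cancer/precancer cell, vectorized.

    Decomposes the segregation sum into (all-neighbor weight) minus
    (same-genotype weight), both computed as ball sums around each cell
    position; normal cells count as one shared all-zero genotype and
    necrotic cells are excluded.
    """
    n = len(cells.cells)
    if n == 0:
        return np.zeros(0)
    shape = grid.sigma_n.shape
    if gather is None:
        gather = _BallGather(shape, config.R_o)
    mm = michaelis_menten(C3, config.kappa_eps)
    count = (grid.sigma_n + grid.sigma_c).astype(float)
    W_total = count * mm
    pos = cells.positions()

    total = gather(W_total, pos)
    m = gather(count, pos) - 1.0                # exclude the focal cell

    same = np.zeros(n)
    site_counts = np.zeros(shape)
    zero_key = np.zeros_like(cells.cells[0].genotype).tobytes()
    for key, members in _genotype_classes(cells).items():
        mpos = pos[members]
        if len(members) == 1 and key != zero_key:
            # a singleton genotype shares no class weight beyond itself
            continue
        site_counts[...] = 0.0
        np.add.at(site_counts, tuple(mpos.T), 1.0)
        if key == zero_key:
            # normal cells carry the unmutated (all-zero) genotype
            site_counts += grid.sigma_n
        same[members] = gather(site_counts * mm, mpos)
    # remove the focal cell's own contribution to its class weight
    self_mm = mm[tuple(pos.T)]
    same = np.where(same > 0, same - self_mm, 0.0)

    beta = np.zeros(n)
    ok = m >= 1
    beta[ok] = (total[ok] - self_mm[ok] - same[ok]) / m[ok]
    return np.clip(beta, 0.0, 1.0)


def beta_for_normal_sites(grid: CellGrid, C3: np.ndarray,
                          config: SimulationConfig,
                          gather: _BallGather | None = None):
    """Segregation index of every normal cell (one shared genotype).

    Returns (positions, beta) for all sites with a normal occupant;
    used for the lattice-wide segregation maps.
    """
    shape = grid.sigma_n.shape
    if gather is None:
        gather = _BallGather(shape, config.R_o)
    pos = np.argwhere(grid.sigma_n == 1)
    if pos.size == 0:
        return pos, np.zeros(0)
    mm = michaelis_menten(C3, config.kappa_eps)
    count = (grid.sigma_n + grid.sigma_c).astype(float)
    total = gather(count * mm, pos)
    m = gather(count, pos) - 1.0
    same = gather(grid.sigma_n * mm, pos) - mm[tuple(pos.T)]
    beta = np.zeros(len(pos))
    ok = m >= 1
    # distinct neighbors of a normal cell are exactly the cancer cells
    beta[ok] = (total[ok] - mm[tuple(pos.T)][ok] - same[ok]) / m[ok]
    return pos, np.clip(beta, 0.0, 1.0)


def block_mean_beta(grid: CellGrid, cells: CellPopulation, C3: np.ndarray,
                    config: SimulationConfig) -> np.ndarray:
    """Mean tumor-cell segregation index on the homogenization blocks.

    The segregation index is carried by the precancer/cancer cells
    (normal cells enter the index only as neighbors); the block map averages
    it over the tumor cells in each block.  Blocks without tumor cells
    have no lineage signal and map to 0.
    """
    shape = grid.sigma_n.shape
    gather = _BallGather(shape, config.R_o)
    block = config.block
    nblocks = tuple(-(-s // block) for s in shape)
    acc = np.zeros(nblocks)
    cnt = np.zeros(nblocks)
    if len(cells.cells):
        positions = cells.positions()
        values = beta_for_cells(grid, cells, C3, config, gather)
        idx = tuple((positions // block).T)
        np.add.at(acc, idx, values)
        np.add.at(cnt, idx, 1.0)
    return np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
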