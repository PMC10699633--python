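"""Steady-state reaction-diffusion transport of glucose, oxygen, estrogen.

Each dimensionless field C_l obeys

    dC_l/dt = lap(C_l) - alpha_l^2 [sigma_n + lambda_l sigma_c] C_l

with Dirichlet C_l = 1 on the capillary face (maximal last-axis index)
and zero-flux (mirror) conditions on every other face.  Nutrients vary
much more slowly than the cellular processes, so only the stationary
solution is ever needed: the quasi-static field is fully relaxed once
per simulation cycle.

Discretization: unit lattice spacing, standard 5-point (2D) / 7-point
(3D) central-difference Laplacian.  The linear system is solved directly
(sparse LU) by default; a damped-Jacobi relaxation is used for the local
homogenization passes and is available as an alternative global method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import CellGrid, Fields, SimulationConfig


class TransportError(RuntimeError):
    pass


@dataclass
class TransportProblem:
    """One field's coefficients: index l in {0,1,2}, rates, tolerances."""

    l: int
    alpha: float
    lam: float
    capillary_value: float = 1.0
    tol: float = 1e-5
    max_iter: int = 20000

    @classmethod
    def from_config(cls, config: SimulationConfig, l: int) -> "TransportProblem":
        return cls(l=l, alpha=config.alpha[l], lam=config.lam[l],
                   tol=config.transport_tol,
                   max_iter=config.transport_max_iter)


def consumption_coefficient(problem: TransportProblem,
                            grid: CellGrid) -> np.ndarray:
    """alpha_l^2 [sigma_n + lambda_l sigma_c] >= 0 at every site."""
    return problem.alpha ** 2 * (grid.sigma_n + problem.lam * grid.sigma_c)


def _capillary_mask(shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[..., -1] = True
    return mask


def _assemble(shape, k: np.ndarray, dirichlet: np.ndarray,
              dirichlet_values: np.ndarray):
    """Sparse system for (lap - k) C = 0 with mirror Neumann faces.

    Dirichlet rows become identity rows with the frozen value on the
    right-hand side.  Missing mirror neighbors simply reduce the
    diagonal neighbor count, which is the standard zero-flux stencil.
    """
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    kf = k.reshape(-1).astype(float)
    dirf = dirichlet.reshape(-1)

    rows, cols, vals = [], [], []
    diag = -kf.copy()
    for axis in range(len(shape)):
        for step in (-1, +1):
            src = [slice(None)] * len(shape)
            dst = [slice(None)] * len(shape)
            if step == -1:
                src[axis] = slice(1, None)
                dst[axis] = slice(0, -1)
            else:
                src[axis] = slice(0, -1)
                dst[axis] = slice(1, None)
            r = idx[tuple(src)].reshape(-1)
            c = idx[tuple(dst)].reshape(-1)
            keep = ~dirf[r]
            rows.append(r[keep])
            cols.append(c[keep])
            vals.append(np.ones(keep.sum()))
            np.add.at(diag, r[keep], -1.0)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)

    all_rows = np.concatenate([rows, np.arange(n)])
    all_cols = np.concatenate([cols, np.arange(n)])
    diag_vals = np.where(dirf, 1.0, diag)
    # zero out assembled off-diagonals on dirichlet rows already excluded
    all_vals = np.concatenate([vals, diag_vals])
    A = sp.csc_matrix((all_vals, (all_rows, all_cols)), shape=(n, n))
    b = np.where(dirf, dirichlet_values.reshape(-1), 0.0)
    return A, b


def residual(C: np.ndarray, k: np.ndarray, dirichlet: np.ndarray,
             dirichlet_values: np.ndarray) -> float:
    """Max-norm residual of the discrete steady-state equations."""
    lap = np.zeros_like(C, dtype=float)
    ndim = C.ndim
    for axis in range(ndim):
        for step in (-1, +1):
            shifted = np.roll(C, -step, axis=axis)
            # mirror: missing neighbor equals the center value
            edge = [slice(None)] * ndim
            edge[axis] = -1 if step == +1 else 0
            shifted[tuple(edge)] = C[tuple(edge)]
            lap += shifted - C
    res = lap - k * C
    res[dirichlet] = C[dirichlet] - dirichlet_values[dirichlet]
    return float(np.abs(res).max())


def _jacobi(C0, k, dirichlet, dirichlet_values, tol, max_iter, omega=0.9):
    C = C0.astype(float).copy()
    C[dirichlet] = dirichlet_values[dirichlet]
    ndim = C.ndim
    nnb = np.zeros_like(C)
    for axis in range(ndim):
        for step in (-1, +1):
            sl = [slice(None)] * ndim
            sl[axis] = slice(1, None) if step == -1 else slice(0, -1)
            nnb[tuple(sl)] += 1.0
    for it in range(max_iter):
        nb_sum = np.zeros_like(C)
        for axis in range(ndim):
            for step in (-1, +1):
                shifted = np.roll(C, -step, axis=axis)
                edge = [slice(None)] * ndim
                edge[axis] = -1 if step == +1 else 0
                shifted[tuple(edge)] = 0.0
                nb_sum += shifted
        C_new = nb_sum / (nnb + k)
        C_new[dirichlet] = dirichlet_values[dirichlet]
        C = (1 - omega) * C + omega * C_new
        if it % 20 == 0 or it == max_iter - 1:
            if residual(C, k, dirichlet, dirichlet_values) < tol:
                return C
    raise TransportError(
        f"relaxation did not converge in {max_iter} iterations; "
        f"residual={residual(C, k, dirichlet, dirichlet_values):.3e}")


def steady_state(problem: TransportProblem, grid: CellGrid,
                 method: str = "direct") -> np.ndarray:
    """Stationary field for one nutrient on the whole lattice.

    Returns C_l with 0 <= C_l <= 1, C_l = 1 on the capillary face and
    the interior equations satisfied to ``problem.tol``.
    """
    grid.validate()
    shape = grid.sigma_n.shape
    k = consumption_coefficient(problem, grid)
    dirichlet = _capillary_mask(shape)
    values = np.full(shape, problem.capillary_value)
    if method == "direct":
        A, b = _assemble(shape, k, dirichlet, values)
        if len(shape) <= 2:
            C = spla.spsolve(A, b).reshape(shape)
        else:
            # sparse LU fill-in is prohibitive for the 7-point stencil;
            # eliminate the Dirichlet rows and use CG on the symmetric
            # negative-definite remainder
            free = ~dirichlet.reshape(-1)
            A_ff = A[free][:, free]
            b_f = b[free] - A[free][:, ~free] @ b[~free]
            M = sp.diags(1.0 / np.abs(A_ff.diagonal()))
            x, info = spla.cg(-A_ff.tocsr(), -b_f, M=M,
                              rtol=1e-10, atol=1e-12,
                              maxiter=problem.max_iter)
            if info != 0:
                raise TransportError(f"CG did not converge (info={info})")
            C = np.array(b)
            C[free] = x
            C = C.reshape(shape)
        res = residual(C, k, dirichlet, values)
        if not np.isfinite(res) or res > max(problem.tol, 1e-8) * 10:
            raise TransportError(f"direct solve residual {res:.3e} too large")
    elif method == "jacobi":
        C0 = np.ones(shape)
        C = _jacobi(C0, k, dirichlet, values, problem.tol, problem.max_iter)
    else:
        raise ValueError(f"unknown method {method!r}")
    # harmless solver noise below zero / above the capillary value
    return np.clip(C, 0.0, problem.capillary_value)


def solve_all(grid: CellGrid, config: SimulationConfig) -> Fields:
    """Relax the three fields to their global steady states."""
    out = []
    for l in range(3):
        out.append(steady_state(TransportProblem.from_config(config, l), grid))
    return Fields(*out)


def _iter_blocks(shape, block):
    """Tile the lattice into `block`-edge boxes (last box may be smaller)."""
    ranges = [range(0, s, block) for s in shape]
    grids = np.meshgrid(*[np.array(list(r)) for r in ranges], indexing="ij")
    starts = np.stack([g.reshape(-1) for g in grids], axis=1)
    for start in starts:
        yield tuple(slice(int(s), int(min(s + block, dim)))
                    for s, dim in zip(start, shape))


def homogenize(fields: Fields, grid: CellGrid, config: SimulationConfig,
               rng: np.random.Generator) -> Fields:
    """Local-then-global relaxation of the three nutrient fields.

    Blocks (20-site edge by default) containing at least one cancer cell
    are visited in uniformly random order and relaxed to their local
    steady state with the block-boundary values frozen as boundary data
    (faces on the global boundary keep the global condition); the global
    steady state is then solved, which leaves the returned fields within
    bounds and below the residual tolerance everywhere.
    """
    shape = grid.sigma_n.shape
    blocks = [bl for bl in _iter_blocks(shape, config.block)
              if grid.sigma_c[bl].sum() > 0]
    order = rng.permutation(len(blocks))
    out = Fields(*(fields[l].copy() for l in range(3)))
    for l in range(3):
        problem = TransportProblem.from_config(config, l)
        k = consumption_coefficient(problem, grid)
        C = out[l]
        for bi in order:
            bl = blocks[bi]
            sub = C[bl]
            subshape = sub.shape
            # freeze the block's boundary ring as Dirichlet data
            dir_mask = np.zeros(subshape, dtype=bool)
            for axis in range(len(subshape)):
                lo = [slice(None)] * len(subshape)
                hi = [slice(None)] * len(subshape)
                lo[axis] = 0
                hi[axis] = -1
                # interior block faces are frozen; global zero-flux faces
                # stay Neumann, the capillary face stays Dirichlet at 1
                if bl[axis].start > 0:
                    dir_mask[tuple(lo)] = True
                if bl[axis].stop < shape[axis]:
                    dir_mask[tuple(hi)] = True
                elif axis == len(subshape) - 1:
                    dir_mask[tuple(hi)] = True   # capillary face
            values = sub.copy()
            try:
                C[bl] = _jacobi(sub, k[bl], dir_mask, values, problem.tol,
                                min(config.transport_max_iter, 400))
            except TransportError:
                # a non-relaxed block only weakens the pre-smoothing;
                # the global solve below still enforces the tolerance
                pass
        out[l] = steady_state(problem, grid)
    return out
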