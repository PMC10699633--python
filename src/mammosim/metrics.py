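"""Tumor-level observables.

The Shannon index H = -sum_i P_i ln P_i measures intratumor
heterogeneity, with P_i the fraction of cancer cells that carry exactly
i mutations (total over the ten genes).  The tumor structure is
characterized by a box-counting fractal dimension of the cancer-cell
occupancy mask, and phenotype composition by the normal / precancer /
cancer fractions among living cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CycleSummary:
    """Per-cycle aggregate observables of one simulation."""

    cycle: int
    n_normal: int
    n_precancer: int
    n_cancer: int
    n_necrotic: int
    cancer_fraction: float
    mean_beta: float
    mean_eta: float
    mean_mutations: float
    shannon: float
    fractal_dimension: float
    births: int = 0
    deaths: int = 0

    #: per-gene total mutation counts (gene order of GENES); not part
    #: of the scalar summary row
    gene_totals: tuple = ()

    FIELDS = ("cycle", "n_normal", "n_precancer", "n_cancer", "n_necrotic",
              "cancer_fraction", "mean_beta", "mean_eta", "mean_mutations",
              "shannon", "fractal_dimension", "births", "deaths")

    def as_dict(self):
        return {k: getattr(self, k) for k in self.FIELDS}


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])


def shannon_index(mutation_counts) -> float:
    """Entropy of the per-cell total-mutation-count distribution.

    Categories are the distinct total counts; P_i is the fraction of
    cancer cells in category i, and 0 ln 0 := 0.
    """
    counts = np.asarray(mutation_counts)
    if counts.size == 0:
        raise ValueError("Shannon index undefined for an empty population")
    _, freq = np.unique(counts, return_counts=True)
    p = freq / freq.sum()
    return float(-(p * np.log(p)).sum())


def box_counting_dimension(mask: np.ndarray,
                           box_sizes=(2, 4, 8, 16, 32)) -> float:
    """Least-squares slope of log N(eps) against log(1/eps).

    Uses dyadic box edges clipped to the mask extent; needs at least
    two usable scales (three are typical for the lattice sizes here).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("box counting needs a nonempty mask")
    shape = mask.shape
    sizes = [b for b in box_sizes if b <= min(shape)]
    if len(sizes) < 2:
        raise ValueError("mask too small: fewer than 2 box scales usable")
    logs_n, logs_inv = [], []
    for b in sizes:
        # pad up to a multiple of b, then OR-reduce each box
        padded_shape = tuple(-(-s // b) * b for s in shape)
        padded = np.zeros(padded_shape, dtype=bool)
        padded[tuple(slice(0, s) for s in shape)] = mask
        view = padded
        for axis in range(mask.ndim):
            new = view.reshape(view.shape[:axis]
                               + (view.shape[axis] // b, b)
                               + view.shape[axis + 1:])
            view = new.any(axis=axis + 1)
        n_boxes = int(view.sum())
        logs_n.append(np.log(n_boxes))
        logs_inv.append(np.log(1.0 / b))
    slope = np.polyfit(logs_inv, logs_n, 1)[0]
    return float(np.clip(slope, 0.0, mask.ndim))


def phenotype_fractions(labels) -> dict:
    """Fractions of normal / precancer / cancer among living cells."""
    labels = list(labels)
    n = len(labels)
    out = {"normal": 0.0, "precancer": 0.0, "cancer": 0.0}
    if n == 0:
        return out
    for lab in labels:
        if lab not in out:
            raise ValueError(f"unknown phenotype label {lab!r}")
        out[lab] += 1.0
    return {k: v / n for k, v in out.items()}


PHENOTYPE_CODES = {"normal": 0, "precancer": 1, "cancer": 2}


def block_phenotype_majority(grid, cells, block):
    """Majority phenotype of the living cells on each block.

    Returns (majority, total): ``majority`` holds the code of the most
    frequent label (0 normal, 1 precancer, 2 cancer; ties resolved
    toward the lower code), -1 for blocks without living cells;
    ``total`` the living-cell count per block.
    """
    shape = grid.sigma_n.shape
    nb = tuple(-(-s // block) for s in shape)
    counts = np.zeros((3,) + nb)
    nidx = np.argwhere(grid.sigma_n == 1)
    if len(nidx):
        np.add.at(counts[0], tuple((nidx // block).T), 1.0)
    for c in cells.cells:
        idx = tuple(np.asarray(c.pos) // block)
        counts[PHENOTYPE_CODES[c.phenotype]][idx] += 1.0
    total = counts.sum(axis=0)
    majority = np.where(total > 0, np.argmax(counts, axis=0), -1)
    return majority, total


def mutation_count_map(grid, cells) -> np.ndarray:
    """Per-site mutation burden: the maximum total count over the
    site's pile of cancer cells (0 where no cell lives)."""
    out = np.zeros(grid.sigma_n.shape, dtype=int)
    for c in cells.cells:
        total = int(np.asarray(c.genotype).sum())
        if total > out[c.pos]:
            out[c.pos] = total
    return out


def rim_interior_mutation_means(grid, cells):
    """Mean per-cell total mutation count on the tumor rim vs interior.

    Rim sites are cancer-occupied sites with at least one von-Neumann
    neighbor free of cancer cells and necrotic debris (the growing
    surface); all other cancer sites are interior.
    """
    occ = (grid.sigma_c >= 1)
    tumor = occ | (grid.sigma_d >= 1)
    ndim = occ.ndim
    has_free_neighbor = np.zeros_like(occ)
    free = ~tumor
    for axis in range(ndim):
        for step in (-1, +1):
            shifted = np.roll(free, step, axis=axis)
            edge = [slice(None)] * ndim
            edge[axis] = 0 if step == +1 else -1
            shifted[tuple(edge)] = False       # outside the lattice
            has_free_neighbor |= shifted
    rim_mask = occ & has_free_neighbor
    rim, interior = [], []
    for c in cells.cells:
        (rim if rim_mask[c.pos] else interior).append(
            int(np.asarray(c.genotype).sum()))
    rim_mean = float(np.mean(rim)) if rim else float("nan")
    interior_mean = float(np.mean(interior)) if interior else float("nan")
    return rim_mean, interior_mean


def segregation_region_means(grid, cells, C3, config) -> dict:
    """Block-mean segregation index by phenotype region.

    Blocks (homogenization edge) are classified by their majority living
    phenotype.  Returns the mean block segregation index over (i)
    cancer-majority blocks in the capillary-proximal half, (ii)
    normal-majority blocks in the distal half, and (iii) all
    precancer-majority blocks; regions without blocks give NaN.
    """
    from .lineage import block_mean_beta
    bb = block_mean_beta(grid, cells, C3, config)
    majority, total = block_phenotype_majority(grid, cells, config.block)
    n_last = bb.shape[-1]
    proximal = np.zeros(bb.shape, dtype=bool)
    proximal[..., n_last // 2:] = True          # capillary side

    def region_mean(mask):
        vals = bb[mask & np.isfinite(bb)]
        return float(vals.mean()) if vals.size else float("nan")

    return {
        "proximal_cancer": region_mean((majority == 2) & proximal),
        "distal_normal": region_mean((majority == 0) & ~proximal),
        "precancer": region_mean(majority == 1),
    }


def average_over_realizations(frames, n=None) -> pd.DataFrame:
    """Per-cycle arithmetic mean of summary trajectories across seeds.

    Runs are aligned to the shortest trajectory (with a warning) and no
    interpolation is performed.
    """
    frames = list(frames)[: n if n else None]
    if not frames:
        raise ValueError("no runs to average")
    lengths = {len(f) for f in frames}
    if len(lengths) > 1:
        warnings.warn("realizations have different cycle counts; "
                      "aligning to the shortest", stacklevel=2)
    m = min(lengths)
    stack = np.stack([f.iloc[:m].to_numpy(dtype=float) for f in frames])
    return pd.DataFrame(stack.mean(axis=0), columns=frames[0].columns)
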