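"""Mortality, enzyme turnover, division, dispersal and translocation.

Cells die by starvation (any quota below its minimum) or at a
guild-specific first-order random rate; dead biomass enters the
dead-microbe substrate pool at the cell's point with its actual (free)
stoichiometry.  Enzymes decay first-order into the dead-enzyme pool.
Cells above their division threshold split 50/50; bacterial offspring
land uniformly on one of the 8 wrap-around neighbors, fungal offspring
move +/-1 in y with total probability rho_y (producing hypha-like
columns) and otherwise stack on the parent point.  Fungal taxa
translocate nutrients: every cell of a taxon is reset to the taxon's
mean quota at the start of each day.
"""
from __future__ import annotations

import numpy as np

from .config import DementConfig, DEAD_MICROBE, DEAD_ENZYME
from .physiology import RunContext
from .world import WorldState, wrap_points

_BACT_OFFSETS = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                          (1, -1), (1, 0), (1, 1)])


def mortality(world: WorldState, ctx: RunContext,
              rng: np.random.Generator) -> np.ndarray:
    """Apply starvation and random death; dead quotas are transferred to
    the dead-microbe substrate pool.  Returns the (C, N, P) mass moved."""
    n = world.n_cells
    if n == 0:
        return np.zeros(3)
    q = world.cell_quota
    starving = (q < ctx.quota_min[None, :]).any(axis=1)
    u = rng.random(n)
    dead = starving | (u < ctx.turnover[world.cell_taxon])
    if not dead.any():
        return np.zeros(3)
    np.add.at(world.substrates[:, DEAD_MICROBE, :],
              world.cell_point[dead], q[dead])
    moved = q[dead].sum(axis=0)
    keep = ~dead
    world.cell_taxon = world.cell_taxon[keep]
    world.cell_point = world.cell_point[keep]
    world.cell_quota = q[keep]
    return moved


def enzyme_turnover(world: WorldState, config: DementConfig) -> float:
    """First-order enzyme decay into the dead-enzyme substrate pool
    (C plus its bound N at z_en per unit C).  Returns decayed enzyme C."""
    if config.tau_enzyme == 0.0:
        return 0.0
    loss = config.tau_enzyme * world.enzymes
    world.enzymes -= loss
    per_point = loss.sum(axis=1)
    world.substrates[:, DEAD_ENZYME, 0] += per_point
    world.substrates[:, DEAD_ENZYME, 1] += config.z_en * per_point
    return float(per_point.sum())


def divide_and_disperse(world: WorldState, ctx: RunContext,
                        rng: np.random.Generator) -> int:
    """Split cells at or above their division threshold 50/50 and place
    the offspring.  Returns the number of divisions."""
    cfg = ctx.config
    mask = world.cell_quota[:, 0] >= ctx.division_threshold[world.cell_taxon]
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 0
    world.cell_quota[idx] *= 0.5
    off_quota = world.cell_quota[idx].copy()
    off_taxon = world.cell_taxon[idx].copy()
    parents = world.cell_point[idx]
    fungal = ctx.is_fungal[off_taxon]

    dx = np.zeros(idx.size, dtype=int)
    dy = np.zeros(idx.size, dtype=int)
    nb = np.flatnonzero(~fungal)
    if nb.size:
        choice = rng.integers(0, 8, size=nb.size)
        dx[nb] = _BACT_OFFSETS[choice, 0]
        dy[nb] = _BACT_OFFSETS[choice, 1]
    nf = np.flatnonzero(fungal)
    if nf.size:
        u = rng.random(nf.size)
        move_y = u < cfg.rho_y
        up = u < 0.5 * cfg.rho_y
        dy[nf] = np.where(move_y, np.where(up, -1, 1), 0)
        if cfg.fungal_lateral_x:
            ux = rng.random(nf.size)
            dx[nf] = np.where(move_y, 0, np.where(ux < 0.5, -1, 1))

    ix, iy = np.divmod(parents, world.ny)
    off_point = wrap_points(ix + dx, iy + dy, world.nx, world.ny)

    world.cell_taxon = np.concatenate([world.cell_taxon, off_taxon])
    world.cell_point = np.concatenate([world.cell_point, off_point])
    world.cell_quota = np.concatenate([world.cell_quota, off_quota])
    return int(idx.size)


def translocate(world: WorldState, ctx: RunContext) -> None:
    """Fungal nutrient translocation: set every cell of each fungal taxon
    to the taxon's lattice-wide mean quota.  Element totals are conserved
    to machine precision."""
    if world.n_cells == 0:
        return
    tax = world.cell_taxon
    fungal_cells = ctx.is_fungal[tax]
    if not fungal_cells.any():
        return
    n_taxa = ctx.community.n_taxa
    counts = np.bincount(tax, minlength=n_taxa).astype(float)
    sums = np.zeros((n_taxa, 3))
    np.add.at(sums, tax, world.cell_quota)
    means = np.divide(sums, counts[:, None], out=np.zeros_like(sums),
                      where=counts[:, None] > 0)
    world.cell_quota[fungal_cells] = means[tax[fungal_cells]]
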