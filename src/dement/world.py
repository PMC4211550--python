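"""The spatial environment: lattice pools, external inputs and leaching.

The world is a 2-D lattice with wrap-around (toroidal) boundaries.  Each
point carries per-substrate and per-monomer C/N/P pools, per-enzyme
concentrations, and any number of resident microbial cells.  Points are
indexed ``p = ix * ny + iy``.  Pools do not diffuse between points; the
only spatial fluxes are cell dispersal and fungal nutrient translocation.

Cells are stored in struct-of-arrays form (taxon id, point index, C/N/P
quotas) for vectorized daily updates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DementConfig
from .community import Community, GUILD_FUNGAL


@dataclass
class WorldState:
    """Lattice pools plus the resident cell population at one instant."""

    nx: int
    ny: int
    substrates: np.ndarray   # (n_points, n_substrates, 3) C/N/P, mg per point
    monomers: np.ndarray     # (n_points, n_monomers, 3); the inorganic-N slot
                             # holds mass in the N column only, inorganic-P in
                             # the P column only
    enzymes: np.ndarray      # (n_points, n_enzymes) enzyme C; bound N is
                             # implicit at z_en * C
    cell_taxon: np.ndarray   # (n_cells,) int
    cell_point: np.ndarray   # (n_cells,) int
    cell_quota: np.ndarray   # (n_cells, 3) C/N/P mg per cell
    temperature: float
    day: int = 0

    @property
    def n_points(self) -> int:
        return self.nx * self.ny

    @property
    def n_cells(self) -> int:
        return len(self.cell_taxon)

    def copy(self) -> "WorldState":
        return WorldState(
            nx=self.nx, ny=self.ny,
            substrates=self.substrates.copy(),
            monomers=self.monomers.copy(),
            enzymes=self.enzymes.copy(),
            cell_taxon=self.cell_taxon.copy(),
            cell_point=self.cell_point.copy(),
            cell_quota=self.cell_quota.copy(),
            temperature=self.temperature,
            day=self.day,
        )

    def biomass_per_taxon(self, n_taxa: int) -> np.ndarray:
        """Total cell C per taxon, length ``n_taxa``."""
        return np.bincount(self.cell_taxon, weights=self.cell_quota[:, 0],
                           minlength=n_taxa)

    def totals(self, z_en: float) -> np.ndarray:
        """System-wide (C, N, P) including cells and enzyme-bound N."""
        tot = self.substrates.sum(axis=(0, 1)) + self.monomers.sum(axis=(0, 1))
        if self.n_cells:
            tot = tot + self.cell_quota.sum(axis=0)
        enz_c = float(self.enzymes.sum())
        tot = tot + np.array([enz_c, z_en * enz_c, 0.0])
        return tot


def wrap_points(ix, iy, nx: int, ny: int):
    """Point indices for (possibly out-of-range) lattice coordinates,
    applying wrap-around in both directions."""
    return (np.mod(ix, nx)) * ny + np.mod(iy, ny)


def neighbors8(point: int, nx: int, ny: int) -> np.ndarray:
    """The 8 wrap-around neighbors of a point (excluding itself)."""
    ix, iy = divmod(point, ny)
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0),
            (1, 1)]
    return np.array([wrap_points(ix + dx, iy + dy, nx, ny)
                     for dx, dy in offs])


def initial_cell_quota(guild_is_fungal: bool, config: DementConfig
                       ) -> np.ndarray:
    """Starting C/N/P quota of a newly seeded cell: C at half the division
    threshold, N and P at the guild's balanced stoichiometry."""
    if guild_is_fungal:
        c = 0.5 * config.c_max_fungi
        fc, fn, fp = (config.frac_c_fungi, config.frac_n_fungi,
                      config.frac_p_fungi)
    else:
        c = 0.5 * config.c_max_bacteria
        fc, fn, fp = (config.frac_c_bacteria, config.frac_n_bacteria,
                      config.frac_p_bacteria)
    mass = c / fc
    return np.array([c, mass * fn, mass * fp])


def initialize_world(seed, community: Community, config: DementConfig
                     ) -> WorldState:
    """Build the initial world state.

    Substrate pools are spread uniformly over the lattice at their initial
    concentrations; each substrate's monomer starts at ``f_ms`` times the
    substrate pool (same stoichiometry); inorganic N and P start empty.
    Cells are placed by independent per-point Poisson draws at the
    configured bacterial and fungal densities, with taxa drawn uniformly
    within each guild.  Fungal cells are 25x larger, so the lower fungal
    density yields equal initial biomass for the two guilds.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    npts = config.x * config.y
    n_sub = config.n_substrates

    substrates = np.zeros((npts, n_sub, 3))
    for s, spec in enumerate(config.substrates):
        substrates[:, s, :] = (spec.init_c, spec.init_n, spec.init_p)
    monomers = np.zeros((npts, config.n_monomers, 3))
    monomers[:, :n_sub, :] = config.f_ms * substrates

    enzymes = np.zeros((npts, config.n_enzymes))

    bact_ids = np.array([t.taxon_id for t in community.taxa
                         if not t.is_fungal])
    fung_ids = np.array([t.taxon_id for t in community.taxa if t.is_fungal])

    taxa_parts, point_parts, quota_parts = [], [], []
    for ids, density, fungal in ((bact_ids, config.density_bacteria, False),
                                 (fung_ids, config.density_fungi, True)):
        if density <= 0:
            continue
        if len(ids) == 0:
            raise ValueError(
                "non-zero initial density for a guild with no taxa")
        counts = rng.poisson(density, size=npts)
        total = int(counts.sum())
        if total == 0:
            continue
        point_parts.append(np.repeat(np.arange(npts), counts))
        taxa_parts.append(rng.choice(ids, size=total))
        quota_parts.append(np.tile(initial_cell_quota(fungal, config),
                                   (total, 1)))

    if taxa_parts:
        cell_taxon = np.concatenate(taxa_parts)
        cell_point = np.concatenate(point_parts)
        cell_quota = np.concatenate(quota_parts)
    else:
        cell_taxon = np.zeros(0, dtype=int)
        cell_point = np.zeros(0, dtype=int)
        cell_quota = np.zeros((0, 3))

    return WorldState(
        nx=config.x, ny=config.y,
        substrates=substrates, monomers=monomers, enzymes=enzymes,
        cell_taxon=cell_taxon.astype(int), cell_point=cell_point.astype(int),
        cell_quota=cell_quota,
        temperature=config.temperature,
    )


def substrate_input_array(config: DementConfig) -> np.ndarray:
    """(n_substrates, 3) daily per-point substrate inputs, with N and P
    following each compound's fixed stoichiometry."""
    arr = np.zeros((config.n_substrates, 3))
    for s, spec in enumerate(config.substrates):
        rn, rp = spec.stoich_ratios()
        arr[s] = (spec.input_substrate, spec.input_substrate * rn,
                  spec.input_substrate * rp)
    return arr


def monomer_input_array(config: DementConfig) -> np.ndarray:
    """(n_monomers, 3) daily per-point monomer inputs (inorganic slots
    receive none)."""
    arr = np.zeros((config.n_monomers, 3))
    for s, spec in enumerate(config.substrates):
        rn, rp = spec.stoich_ratios()
        arr[s] = (spec.input_monomer, spec.input_monomer * rn,
                  spec.input_monomer * rp)
    return arr


def apply_inputs(world: WorldState, config: DementConfig) -> np.ndarray:
    """Add daily external substrate and monomer inputs, uniformly across
    the lattice.  Returns total added (C, N, P) for the mass ledger."""
    sub_in = substrate_input_array(config)
    mon_in = monomer_input_array(config)
    world.substrates += sub_in[None, :, :]
    world.monomers += mon_in[None, :, :]
    return (sub_in.sum(axis=0) + mon_in.sum(axis=0)) * world.n_points


def apply_leaching(world: WorldState, config: DementConfig) -> np.ndarray:
    """Leach dissolved pools (monomers and inorganic N/P) at rate ``L``
    per day; polymers, enzymes and cells do not leach.  Returns leached
    (C, N, P) totals."""
    leached = config.leaching * world.monomers.sum(axis=(0, 1))
    world.monomers *= (1.0 - config.leaching)
    return leached


def world_frame(world: WorldState, config: DementConfig) -> pd.DataFrame:
    """Tidy per-point snapshot (point, pool, element, value) for
    debugging; not used on the hot path."""
    rows = []
    names = [s.name for s in config.substrates]
    mon_names = [f"{n}_monomer" for n in names] + ["InorganicN", "InorganicP"]
    for p in range(world.n_points):
        for s, name in enumerate(names):
            for e, el in enumerate(("C", "N", "P")):
                rows.append((p, name, el, world.substrates[p, s, e]))
        for m, name in enumerate(mon_names):
            for e, el in enumerate(("C", "N", "P")):
                rows.append((p, name, el, world.monomers[p, m, e]))
    return pd.DataFrame(rows, columns=["point", "pool", "element", "value"])
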