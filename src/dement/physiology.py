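"""Per-cell daily metabolism.

Each day, extracellular enzymes degrade substrates into monomers; cells
take up monomers they have transporters for; assimilated carbon is split
by realized CUE into growth and growth respiration; enzyme production is
paid from cell quotas; and partial stoichiometric homeostasis respires
excess C (overflow) and mineralizes excess N/P back to the local
inorganic pools.

All operations are vectorized over cells and lattice points.  The
:class:`RunContext` caches community matrices and temperature-adjusted
kinetic constants, which are fixed for a constant-temperature run.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DementConfig, CELLULOSE, HEMICELLULOSE, LIGNIN
from .community import Community
from .kinetics import arrhenius_factor, lignocellulose_multiplier
from .world import WorldState


def realized_cue(eps_int, t, m_t=-0.016, t_ref=20.0):
    """Realized CUE at temperature ``t``: eps_int + m_T*(T - T_ref),
    clamped to [0, 1] (negative growth is expressed through starvation
    mortality rather than negative CUE)."""
    eps = np.asarray(eps_int, dtype=float) + m_t * (t - t_ref)
    out = np.clip(eps, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class RunContext:
    """Precomputed community matrices and temperature-adjusted kinetics."""

    config: DementConfig
    community: Community
    temperature: float
    # enzymes
    enz_vmax_t: np.ndarray      # (n_enzymes, n_substrates), 0 off-target
    enz_km_t: np.ndarray        # (n_enzymes, n_substrates)
    # uptake
    upt_vmax_t: float
    upt_km_t: float
    # taxa
    taxon_enz: np.ndarray       # (n_taxa, n_enzymes) 0/1 possession
    n_enz_genes: np.ndarray     # (n_taxa,)
    n_upt_genes: np.ndarray     # (n_taxa,)
    reach_alloc: np.ndarray     # (n_taxa, n_monomers): 1/n_reach on
                                # reachable monomers, 0 elsewhere
    eps_int: np.ndarray         # (n_taxa,)
    eps_realized: np.ndarray    # (n_taxa,) clamped realized CUE at T
    is_fungal: np.ndarray       # (n_taxa,) bool
    division_threshold: np.ndarray  # (n_taxa,)
    turnover: np.ndarray        # (n_taxa,)
    frac_upper: np.ndarray      # (n_taxa, 3) element-fraction upper bounds
    quota_min: np.ndarray       # (3,) starvation thresholds


def build_context(community: Community, config: DementConfig,
                  temperature: float | None = None) -> RunContext:
    t = config.temperature if temperature is None else temperature
    n_e, n_s = config.n_enzymes, config.n_substrates
    n_taxa = community.n_taxa

    enz_vmax_t = np.zeros((n_e, n_s))
    enz_km_t = np.ones((n_e, n_s))  # harmless placeholder off-target
    fk = arrhenius_factor(t, config.t_ref, config.ea_km)
    for e in community.enzymes:
        for s, ea in zip(e.target_substrates, e.ea_vmax):
            enz_vmax_t[e.enzyme_id, s] = e.vmax * arrhenius_factor(
                t, config.t_ref, ea)
            enz_km_t[e.enzyme_id, s] = e.km * fk

    upt_vmax_t = config.vmax_uptake * arrhenius_factor(
        t, config.t_ref, config.ea_uptake)
    km_u = config.km_upt_slope * config.vmax_uptake + config.km_upt_intercept
    upt_km_t = km_u * fk

    taxon_enz = np.zeros((n_taxa, n_e))
    reach = np.zeros((n_taxa, config.n_monomers), dtype=bool)
    for tax in community.taxa:
        taxon_enz[tax.taxon_id, list(tax.enzyme_genes)] = 1.0
        for tr in tax.uptake_genes:
            reach[tax.taxon_id,
                  list(community.transporters[tr].target_monomers)] = True
    n_reach = reach.sum(axis=1)
    reach_alloc = np.divide(reach.astype(float), n_reach[:, None],
                            out=np.zeros_like(reach, dtype=float),
                            where=n_reach[:, None] > 0)

    eps_int = np.array([tax.eps_int for tax in community.taxa])
    is_fungal = np.array([tax.is_fungal for tax in community.taxa])
    frac_upper = np.empty((n_taxa, 3))
    frac_upper[~is_fungal] = (config.frac_c_bacteria + config.tol_c,
                              config.frac_n_bacteria + config.tol_n,
                              config.frac_p_bacteria + config.tol_p)
    frac_upper[is_fungal] = (config.frac_c_fungi + config.tol_c,
                             config.frac_n_fungi + config.tol_n,
                             config.frac_p_fungi + config.tol_p)

    return RunContext(
        config=config, community=community, temperature=t,
        enz_vmax_t=enz_vmax_t, enz_km_t=enz_km_t,
        upt_vmax_t=float(upt_vmax_t), upt_km_t=float(upt_km_t),
        taxon_enz=taxon_enz,
        n_enz_genes=np.array([len(tax.enzyme_genes)
                              for tax in community.taxa]),
        n_upt_genes=np.array([len(tax.uptake_genes)
                              for tax in community.taxa]),
        reach_alloc=reach_alloc,
        eps_int=eps_int,
        eps_realized=np.asarray(realized_cue(eps_int, t, config.m_t,
                                             config.t_ref)),
        is_fungal=is_fungal,
        division_threshold=np.array([tax.division_threshold_c
                                     for tax in community.taxa]),
        turnover=np.array([tax.turnover_rate for tax in community.taxa]),
        frac_upper=frac_upper,
        quota_min=np.array([config.c_min, config.n_min, config.p_min]),
    )


def degrade_substrates(world: WorldState, ctx: RunContext) -> np.ndarray:
    """Enzymatic decay of substrates into their monomers.

    Per point and substrate the decay flux sums Michaelis-Menten terms
    over the local enzyme pools, with capacity proportional to enzyme
    concentration (Vmax is per mg enzyme).  Cellulose decay is scaled by
    the local lignocellulose multiplier.  Decay is capped at the standing
    pool and moves C, N and P in the pool's current proportions.

    Returns per-substrate decayed C totals (for diagnostics).
    """
    cfg = ctx.config
    S = world.substrates
    sc = S[:, :, 0]
    E = world.enzymes
    npts, n_sub = sc.shape

    decay = np.zeros_like(sc)
    for s in range(n_sub):
        v = ctx.enz_vmax_t[:, s]
        if not v.any():
            continue
        scs = sc[:, s]
        denom = ctx.enz_km_t[:, s][None, :] + scs[:, None]  # (npts, n_e)
        ratio = np.divide(v[None, :], denom, out=np.zeros_like(denom),
                          where=denom > 0)
        decay[:, s] = (E * ratio).sum(axis=1) * scs

    mult = lignocellulose_multiplier(sc[:, LIGNIN], sc[:, CELLULOSE],
                                     cfg.lci_slope)
    decay[:, CELLULOSE] *= mult
    if cfg.lci_on_hemicellulose:
        decay[:, HEMICELLULOSE] *= mult

    np.minimum(decay, sc, out=decay)
    frac = np.divide(decay, sc, out=np.zeros_like(decay), where=sc > 0)
    moved = S * frac[:, :, None]
    S -= moved
    world.monomers[:, :n_sub, :] += moved
    return decay.sum(axis=0)


def monomer_scalar_pools(world: WorldState, ctx: RunContext) -> np.ndarray:
    """(n_points, n_monomers) scalar pool sizes driving uptake kinetics:
    C mass for organic monomers, N mass for the inorganic-N slot, P mass
    for the inorganic-P slot."""
    cfg = ctx.config
    scalar = world.monomers[:, :, 0].copy()
    scalar[:, cfg.inorganic_n_index] = world.monomers[:,
                                                      cfg.inorganic_n_index, 1]
    scalar[:, cfg.inorganic_p_index] = world.monomers[:,
                                                      cfg.inorganic_p_index, 2]
    return scalar


def take_up(world: WorldState, ctx: RunContext
            ) -> tuple[np.ndarray, np.ndarray]:
    """Monomer uptake by all cells.

    Per cell and reachable monomer the demand is a Michaelis-Menten flux
    with capacity ``V_U(T) * cellC`` split equally across the cell's
    reachable monomers.  Where the summed demand at a point exceeds the
    pool, allocations are scaled down proportionally.  Elements are
    assimilated in the pool's current proportions and removed from the
    lattice.

    Returns ``(assimilated, gross_uptake_c)``: per-cell (C, N, P) gains
    and the per-cell scalar gross uptake (basis for inducible enzyme
    production).  Quotas are *not* yet updated.
    """
    n_cells = world.n_cells
    cfg = ctx.config
    if n_cells == 0:
        return np.zeros((0, 3)), np.zeros(0)

    pts = world.cell_point
    tax = world.cell_taxon
    scalar = monomer_scalar_pools(world, ctx)          # (npts, n_mon)
    sat = scalar / (ctx.upt_km_t + scalar + 1e-300)
    demand = (ctx.upt_vmax_t * world.cell_quota[:, 0][:, None]
              * ctx.reach_alloc[tax] * sat[pts])       # (n_cells, n_mon)

    total = np.zeros_like(scalar)
    np.add.at(total, pts, demand)
    scale = np.ones_like(scalar)
    over = total > scalar
    scale[over] = scalar[over] / total[over]
    uptake = demand * scale[pts]
    removed = np.minimum(total * scale, scalar)        # == min(total, pool)

    ratio = np.divide(world.monomers, scalar[:, :, None],
                      out=np.zeros_like(world.monomers),
                      where=scalar[:, :, None] > 0)
    assim = np.einsum("cm,cme->ce", uptake, ratio[pts])
    gross = uptake.sum(axis=1)

    remfrac = np.divide(removed, scalar, out=np.zeros_like(scalar),
                        where=scalar > 0)
    world.monomers *= (1.0 - remfrac[:, :, None])
    return assim, gross


def grow(world: WorldState, ctx: RunContext, assim: np.ndarray) -> float:
    """Partition assimilated C by realized CUE: the eps share is retained
    in the C quota and the (1 - eps) share is respired (growth
    respiration); all assimilated N and P enter the quotas.  Returns total
    growth respiration C."""
    if world.n_cells == 0:
        return 0.0
    eps = ctx.eps_realized[world.cell_taxon]
    resp = float(((1.0 - eps) * assim[:, 0]).sum())
    world.cell_quota[:, 0] += eps * assim[:, 0]
    world.cell_quota[:, 1] += assim[:, 1]
    world.cell_quota[:, 2] += assim[:, 2]
    return resp


def produce_enzymes(world: WorldState, ctx: RunContext,
                    gross_uptake_c: np.ndarray) -> tuple[float, float]:
    """Extracellular enzyme production.

    Per possessed enzyme: a constitutive C cost ``beta_EC * cellC`` per
    day plus an inducible C cost ``Z_EC * gross uptake C``; the N cost is
    ``z_en`` times the C cost.  Costs are paid from the cell's quotas and
    pro-rated if either quota would fall below its starvation minimum.
    Produced mass is added to the cell's point, split equally over the
    taxon's enzymes.

    Returns total (C, N) transferred from cells to enzyme pools.
    """
    cfg = ctx.config
    if world.n_cells == 0:
        return 0.0, 0.0
    tax = world.cell_taxon
    n_genes = ctx.n_enz_genes[tax].astype(float)
    cost_c = n_genes * (cfg.beta_ec * world.cell_quota[:, 0]
                        + cfg.z_ec * gross_uptake_c)
    cost_n = cfg.z_en * cost_c

    avail_c = np.maximum(world.cell_quota[:, 0] - ctx.quota_min[0], 0.0)
    avail_n = np.maximum(world.cell_quota[:, 1] - ctx.quota_min[1], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.minimum(
            1.0,
            np.minimum(np.where(cost_c > 0, avail_c / cost_c, 1.0),
                       np.where(cost_n > 0, avail_n / cost_n, 1.0)))
    cost_c *= scale
    cost_n = cfg.z_en * cost_c

    world.cell_quota[:, 0] -= cost_c
    world.cell_quota[:, 1] -= cost_n

    per_enzyme = np.divide(cost_c, n_genes, out=np.zeros_like(cost_c),
                           where=n_genes > 0)
    alloc = np.zeros((world.n_points, ctx.community.n_taxa))
    np.add.at(alloc, (world.cell_point, tax), per_enzyme)
    world.enzymes += alloc @ ctx.taxon_enz
    return float(cost_c.sum()), float(cost_n.sum())


def homeostasis(world: WorldState, ctx: RunContext,
                max_iter: int = 50) -> tuple[float, float, float]:
    """Partial stoichiometric homeostasis.

    If a cell's element mass fraction exceeds its guild's upper tolerance
    band, the excess is removed exactly to the band boundary: excess C is
    respired (overflow respiration, ledgered separately from growth
    respiration) and excess N/P is mineralized to the local inorganic
    pools.  Because the upper bounds sum to more than 1, at most one
    element can be out of band at a time; removal is iterated since
    shrinking the cell can push another element over its bound.

    Returns (overflow C, mineralized N, mineralized P) totals.
    """
    cfg = ctx.config
    if world.n_cells == 0:
        return 0.0, 0.0, 0.0
    q = world.cell_quota
    pts = world.cell_point
    totals = np.zeros(3)
    idx = np.arange(world.n_cells)          # cells possibly out of band
    for _ in range(max_iter):
        qs = q[idx]
        upper = ctx.frac_upper[world.cell_taxon[idx]]
        mass = qs.sum(axis=1)
        excess = (qs - upper * mass[:, None]) / (1.0 - upper)
        np.maximum(excess, 0.0, out=excess)
        active = excess.max(axis=1) > 1e-15 * np.maximum(mass, 1.0)
        if not active.any():
            break
        idx = idx[active]
        excess = excess[active]
        q[idx] -= excess
        totals += excess.sum(axis=0)
        np.add.at(world.monomers[:, cfg.inorganic_n_index, 1], pts[idx],
                  excess[:, 1])
        np.add.at(world.monomers[:, cfg.inorganic_p_index, 2], pts[idx],
                  excess[:, 2])
    return float(totals[0]), float(totals[1]), float(totals[2])
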