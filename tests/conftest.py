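"""Shared fixtures and tiny hand-built worlds/communities for unit tests."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from dement.config import DementConfig, STARCH
from dement.community import (Community, EnzymeDef, TransporterDef,
                              TaxonTraits, intrinsic_cue)
from dement.world import WorldState

settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cfg() -> DementConfig:
    return DementConfig()


@pytest.fixture
def tiny_cfg() -> DementConfig:
    """A 5x5 lattice with the standard chemistry."""
    return DementConfig(x=5, y=5)


def blank_world(cfg: DementConfig, temperature: float = 20.0) -> WorldState:
    """An empty world (no pools, no cells) on the configured lattice."""
    npts = cfg.x * cfg.y
    return WorldState(
        nx=cfg.x, ny=cfg.y,
        substrates=np.zeros((npts, cfg.n_substrates, 3)),
        monomers=np.zeros((npts, cfg.n_monomers, 3)),
        enzymes=np.zeros((npts, cfg.n_enzymes)),
        cell_taxon=np.zeros(0, dtype=int),
        cell_point=np.zeros(0, dtype=int),
        cell_quota=np.zeros((0, 3)),
        temperature=temperature,
    )


def add_cells(world: WorldState, taxon, point, quota) -> None:
    """Append cells given parallel sequences of taxon ids, points and
    (C, N, P) quotas."""
    world.cell_taxon = np.concatenate([world.cell_taxon,
                                       np.asarray(taxon, dtype=int)])
    world.cell_point = np.concatenate([world.cell_point,
                                       np.asarray(point, dtype=int)])
    world.cell_quota = np.concatenate([world.cell_quota,
                                       np.asarray(quota, dtype=float)
                                       .reshape(-1, 3)])


def single_taxon_community(cfg: DementConfig, substrate: int = STARCH,
                           guild: str = "bacterial",
                           n_enzyme_copies: int = 1,
                           division_threshold: float | None = None,
                           turnover: float | None = None) -> Community:
    """One taxon possessing ``n_enzyme_copies`` identical enzymes that
    all degrade one substrate, plus one transporter for its monomer."""
    spec = cfg.substrates[substrate]
    enzymes = tuple(
        EnzymeDef(i, (substrate,), cfg.vmax_enzyme,
                  cfg.km_enz_slope * cfg.vmax_enzyme + cfg.km_enz_intercept,
                  (spec.ea_decay,), cfg.ea_km)
        for i in range(n_enzyme_copies))
    km_u = cfg.km_upt_slope * cfg.vmax_uptake + cfg.km_upt_intercept
    transporters = (TransporterDef(0, (substrate,), cfg.vmax_uptake, km_u,
                                   cfg.ea_uptake, cfg.ea_km),)
    f_e = n_enzyme_copies / cfg.e_max
    f_u = 1 / cfg.n_transporters
    fungal = guild == "fungal"
    taxon = TaxonTraits(
        taxon_id=0, guild=guild,
        enzyme_genes=tuple(range(n_enzyme_copies)), uptake_genes=(0,),
        f_e=f_e, f_u=f_u, eps_int=intrinsic_cue(f_e, f_u, cfg),
        division_threshold_c=(division_threshold if division_threshold
                              is not None else
                              (cfg.c_max_fungi if fungal
                               else cfg.c_max_bacteria)),
        turnover_rate=(turnover if turnover is not None else
                       (cfg.tau_fungi if fungal else cfg.tau_bacteria)),
    )
    return Community(enzymes=enzymes, transporters=transporters,
                     taxa=(taxon,))
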