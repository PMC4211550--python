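"""Daily scheduler, paired-warming experiments and summary statistics.

One model day applies, in order: fungal translocation, substrate
degradation, monomer uptake, CUE-partitioned growth, enzyme production,
stoichiometric homeostasis, mortality, enzyme turnover, division and
dispersal, leaching, and external inputs.  Every step's fluxes are
collected in a :class:`FluxLedger` so that daily element conservation can
be audited: total C changes only by inputs minus respiration minus
leaching; total N and P change only by inputs minus leaching.

The paired-warming driver runs two simulations per replicate pair — one
at each temperature — from identical community, placement and dynamics
random streams, so the runs differ only through temperature-dependent
code paths.  Pair deltas (warm minus cool) of biomass-weighted intrinsic
CUE, mean biomass C and mean substrate C are analyzed with one-sample
t-tests against zero and with ordinary least-squares regressions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DementConfig
from .community import Community, generate_community
from .physiology import (RunContext, build_context, degrade_substrates,
                         take_up, grow, produce_enzymes, homeostasis)
from .demography import (mortality, enzyme_turnover, divide_and_disperse,
                         translocate)
from .world import WorldState, initialize_world, apply_inputs, apply_leaching


@dataclass
class FluxLedger:
    """Per-day system-level flux totals (all mg, all non-negative)."""

    input_c: float = 0.0
    input_n: float = 0.0
    input_p: float = 0.0
    leached_c: float = 0.0
    leached_n: float = 0.0
    leached_p: float = 0.0
    gross_uptake_c: float = 0.0
    growth_resp_c: float = 0.0
    overflow_resp_c: float = 0.0
    mineralized_n: float = 0.0
    mineralized_p: float = 0.0
    enzyme_prod_c: float = 0.0
    enzyme_prod_n: float = 0.0
    enzyme_decay_c: float = 0.0
    death_c: float = 0.0
    death_n: float = 0.0
    death_p: float = 0.0
    decay_c: float = 0.0
    divisions: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def conservation_errors(before: np.ndarray, after: np.ndarray,
                        ledger: FluxLedger) -> np.ndarray:
    """Relative daily mass-balance errors for (C, N, P).

    Expected changes: dC = inputs - growth resp - overflow resp - leached;
    dN = inputs - leached; dP = inputs - leached.  All other fluxes are
    internal transfers.
    """
    expected = np.array([
        ledger.input_c - ledger.growth_resp_c - ledger.overflow_resp_c
        - ledger.leached_c,
        ledger.input_n - ledger.leached_n,
        ledger.input_p - ledger.leached_p,
    ])
    scale = np.maximum(np.abs(before), 1.0)
    return np.abs((after - before) - expected) / scale


def step_day(world: WorldState, ctx: RunContext,
             rng: np.random.Generator) -> FluxLedger:
    """Advance the world by one day and return the day's flux ledger."""
    cfg = ctx.config
    led = FluxLedger()

    translocate(world, ctx)
    led.decay_c = float(degrade_substrates(world, ctx).sum())
    assim, gross = take_up(world, ctx)
    led.gross_uptake_c = float(gross.sum())
    led.growth_resp_c = grow(world, ctx, assim)
    led.enzyme_prod_c, led.enzyme_prod_n = produce_enzymes(world, ctx, gross)
    led.overflow_resp_c, led.mineralized_n, led.mineralized_p = \
        homeostasis(world, ctx)
    dead = mortality(world, ctx, rng)
    led.death_c, led.death_n, led.death_p = map(float, dead)
    led.enzyme_decay_c = enzyme_turnover(world, cfg)
    led.divisions = divide_and_disperse(world, ctx, rng)
    leached = apply_leaching(world, cfg)
    led.leached_c, led.leached_n, led.leached_p = map(float, leached)
    added = apply_inputs(world, cfg)
    led.input_c, led.input_n, led.input_p = map(float, added)

    world.day += 1
    if not np.isfinite(world.cell_quota).all():
        raise FloatingPointError(f"non-finite cell quota on day {world.day}")
    return led


@dataclass
class RunSummary:
    """Daily time series and scalar summaries of one simulation run."""

    scenario: str
    temperature: float
    seed: int | None
    days: int
    # per-day series, length days + 1 (day 0 = initial state)
    day: np.ndarray
    substrate_c: np.ndarray          # lattice-total substrate C
    monomer_c: np.ndarray
    enzyme_c: np.ndarray
    biomass_c: np.ndarray            # lattice-total cell C
    n_cells: np.ndarray
    community_eps_int: np.ndarray    # per-day biomass-weighted eps_int
    taxon_biomass: np.ndarray        # (days+1, n_taxa)
    substrate_pools: np.ndarray      # (days+1, n_substrates) C
    # taxon metadata
    taxon_eps_int: np.ndarray
    taxon_n_enzymes: np.ndarray
    taxon_n_uptake: np.ndarray
    max_conservation_error: float = float("nan")

    # -- scalar summaries --------------------------------------------------
    @property
    def cue_biomass_weighted(self) -> float:
        """Biomass-weighted mean intrinsic CUE across the whole run."""
        w = self.taxon_biomass.sum()
        if w == 0:
            return float("nan")
        return float((self.taxon_biomass @ self.taxon_eps_int).sum() / w)

    @property
    def mean_biomass_c(self) -> float:
        return float(self.biomass_c.mean())

    @property
    def mean_substrate_c(self) -> float:
        return float(self.substrate_c.mean())

    @property
    def mean_enzyme_genes(self) -> float:
        """Biomass-weighted mean number of enzyme genes over the run."""
        w = self.taxon_biomass.sum()
        if w == 0:
            return float("nan")
        return float((self.taxon_biomass @ self.taxon_n_enzymes).sum() / w)

    @property
    def mean_uptake_genes(self) -> float:
        w = self.taxon_biomass.sum()
        if w == 0:
            return float("nan")
        return float((self.taxon_biomass @ self.taxon_n_uptake).sum() / w)

    def summary_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "temperature": self.temperature,
            "seed": self.seed,
            "days": self.days,
            "cue_biomass_weighted": self.cue_biomass_weighted,
            "mean_biomass_c": self.mean_biomass_c,
            "mean_substrate_c": self.mean_substrate_c,
            "mean_enzyme_genes": self.mean_enzyme_genes,
            "mean_uptake_genes": self.mean_uptake_genes,
            "final_biomass_c": float(self.biomass_c[-1]),
            "final_substrate_c": float(self.substrate_c[-1]),
            "final_n_cells": int(self.n_cells[-1]),
        }

    def timeseries_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.day,
            "substrate_c": self.substrate_c,
            "monomer_c": self.monomer_c,
            "enzyme_c": self.enzyme_c,
            "biomass_c": self.biomass_c,
            "n_cells": self.n_cells,
            "community_eps_int": self.community_eps_int,
        })

    def taxon_frame(self, substrate_names=None) -> pd.DataFrame:
        """Per-day per-taxon biomass in long form, with enzyme-count
        metadata (one line per taxon per day)."""
        n_taxa = self.taxon_biomass.shape[1]
        days = np.repeat(self.day, n_taxa)
        tax = np.tile(np.arange(n_taxa), len(self.day))
        return pd.DataFrame({
            "day": days,
            "taxon_id": tax,
            "biomass_c": self.taxon_biomass.ravel(),
            "n_enzyme_genes": np.tile(self.taxon_n_enzymes, len(self.day)),
            "n_uptake_genes": np.tile(self.taxon_n_uptake, len(self.day)),
            "eps_int": np.tile(self.taxon_eps_int, len(self.day)),
        })

    def substrate_frame(self, substrate_names) -> pd.DataFrame:
        df = pd.DataFrame(self.substrate_pools,
                          columns=list(substrate_names))
        df.insert(0, "day", self.day)
        return df

    def save(self, outdir: str | Path, substrate_names=None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2, sort_keys=True))
        self.timeseries_frame().to_csv(outdir / "timeseries.csv", index=False)
        self.taxon_frame().to_csv(outdir / "taxon_biomass.csv", index=False)
        if substrate_names is not None:
            self.substrate_frame(substrate_names).to_csv(
                outdir / "substrate_pools.csv", index=False)


def _record(world: WorldState, ctx: RunContext, i: int, rec: dict) -> None:
    n_taxa = ctx.community.n_taxa
    btax = world.biomass_per_taxon(n_taxa)
    b = btax.sum()
    rec["substrate_c"][i] = world.substrates[:, :, 0].sum()
    rec["monomer_c"][i] = world.monomers[:, :, 0].sum()
    rec["enzyme_c"][i] = world.enzymes.sum()
    rec["biomass_c"][i] = b
    rec["n_cells"][i] = world.n_cells
    rec["taxon_biomass"][i] = btax
    rec["substrate_pools"][i] = world.substrates[:, :, 0].sum(axis=0)
    rec["community_eps_int"][i] = (btax @ ctx.eps_int / b) if b > 0 \
        else np.nan


def _run(world: WorldState, ctx: RunContext, rng: np.random.Generator,
         days: int, scenario: str, seed: int | None,
         audit: bool = False, progress=None) -> RunSummary:
    n_taxa = ctx.community.n_taxa
    cfg = ctx.config
    rec = {
        "substrate_c": np.zeros(days + 1),
        "monomer_c": np.zeros(days + 1),
        "enzyme_c": np.zeros(days + 1),
        "biomass_c": np.zeros(days + 1),
        "n_cells": np.zeros(days + 1, dtype=int),
        "community_eps_int": np.zeros(days + 1),
        "taxon_biomass": np.zeros((days + 1, n_taxa)),
        "substrate_pools": np.zeros((days + 1, cfg.n_substrates)),
    }
    _record(world, ctx, 0, rec)
    max_err = 0.0
    for d in range(1, days + 1):
        if audit:
            before = world.totals(cfg.z_en)
        ledger = step_day(world, ctx, rng)
        if audit:
            err = conservation_errors(before, world.totals(cfg.z_en), ledger)
            max_err = max(max_err, float(err.max()))
        _record(world, ctx, d, rec)
        if progress is not None and d % progress == 0:
            print(f"day {d}/{days}: biomass C {rec['biomass_c'][d]:.2f}, "
                  f"substrate C {rec['substrate_c'][d]:.1f}, "
                  f"cells {rec['n_cells'][d]}")
    return RunSummary(
        scenario=scenario, temperature=world.temperature, seed=seed,
        days=days, day=np.arange(days + 1),
        taxon_eps_int=ctx.eps_int.copy(),
        taxon_n_enzymes=ctx.n_enz_genes.copy(),
        taxon_n_uptake=ctx.n_upt_genes.copy(),
        max_conservation_error=max_err if audit else float("nan"),
        **rec,
    )


def run_simulation(config: DementConfig, seed: int, *,
                   days: int | None = None,
                   temperature: float | None = None,
                   scenario: str | None = None,
                   community: Community | None = None,
                   world: WorldState | None = None,
                   audit: bool = False, progress=None) -> RunSummary:
    """Run one simulation.

    The seed feeds three independent named streams (community generation,
    cell placement, daily dynamics), so a pair of runs sharing a seed and
    differing only in ``temperature`` starts from identical communities
    and identical cell placement.
    """
    if scenario is not None:
        config = config.with_scenario(scenario)
    days = config.days if days is None else days
    t = config.temperature if temperature is None else temperature

    ss = np.random.SeedSequence(seed)
    s_comm, s_place, s_dyn = ss.spawn(3)
    if community is None:
        community = generate_community(np.random.default_rng(s_comm), config)
    if world is None:
        world = initialize_world(np.random.default_rng(s_place), community,
                                 config)
    world.temperature = t
    ctx = build_context(community, config, t)
    rng = np.random.default_rng(s_dyn)
    return _run(world, ctx, rng, days, scenario or "custom", seed,
                audit=audit, progress=progress)


# ---------------------------------------------------------------------------
# paired experiment and statistics

def one_sample_t(x, popmean: float = 0.0) -> dict:
    """One-sample t-test of ``x`` against ``popmean`` from closed forms:
    t = (mean - popmean) / (sd / sqrt(n)).  Degenerate (zero-variance or
    n < 2) samples yield NaN statistics and ``degenerate=True``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = float(x.mean()) if n else float("nan")
    if n < 2 or np.allclose(x, x[0]):
        return {"mean": mean, "t": float("nan"), "p": float("nan"),
                "df": n - 1, "n": n, "degenerate": True}
    sd = float(x.std(ddof=1))
    t = (mean - popmean) / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return {"mean": mean, "t": float(t), "p": p, "df": n - 1, "n": n,
            "degenerate": False}


def simple_ols(x, y) -> dict:
    """Ordinary least squares y = a + b*x from closed forms, with R^2 and
    the two-sided p-value of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.allclose(x, x[0]):
        return {"slope": float("nan"), "intercept": float("nan"),
                "r_squared": float("nan"), "p": float("nan"), "n": n}
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    sse = (resid ** 2).sum()
    sst = ((y - ym) ** 2).sum()
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    se = np.sqrt(sse / (n - 2) / sxx) if sse > 0 else 0.0
    if se == 0:
        t = float("inf") if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return {"slope": float(slope), "intercept": float(intercept),
            "r_squared": float(r2), "p": p, "n": n}


@dataclass
class PairedResult:
    """Outcome of a paired-warming experiment for one tradeoff scenario."""

    scenario: str
    t_low: float
    t_high: float
    n_pairs: int
    pairs: pd.DataFrame       # one row per pair with per-temp scalars and
                              # deltas (high minus low temperature)
    t_tests: dict             # variable -> one_sample_t result on deltas
    regressions: dict         # response -> simple_ols of delta vs delta_eps

    @property
    def mean_delta_eps(self) -> float:
        return float(self.pairs["delta_eps_int"].mean())

    def stats_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "t_low": self.t_low,
            "t_high": self.t_high,
            "n_pairs": self.n_pairs,
            "mean_delta_eps_int": self.mean_delta_eps,
            "t_tests": self.t_tests,
            "regressions": self.regressions,
        }

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(outdir / "pairs.csv", index=False)
        (outdir / "stats.json").write_text(
            json.dumps(self.stats_dict(), indent=2, sort_keys=True))


def analyze_pairs(pairs: pd.DataFrame, scenario: str, t_low: float,
                  t_high: float) -> PairedResult:
    """Statistics on a pair table that already has delta_* columns."""
    t_tests = {v: one_sample_t(pairs[f"delta_{v}"])
               for v in ("eps_int", "biomass_c", "substrate_c")}
    regressions = {
        "delta_biomass_c": simple_ols(pairs["delta_eps_int"],
                                      pairs["delta_biomass_c"]),
        "delta_substrate_c": simple_ols(pairs["delta_eps_int"],
                                        pairs["delta_substrate_c"]),
    }
    return PairedResult(scenario=scenario, t_low=t_low, t_high=t_high,
                        n_pairs=len(pairs), pairs=pairs, t_tests=t_tests,
                        regressions=regressions)


def run_paired_experiment(config: DementConfig, seed: int, *,
                          n_pairs: int = 20, t_low: float = 15.0,
                          t_high: float = 20.0, scenario: str = "high",
                          days: int | None = None, audit: bool = False,
                          progress: bool = False) -> PairedResult:
    """Paired warming experiment.

    Each replicate pair draws a fresh community and placement from its own
    seed and runs both temperatures from the same initial state and the
    same dynamics stream; deltas are warm minus cool.
    """
    config = config.with_scenario(scenario)
    days = config.days if days is None else days
    root = np.random.SeedSequence(seed)
    rows = []
    for i, pair_ss in enumerate(root.spawn(n_pairs)):
        s_comm, s_place, s_dyn = pair_ss.spawn(3)
        community = generate_community(np.random.default_rng(s_comm), config)
        world0 = initialize_world(np.random.default_rng(s_place), community,
                                  config)
        out = {}
        for t in (t_low, t_high):
            w = world0.copy()
            w.temperature = t
            ctx = build_context(community, config, t)
            rng = np.random.default_rng(s_dyn)   # identical stream per temp
            out[t] = _run(w, ctx, rng, days, scenario, seed, audit=audit)
        lo, hi = out[t_low], out[t_high]
        rows.append({
            "pair": i,
            "eps_int_low": lo.cue_biomass_weighted,
            "eps_int_high": hi.cue_biomass_weighted,
            "biomass_c_low": lo.mean_biomass_c,
            "biomass_c_high": hi.mean_biomass_c,
            "substrate_c_low": lo.mean_substrate_c,
            "substrate_c_high": hi.mean_substrate_c,
            "enzyme_genes_low": lo.mean_enzyme_genes,
            "enzyme_genes_high": hi.mean_enzyme_genes,
            "uptake_genes_low": lo.mean_uptake_genes,
            "uptake_genes_high": hi.mean_uptake_genes,
        })
        rows[-1]["delta_eps_int"] = (rows[-1]["eps_int_high"]
                                     - rows[-1]["eps_int_low"])
        rows[-1]["delta_biomass_c"] = (rows[-1]["biomass_c_high"]
                                       - rows[-1]["biomass_c_low"])
        rows[-1]["delta_substrate_c"] = (rows[-1]["substrate_c_high"]
                                         - rows[-1]["substrate_c_low"])
        if progress:
            print(f"pair {i + 1}/{n_pairs}: "
                  f"delta eps_int = {rows[-1]['delta_eps_int']:+.4f}")
    pairs = pd.DataFrame(rows)
    return analyze_pairs(pairs, scenario, t_low, t_high)


# ---------------------------------------------------------------------------
# gene-equivalence of a CUE change

def genes_for_adaptation(target_delta_cue: float, m_e: float, m_u: float,
                         e_max: int = 40, n_u: int = 14
                         ) -> tuple[float, float]:
    """Gene reductions achieving a target intrinsic-CUE increase.

    Inverts eps_int = eps0 + f_E*m_E + f_U*m_U allocating half of the CUE
    gain to enzyme investment and half to uptake investment:
    dn_E = (target/2) * E_max/|m_E| and dn_U = (target/2) * N_U/|m_U|.
    """
    if m_e == 0 or m_u == 0:
        raise ValueError("tradeoff slopes must be non-zero")
    return (0.5 * target_delta_cue * e_max / abs(m_e),
            0.5 * target_delta_cue * n_u / abs(m_u))


def delta_cue_from_genes(d_enzyme_genes: float, d_uptake_genes: float,
                         m_e: float, m_u: float, e_max: int = 40,
                         n_u: int = 14) -> float:
    """Forward map: intrinsic-CUE gain from shedding the given numbers of
    enzyme and uptake genes."""
    return (d_enzyme_genes / e_max * abs(m_e)
            + d_uptake_genes / n_u * abs(m_u))
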