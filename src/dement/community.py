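"""Random generation of the enzyme pool, transporter pool and virtual taxa.

The community consists of a shared pool of extracellular enzymes (each
targeting one or more organic substrates, with per-substrate Vmax reduced
for generalist enzymes under a specificity-efficiency tradeoff), a shared
pool of uptake transporters (each targeting one or more of the 14 uptake
targets: 12 substrate-derived monomers plus inorganic N and P), and
virtual taxa that possess random subsets of both pools.

A taxon's intrinsic CUE is tied to its resource-acquisition investment:

    eps_int = eps0 + f_E * m_E + f_U * m_U

where f_E is the fraction of the maximum enzyme complement possessed and
f_U the fraction of transporters possessed.  Every taxon must be able to
take up at least one organic monomer and every monomer released by the
enzymes it carries; gene sets are repaired after random assignment to
enforce this, and f_U reflects the repaired set.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DementConfig

GUILD_BACTERIAL = "bacterial"
GUILD_FUNGAL = "fungal"


@dataclass(frozen=True)
class EnzymeDef:
    """A community-level enzyme: target substrates and catalytic constants.

    ``vmax`` is the per-substrate maximum rate at the reference temperature
    (mg substrate per mg enzyme per day), identical across the enzyme's
    targets; generalists pay V_E * n_targets^(-theta).  ``km`` is tied
    linearly to vmax.  ``ea_vmax`` holds the substrate-specific activation
    energies (kJ mol^-1), aligned with ``target_substrates``.
    """

    enzyme_id: int
    target_substrates: tuple[int, ...]
    vmax: float
    km: float
    ea_vmax: tuple[float, ...]
    ea_km: float

    @property
    def n_targets(self) -> int:
        return len(self.target_substrates)


@dataclass(frozen=True)
class TransporterDef:
    """A community-level uptake transporter and its kinetic constants."""

    transporter_id: int
    target_monomers: tuple[int, ...]
    vmax: float   # mg substrate per mg biomass C per day, at T_ref
    km: float     # mg cm^-3 at T_ref
    ea_vmax: float
    ea_km: float


@dataclass(frozen=True)
class TaxonTraits:
    """A virtual taxon: guild, gene sets, investment fractions, CUE and
    demographic constants."""

    taxon_id: int
    guild: str                       # 'bacterial' | 'fungal'
    enzyme_genes: tuple[int, ...]    # possessed enzymes (ids into the pool)
    uptake_genes: tuple[int, ...]    # possessed transporters
    f_e: float                       # |enzyme_genes| / E_max
    f_u: float                       # |uptake_genes| / N_U
    eps_int: float                   # intrinsic CUE at T_ref (mg mg^-1)
    division_threshold_c: float      # mg C per cell triggering division
    turnover_rate: float             # random death rate (day^-1)

    @property
    def is_fungal(self) -> bool:
        return self.guild == GUILD_FUNGAL


@dataclass(frozen=True)
class Community:
    enzymes: tuple[EnzymeDef, ...]
    transporters: tuple[TransporterDef, ...]
    taxa: tuple[TaxonTraits, ...]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def intrinsic_cue(f_e: float, f_u: float, config: DementConfig) -> float:
    """Intrinsic CUE from investment fractions:
    eps0 + f_E*m_E + f_U*m_U."""
    return config.eps0 + f_e * config.m_e + f_u * config.m_u


def _assign_targets(rng: np.random.Generator, n_items: int, n_targets: int,
                    min_coverage: int) -> list[set[int]]:
    """Random target sets (each of uniform random size >= 1), repaired so
    that every target is covered by at least ``min_coverage`` items."""
    if n_items <= 0:
        raise ValueError("cannot build a pool with zero members")
    if n_items < min_coverage:
        raise ValueError(
            f"coverage of {min_coverage} unreachable with {n_items} members")
    sets = []
    for _ in range(n_items):
        size = int(rng.integers(1, n_targets + 1))
        sets.append(set(rng.choice(n_targets, size=size, replace=False).tolist()))
    for target in range(n_targets):
        holders = [i for i, s in enumerate(sets) if target in s]
        missing = [i for i, s in enumerate(sets) if target not in s]
        while len(holders) < min_coverage:
            pick = missing[int(rng.integers(0, len(missing)))]
            sets[pick].add(target)
            missing.remove(pick)
            holders.append(pick)
    return sets


def build_enzyme_pool(seed, config: DementConfig | None = None) -> tuple[EnzymeDef, ...]:
    """Generate the community enzyme pool.

    Each enzyme targets a uniform-random subset (size >= 1) of the organic
    substrates; every substrate ends up degradable by at least
    ``min_enzymes_per_substrate`` enzymes.  Per-substrate Vmax is
    V_E * n_targets^(-theta) and Km = km_enz_slope*Vmax + km_enz_intercept.
    """
    config = config or DementConfig()
    rng = _as_rng(seed)
    sets = _assign_targets(rng, config.n_enzymes, config.n_substrates,
                           config.min_enzymes_per_substrate)
    pool = []
    for i, s in enumerate(sets):
        targets = tuple(sorted(s))
        vmax = config.vmax_enzyme * len(targets) ** (-config.theta)
        km = config.km_enz_slope * vmax + config.km_enz_intercept
        if km < 0:
            raise ValueError("negative Km implied by km_enz_* parameters")
        pool.append(EnzymeDef(
            enzyme_id=i,
            target_substrates=targets,
            vmax=vmax,
            km=km,
            ea_vmax=tuple(config.substrates[t].ea_decay for t in targets),
            ea_km=config.ea_km,
        ))
    return tuple(pool)


def build_transporter_pool(seed, config: DementConfig | None = None
                           ) -> tuple[TransporterDef, ...]:
    """Generate the community transporter pool.

    Each transporter targets a uniform-random subset (size >= 1) of the 14
    uptake targets (12 substrate-derived monomers + inorganic N + inorganic
    P); every target is reachable by at least
    ``min_transporters_per_monomer`` transporters.  Vmax is constant across
    transporters and Km = km_upt_slope*Vmax + km_upt_intercept.
    """
    config = config or DementConfig()
    rng = _as_rng(seed)
    sets = _assign_targets(rng, config.n_transporters, config.n_monomers,
                           config.min_transporters_per_monomer)
    vmax = config.vmax_uptake
    km = config.km_upt_slope * vmax + config.km_upt_intercept
    if km < 0:
        raise ValueError("negative Km implied by km_upt_* parameters")
    return tuple(
        TransporterDef(
            transporter_id=i,
            target_monomers=tuple(sorted(s)),
            vmax=vmax,
            km=km,
            ea_vmax=config.ea_uptake,
            ea_km=config.ea_km,
        )
        for i, s in enumerate(sets)
    )


def generate_taxa(seed, enzymes, transporters,
                  config: DementConfig | None = None) -> tuple[TaxonTraits, ...]:
    """Generate the virtual taxa.

    Gene-set sizes are uniform on their allowed ranges (0..E_max enzymes,
    1..N_U transporters); members are drawn uniformly without replacement.
    Sets are then repaired so each taxon can take up every monomer its
    enzymes release and at least one organic monomer; eps_int is computed
    from the final (repaired) sets.
    """
    config = config or DementConfig()
    rng = _as_rng(seed)
    n = config.n_taxa
    n_fungal = int(round(n * config.fungal_fraction))
    guilds = np.array([GUILD_FUNGAL] * n_fungal
                      + [GUILD_BACTERIAL] * (n - n_fungal))
    rng.shuffle(guilds)

    n_enzymes = len(enzymes)
    n_transporters = len(transporters)
    organic_monomers = set(range(config.n_substrates))
    # transporters reaching each monomer, for the repair step
    reachers: dict[int, list[int]] = {m: [] for m in range(config.n_monomers)}
    for tr in transporters:
        for m in tr.target_monomers:
            reachers[m].append(tr.transporter_id)

    taxa = []
    for i in range(n):
        n_e = int(rng.integers(0, config.e_max + 1))
        enz = set(rng.choice(n_enzymes, size=min(n_e, n_enzymes),
                             replace=False).tolist())
        n_u = int(rng.integers(1, config.n_transporters + 1))
        upt = set(rng.choice(n_transporters, size=n_u, replace=False).tolist())

        covered = set()
        for t in upt:
            covered.update(transporters[t].target_monomers)
        # must reach every monomer released by the taxon's own enzymes
        required = set()
        for e in enz:
            required.update(enzymes[e].target_substrates)
        for m in sorted(required - covered):
            options = [t for t in reachers[m] if t not in upt]
            if not options:   # already covered via another transporter
                continue
            pick = options[int(rng.integers(0, len(options)))]
            upt.add(pick)
            covered.update(transporters[pick].target_monomers)
        # must reach at least one organic monomer
        if not covered & organic_monomers:
            options = [t.transporter_id for t in transporters
                       if set(t.target_monomers) & organic_monomers
                       and t.transporter_id not in upt]
            pick = options[int(rng.integers(0, len(options)))]
            upt.add(pick)

        f_e = len(enz) / config.e_max
        f_u = len(upt) / config.n_transporters
        guild = str(guilds[i])
        taxa.append(TaxonTraits(
            taxon_id=i,
            guild=guild,
            enzyme_genes=tuple(sorted(enz)),
            uptake_genes=tuple(sorted(upt)),
            f_e=f_e,
            f_u=f_u,
            eps_int=intrinsic_cue(f_e, f_u, config),
            division_threshold_c=(config.c_max_fungi
                                  if guild == GUILD_FUNGAL
                                  else config.c_max_bacteria),
            turnover_rate=(config.tau_fungi if guild == GUILD_FUNGAL
                           else config.tau_bacteria),
        ))
    return tuple(taxa)


def generate_community(seed, config: DementConfig | None = None) -> Community:
    """Build enzymes, transporters and taxa from one seed (three draws off
    a single stream, so the whole community is reproducible bit-for-bit)."""
    config = config or DementConfig()
    rng = _as_rng(seed)
    enzymes = build_enzyme_pool(rng, config)
    transporters = build_transporter_pool(rng, config)
    taxa = generate_taxa(rng, enzymes, transporters, config)
    return Community(enzymes=enzymes, transporters=transporters, taxa=taxa)


# ---------------------------------------------------------------------------
# serialization

def taxa_frame(community: Community) -> pd.DataFrame:
    """One row per taxon: guild, gene sets (';'-delimited ids), investment
    fractions and intrinsic CUE."""
    return pd.DataFrame([{
        "taxon_id": t.taxon_id,
        "guild": t.guild,
        "enzyme_genes": ";".join(map(str, t.enzyme_genes)),
        "uptake_genes": ";".join(map(str, t.uptake_genes)),
        "f_e": t.f_e,
        "f_u": t.f_u,
        "eps_int": t.eps_int,
        "division_threshold_c": t.division_threshold_c,
        "turnover_rate": t.turnover_rate,
    } for t in community.taxa])


def enzymes_frame(community: Community) -> pd.DataFrame:
    return pd.DataFrame([{
        "enzyme_id": e.enzyme_id,
        "target_substrates": ";".join(map(str, e.target_substrates)),
        "vmax": e.vmax,
        "km": e.km,
        "ea_vmax": ";".join(map(str, e.ea_vmax)),
        "ea_km": e.ea_km,
    } for e in community.enzymes])


def transporters_frame(community: Community) -> pd.DataFrame:
    return pd.DataFrame([{
        "transporter_id": t.transporter_id,
        "target_monomers": ";".join(map(str, t.target_monomers)),
        "vmax": t.vmax,
        "km": t.km,
        "ea_vmax": t.ea_vmax,
        "ea_km": t.ea_km,
    } for t in community.transporters])


def save_community(community: Community, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # %.17g keeps doubles exact through the text round trip
    taxa_frame(community).to_csv(outdir / "taxa.csv", index=False,
                                 float_format="%.17g")
    enzymes_frame(community).to_csv(outdir / "enzymes.csv", index=False,
                                    float_format="%.17g")
    transporters_frame(community).to_csv(outdir / "transporters.csv",
                                         index=False, float_format="%.17g")


def _parse_ids(s) -> tuple[int, ...]:
    if isinstance(s, float) and np.isnan(s):
        return ()
    s = str(s)
    return tuple(int(x) for x in s.split(";")) if s else ()


def load_community(indir: str | Path) -> Community:
    """Inverse of :func:`save_community`."""
    indir = Path(indir)
    ef = pd.read_csv(indir / "enzymes.csv", float_precision="round_trip")
    tf = pd.read_csv(indir / "transporters.csv",
                     float_precision="round_trip")
    xf = pd.read_csv(indir / "taxa.csv", float_precision="round_trip")
    enzymes = tuple(EnzymeDef(
        enzyme_id=int(r.enzyme_id),
        target_substrates=_parse_ids(r.target_substrates),
        vmax=float(r.vmax),
        km=float(r.km),
        ea_vmax=tuple(float(x) for x in str(r.ea_vmax).split(";")),
        ea_km=float(r.ea_km),
    ) for r in ef.itertuples())
    transporters = tuple(TransporterDef(
        transporter_id=int(r.transporter_id),
        target_monomers=_parse_ids(r.target_monomers),
        vmax=float(r.vmax),
        km=float(r.km),
        ea_vmax=float(r.ea_vmax),
        ea_km=float(r.ea_km),
    ) for r in tf.itertuples())
    taxa = tuple(TaxonTraits(
        taxon_id=int(r.taxon_id),
        guild=str(r.guild),
        enzyme_genes=_parse_ids(r.enzyme_genes),
        uptake_genes=_parse_ids(r.uptake_genes),
        f_e=float(r.f_e),
        f_u=float(r.f_u),
        eps_int=float(r.eps_int),
        division_threshold_c=float(r.division_threshold_c),
        turnover_rate=float(r.turnover_rate),
    ) for r in xf.itertuples())
    return Community(enzymes=enzymes, transporters=transporters, taxa=taxa)
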