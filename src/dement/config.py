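"""Model configuration: physiological parameters and substrate chemistry.

The defaults describe a plant-litter decomposition setting (southern
California grassland litter chemistry) with a community of 100 virtual
taxa, 12 organic substrates, up to 50 extracellular enzymes and 14 uptake
transporters on a 100 x 100 lattice.  All concentrations are volumetric
(mg cm^-3); each lattice point represents a nominal 1 cm^3 of litter, so
per-point pool values equal the volumetric concentrations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
import yaml

ELEMENTS = ("C", "N", "P")

# Substrate indices (fixed layout; monomers derived from substrates share
# the same index, inorganic N and P occupy the two extra monomer slots).
DEAD_MICROBE = 0
DEAD_ENZYME = 1
CELLULOSE = 2
HEMICELLULOSE = 3
STARCH = 4
CHITIN = 5
LIGNIN = 6
PROTEIN1 = 7
PROTEIN2 = 8
PROTEIN3 = 9
ORGANIC_P1 = 10
ORGANIC_P2 = 11


@dataclass(frozen=True)
class SubstrateSpec:
    """Chemistry of one substrate: initial pools, inputs, decay sensitivity.

    ``init_c/n/p`` are the initial pool sizes (mg cm^-3) and also define
    the compound's fixed stoichiometry.  ``input_substrate`` and
    ``input_monomer`` are daily C inputs (mg cm^-3 day^-1) to the polymer
    pool and directly to its soluble monomer; input N and P follow the
    compound stoichiometry.  ``ea_decay`` is the activation energy
    (kJ mol^-1) for enzymatic decay of this substrate.
    """

    name: str
    init_c: float
    init_n: float
    init_p: float
    input_substrate: float
    input_monomer: float
    ea_decay: float

    def stoich_ratios(self) -> tuple[float, float]:
        """(N:C, P:C) mass ratios of the compound; (0, 0) for empty pools."""
        if self.init_c <= 0.0:
            return 0.0, 0.0
        return self.init_n / self.init_c, self.init_p / self.init_c


# Initial pools, input rates and decay activation energies for the default
# litter chemistry.  The dead-microbe and dead-enzyme pools start empty and
# receive no external inputs; they are fed by mortality and enzyme decay.
DEFAULT_SUBSTRATES: tuple[SubstrateSpec, ...] = (
    SubstrateSpec("DeadMicrobe", 0.0, 0.0, 0.0, 0.0, 0.0, 37.0),
    SubstrateSpec("DeadEnzyme", 0.0, 0.0, 0.0, 0.0, 0.0, 35.0),
    SubstrateSpec("Cellulose", 146.89, 0.0, 0.0, 0.4024, 0.01811, 36.0),
    SubstrateSpec("Hemicellulose", 85.86, 0.0, 0.0, 0.2352, 0.01058, 35.0),
    SubstrateSpec("Starch", 12.21, 0.0, 0.0, 0.0335, 0.00151, 35.0),
    SubstrateSpec("Chitin", 5.00, 0.8325, 0.0, 0.0137, 0.00062, 37.0),
    SubstrateSpec("Lignin", 48.51, 0.4043, 0.0, 0.1329, 0.00598, 39.0),
    SubstrateSpec("Protein1", 10.60, 2.0970, 0.0, 0.0290, 0.00131, 35.0),
    SubstrateSpec("Protein2", 10.60, 2.0970, 0.0, 0.0290, 0.00131, 35.0),
    SubstrateSpec("Protein3", 10.60, 2.0970, 0.0, 0.0290, 0.00131, 35.0),
    SubstrateSpec("OrganicP1", 12.48, 0.0, 0.4785, 0.0342, 0.00154, 36.0),
    SubstrateSpec("OrganicP2", 1.82, 0.7975, 0.4785, 0.0050, 0.00022, 34.0),
)

# Tradeoff scenarios: slope of intrinsic CUE vs. enzyme/uptake investment
# used by the simulation model (m_E = m_U).
SCENARIO_SLOPES = {"high": -0.2, "low": -0.1}

# Tradeoff scenarios for the analytical model (slope of intrinsic CUE vs.
# reference uptake rate).
ANALYTICAL_SCENARIO_SLOPES = {"high": -0.4, "low": -0.2}


@dataclass
class DementConfig:
    """All tunable model parameters with their default values.

    Units follow the conventions above: masses in mg, volumes in cm^3,
    time in days, temperatures in degrees Celsius, activation energies in
    kJ mol^-1.
    """

    # -- run geometry and duration ------------------------------------
    days: int = 5000                  # simulation length (iterations)
    x: int = 100                      # lattice length
    y: int = 100                      # lattice width
    temperature: float = 20.0         # ambient temperature (deg C)
    t_ref: float = 20.0               # reference temperature for kinetics/CUE

    # -- community size -----------------------------------------------
    n_enzymes: int = 50               # enzymes in the community pool (N_E)
    n_substrates: int = 12            # organic substrates (N_S)
    n_transporters: int = 14          # uptake transporters (N_U)
    n_taxa: int = 100                 # virtual taxa
    fungal_fraction: float = 0.5      # fraction of taxa that are fungal

    # -- kinetics -------------------------------------------------------
    ea_uptake: float = 35.0           # activation energy for uptake (E_a)
    ea_km: float = 20.0               # activation energy for Km (E_aK)
    vmax_enzyme: float = 100.0        # enzyme Vmax at T_ref (V_E)
    vmax_uptake: float = 5.0          # uptake Vmax at T_ref (V_U)
    km_enz_slope: float = 10.0        # Km = slope*Vmax + intercept (enzymes)
    km_enz_intercept: float = 0.0
    km_upt_slope: float = 0.2         # Km = slope*Vmax + intercept (uptake)
    km_upt_intercept: float = 0.0
    lci_slope: float = -0.8           # cellulose decay penalty per unit LCI
    lci_on_hemicellulose: bool = False  # also penalize hemicellulose decay
    theta: float = 1.0                # specificity-efficiency tradeoff strength

    # -- community assembly constraints ---------------------------------
    min_enzymes_per_substrate: int = 1   # E_S
    min_transporters_per_monomer: int = 1  # U_M
    e_max: int = 40                   # max enzymes per taxon

    # -- carbon use efficiency ------------------------------------------
    eps0: float = 0.5                 # CUE intercept (mg mg^-1)
    m_t: float = -0.016               # CUE temperature slope (mg mg^-1 C^-1)
    m_e: float = -0.2                 # CUE change with enzyme investment
    m_u: float = -0.2                 # CUE change with uptake investment

    # -- enzyme production costs ----------------------------------------
    z_ec: float = 5e-5                # inducible C cost per enzyme per unit uptake
    beta_ec: float = 5e-5             # constitutive C cost per enzyme per unit biomass/day
    z_en: float = 0.3                 # enzyme N cost as a fraction of C cost

    # -- turnover and transport -----------------------------------------
    leaching: float = 0.1             # dissolved-pool leaching rate (day^-1)
    tau_enzyme: float = 0.04          # enzyme turnover (day^-1)
    tau_bacteria: float = 0.02        # bacterial random death (day^-1)
    tau_fungi: float = 0.01           # fungal random death (day^-1)

    # -- initialization --------------------------------------------------
    f_ms: float = 0.045               # initial monomer as a fraction of substrate
    density_bacteria: float = 0.1     # initial bacterial cells per lattice point
    density_fungi: float = 0.004      # initial fungal cells per lattice point
    fungal_biomass_fraction: float = 0.5  # initial fungal share of biomass

    # -- biomass stoichiometry -------------------------------------------
    frac_c_bacteria: float = 0.825
    frac_n_bacteria: float = 0.160
    frac_p_bacteria: float = 0.015
    frac_c_fungi: float = 0.900
    frac_n_fungi: float = 0.090
    frac_p_fungi: float = 0.010
    tol_c: float = 0.090              # tolerance on C fraction
    tol_n: float = 0.040              # tolerance on N fraction
    tol_p: float = 0.005              # tolerance on P fraction

    # -- demography --------------------------------------------------------
    c_min: float = 0.086              # starvation thresholds (mg per cell)
    n_min: float = 0.012
    p_min: float = 0.002
    c_max_bacteria: float = 2.0       # division threshold (mg C per cell)
    c_max_fungi: float = 50.0
    rho_y: float = 0.05               # fungal probability of dispersing in y
    dispersal_distance: int = 1       # max dispersal distance (lattice points)
    fungal_lateral_x: bool = False    # non-y fungal offspring move in x instead
                                      # of stacking on the parent point

    # -- substrate chemistry ----------------------------------------------
    substrates: tuple[SubstrateSpec, ...] = DEFAULT_SUBSTRATES

    def __post_init__(self) -> None:
        self.validate()

    # Monomer layout: one soluble monomer per substrate plus inorganic N, P.
    @property
    def n_monomers(self) -> int:
        return self.n_substrates + 2

    @property
    def inorganic_n_index(self) -> int:
        return self.n_substrates

    @property
    def inorganic_p_index(self) -> int:
        return self.n_substrates + 1

    def validate(self) -> None:
        if len(self.substrates) != self.n_substrates:
            raise ValueError(
                f"n_substrates={self.n_substrates} but "
                f"{len(self.substrates)} substrate specs given"
            )
        if not 0.0 < self.eps0 <= 1.0:
            raise ValueError("eps0 must lie in (0, 1]")
        if self.e_max <= 0 or self.n_transporters <= 0:
            raise ValueError("e_max and n_transporters must be positive")
        for name in ("leaching", "tau_enzyme", "tau_bacteria", "tau_fungi",
                     "rho_y"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.c_max_fungi - 25.0 * self.c_max_bacteria) > 1e-9:
            # Fungal cells are 25x larger by construction; a different ratio
            # is allowed but the initial biomass split then deviates from
            # fungal_biomass_fraction.
            pass

    def with_scenario(self, scenario: str) -> "DementConfig":
        """Return a copy with tradeoff slopes set for 'high' or 'low'."""
        try:
            slope = SCENARIO_SLOPES[scenario]
        except KeyError:
            raise ValueError(f"unknown scenario {scenario!r}; expected "
                             f"{sorted(SCENARIO_SLOPES)}") from None
        return replace(self, m_e=slope, m_u=slope)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["substrates"] = [asdict(s) for s in self.substrates]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DementConfig":
        d = dict(d)
        subs = d.pop("substrates", None)
        if subs is not None:
            d["substrates"] = tuple(
                s if isinstance(s, SubstrateSpec) else SubstrateSpec(**s)
                for s in subs
            )
        return cls(**d)

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "DementConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(**overrides) -> DementConfig:
    """The shipped default configuration, optionally overridden."""
    return replace(DementConfig(), **overrides) if overrides else DementConfig()
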