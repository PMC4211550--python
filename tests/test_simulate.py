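"""Daily scheduler, run summaries, paired experiment and statistics."""
import json

import numpy as np
import pytest
from scipy import stats as sps

from dement.config import DementConfig, STARCH
from dement.community import generate_community, intrinsic_cue
from dement.kinetics import arrhenius_factor
from dement.physiology import build_context
from dement.world import initialize_world
from dement.simulate import (step_day, run_simulation, run_paired_experiment,
                             one_sample_t, simple_ols, analyze_pairs,
                             genes_for_adaptation, delta_cue_from_genes,
                             RunSummary, conservation_errors)
import pandas as pd

from conftest import blank_world, add_cells, single_taxon_community


# ---------------------------------------------------------------------------
# scalar (non-spatial) oracle for the daily update

def scalar_oracle(cfg, eps_int, days, t):
    """Independently coded single-point recurrence for one bacterial taxon
    with one enzyme and one substrate (starch): decay, uptake, growth,
    enzyme production, C-overflow homeostasis, enzyme turnover, leaching,
    inputs — no dispersal, no mortality, no division."""
    fa_s = arrhenius_factor(t, 20.0, 35.0)      # starch decay Ea
    fa_k = arrhenius_factor(t, 20.0, 20.0)
    fa_u = arrhenius_factor(t, 20.0, 35.0)      # uptake Ea
    vt, kt = 100.0 * fa_s, 1000.0 * fa_k
    vut, kut = 5.0 * fa_u, 1.0 * fa_k
    eps = min(max(eps_int + cfg.m_t * (t - 20.0), 0.0), 1.0)
    upper_c = cfg.frac_c_bacteria + cfg.tol_c

    s = 12.21
    m = 5.0   # rich starting monomer pool so overflow is exercised
    e = 0.01
    c, n, p = 1.0, 0.19, 0.018
    traj = []
    for _ in range(days):
        d = min(vt * e * s / (kt + s), s)
        s -= d
        m += d
        u = min(vut * c * m / (kut + m), m)
        m -= u
        c += eps * u
        cost = cfg.beta_ec * c + cfg.z_ec * u     # one enzyme gene
        avail_c = max(c - cfg.c_min, 0.0)
        avail_n = max(n - cfg.n_min, 0.0)
        scale = min(1.0, avail_c / cost if cost > 0 else 1.0,
                    avail_n / (cfg.z_en * cost) if cost > 0 else 1.0)
        cost *= scale
        c -= cost
        n -= cfg.z_en * cost
        e += cost
        while True:   # homeostatic overflow respiration (C only here)
            mass = c + n + p
            x = (c - upper_c * mass) / (1.0 - upper_c)
            if x <= 1e-15 * max(mass, 1.0):
                break
            c -= x
        e *= (1.0 - cfg.tau_enzyme)
        m *= (1.0 - cfg.leaching)
        s += cfg.substrates[STARCH].input_substrate
        m += cfg.substrates[STARCH].input_monomer
        traj.append((s, m, e, c, n))
    return np.array(traj)


def test_step_day_matches_scalar_oracle(tiny_cfg):
    """A uniform world of identical single-cell points must follow the
    non-spatial recurrence exactly when dispersal and mortality are off."""
    cfg = tiny_cfg
    t = 25.0
    com = single_taxon_community(cfg, substrate=STARCH,
                                 division_threshold=1e9, turnover=0.0)
    ctx = build_context(com, cfg, t)
    w = blank_world(cfg, temperature=t)
    npts = w.n_points
    w.substrates[:, STARCH, 0] = 12.21
    w.monomers[:, STARCH, 0] = 5.0
    w.enzymes[:, 0] = 0.01
    add_cells(w, [0] * npts, list(range(npts)), [(1.0, 0.19, 0.018)] * npts)

    expected = scalar_oracle(cfg, com.taxa[0].eps_int, days=10, t=t)
    rng = np.random.default_rng(0)
    for day in range(10):
        step_day(w, ctx, rng)
        s, m, e, c, n = expected[day]
        assert np.allclose(w.substrates[:, STARCH, 0], s, rtol=1e-9)
        assert np.allclose(w.monomers[:, STARCH, 0], m, rtol=1e-9)
        assert np.allclose(w.enzymes[:, 0], e, rtol=1e-9)
        assert np.allclose(w.cell_quota[:, 0], c, rtol=1e-9)
        assert np.allclose(w.cell_quota[:, 1], n, rtol=1e-9)
        if day == 0:
            # the C bloom exercises the overflow branch on day one:
            # cells sit exactly at the upper C-fraction band boundary
            frac_c = w.cell_quota[0, 0] / w.cell_quota[0].sum()
            assert frac_c == pytest.approx(0.915, abs=1e-9)


# ---------------------------------------------------------------------------
# no-biology closed forms

def test_empty_world_follows_input_and_leaching_closed_forms():
    cfg = DementConfig(x=6, y=6, density_bacteria=0.0, density_fungi=0.0)
    com = generate_community(4, cfg)
    ctx = build_context(com, cfg, 20.0)
    w = initialize_world(0, com, cfg)
    assert w.n_cells == 0
    s0 = w.substrates[0, :, 0].copy()
    m0 = w.monomers[0, :, 0].copy()
    sub_in = np.array([s.input_substrate for s in cfg.substrates])
    mon_in = np.array([s.input_monomer for s in cfg.substrates] + [0.0, 0.0])
    rng = np.random.default_rng(0)
    days = 30
    for _ in range(days):
        step_day(w, ctx, rng)
    # substrates: pool(t) = pool(0) + input * t, exactly
    assert np.allclose(w.substrates[0, :, 0], s0 + sub_in * days, rtol=1e-12)
    # monomers: linear input + geometric leaching recurrence closed form
    g = 1.0 - cfg.leaching
    expected_m = (g ** days) * m0 + mon_in * (1 - g ** days) / cfg.leaching
    assert np.allclose(w.monomers[0, :, 0], expected_m, rtol=1e-12)
    # uniform across points
    assert np.allclose(w.substrates[:, :, 0], w.substrates[0, :, 0])


def test_single_day_ledger_conserves_mass(tiny_cfg):
    cfg = tiny_cfg
    com = generate_community(8, cfg)
    ctx = build_context(com, cfg, 20.0)
    w = initialize_world(1, com, cfg)
    rng = np.random.default_rng(2)
    for _ in range(5):
        before = w.totals(cfg.z_en)
        ledger = step_day(w, ctx, rng)
        err = conservation_errors(before, w.totals(cfg.z_en), ledger)
        assert err.max() < 1e-10
        for v in ledger.as_dict().values():
            assert np.isfinite(v) and v >= 0


# ---------------------------------------------------------------------------
# run summaries

def test_zero_day_run_equals_initial_state():
    cfg = DementConfig(x=8, y=8)
    s = run_simulation(cfg, seed=3, days=0, scenario="high")
    assert len(s.biomass_c) == 1
    assert s.mean_substrate_c == pytest.approx(
        sum(x.init_c for x in cfg.substrates) * 64)
    assert s.cue_biomass_weighted == pytest.approx(
        s.community_eps_int[0])


def test_biomass_weighted_cue_example():
    # two taxa with biomasses (1, 3) and eps_int (0.2, 0.4) -> 0.35
    days1 = np.arange(1)
    s = RunSummary(
        scenario="high", temperature=20.0, seed=0, days=0, day=days1,
        substrate_c=np.zeros(1), monomer_c=np.zeros(1),
        enzyme_c=np.zeros(1), biomass_c=np.array([4.0]),
        n_cells=np.array([2]), community_eps_int=np.array([0.35]),
        taxon_biomass=np.array([[1.0, 3.0]]),
        substrate_pools=np.zeros((1, 12)),
        taxon_eps_int=np.array([0.2, 0.4]),
        taxon_n_enzymes=np.array([5, 10]),
        taxon_n_uptake=np.array([2, 4]),
    )
    assert s.cue_biomass_weighted == pytest.approx(0.35)
    assert s.mean_enzyme_genes == pytest.approx((5 + 30) / 4)


def test_run_is_deterministic():
    cfg = DementConfig(x=10, y=10)
    a = run_simulation(cfg, seed=5, days=20, scenario="high")
    b = run_simulation(cfg, seed=5, days=20, scenario="high")
    assert json.dumps(a.summary_dict(), sort_keys=True) == \
        json.dumps(b.summary_dict(), sort_keys=True)
    assert np.array_equal(a.taxon_biomass, b.taxon_biomass)


def test_summary_scalars_recomputable_from_series():
    cfg = DementConfig(x=8, y=8)
    s = run_simulation(cfg, seed=6, days=15, scenario="low")
    assert s.mean_biomass_c == pytest.approx(s.biomass_c.mean())
    assert s.mean_substrate_c == pytest.approx(s.substrate_c.mean())
    w = s.taxon_biomass.sum()
    assert s.cue_biomass_weighted == pytest.approx(
        (s.taxon_biomass @ s.taxon_eps_int).sum() / w)
    lo, hi = s.taxon_eps_int.min(), s.taxon_eps_int.max()
    assert lo <= s.cue_biomass_weighted <= hi


def test_run_outputs_written(tmp_path):
    cfg = DementConfig(x=6, y=6)
    s = run_simulation(cfg, seed=1, days=3, scenario="high")
    s.save(tmp_path, substrate_names=[x.name for x in cfg.substrates])
    assert (tmp_path / "summary.json").exists()
    df = pd.read_csv(tmp_path / "timeseries.csv")
    assert len(df) == 4
    sub = pd.read_csv(tmp_path / "substrate_pools.csv")
    assert "Cellulose" in sub.columns


# ---------------------------------------------------------------------------
# paired experiment

def test_identical_temperatures_give_zero_deltas():
    cfg = DementConfig(x=6, y=6)
    r = run_paired_experiment(cfg, seed=9, n_pairs=2, t_low=20.0,
                              t_high=20.0, days=10, scenario="high")
    assert np.allclose(r.pairs["delta_eps_int"], 0.0)
    assert np.allclose(r.pairs["delta_biomass_c"], 0.0)
    assert np.allclose(r.pairs["delta_substrate_c"], 0.0)
    assert r.t_tests["eps_int"]["degenerate"]


def test_paired_driver_is_deterministic():
    cfg = DementConfig(x=6, y=6)
    a = run_paired_experiment(cfg, seed=11, n_pairs=2, days=8,
                              scenario="high")
    b = run_paired_experiment(cfg, seed=11, n_pairs=2, days=8,
                              scenario="high")
    pd.testing.assert_frame_equal(a.pairs, b.pairs)


# ---------------------------------------------------------------------------
# statistics against closed forms and scripted pairs

def test_one_sample_t_matches_scipy():
    rng = np.random.default_rng(0)
    x = rng.normal(0.3, 1.0, size=25)
    mine = one_sample_t(x)
    ref = sps.ttest_1samp(x, 0.0)
    assert mine["t"] == pytest.approx(ref.statistic)
    assert mine["p"] == pytest.approx(ref.pvalue)


def test_ols_matches_scipy():
    rng = np.random.default_rng(1)
    x = rng.random(30)
    y = 2.0 + 1.5 * x + rng.normal(0, 0.1, 30)
    mine = simple_ols(x, y)
    ref = sps.linregress(x, y)
    assert mine["slope"] == pytest.approx(ref.slope)
    assert mine["intercept"] == pytest.approx(ref.intercept)
    assert mine["r_squared"] == pytest.approx(ref.rvalue ** 2)
    assert mine["p"] == pytest.approx(ref.pvalue)


def test_scripted_pairs_give_known_t_and_slope():
    # three hand-built pairs: deltas (1, 2, 3) -> t = 2 / (1/sqrt(3))
    pairs = pd.DataFrame({
        "pair": [0, 1, 2],
        "delta_eps_int": [1.0, 2.0, 3.0],
        "delta_biomass_c": [2.0, 4.0, 7.0],
        "delta_substrate_c": [1.0, 1.0, 1.0],
    })
    r = analyze_pairs(pairs, "high", 15.0, 20.0)
    assert r.t_tests["eps_int"]["t"] == pytest.approx(2.0 * np.sqrt(3.0))
    # OLS of (2,4,7) on (1,2,3): slope 2.5, intercept -2/3
    reg = r.regressions["delta_biomass_c"]
    assert reg["slope"] == pytest.approx(2.5)
    assert reg["intercept"] == pytest.approx(-2.0 / 3.0)
    assert r.t_tests["substrate_c"]["degenerate"]


def test_degenerate_t_flagged():
    out = one_sample_t(np.zeros(5))
    assert out["degenerate"] and np.isnan(out["t"])


# ---------------------------------------------------------------------------
# gene-equivalence of a CUE change

class TestGeneEquivalence:
    def test_inversion(self):
        d_e, d_u = genes_for_adaptation(0.04, m_e=-0.2, m_u=-0.2)
        assert d_e == pytest.approx(4.0)
        assert d_u == pytest.approx(1.4)

    def test_forward_map(self):
        # shedding 1.4 enzyme + 0.5 uptake genes under the high tradeoff
        delta = delta_cue_from_genes(1.4, 0.5, m_e=-0.2, m_u=-0.2)
        assert delta == pytest.approx(0.0141, abs=5e-4)

    def test_zero_target(self):
        assert genes_for_adaptation(0.0, -0.2, -0.2) == (0.0, 0.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            genes_for_adaptation(0.04, 0.0, -0.2)

    def test_round_trip(self):
        d_e, d_u = genes_for_adaptation(0.025, m_e=-0.1, m_u=-0.15)
        assert delta_cue_from_genes(d_e, d_u, -0.1, -0.15) == \
            pytest.approx(0.025)
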