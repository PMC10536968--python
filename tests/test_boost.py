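"""Harmonic boost law, parameter estimation, providers and the protocol."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selgamd.gamd_boost import (
    AdaptiveBoostProvider,
    BoostParameters,
    RegionStatistics,
    SelectiveBoostProvider,
    StageLengths,
    apply_dual_boost,
    boost_energy,
    estimate_parameters,
    force_scale,
    run_protocol,
    run_standard_gamd,
)
from selgamd.md_engine import IntegratorConfig, run
from selgamd.region_decomposition import (
    AccelerationRegionSpec,
    DecomposedSystem,
    validate_regions,
)
from selgamd import make_double_well


@st.composite
def _vek(draw):
    v_min = draw(st.floats(-200, 200))
    spread = draw(st.floats(1e-3, 500))
    k0 = draw(st.floats(1e-6, 1.0))
    v = draw(st.floats(-400, 400))
    E = v_min + spread
    return v, BoostParameters(E=E, k=k0 / spread, k0=k0, sigma0=1.0), v_min


@settings(max_examples=300, deadline=None, derandomize=True)
@given(_vek())
def test_boost_law_properties(case):
    v, p, v_min = case
    dv = boost_energy(v, p)
    assert dv >= 0.0
    if v >= p.E:
        assert dv == 0.0
        assert force_scale(v, p) == 1.0
    else:
        assert dv == pytest.approx(0.5 * p.k * (p.E - v) ** 2)
        lam = force_scale(v, p)
        assert lam == pytest.approx(1.0 - p.k * (p.E - v))
        if v >= v_min and p.k0 <= 1.0:
            assert -1e-9 <= lam <= 1.0 + 1e-9


def test_boost_law_boundary_values():
    p = BoostParameters(E=10.0, k=0.1, k0=1.0, sigma0=1.0)
    assert boost_energy(10.0, p) == 0.0
    assert boost_energy(12.0, p) == 0.0
    # V = v_min, E = v_max, k0 = 1: dv = (v_max - v_min)/2
    v_min, v_max = 2.0, 12.0
    p2 = BoostParameters(E=v_max, k=1.0 / (v_max - v_min), k0=1.0, sigma0=1.0)
    assert boost_energy(v_min, p2) == pytest.approx((v_max - v_min) / 2.0)
    assert force_scale(v_min, p2) == pytest.approx(0.0)


def test_force_scale_is_derivative_of_modified_potential():
    p = BoostParameters(E=15.0, k=0.05, k0=0.75, sigma0=1.0)
    h = 1e-6
    for v in np.linspace(-5.0, 20.0, 23):
        fd = 1.0 + (boost_energy(v + h, p) - boost_energy(v - h, p)) / (2 * h)
        assert force_scale(v, p) == pytest.approx(fd, rel=1e-6, abs=1e-6)


def test_region_statistics_streaming(rng):
    data = rng.normal(5.0, 2.0, size=1000)
    stats = RegionStatistics()
    for v in data:
        stats.update(v)
    assert stats.n_samples == 1000
    assert stats.v_avg == pytest.approx(data.mean(), rel=1e-12)
    assert stats.v_std == pytest.approx(data.std(), rel=1e-9)
    assert stats.v_min == data.min() and stats.v_max == data.max()
    # order independence within floating tolerance
    stats2 = RegionStatistics()
    for v in rng.permutation(data):
        stats2.update(v)
    assert stats2.v_avg == pytest.approx(stats.v_avg, rel=1e-12)
    assert stats2.v_std == pytest.approx(stats.v_std, rel=1e-9)


def test_estimate_parameters_formula():
    stats = RegionStatistics()
    for v in [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]:
        stats.update(v)
    sigma0 = 1.0
    p = estimate_parameters(stats, sigma0)
    spread = stats.v_max - stats.v_min
    expect_k0 = min(
        1.0, (sigma0 / stats.v_std) * spread / (stats.v_max - stats.v_avg)
    )
    assert p.E == stats.v_max
    assert p.k0 == pytest.approx(expect_k0)
    assert p.k == pytest.approx(expect_k0 / spread)
    assert p.k0 < 1.0  # this fixture is in the uncapped branch

    # very small v_std: capped at 1
    tight = RegionStatistics()
    for v in [5.0, 5.0001, 4.9999, 5.0, 10.0]:
        tight.update(v)
    assert estimate_parameters(tight, 10.0).k0 == 1.0

    degen = RegionStatistics()
    degen.update(3.0)
    degen.update(3.0)
    with pytest.warns(UserWarning, match="degenerate"):
        p0 = estimate_parameters(degen, 10.0)
    assert p0.k == 0.0
    assert boost_energy(-100.0, p0) == 0.0

    with pytest.raises(ValueError):
        estimate_parameters(RegionStatistics(), 10.0)


def _surface_region_set(surface, sigma0=10.0):
    spec = AccelerationRegionSpec("all", frozenset({"b0"}), sigma0=sigma0)
    return validate_regions([spec], list(surface.catalogue))


def test_selective_equals_monolithic_reference(double_well, make_cfg):
    """M=1 selective GaMD is bit-identical to the independent single-boost
    reference over the full staged protocol."""
    cfg = make_cfg(1, seed=11)
    stages = StageLengths(cmd=2000, search=3000, production=10_000)
    rs = _surface_region_set(double_well)
    sel = run_protocol(double_well, rs, cfg, stages)
    (E, k), _cmd, _search, prod = run_standard_gamd(
        double_well, cfg, stages, sigma0=10.0
    )
    p = sel.params["all"]
    assert (p.E, p.k) == (E, k)
    assert np.array_equal(sel.production.positions, prod.positions)
    assert np.array_equal(sel.production.total_dv, prod.total_dv)
    assert np.array_equal(sel.production.term_energies, prod.term_energies)


def test_recorded_boost_replays_from_recorded_energy(double_well, make_cfg):
    """Per-frame dV equals boost_energy applied to the per-frame region V."""
    rs = _surface_region_set(double_well)
    res = run_protocol(
        double_well, rs, make_cfg(1, seed=2),
        StageLengths(cmd=2000, search=2000, production=5000),
    )
    p = res.params["all"]
    v = res.production.term_energies[:, 0]
    replay = np.array([boost_energy(x, p) for x in v])
    assert np.array_equal(replay, res.production.total_dv)


def test_search_length_zero_uses_cmd_statistics(double_well, make_cfg):
    rs = _surface_region_set(double_well)
    res = run_protocol(
        double_well, rs, make_cfg(1, seed=5),
        StageLengths(cmd=3000, search=0, production=100),
    )
    assert res.search is None
    expect = estimate_parameters(res.stats["all"], 10.0)
    assert res.params["all"] == expect


def test_stage_length_validation():
    with pytest.raises(ValueError):
        StageLengths(cmd=0, search=10, production=10)
    with pytest.raises(ValueError):
        StageLengths(cmd=10, search=-1, production=10)
    with pytest.raises(ValueError):
        StageLengths(cmd=10, search=10, production=0)


def test_update_interval_exceeding_search_is_an_error(double_well, make_cfg):
    rs = _surface_region_set(double_well)
    with pytest.raises(ValueError, match="update interval"):
        run_protocol(
            double_well, rs, make_cfg(1),
            StageLengths(cmd=100, search=50, production=100),
            update_interval=60,
        )


def _dual_region_set(model):
    cat = list(model.catalogue)
    specs = [
        AccelerationRegionSpec(
            "solute", frozenset({"b0", "d0", "0-0", "0-1"}), dual_boost=True
        ),
        AccelerationRegionSpec(
            "solvent", frozenset({"b1", "d1", "1-1"}), dual_boost=True
        ),
    ]
    return validate_regions(specs, cat)


def test_dual_boost_composition(small_mixture):
    model = DecomposedSystem(small_mixture, dual_boost=True)
    rs = _dual_region_set(model)
    energies, _ = model.term_energies_forces(small_mixture.positions)
    labels = [t.label for t in model.catalogue]

    p_tot = BoostParameters(E=200.0, k=0.01, k0=0.5, sigma0=1.0)
    p_dih = BoostParameters(E=50.0, k=0.05, k0=0.5, sigma0=1.0)
    out = apply_dual_boost(
        energies, rs,
        params={"solute": p_tot, "solvent": p_tot},
        dihedral_params={"solute": p_dih, "solvent": p_dih},
    )
    v_rest = sum(energies[labels.index(l)] for l in ("b0", "0-0", "0-1"))
    v_dih = energies[labels.index("d0")]
    assert out["solute"][0] == pytest.approx(boost_energy(v_rest, p_tot))
    assert out["solute"][1] == pytest.approx(boost_energy(v_dih, p_dih))

    # solvent has no torsions: dihedral sub-term energy is identically zero
    assert energies[labels.index("d1")] == 0.0
    assert out["solvent"][1] == boost_energy(0.0, p_dih)

    # k_dih = 0 reduces to the single-boost result
    off = BoostParameters.none()
    single = apply_dual_boost(
        energies, rs, params={"solute": p_tot}, dihedral_params={"solute": off}
    )
    assert single["solute"][1] == 0.0
    assert single["solute"][0] == pytest.approx(boost_energy(v_rest, p_tot))


def test_dual_boost_without_torsions_warns(small_mixture):
    model = DecomposedSystem(small_mixture, dual_boost=False)
    with pytest.warns(UserWarning, match="no\\s+dihedral"):
        validate_regions(
            [AccelerationRegionSpec("s", frozenset({"b1"}), dual_boost=True)],
            list(model.catalogue),
        )


def test_unaccelerated_region_gets_no_boost(double_well, make_cfg):
    spec = AccelerationRegionSpec(
        "all", frozenset({"b0"}), accelerate=False
    )
    rs = validate_regions([spec], list(double_well.catalogue))
    provider = SelectiveBoostProvider(
        rs, {"all": BoostParameters(E=1e6, k=0.1, k0=1.0, sigma0=1.0)}
    )
    traj = run(double_well, make_cfg(500, seed=1), bias=provider)
    assert np.all(traj.total_dv == 0.0)


def test_boosted_double_well_crosses_barrier_more(double_well, make_cfg):
    """The boost enhances well-to-well exchange relative to cMD."""
    def crossings(traj):
        s = np.sign(traj.positions[:, 0])
        s = s[s != 0]
        return int((s[1:] != s[:-1]).sum())

    cfg = make_cfg(40_000, seed=9, stride=10)
    plain = run(double_well, cfg)
    rs = _surface_region_set(double_well)
    res = run_protocol(
        double_well, rs, make_cfg(1, seed=9, stride=10),
        StageLengths(cmd=5000, search=10_000, production=40_000),
    )
    assert crossings(res.production) > crossings(plain)
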