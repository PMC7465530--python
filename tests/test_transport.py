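"""Transport solver: unit conversions, domain building, analytic oracles."""

import numpy as np
import pytest
from scipy.special import erfc

from lpschip import transport as T

HOUR = 3600.0


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("c, mw, expected", [
    (10.0, 70.0, 1.4286e-4),   # the chip's LPS dose
    (0.0, 55.0, 0.0),
    (70.0, 70.0, 1.0e-3),
])
def test_mass_to_molar(c, mw, expected):
    assert T.mass_to_molar(c, mw) == pytest.approx(expected, rel=1e-4)


def test_mass_molar_round_trip():
    assert T.molar_to_mass(T.mass_to_molar(3.7, 82.0), 82.0) == pytest.approx(3.7)


def test_mass_to_molar_rejects_bad_mw():
    with pytest.raises(T.TransportError):
        T.mass_to_molar(10.0, 0.0)
    with pytest.raises(T.TransportError):
        T.mass_to_molar(-1.0, 70.0)


@pytest.mark.parametrize("p, x0, k, expected", [
    (3.70e-8, 2e-6, 1.0, 7.4e-14),   # endothelial monolayer
    (5.0e-8, 0.0, 1.0, 0.0),
    (1.0e-8, 1.0e-6, 1.0, 1.0e-14),
    (1.0e-8, 1.0e-6, 2.0, 2.0e-14),
])
def test_barrier_diffusivity(p, x0, k, expected):
    assert T.barrier_diffusivity(p, x0, k) == pytest.approx(expected, rel=1e-12)


def test_barrier_diffusivity_rejects_negative():
    with pytest.raises(T.TransportError):
        T.barrier_diffusivity(-1e-8, 2e-6)


# ---------------------------------------------------------------------------
# domain construction
# ---------------------------------------------------------------------------

def test_default_domain_partitions_cells():
    dom = T.build_domain(dx_um=1.0)
    counts = {r: int((dom.region == r).sum()) for r in T.REGIONS}
    assert counts == {"source": 500, "gel": 1000, "barrier": 2, "vessel": 1000}
    assert sum(counts.values()) == dom.n
    # property maps follow the regions
    assert np.all(dom.porosity[dom.mask("gel")] == 0.8)
    assert np.all(dom.porosity[~dom.mask("gel")] == 1.0)
    assert np.all(dom.diffusivity[dom.mask("barrier")] == pytest.approx(7.4e-14))


def test_resolved_barrier_needs_two_cells():
    with pytest.raises(T.TransportError, match="interface"):
        T.build_domain(dx_um=2.0, barrier_mode="resolved")


def test_interface_mode_has_no_barrier_cells():
    dom = T.build_domain(dx_um=2.0, barrier_mode="interface")
    assert not (dom.region == "barrier").any()
    assert dom.interface_conductance == pytest.approx(3.70e-8)
    # the marked face separates gel from vessel
    assert dom.region[dom.interface_index] == "gel"
    assert dom.region[dom.interface_index + 1] == "vessel"


# ---------------------------------------------------------------------------
# solver properties
# ---------------------------------------------------------------------------

def _uniform_domain(n, dx_um, d, phi=1.0):
    widths = np.full(n, dx_um)
    return T.Domain(x_um=np.cumsum(widths) - widths / 2,
                    dx_m=widths * 1e-6,
                    diffusivity=np.full(n, d),
                    porosity=np.full(n, phi),
                    region=np.array(["gel"] * n))


def test_uniform_initial_state_is_steady():
    dom = _uniform_domain(200, 5.0, 3e-11)
    res = T.simulate(dom, t_end_s=HOUR, dt_s=60.0, source_mode="diffusive",
                     c_init=np.full(200, 4.2))
    assert np.allclose(res.field.values, 4.2, rtol=1e-12)


def test_mass_conserved_to_tolerance():
    res = T.run_default_simulation()
    assert res.max_mass_drift <= 1e-3
    # direct solves actually conserve to machine precision
    assert res.max_mass_drift <= 1e-8


def test_field_nonnegative_and_bounded():
    res = T.run_default_simulation()
    assert res.field.values.min() >= 0.0
    assert res.field.values.max() <= 10.0 + 1e-9


@pytest.mark.parametrize("scheme", ["backward_euler", "crank_nicolson"])
def test_erfc_limit(scheme):
    """Barrier-free gel with a maintained source approaches the
    semi-infinite erfc profile."""
    d = 3.0e-11
    n, dx = 750, 2.0
    dom = _uniform_domain(n, dx, d)
    dom.region = np.array(["source"] + ["gel"] * (n - 1))
    c0 = 10.0
    init = np.zeros(n)
    init[0] = c0
    t_end = HOUR
    res = T.simulate(dom, t_end_s=t_end, dt_s=5.0, scheme=scheme,
                     source_mode="fixed", c_init=init,
                     store_times_s=np.array([t_end]))
    x = (dom.x_um - dom.x_um[0]) * 1e-6          # from the held cell centre
    analytic = c0 * erfc(x / (2 * np.sqrt(d * t_end)))
    sim = res.field.values[-1]
    interior = slice(1, 500)
    err = np.abs(sim[interior] - analytic[interior]) / c0
    assert err.max() <= 0.02


def test_two_compartment_membrane_decay():
    """Two well-mixed compartments across a membrane lose their
    concentration difference as exp(-t P (1/V1 + 1/V2))."""
    p = 3.7e-8
    w1, w2 = 200e-6, 300e-6
    big_d = 1.0e-6   # effectively well-mixed cells
    dom = T.Domain(x_um=np.array([100.0, 350.0]),
                   dx_m=np.array([w1, w2]),
                   diffusivity=np.array([big_d, big_d]),
                   porosity=np.array([1.0, 1.0]),
                   region=np.array(["source", "vessel"]),
                   interface_conductance=p, interface_index=0)
    rate = p * (1 / w1 + 1 / w2)
    t_end = 2.0 / rate
    res = T.simulate(dom, t_end_s=t_end, dt_s=5.0, source_mode="diffusive",
                     c_init=np.array([10.0, 0.0]),
                     store_times_s=np.array([0.0, t_end]))
    dc0 = res.field.values[0, 0] - res.field.values[0, 1]
    dc1 = res.field.values[-1, 0] - res.field.values[-1, 1]
    rate_sim = -np.log(dc1 / dc0) / t_end
    assert rate_sim == pytest.approx(rate, rel=0.02)


def test_resolved_and_interface_barriers_agree():
    """A resolved 2-um layer at K*P*x0 and a flux interface at P give the
    same vessel filling within 5%."""
    res_r = T.run_default_simulation(barrier_mode="resolved")
    res_i = T.run_default_simulation(barrier_mode="interface")
    for h in (4, 8, 12):
        vr = res_r.field.region_mean("vessel", h * HOUR)
        vi = res_i.field.region_mean("vessel", h * HOUR)
        assert vi == pytest.approx(vr, rel=0.05)


def test_grid_and_timestep_convergence():
    """Halving dx and dt moves the 4-h vessel mean by < 2%."""
    coarse = T.run_default_simulation(dx_um=1.0, dt_s=10.0, t_end_s=4 * HOUR)
    fine = T.run_default_simulation(dx_um=0.5, dt_s=5.0, t_end_s=4 * HOUR)
    vc = coarse.field.region_mean("vessel", 4 * HOUR)
    vf = fine.field.region_mean("vessel", 4 * HOUR)
    assert vf == pytest.approx(vc, rel=0.02)


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def default_run():
    return T.run_default_simulation()


def test_initial_profile_is_step(default_run):
    prof = default_run.field.line_profile(0.0)
    src = default_run.field.domain.mask("source")
    assert np.all(prof["concentration"].to_numpy()[src] == 10.0)
    assert np.all(prof["concentration"].to_numpy()[~src] == 0.0)


def test_profile_monotone_from_source_to_vessel(default_run):
    prof = default_run.field.line_profile(4 * HOUR)["concentration"].to_numpy()
    assert np.all(np.diff(prof) <= 1e-9)


def test_profile_drops_across_barrier(default_run):
    field = default_run.field
    dom = field.domain
    k = np.argmin(np.abs(field.times_s - 4 * HOUR))
    gel_edge = field.values[k, dom.mask("gel")][-1]
    ves_edge = field.values[k, dom.mask("vessel")][0]
    assert ves_edge < 0.5 * gel_edge


def test_region_mean_examples(default_run):
    f = default_run.field
    assert f.region_mean("vessel", 0.0) == 0.0
    gel = f.values[0, f.domain.mask("gel")]
    assert gel.min() <= f.region_mean("gel", 0.0) <= gel.max()
    with pytest.raises(T.TransportError):
        f.region_mean("lumen", 0.0)
    with pytest.raises(T.TransportError):
        f.line_profile(-5.0)


def test_vessel_mean_strictly_increases(default_run):
    series = default_run.region_series["vessel"].to_numpy()
    assert np.all(np.diff(series[1:]) > 0)


def test_gel_relative_range_non_increasing(default_run):
    rr = [default_run.field.relative_range("gel", h * HOUR) for h in (4, 8, 12)]
    assert rr[0] > rr[1] > rr[2]


def test_unit_conversion_round_trips_on_field(default_run):
    f = default_run.field
    back = f.to_unit("mol/m^3").to_unit("ug/mL")
    assert np.allclose(back.values, f.values, rtol=1e-12)


def test_divergent_parameters_rejected():
    with pytest.raises(T.TransportError):
        T.TransportParams(porosity=0.0)
    with pytest.raises(T.TransportError):
        T.TransportParams(d_gel=-1e-11)
    with pytest.raises(T.TransportError):
        T.ChipGeometry(gel_width_um=-5)
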