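"""Solute transport across a microfluidic chip cross-section.

Models time-dependent diffusion of LPS from a source media channel, through a
porous collagen-gel region and a thin endothelial barrier, into the blood-vessel
(BV) media channel, as a 1D finite-volume problem on the chip cross-section.

The porous region follows the diluted-species-in-porous-media formulation:
``phi * dC/dt = d/dx (D dC/dx)`` with porosity ``phi`` scaling the storage term
and the effective gel diffusivity used directly. The endothelial barrier is
either resolved as a thin layer of diffusivity ``D_b = K * P * x0`` or imposed
as an interface flux condition ``J = P * (C_gel - C_vessel)``; the two are
algebraically equivalent for a passive layer and the solver supports both.

All internal arithmetic is in SI (m, s, g/m^3 == ug/mL for mass concentration);
reported concentrations are ug/mL, with molar conversion helpers provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

logger = logging.getLogger(__name__)

UM = 1e-6  # metres per micrometre
HOUR = 3600.0

#: Region labels in source-to-vessel order.
REGIONS = ("source", "gel", "barrier", "vessel")


class TransportError(ValueError):
    """Invalid transport parameter or domain configuration."""


class NumericalFailure(RuntimeError):
    """The implicit solve produced a non-finite or divergent field."""


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def mass_to_molar(c_mass_ug_ml: float, mw_kda: float) -> float:
    """Convert a mass concentration (ug/mL) to molar (mol/m^3).

    1 ug/mL equals 1 g/m^3, so ``c [mol/m^3] = c [ug/mL] / (MW [g/mol])`` with
    ``MW [g/mol] = 1000 * MW [kDa]``. Ten ug/mL of a 70 kDa solute is therefore
    1.4286e-4 mol/m^3.
    """
    if mw_kda <= 0:
        raise TransportError(f"molecular weight must be positive, got {mw_kda} kDa")
    if c_mass_ug_ml < 0:
        raise TransportError(f"mass concentration must be >= 0, got {c_mass_ug_ml}")
    return c_mass_ug_ml / (mw_kda * 1e3)


def molar_to_mass(c_molar: float, mw_kda: float) -> float:
    """Inverse of :func:`mass_to_molar` (mol/m^3 -> ug/mL)."""
    if mw_kda <= 0:
        raise TransportError(f"molecular weight must be positive, got {mw_kda} kDa")
    return c_molar * mw_kda * 1e3


def barrier_diffusivity(permeability: float, thickness_m: float,
                        partition_coefficient: float = 1.0) -> float:
    """Effective layer diffusivity of a thin membrane, ``D = K * P * x0``.

    A permeability coefficient P (m/s) measured across a layer of thickness
    x0 corresponds to an apparent diffusivity ``K*P*x0`` inside the layer;
    with purely paracellular transport the partition coefficient K is 1.
    """
    if permeability < 0 or thickness_m < 0:
        raise TransportError("permeability and thickness must be >= 0")
    if partition_coefficient <= 0:
        raise TransportError("partition coefficient must be > 0")
    return partition_coefficient * permeability * thickness_m


# ---------------------------------------------------------------------------
# geometry and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChipGeometry:
    """1D cross-section layout: source channel | gel | barrier | vessel channel.

    Widths are in micrometres. The endothelial barrier sits at the gel/vessel
    interface; ``barrier_position_um`` is the coordinate of that interface
    measured from the outer wall of the source channel.
    """

    source_channel_width_um: float = 500.0
    gel_width_um: float = 1000.0
    vessel_channel_width_um: float = 1000.0
    channel_height_um: float = 250.0
    barrier_thickness_um: float = 2.0

    def __post_init__(self) -> None:
        for name in ("source_channel_width_um", "gel_width_um",
                     "vessel_channel_width_um", "channel_height_um",
                     "barrier_thickness_um"):
            if getattr(self, name) <= 0:
                raise TransportError(f"{name} must be positive")
        if self.barrier_thickness_um >= 0.5 * self.gel_width_um:
            raise TransportError("barrier must be thin relative to the gel")

    @property
    def barrier_position_um(self) -> float:
        return self.source_channel_width_um + self.gel_width_um

    @property
    def total_width_um(self) -> float:
        return (self.source_channel_width_um + self.gel_width_um
                + self.barrier_thickness_um + self.vessel_channel_width_um)


@dataclass(frozen=True)
class TransportParams:
    """Physical transport parameters.

    Defaults are for 10 ug/mL LPS (~70 kDa) diffusing through 2.0 mg/mL
    collagen (porosity 0.8, D = 3.0e-11 m^2/s) across an endothelial
    monolayer of permeability 3.70e-8 m/s. ``d_barrier`` is derived as
    ``K*P*x0`` unless given explicitly.
    """

    d_gel: float = 3.0e-11            # m^2/s
    porosity: float = 0.8             # of the collagen gel
    permeability: float = 3.70e-8     # m/s, endothelial monolayer
    partition_coefficient: float = 1.0
    d_barrier: float | None = None    # m^2/s; derived from P when None
    d_channel: float = 4.0e-11        # m^2/s, free medium in the channels
    c_source_ug_ml: float = 10.0
    mw_kda: float = 70.0

    def __post_init__(self) -> None:
        if not (0.0 < self.porosity <= 1.0):
            raise TransportError(f"porosity must be in (0, 1], got {self.porosity}")
        for name in ("d_gel", "d_channel"):
            if getattr(self, name) <= 0:
                raise TransportError(f"{name} must be positive")
        if self.permeability < 0:
            raise TransportError("permeability must be >= 0")
        if self.d_barrier is not None and self.d_barrier <= 0:
            raise TransportError("d_barrier must be positive when given")
        if self.c_source_ug_ml < 0:
            raise TransportError("source concentration must be >= 0")
        if self.mw_kda <= 0:
            raise TransportError("molecular weight must be positive")

    def barrier_d(self, geometry: ChipGeometry) -> float:
        if self.d_barrier is not None:
            return self.d_barrier
        return barrier_diffusivity(self.permeability,
                                   geometry.barrier_thickness_um * UM,
                                   self.partition_coefficient)

    @property
    def c_source_molar(self) -> float:
        return mass_to_molar(self.c_source_ug_ml, self.mw_kda)


# ---------------------------------------------------------------------------
# discretized domain
# ---------------------------------------------------------------------------

@dataclass
class Domain:
    """Cell-centred finite-volume discretization of the cross-section.

    ``x_um`` holds cell-centre coordinates, ``dx_m`` cell widths,
    ``diffusivity``/``porosity`` per-cell property maps and ``region``
    a label per cell. An optional ``interface_conductance`` (m/s) between
    cells ``interface_index`` and ``interface_index + 1`` replaces a
    resolved barrier layer (interface mode).
    """

    x_um: np.ndarray
    dx_m: np.ndarray
    diffusivity: np.ndarray
    porosity: np.ndarray
    region: np.ndarray                       # array of region-label strings
    geometry: ChipGeometry | None = None
    params: TransportParams | None = None
    interface_conductance: float | None = None
    interface_index: int | None = None

    def mask(self, label: str) -> np.ndarray:
        m = self.region == label
        if not m.any():
            raise TransportError(f"unknown or empty region {label!r}; "
                                 f"have {sorted(set(self.region.tolist()))}")
        return m

    @property
    def n(self) -> int:
        return self.x_um.size

    def conductances(self) -> np.ndarray:
        """Face conductances g_i (m/s) linking cells i and i+1.

        Series (harmonic) composition of the half-cell resistances on either
        side of each face; in interface mode the membrane permeability is
        added in series at the marked face.
        """
        half = 0.5 * self.dx_m / self.diffusivity     # resistance of half cell
        res = half[:-1] + half[1:]
        if self.interface_conductance is not None:
            res[self.interface_index] += 1.0 / self.interface_conductance
        return 1.0 / res


def build_domain(geometry: ChipGeometry | None = None,
                 params: TransportParams | None = None,
                 dx_um: float = 1.0,
                 barrier_mode: str = "resolved") -> Domain:
    """Discretize the chip cross-section.

    ``barrier_mode="resolved"`` represents the endothelial barrier as grid
    cells of diffusivity ``K*P*x0 / x0``-equivalent (i.e. ``d_barrier``); it
    requires at least two cells inside the layer. ``barrier_mode="interface"``
    collapses the barrier to a flux condition ``J = P (C_gel - C_vessel)`` at
    the gel/vessel face, which permits coarse grids.
    """
    geometry = geometry or ChipGeometry()
    params = params or TransportParams()
    if dx_um <= 0:
        raise TransportError("dx_um must be positive")
    if barrier_mode not in ("resolved", "interface"):
        raise TransportError(f"unknown barrier_mode {barrier_mode!r}")

    def cells(width_um: float, target_dx: float) -> np.ndarray:
        n = max(1, int(round(width_um / target_dx)))
        return np.full(n, width_um / n)

    src = cells(geometry.source_channel_width_um, dx_um)
    gel = cells(geometry.gel_width_um, dx_um)
    ves = cells(geometry.vessel_channel_width_um, dx_um)

    if barrier_mode == "resolved":
        n_bar = int(round(geometry.barrier_thickness_um / dx_um))
        if n_bar < 2:
            raise TransportError(
                f"dx_um={dx_um} places {n_bar} cell(s) inside the "
                f"{geometry.barrier_thickness_um} um barrier; use dx_um <= "
                f"{geometry.barrier_thickness_um / 2} or barrier_mode='interface'")
        bar = np.full(n_bar, geometry.barrier_thickness_um / n_bar)
        widths = np.concatenate([src, gel, bar, ves])
        region = np.array(["source"] * src.size + ["gel"] * gel.size
                          + ["barrier"] * bar.size + ["vessel"] * ves.size)
        d_map = {"source": params.d_channel, "gel": params.d_gel,
                 "barrier": params.barrier_d(geometry), "vessel": params.d_channel}
        iface_g = iface_i = None
    else:
        widths = np.concatenate([src, gel, ves])
        region = np.array(["source"] * src.size + ["gel"] * gel.size
                          + ["vessel"] * ves.size)
        d_map = {"source": params.d_channel, "gel": params.d_gel,
                 "vessel": params.d_channel}
        iface_g = params.partition_coefficient * params.permeability
        iface_i = src.size + gel.size - 1

    diffusivity = np.array([d_map[r] for r in region])
    porosity = np.where(region == "gel", params.porosity, 1.0)
    dx_m = widths * UM
    x_um = np.cumsum(widths) - widths / 2
    return Domain(x_um=x_um, dx_m=dx_m, diffusivity=diffusivity,
                  porosity=porosity, region=region, geometry=geometry,
                  params=params, interface_conductance=iface_g,
                  interface_index=iface_i)


# ---------------------------------------------------------------------------
# concentration field and probes
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationField:
    """Time-indexed concentration snapshots on the domain grid.

    ``values[k, i]`` is the concentration at ``times_s[k]``, cell ``i``,
    in the units named by ``unit`` ("ug/mL" or "mol/m^3").
    """

    x_um: np.ndarray
    times_s: np.ndarray
    values: np.ndarray
    unit: str = "ug/mL"
    domain: Domain | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (self.times_s.size, self.x_um.size):
            raise TransportError("values must be (n_times, n_cells)")

    def to_unit(self, unit: str) -> "ConcentrationField":
        if unit == self.unit:
            return self
        mw = self.domain.params.mw_kda if self.domain and self.domain.params else 70.0
        if (self.unit, unit) == ("ug/mL", "mol/m^3"):
            vals = self.values / (mw * 1e3)
        elif (self.unit, unit) == ("mol/m^3", "ug/mL"):
            vals = self.values * (mw * 1e3)
        else:
            raise TransportError(f"cannot convert {self.unit!r} -> {unit!r}")
        return ConcentrationField(self.x_um, self.times_s, vals, unit, self.domain)

    def _time_index(self, t_s: float) -> int:
        if t_s < 0:
            raise TransportError(f"time must be >= 0, got {t_s}")
        return int(np.argmin(np.abs(self.times_s - t_s)))

    def line_profile(self, t_s: float) -> pd.DataFrame:
        """Concentration along the cross-section at the stored time nearest t_s.

        Positions run from the source channel toward the vessel channel, so the
        profile exhibits the near-discontinuous drop across the barrier.
        """
        k = self._time_index(t_s)
        return pd.DataFrame({"position_um": self.x_um,
                             "concentration": self.values[k],
                             "time_s": self.times_s[k]})

    def region_mean(self, region: str, t_s: float) -> float:
        """Arithmetic mean concentration over a region at the nearest stored time."""
        if self.domain is None:
            raise TransportError("field has no domain; region masks unavailable")
        k = self._time_index(t_s)
        m = self.domain.mask(region)
        return float(self.values[k, m].mean())

    def relative_range(self, region: str, t_s: float) -> float:
        """(max - min) / mean over a region — the profile-flatness measure."""
        if self.domain is None:
            raise TransportError("field has no domain; region masks unavailable")
        k = self._time_index(t_s)
        v = self.values[k, self.domain.mask(region)]
        return float((v.max() - v.min()) / v.mean())


@dataclass
class SimulationResult:
    """Field snapshots plus dense per-region mean time series and mass audit."""

    field: ConcentrationField
    region_series: pd.DataFrame     # columns: time_s, one per region label
    mass_audit: pd.DataFrame        # columns: time_s, total_mass, rel_drift

    @property
    def max_mass_drift(self) -> float:
        return float(np.abs(self.mass_audit["rel_drift"]).max())


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def simulate(domain: Domain,
             t_end_s: float = 12 * HOUR,
             dt_s: float = 10.0,
             scheme: str = "backward_euler",
             source_mode: str = "well_mixed",
             c_init: np.ndarray | None = None,
             store_times_s: np.ndarray | None = None,
             store_every_s: float = 600.0) -> SimulationResult:
    """Integrate the diffusion problem with no-flux outer boundaries.

    The spatial operator is conservative finite-volume with harmonic-mean face
    conductances; time stepping is unconditionally stable implicit (backward
    Euler by default, ``scheme="crank_nicolson"`` optional). The initial state
    is source channel at ``c_source`` and zero elsewhere unless ``c_init``
    is supplied.

    ``source_mode`` controls the source channel:

    - ``"well_mixed"`` (default): finite reservoir, homogenised every step;
    - ``"diffusive"``: plain diffusive region, no special treatment;
    - ``"fixed"``: held at the initial source concentration (Dirichlet-like).

    Porosity-weighted total mass is audited at every stored time; a relative
    drift above 1e-3 (or any non-finite value) raises :class:`NumericalFailure`.
    """
    if dt_s <= 0:
        raise TransportError("dt_s must be positive")
    if t_end_s <= 0:
        raise TransportError("t_end_s must be positive")
    if scheme not in ("backward_euler", "crank_nicolson"):
        raise TransportError(f"unknown scheme {scheme!r}")
    if source_mode not in ("well_mixed", "diffusive", "fixed"):
        raise TransportError(f"unknown source_mode {source_mode!r}")

    n = domain.n
    src_mask = domain.region == "source"
    if c_init is None:
        c_source = domain.params.c_source_ug_ml if domain.params else 10.0
        c = np.where(src_mask, c_source, 0.0).astype(float)
    else:
        c = np.asarray(c_init, dtype=float).copy()
        if c.shape != (n,):
            raise TransportError(f"c_init must have shape ({n},)")

    g = domain.conductances()
    cap = domain.porosity * domain.dx_m          # storage capacity per cell
    # L c = flux divergence (negative semi-definite)
    main = np.zeros(n)
    main[:-1] -= g
    main[1:] -= g
    lap = sp.diags([g, main, g], [-1, 0, 1], format="csc")
    ident_cap = sp.diags(cap / dt_s, format="csc")
    if scheme == "backward_euler":
        lhs = (ident_cap - lap).tolil()
        rhs_op = ident_cap.tolil()
    else:
        lhs = (ident_cap - 0.5 * lap).tolil()
        rhs_op = (ident_cap + 0.5 * lap).tolil()
    if source_mode == "fixed" and src_mask.any():
        # Dirichlet rows: held cells satisfy c_new = c_old exactly, so the
        # flux into their neighbours sees the full held concentration
        for i in np.flatnonzero(src_mask):
            lhs.rows[i], lhs.data[i] = [i], [1.0]
            rhs_op.rows[i], rhs_op.data[i] = [i], [1.0]
    lhs = lhs.tocsc()
    rhs_op = rhs_op.tocsc()
    lu = spla.splu(lhs)

    n_steps = int(np.ceil(t_end_s / dt_s - 1e-12))
    if store_times_s is None:
        store_times_s = np.arange(0.0, t_end_s + 0.5 * dt_s, store_every_s)
        for t in (0.0, 4 * HOUR, 8 * HOUR, 12 * HOUR):
            if t <= t_end_s and not np.any(np.isclose(store_times_s, t)):
                store_times_s = np.append(store_times_s, t)
        store_times_s = np.unique(store_times_s)
    store_times_s = np.asarray(store_times_s, dtype=float)
    store_steps = {int(round(t / dt_s)) for t in store_times_s}

    labels = [r for r in REGIONS if (domain.region == r).any()]
    masks = {r: domain.region == r for r in labels}
    mass0 = float((cap * c).sum())

    snaps, snap_times = [], []
    series_rows = []
    audit_rows = []

    def record(step: int) -> None:
        t = step * dt_s
        row = {"time_s": t}
        row.update({r: float(c[masks[r]].mean()) for r in labels})
        series_rows.append(row)
        if step in store_steps:
            snaps.append(c.copy())
            snap_times.append(t)
            mass = float((cap * c).sum())
            drift = (mass - mass0) / mass0 if mass0 > 0 else 0.0
            audit_rows.append({"time_s": t, "total_mass": mass,
                               "rel_drift": drift})
            logger.debug("t=%.0f s mass=%.6e drift=%.3e", t, mass, drift)

    record(0)
    for step in range(1, n_steps + 1):
        c = lu.solve(rhs_op @ c)
        if source_mode == "well_mixed" and src_mask.any():
            c[src_mask] = (cap[src_mask] * c[src_mask]).sum() / cap[src_mask].sum()
        if not np.all(np.isfinite(c)):
            raise NumericalFailure(f"non-finite concentration at step {step}")
        record(step)

    field = ConcentrationField(domain.x_um, np.array(snap_times),
                               np.vstack(snaps), "ug/mL", domain)
    audit = pd.DataFrame(audit_rows)
    result = SimulationResult(field=field,
                              region_series=pd.DataFrame(series_rows),
                              mass_audit=audit)
    if source_mode in ("well_mixed", "diffusive"):
        if result.max_mass_drift > 1e-3:
            raise NumericalFailure(
                f"mass drift {result.max_mass_drift:.2e} exceeds 1e-3; "
                f"diagnostics: dt={dt_s}, n={n}, scheme={scheme}")
    return result


def run_default_simulation(geometry: ChipGeometry | None = None,
                           params: TransportParams | None = None,
                           dx_um: float = 1.0, dt_s: float = 10.0,
                           t_end_s: float = 12 * HOUR,
                           barrier_mode: str = "resolved",
                           source_mode: str = "well_mixed",
                           scheme: str = "backward_euler") -> SimulationResult:
    """Build the default domain and run the full 12 h transport solve."""
    domain = build_domain(geometry, params, dx_um=dx_um, barrier_mode=barrier_mode)
    return simulate(domain, t_end_s=t_end_s, dt_s=dt_s, scheme=scheme,
                    source_mode=source_mode)
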