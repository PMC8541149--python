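"""Explicit transient integrator for the reduced-order coaxial-tube model.

The spinal canal is collapsed onto a 1-D axial grid carrying three coupled
subsystems: CSF in the subarachnoid space (SAS), fluid in the syrinx cavity,
and the spinal cord as an axially elastic rod.  On a staggered grid
(pressures, areas and cord displacement at cell centers; axial fluid
velocities at faces) the governing equations are, per unit length:

  SAS continuity     (A_s0/K_a) dp_s/dt + da_s/dt + d(A_s0 u_s)/dx = 0
  SAS momentum       rho A_s0 du_s/dt = -A_s0 dp_s/dx - D_s u_s
  syrinx continuity  (A_f0/K_a) dp_f/dt + da_f/dt + d(A_f0 u_f)/dx = 0
  syrinx momentum    rho A_f0 du_f/dt = -A_f0 dp_f/dx - D_f (u_f - v_c)
  cord momentum      rho_c A_c dv_c/dt = d(E A_c dw/dx)/dx
                       + (p_f - p_s) dA_f0/dx + D_f (u_f - v_c)
                       - 2 nu A_c dp_s/dx + (1 - 2 nu) p_s dA_c/dx
  tube laws          a_f = C_f (p_f - p_s)
                     a_s = -a_f + 2 nu A_c dw/dx + w dA_c/dx
                           - C_w (p_ext - p_s)

with closed fluid ends (u_s = 0 at both canal termini, u_f = 0 at the
cavity termini) and the cord pinned axially at both ends (w = 0 at the
boundary faces).  The pressure forces on the cord are the exact discrete
adjoints of the cord terms in the SAS tube law (Poisson radial squeeze plus
taper advection of the immersed rod), so pressure-cord energy exchange is
conservative and the syrinx-free cord is loaded on the deviatoric
(1 - 2 nu) p scale by the pressurization of a tapering canal.  The
transmural end-cap force (p_f - p_s) dA_f0/dx is what concentrates load at
the syrinx termini — the slosh mechanism under scrutiny.

Time integration is an explicit staggered (leapfrog-type) scheme: face
velocities from pressure gradients and drag (drag semi-implicit, preserving
exact linearity), then center pressures from the local 2x2
continuity/tube-law relations, then cord displacement.  Entirely
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np

from .configurations import ModelConfig
from .errors import InstabilityError, ValidationError
from .materials import (
    MM,
    CoefficientField,
    ExcitationSpec,
    MaterialSet,
    NumericsOptions,
    epidural_pressure,
    epidural_pressure_rate,
    korteweg_speed,
)

OUTPUT_FIELDS = ("p_s", "p_f", "u_s", "u_f", "w", "v_c")


@dataclass
class DiscreteSystem:
    """Assembled staggered-grid system ready for time integration (SI units)."""

    config: ModelConfig
    coeffs: CoefficientField
    materials: MaterialSet
    numerics: NumericsOptions
    x: np.ndarray          # cell centers [m]
    dx: float
    A_s0: np.ndarray       # SAS rest area at centers [m^2]
    A_f0: np.ndarray       # syrinx rest area at centers [m^2]
    A_c: np.ndarray        # cord annulus rest area at centers [m^2]
    A_s0_f: np.ndarray     # SAS area at faces
    A_f0_flux: np.ndarray  # syrinx area at faces, zero at cavity termini
    A_f0_geo: np.ndarray   # syrinx area at faces incl. one-cell end taper
    A_c_f: np.ndarray      # cord area at faces
    fluid_center: np.ndarray  # bool, syrinx present at center
    fluid_face: np.ndarray    # bool, syrinx fluid can cross this face
    exc_mask: np.ndarray      # bool, epidural pressure acts on this center
    dt: float
    duration: float

    @property
    def n_centers(self) -> int:
        return len(self.x)


@dataclass
class SolverState:
    """Instantaneous fields during integration (SI units)."""

    t: float
    p_s: np.ndarray
    p_f: np.ndarray
    u_s: np.ndarray   # at faces
    u_f: np.ndarray   # at faces
    w: np.ndarray
    v_c: np.ndarray
    drag_exchange: np.ndarray  # per-face drag force density fluid->cord [N/m]

    def a_f(self, coeffs: CoefficientField) -> np.ndarray:
        return coeffs.C_f * (self.p_f - self.p_s)


@dataclass
class SimulationResult:
    """Stored field histories (output stride) plus stride-independent maxima."""

    x_mm: np.ndarray
    t: np.ndarray
    fields: dict                 # name -> (n_times, n_centers) arrays, SI
    raw_peak_stress: np.ndarray  # per-center running max of |E_cord dw/dx| [Pa]
    audit: dict                  # t, injected, compressibility, cord_strain [m^3]
    meta: dict

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("x_mm", data=self.x_mm)
            f.create_dataset("t", data=self.t)
            for k, v in self.fields.items():
                f.create_dataset(k, data=v)
            f.create_dataset("raw_peak_stress", data=self.raw_peak_stress)
            g = f.create_group("audit")
            for k, v in self.audit.items():
                g.create_dataset(k, data=v)
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path: str) -> "SimulationResult":
        with h5py.File(path, "r") as f:
            fields = {k: f[k][()] for k in OUTPUT_FIELDS if k in f}
            audit = {k: f["audit"][k][()] for k in f["audit"]}
            meta = dict(f.attrs)
            return cls(
                x_mm=f["x_mm"][()],
                t=f["t"][()],
                fields=fields,
                raw_peak_stress=f["raw_peak_stress"][()],
                audit=audit,
                meta=meta,
            )


def _face_average(c: np.ndarray, edge: str = "copy") -> np.ndarray:
    """Center values -> faces by arithmetic mean; edges copy or zero."""
    f = np.empty(len(c) + 1)
    f[1:-1] = 0.5 * (c[:-1] + c[1:])
    if edge == "copy":
        f[0], f[-1] = c[0], c[-1]
    else:
        f[0] = f[-1] = 0.0
    return f


def assemble(
    config: ModelConfig,
    coeffs: CoefficientField,
    materials: MaterialSet | None = None,
    numerics: NumericsOptions | None = None,
) -> DiscreteSystem:
    """Build the staggered discrete system from a configuration."""
    materials = materials or MaterialSet()
    numerics = numerics or NumericsOptions()
    materials.validate()
    numerics.validate()
    coeffs.validate()
    anat = config.anatomy
    x_mm = anat.x_mm
    dxs = np.diff(x_mm)
    if np.any(np.abs(dxs - dxs[0]) > 1e-9):
        raise ValidationError("assemble requires a uniform grid")
    if len(coeffs.C_f) != len(x_mm) or len(coeffs.C_w) != len(x_mm):
        raise ValidationError("coefficient arrays do not match the grid")
    dx = float(dxs[0]) * MM

    A_s0 = anat.area_sas_mm2 * MM**2
    A_f0 = config.area_syrinx_mm2 * MM**2
    A_c = config.area_cord_annulus_mm2 * MM**2
    if np.any(A_s0 <= 0) or np.any(A_c <= 0):
        raise ValidationError("SAS and cord areas must be strictly positive")

    fluid_center = A_f0 > 0
    fluid_face = np.zeros(len(x_mm) + 1, dtype=bool)
    fluid_face[1:-1] = fluid_center[:-1] & fluid_center[1:]

    A_f0_pad = np.concatenate([[0.0], A_f0, [0.0]])
    A_f0_geo = 0.5 * (A_f0_pad[:-1] + A_f0_pad[1:])  # tapers to 0 over one cell
    A_f0_flux = np.where(fluid_face, A_f0_geo, 0.0)

    system = DiscreteSystem(
        config=config,
        coeffs=coeffs,
        materials=materials,
        numerics=numerics,
        x=x_mm * MM,
        dx=dx,
        A_s0=A_s0,
        A_f0=A_f0,
        A_c=A_c,
        A_s0_f=_face_average(A_s0),
        A_f0_flux=A_f0_flux,
        A_f0_geo=A_f0_geo,
        A_c_f=_face_average(A_c),
        fluid_center=fluid_center,
        fluid_face=fluid_face,
        exc_mask=anat.excitation_mask.copy(),
        dt=0.0,
        duration=numerics.duration_s,
    )
    system.dt = stable_timestep(system)
    return system


def max_wave_speed(system: DiscreteSystem) -> float:
    """Fastest characteristic speed in the assembled system [m/s].

    Spans the artificial-compressibility sound speed sqrt(K_a/rho), the cord
    bar speed sqrt(E/rho_c) (including its pressure-coupling stiffening), and
    the Korteweg speeds of both compliant tubes.
    """
    m = system.materials
    K_a = system.coeffs.K_a
    speeds = [math.sqrt(K_a / m.rho_csf), math.sqrt(m.E_cord / m.rho_cord)]
    # cord stiffened by the Poisson pressure coupling through the SAS storage
    alpha = system.A_s0 / K_a + system.coeffs.C_w + system.coeffs.C_f
    E_coupled = m.E_cord + (2 * m.nu_cord) ** 2 * np.max(system.A_c**2 / (alpha * system.A_c))
    speeds.append(math.sqrt(E_coupled / m.rho_cord))
    C_sas = system.A_s0 / K_a + system.coeffs.C_w
    speeds.append(float(np.max(korteweg_speed(system.A_s0, C_sas, m.rho_csf))))
    if system.fluid_center.any():
        sel = system.fluid_center
        C_syr = system.A_f0[sel] / K_a + system.coeffs.C_f[sel]
        speeds.append(float(np.max(korteweg_speed(system.A_f0[sel], C_syr, m.rho_csf))))
    c_max = max(speeds)
    if not np.isfinite(c_max) or c_max <= 0:
        raise ValidationError("degenerate areas or coefficients in CFL estimate")
    return c_max


def stable_timestep(system: DiscreteSystem, safety: float | None = None) -> float:
    """CFL-limited time step dt = safety * dx / c_max."""
    if safety is None:
        safety = system.numerics.cfl_safety
    if safety <= 0:
        raise ValidationError("CFL safety factor must be positive")
    return safety * system.dx / max_wave_speed(system)


def run(
    system: DiscreteSystem,
    excitation: ExcitationSpec | None = None,
    store_fields: bool = True,
) -> SimulationResult:
    """Time-integrate the assembled system under the epidural pulse.

    Running stress maxima are updated every step regardless of the output
    stride, so peak maps are stride-independent.  Raises InstabilityError
    (with step and station) if any field turns non-finite.
    """
    excitation = excitation or ExcitationSpec()
    excitation.validate()
    m = system.materials
    co = system.coeffs
    dt, dx = system.dt, system.dx
    if dt <= 0:
        raise ValidationError("time step not set; assemble() first")
    if system.duration < excitation.pulse_duration_s:
        raise ValidationError("simulated duration must cover the pulse")
    n_steps = int(math.ceil(system.duration / dt))
    stride = max(1, int(round(system.numerics.output_stride_s / dt)))

    nc = system.n_centers
    x_mm = system.x / MM
    p_s = np.zeros(nc)
    p_f = np.zeros(nc)
    w = np.zeros(nc)
    v_c = np.zeros(nc)
    u_s = np.zeros(nc + 1)
    u_f = np.zeros(nc + 1)

    E, nu = m.E_cord, m.nu_cord
    rho, rho_c = m.rho_csf, m.rho_cord
    ff = system.fluid_face
    fc = system.fluid_center
    A_s0f_in = system.A_s0_f[1:-1]
    A_f0_flux = system.A_f0_flux
    kappa_f = np.zeros(nc + 1)
    kappa_f[ff] = dt * co.D_f / (rho * A_f0_flux[ff])
    kappa_s = dt * co.D_s / (rho * A_s0f_in)
    dA_f0dx = (system.A_f0_geo[1:] - system.A_f0_geo[:-1]) / dx
    dA_cdx = (system.A_c_f[1:] - system.A_c_f[:-1]) / dx
    # linear artificial viscosity nu_art = a * c_max * dx damping grid-scale
    # ringing; explicit diffusion number a * CFL < 1/2 by construction
    visc = system.numerics.artificial_viscosity * max_wave_speed(system) * dx
    dcoef = dt * visc / dx**2

    # pressure-update 2x2 coefficients
    alpha = system.A_s0 / co.K_a + co.C_w + co.C_f
    beta = system.A_f0 / co.K_a + co.C_f
    det = np.where(fc, alpha * beta - co.C_f**2, 1.0)  # 2x2 solve on fluid only
    inv_alpha = 1.0 / alpha
    exc = system.exc_mask.astype(float)
    inv_rhocA = 1.0 / (rho_c * system.A_c)
    EA_cf = E * system.A_c_f[1:-1]

    n_out = n_steps // stride + 1
    t_out = np.zeros(n_out)
    hist = {k: np.zeros((n_out, nc)) for k in OUTPUT_FIELDS} if store_fields else {}
    audit_t = np.zeros(n_out)
    audit_inj = np.zeros(n_out)
    audit_comp = np.zeros(n_out)
    audit_strain = np.zeros(n_out)
    audit_imp_cord = np.zeros(n_out)
    audit_imp_fluid = np.zeros(n_out)
    raw_peak = np.zeros(nc)
    imp_cord = 0.0   # accumulated drag impulse received by the cord
    imp_fluid = 0.0  # accumulated drag impulse given up by the syrinx fluid

    def record(i_out: int, t: float) -> None:
        t_out[i_out] = t
        if store_fields:
            hist["p_s"][i_out] = p_s
            hist["p_f"][i_out] = np.where(fc, p_f, p_s)
            hist["u_s"][i_out] = 0.5 * (u_s[:-1] + u_s[1:])
            uf_c = 0.5 * (u_f[:-1] + u_f[1:])
            hist["u_f"][i_out] = np.where(fc, uf_c, 0.0)
            hist["w"][i_out] = w
            hist["v_c"][i_out] = v_c
        p_ext = epidural_pressure(t, excitation) * exc
        audit_t[i_out] = t
        audit_inj[i_out] = np.sum(co.C_w * (p_ext - p_s)) * dx
        audit_comp[i_out] = np.sum((system.A_s0 * p_s + system.A_f0 * p_f) / co.K_a) * dx
        wf = _face_average(w, edge="zero")
        audit_strain[i_out] = 2 * nu * np.sum(system.A_c * (wf[1:] - wf[:-1])) + np.sum(
            w * dA_cdx
        ) * dx
        audit_imp_cord[i_out] = imp_cord
        audit_imp_fluid[i_out] = imp_fluid

    record(0, 0.0)
    i_out = 0
    t = 0.0
    # overflow on a divergent run is caught by the finiteness checks below
    err_state = np.errstate(over="ignore", invalid="ignore")
    err_state.__enter__()
    try:
        for step in range(1, n_steps + 1):
            t_mid = t + 0.5 * dt

            # --- face velocity updates (values at t + dt/2) ---
            dps = (p_s[1:] - p_s[:-1]) / dx
            u_s[1:-1] = (u_s[1:-1] - dt * dps / rho) / (1.0 + kappa_s)
            if dcoef > 0:
                u_s[1:-1] += dcoef * (u_s[2:] - 2 * u_s[1:-1] + u_s[:-2])
            v_cf = _face_average(v_c, edge="zero")
            dpf = (p_f[1:] - p_f[:-1]) / dx
            u_f_new = np.zeros(nc + 1)
            u_f_new[1:-1] = (u_f[1:-1] - dt * dpf / rho + kappa_f[1:-1] * v_cf[1:-1]) / (
                1.0 + kappa_f[1:-1]
            )
            u_f = np.where(ff, u_f_new, 0.0)
            if dcoef > 0:
                u_f[1:-1] += dcoef * (u_f[2:] - 2 * u_f[1:-1] + u_f[:-2])
                u_f = np.where(ff, u_f, 0.0)

            # drag force density fluid -> cord, used with opposite signs on the
            # two sides (momentum bookkeeping exact by construction)
            drag_face = np.where(ff, co.D_f * (u_f - v_cf), 0.0)
            drag_on_cord = 0.5 * (drag_face[:-1] + drag_face[1:])
            imp_cord += dt * dx * float(np.sum(drag_on_cord))
            imp_fluid += dt * dx * float(np.sum(drag_face))

            # --- cord velocity update ---
            # pinned at the boundary FACES via mirror ghosts (w_ghost = -w_edge),
            # matching the v_cf = 0 convention of the continuity coupling and
            # keeping the Dirichlet treatment second-order
            T = np.zeros(nc + 1)
            T[1:-1] = EA_cf * (w[1:] - w[:-1]) / dx
            T[0] = E * system.A_c_f[0] * (2.0 * w[0]) / dx
            T[-1] = E * system.A_c_f[-1] * (-2.0 * w[-1]) / dx
            elastic = (T[1:] - T[:-1]) / dx
            # Immersed-rod pressure force: Poisson radial squeeze plus lateral
            # pressure on the tapering cross-section.  Discretely the exact
            # negative adjoint of the cord terms in the SAS continuity update,
            # so pressure-cord energy exchange is conservative.
            g = _face_average(system.A_c * p_s)
            poisson = -2 * nu * (g[1:] - g[:-1]) / dx + p_s * dA_cdx
            endcap = (p_f - p_s) * dA_f0dx
            v_c = v_c + dt * (elastic + poisson + endcap + drag_on_cord) * inv_rhocA
            if dcoef > 0:
                v_c[1:-1] += dcoef * (v_c[2:] - 2 * v_c[1:-1] + v_c[:-2])
                v_c[0] += dcoef * (v_c[1] - 3 * v_c[0])    # mirror ghost -v_c[0]
                v_c[-1] += dcoef * (v_c[-2] - 3 * v_c[-1])

            # --- pressure updates (t -> t + dt) via local 2x2 tube-law systems ---
            # closed ends: u_s, u_f are identically zero on the boundary faces
            div_s = (system.A_s0_f[1:] * u_s[1:] - system.A_s0_f[:-1] * u_s[:-1]) / dx
            flux_f = A_f0_flux * u_f
            div_f = (flux_f[1:] - flux_f[:-1]) / dx
            v_cf_new = _face_average(v_c, edge="zero")
            div_vc = (v_cf_new[1:] - v_cf_new[:-1]) / dx
            pext_rate = epidural_pressure_rate(t_mid, excitation) * exc
            cord_area_rate = 2 * nu * system.A_c * div_vc + v_c * dA_cdx
            rhs1 = -div_s - cord_area_rate + co.C_w * pext_rate
            rhs2 = -div_f
            dp_s = np.where(fc, (beta * rhs1 + co.C_f * rhs2) / det, rhs1 * inv_alpha)
            dp_f = np.where(fc, (co.C_f * rhs1 + alpha * rhs2) / det, dp_s)
            p_s = p_s + dt * dp_s
            p_f = p_f + dt * dp_f

            # --- displacement and stress bookkeeping ---
            w = w + dt * v_c
            strain = np.zeros(nc)
            strain[1:-1] = (w[2:] - w[:-2]) / (2 * dx)
            strain[0] = (w[1] + w[0]) / (2 * dx)      # mirror ghost -w[0]
            strain[-1] = (-w[-1] - w[-2]) / (2 * dx)  # mirror ghost -w[-1]
            np.maximum(raw_peak, E * np.abs(strain), out=raw_peak)

            t = step * dt
            if step % 50 == 0 and not np.isfinite(p_s).all():
                k = int(np.argmax(~np.isfinite(p_s)))
                raise InstabilityError(step, k, float(x_mm[k]), "p_s")
            if step % stride == 0 and i_out + 1 < n_out:
                i_out += 1
                record(i_out, t)

    finally:
        err_state.__exit__(None, None, None)

    if not (
        np.isfinite(p_s).all()
        and np.isfinite(w).all()
        and np.isfinite(u_s).all()
        and np.isfinite(u_f).all()
    ):
        for name, arr in (("p_s", p_s), ("w", w)):
            if not np.isfinite(arr).all():
                k = int(np.argmax(~np.isfinite(arr)))
                raise InstabilityError(n_steps, k, float(x_mm[k]), name)
        raise InstabilityError(n_steps, 0, float(x_mm[0]), "u")

    t_used = t_out[: i_out + 1]
    return SimulationResult(
        x_mm=x_mm.copy(),
        t=t_used.copy(),
        fields={k: v[: i_out + 1] for k, v in hist.items()},
        raw_peak_stress=raw_peak,
        audit={
            "t": audit_t[: i_out + 1].copy(),
            "injected": audit_inj[: i_out + 1].copy(),
            "compressibility": audit_comp[: i_out + 1].copy(),
            "cord_strain": audit_strain[: i_out + 1].copy(),
            "drag_impulse_cord": audit_imp_cord[: i_out + 1].copy(),
            "drag_impulse_fluid": audit_imp_fluid[: i_out + 1].copy(),
        },
        meta={
            "name": system.config.name,
            "dt": dt,
            "dx_mm": dx / MM,
            "n_steps": n_steps,
            "duration_s": system.duration,
            "E_cord": E,
        },
    )


def stress_field(result: SimulationResult, coeffs: CoefficientField) -> np.ndarray:
    """Per-station, per-time stress measure s(x, t) = gamma |E_cord dw/dx| [Pa].

    Requires stored displacement histories; the stride-independent per-station
    peak is available from :func:`peak_stress` without histories.
    """
    if coeffs.gamma is None:
        raise ValidationError(
            "stress scale gamma is unset; run sloshsim.experiment.calibrate() "
            "or supply NumericsOptions(gamma=...)"
        )
    if "w" not in result.fields or not len(result.fields["w"]):
        raise ValidationError("result holds no displacement history")
    w = result.fields["w"]
    dx = (result.x_mm[1] - result.x_mm[0]) * MM
    strain = np.zeros_like(w)
    strain[:, 1:-1] = (w[:, 2:] - w[:, :-2]) / (2 * dx)
    strain[:, 0] = (w[:, 1] + w[:, 0]) / (2 * dx)
    strain[:, -1] = (-w[:, -1] - w[:, -2]) / (2 * dx)
    E = result.meta.get("E_cord", MaterialSet().E_cord)
    return coeffs.gamma * np.abs(E * strain)


def peak_stress(result: SimulationResult, coeffs: CoefficientField) -> np.ndarray:
    """Per-station peak-over-time stress from the running maxima [Pa]."""
    if coeffs.gamma is None:
        raise ValidationError(
            "stress scale gamma is unset; run sloshsim.experiment.calibrate() "
            "or supply NumericsOptions(gamma=...)"
        )
    return coeffs.gamma * result.raw_peak_stress


def volume_audit(result: SimulationResult) -> dict:
    """Volume-conservation report of a stored run.

    Balances the wall volume injected by the epidural excitation against
    fluid storage (artificial compressibility) plus the cord Poisson strain
    volume; the residual is reported as a fraction of the peak injected
    volume (zero-excitation runs report a zero residual).
    """
    a = result.audit
    injected = a["injected"]
    stored = a["compressibility"] + a["cord_strain"]
    peak = float(np.max(np.abs(injected)))
    resid = np.abs(injected - stored)
    return {
        "t": a["t"],
        "injected": injected,
        "stored": stored,
        "peak_injected": peak,
        "max_residual": float(np.max(resid)),
        "residual_fraction": float(np.max(resid) / peak) if peak > 0 else 0.0,
    }
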