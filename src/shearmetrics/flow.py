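"""Reduced-order pulsatile pipe-flow models.

Transient laminar flow in a rigid straight pipe driven by a periodic flow
rate or pressure gradient.  Two routes to the wall shear stress are provided:

* :func:`womersley_wss` — the analytic oscillatory pipe-flow solution
  (Bessel-function form) evaluated per Fourier harmonic of the flow rate;
  the steady harmonic contributes the Poiseuille wall shear
  ``tau = 4 mu Q_mean / (pi R^3)``.
* :func:`fd_pipe_solver` — a Crank–Nicolson finite-difference solution of
  the axisymmetric axial momentum equation
  ``rho du/dt = G(t) + mu (1/r) d/dr (r du/dr)`` with no slip at the wall,
  run over several cardiac cycles until the start-up transient has decayed.

Both return the *signed* axial wall shear (positive in the forward flow
direction); reversal during the cycle shows up as negative values.

Units: SI throughout this module (m, s, Pa), except Waveform values which
carry the units of the signal they represent (mm/s or mm³/s by convention
elsewhere in the package — the solver interfaces take flow rates in m³/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

LAMINAR_RE_LIMIT = 2000.0


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood model: density (kg/m³) and dynamic viscosity (Pa·s)."""

    density: float = 1060.0
    viscosity: float = 3.5e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass(frozen=True)
class PipeSpec:
    """Discretisation of the straight-pipe solver.

    radius in metres; ``nt`` time steps per cardiac cycle (default 100);
    ``nr`` radial intervals; ``harmonics`` Fourier harmonics retained by the
    analytic solution.
    """

    radius: float
    harmonics: int = 8
    nr: int = 100
    nt: int = 100

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pipe radius must be positive")
        if self.harmonics < 1:
            raise ValueError("need at least one harmonic")
        if self.nr < 16:
            raise ValueError("nr must be >= 16")
        if self.nt < 4:
            raise ValueError("nt must be >= 4")


class Waveform:
    """One period of a cardiac velocity or flow-rate signal.

    Samples span ``[0, T)``; the value at ``t = T`` is identified with the
    value at ``t = 0`` (periodic closure). Evaluation between samples uses
    periodic linear interpolation.
    """

    def __init__(self, times, values, period: float, kind: str = "velocity"):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if period <= 0:
            raise ValueError("period must be positive")
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if times[0] != 0.0:
            raise ValueError("waveform must start at t = 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if times[-1] > period:
            raise ValueError("times must not exceed the period")
        if kind not in ("velocity", "flow"):
            raise ValueError("kind must be 'velocity' or 'flow'")
        if times[-1] == period:  # drop duplicated closure sample
            if not np.isclose(values[-1], values[0]):
                raise ValueError("value at t = T must equal value at t = 0")
            times, values = times[:-1], values[:-1]
        self.times = times
        self.values = values
        self.period = float(period)
        self.kind = kind

    def __len__(self) -> int:
        return len(self.times)

    def __call__(self, t) -> np.ndarray:
        tm = np.mod(np.asarray(t, dtype=float), self.period)
        tt = np.concatenate([self.times, [self.period]])
        vv = np.concatenate([self.values, [self.values[0]]])
        return np.interp(tm, tt, vv)

    def mean(self) -> float:
        """Cycle mean, via the periodic trapezoidal rule."""
        tt = np.concatenate([self.times, [self.period]])
        vv = np.concatenate([self.values, [self.values[0]]])
        return float(np.trapezoid(vv, tt) / self.period)

    def scaled(self, factor: float, kind: str | None = None) -> "Waveform":
        return Waveform(self.times, self.values * factor, self.period,
                        kind or self.kind)

    @classmethod
    def from_csv(cls, path, period: float | None = None,
                 kind: str = "velocity") -> "Waveform":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        t, v = data[:, 0], data[:, 1]
        if period is None:
            period = float(t[-1]) if np.isclose(v[-1], v[0]) else float(
                t[-1] + (t[-1] - t[-2]))
        return cls(t, v, period, kind)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_s,value\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.9g},{v:.9g}\n")


def fourier_decompose(waveform: Waveform, harmonics: int) -> np.ndarray:
    """One-sided complex Fourier coefficients ``c_0 .. c_H`` of a waveform.

    ``c_0`` is the cycle mean; the signal is reconstructed as
    ``c_0 + sum_k 2 Re[c_k exp(i k w t)]``. Non-uniformly sampled waveforms
    are resampled onto a uniform grid (periodic linear interpolation) before
    the DFT.
    """
    if len(waveform) < 2 * harmonics + 1:
        raise ValueError(
            f"waveform has {len(waveform)} samples; needs >= {2 * harmonics + 1}")
    n = len(waveform)
    t_uniform = np.arange(n) * waveform.period / n
    uniform = (np.allclose(waveform.times, t_uniform))
    samples = waveform.values if uniform else waveform(t_uniform)
    spec = np.fft.rfft(samples) / n
    return spec[: harmonics + 1]


def reynolds_number(mean_velocity: float, diameter: float,
                    fluid: FluidProperties = FluidProperties()) -> float:
    """Re = rho v d / mu; warns when the laminar assumption is doubtful."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if mean_velocity < 0:
        raise ValueError("mean velocity must be nonnegative")
    re = fluid.density * mean_velocity * diameter / fluid.viscosity
    if re > LAMINAR_RE_LIMIT:
        warnings.warn(
            f"Re = {re:.0f} exceeds {LAMINAR_RE_LIMIT:.0f}; laminar-flow "
            "assumption may not hold", stacklevel=2)
    return re


def womersley_number(radius: float, omega: float,
                     fluid: FluidProperties) -> float:
    """alpha = R sqrt(omega rho / mu)."""
    return radius * np.sqrt(omega / fluid.kinematic_viscosity)


def womersley_wss(pipe: PipeSpec, fluid: FluidProperties,
                  flow_harmonics: np.ndarray, period: float) -> np.ndarray:
    """Analytic wall shear over one cycle for a harmonic flow-rate forcing.

    Parameters
    ----------
    flow_harmonics : complex array ``c_0 .. c_H`` from
        :func:`fourier_decompose` of a *flow-rate* waveform in m³/s.
    period : cardiac period T in seconds.

    Returns
    -------
    tau : (nt,) signed wall shear (Pa) at times ``k T / nt``, k = 0..nt-1.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    c = np.asarray(flow_harmonics, dtype=complex)
    R = pipe.radius
    omega0 = 2.0 * np.pi / period
    t = np.arange(pipe.nt) * period / pipe.nt
    # steady component: Poiseuille
    tau = np.full(pipe.nt, 4.0 * fluid.viscosity * c[0].real / (np.pi * R**3))
    for k in range(1, len(c)):
        omega = k * omega0
        alpha = womersley_number(R, omega, fluid)
        zeta = 1j**1.5 * alpha
        j0, j1 = jv(0, zeta), jv(1, zeta)
        # u = -(iG/(rho w)) [1 - J0(zeta r/R)/J0(zeta)] for forcing G e^{iwt}
        q_per_g = (-1j * np.pi * R**2 / (fluid.density * omega)) * (
            1.0 - 2.0 * j1 / (zeta * j0))
        g_k = c[k] / q_per_g
        tau_k = fluid.viscosity * (1j * g_k / (fluid.density * omega)) * (
            zeta / R) * (j1 / j0)
        tau += 2.0 * np.real(tau_k * np.exp(1j * omega * t))
    return tau


class SolverError(RuntimeError):
    """Raised when the finite-difference solution degenerates."""


@dataclass
class PipeSolution:
    """Final-cycle solution of the transient pipe solver.

    ``u`` is the axial velocity on the radial grid ``r`` at the ``nt`` final
    cycle instants; ``tau`` the signed wall shear; ``cycle_residual`` the
    relative change in tau between the last two simulated cycles (a
    periodicity diagnostic).
    """

    times: np.ndarray
    r: np.ndarray
    u: np.ndarray
    tau: np.ndarray
    cycle_residual: float


def fd_pipe_solver(pipe: PipeSpec, fluid: FluidProperties,
                   pressure_gradient: Waveform, n_cycles: int = 3,
                   converge_tol: float | None = None,
                   max_cycles: int = 60) -> PipeSolution:
    """Crank–Nicolson solution of pulsatile laminar pipe flow.

    ``pressure_gradient`` supplies G(t) = -dp/dz (Pa/m) over one cycle.  The
    velocity starts from rest and at least ``n_cycles`` cycles are stepped so
    the start-up transient decays; the last cycle is returned.  When
    ``converge_tol`` is given, additional cycles (up to ``max_cycles``) are
    run until the cycle-to-cycle relative change in the wall shear falls
    below it.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rho, mu, nu = fluid.density, fluid.viscosity, fluid.kinematic_viscosity
    R, nr, nt = pipe.radius, pipe.nr, pipe.nt
    T = pressure_gradient.period
    dr = R / nr
    dt = T / nt
    r = np.arange(nr + 1) * dr

    # spatial operator A: nu * (u'' + u'/r), unknowns j = 0..nr-1 (u[nr]=0)
    lower = np.zeros(nr)
    diag = np.zeros(nr)
    upper = np.zeros(nr)
    # axis (r=0): L'Hopital => 2 u'' => 4 (u1-u0)/dr^2
    diag[0] = -4.0 * nu / dr**2
    upper[0] = 4.0 * nu / dr**2
    j = np.arange(1, nr)
    lower[j] = nu * (1.0 / dr**2 - 1.0 / (2.0 * r[j] * dr))
    diag[j] = -2.0 * nu / dr**2
    upper[j] = nu * (1.0 / dr**2 + 1.0 / (2.0 * r[j] * dr))

    # banded matrices for (I -+ dt/2 A)
    from scipy.linalg import solve_banded

    ab = np.zeros((3, nr))
    ab[0, 1:] = -0.5 * dt * upper[:-1]
    ab[1, :] = 1.0 - 0.5 * dt * diag
    ab[2, :-1] = -0.5 * dt * lower[1:]

    def apply_explicit(u_in: np.ndarray) -> np.ndarray:
        out = u_in * (1.0 + 0.5 * dt * diag)
        out[:-1] += 0.5 * dt * upper[:-1] * u_in[1:]
        out[1:] += 0.5 * dt * lower[1:] * u_in[:-1]
        return out

    t_grid = np.arange(nt) * dt
    g = pressure_gradient(t_grid)

    u = np.zeros(nr)  # start from rest
    prev_tau = None
    residual = np.inf

    def wall_shear(u_in: np.ndarray) -> float:
        # tau = -mu du/dr|_R, one-sided 2nd order with u[nr] = 0
        return float(-mu * (-4.0 * u_in[-1] + u_in[-2]) / (2.0 * dr))

    total = n_cycles
    cycle = 0
    tau_cycle = np.zeros(nt)
    u_cycle = np.zeros((nt, nr + 1))
    while cycle < total:
        for k in range(nt):
            tau_cycle[k] = wall_shear(u)
            u_cycle[k, :nr] = u
            g_mid = 0.5 * (g[k] + g[(k + 1) % nt])
            rhs = apply_explicit(u) + dt * g_mid / rho
            u = solve_banded((1, 1), ab, rhs)
            if not np.all(np.isfinite(u)):
                raise SolverError(
                    f"solution lost finiteness in cycle {cycle + 1}, "
                    f"step {k + 1} (dt={dt:.3g}, dr={dr:.3g})")
        if prev_tau is not None:
            scale = max(np.max(np.abs(tau_cycle)), 1e-300)
            residual = float(np.max(np.abs(tau_cycle - prev_tau)) / scale)
        prev_tau = tau_cycle.copy()
        cycle += 1
        if (cycle >= n_cycles and converge_tol is not None
                and residual > converge_tol and cycle < max_cycles):
            total = cycle + 1
    if converge_tol is not None and residual > converge_tol:
        warnings.warn(
            f"pipe solver cycle residual {residual:.2e} above requested "
            f"{converge_tol:.2e} after {cycle} cycles", stacklevel=2)
    return PipeSolution(times=t_grid, r=r, u=u_cycle, tau=tau_cycle.copy(),
                        cycle_residual=residual)


def split_flow(inlet: Waveform, ratios, residual_fraction: float = 0.0
               ) -> list[Waveform]:
    """Split an inlet flow waveform among branches by fixed volume ratios.

    Each branch receives ``inlet * w_i / sum(w)`` at every instant.  When
    ``residual_fraction`` in (0, 1] is given, the named ratios share only
    ``1 - residual_fraction`` of the inlet and a final residual branch (the
    descending aorta) is appended carrying the remainder.
    """
    w = np.asarray(ratios, dtype=float)
    if w.size == 0 or np.any(w < 0) or w.sum() == 0:
        raise ValueError("ratios must be nonnegative with a positive sum")
    if not 0.0 <= residual_fraction < 1.0:
        raise ValueError("residual_fraction must be in [0, 1)")
    fractions = list((1.0 - residual_fraction) * w / w.sum())
    if residual_fraction > 0:
        fractions.append(residual_fraction)
    return [inlet.scaled(f, kind="flow") for f in fractions]
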