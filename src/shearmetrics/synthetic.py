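"""Synthetic inputs for exercising the pipeline end to end.

Real inputs to this kind of analysis — a micro-CT-derived aortic surface,
Doppler-measured velocity waveforms, CFD wall shear fields, and histological
wall measurements — are rarely shareable.  This module generates statistical
stand-ins with *planted, analytically known* structure so every pipeline
stage can be validated against ground truth:

* a curved-arch vessel surface (torus-segment tube) with named inner-arch /
  outer-arch regions — disturbed, oscillatory flow concentrates on the
  lesser curvature (inner wall) of a real aortic arch, and the planted WSS
  fields reproduce that spatial pattern;
* rat-like periodic velocity waveforms parameterised by heart rate and peak
  systolic velocity (rat HR ~270-380 beats/min, ascending-aorta peak
  velocities ~1.5-2.2 m/s);
* per-node WSS vector time series of the form ``(a + b sin(w t)) e`` with a
  fixed direction ``e``, for which OSI and TAWSS have closed forms, the
  oscillation amplitude ratio peaking on the inner arch;
* per-animal study tables in which wall thickness (and elastin-layer
  thickness) depend linearly on a regional haemodynamic metric plus
  Gaussian noise, optionally calibrated to a target population Pearson r.

Every generator takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import Waveform
from .mesh import RegionMask, SurfaceMesh
from .metrics import WSSField

GROUPS = ("WKY-CON", "SHR-CON", "WKY-NIF", "SHR-NIF")


@dataclass(frozen=True)
class ArchSpec:
    """Torus-segment tube standing in for an aortic arch.

    The centerline is a circular arc of radius ``centerline_radius_mm``
    spanning ``arch_angle`` radians; the vessel wall is a tube of radius
    ``vessel_radius_mm`` around it.  The inner arch (lesser curvature) is
    the strip of the tube closest to the arc's centre of curvature, with
    angular half-width ``inner_window / 2`` in the tube's circumferential
    angle.  Default dimensions are rat-aorta scale.
    """

    centerline_radius_mm: float = 4.0
    vessel_radius_mm: float = 1.0
    arch_angle: float = np.pi
    n_axial: int = 64
    n_circ: int = 96
    inner_window: float = 0.5

    def __post_init__(self) -> None:
        if self.centerline_radius_mm <= 0 or self.vessel_radius_mm <= 0:
            raise ValueError("radii must be positive")
        if self.centerline_radius_mm <= self.vessel_radius_mm:
            raise ValueError("centerline radius must exceed vessel radius")
        if self.n_axial < 8 or self.n_circ < 8:
            raise ValueError("resolution must be at least 8 x 8")
        if not 0.0 < self.inner_window < 2.0 * np.pi:
            raise ValueError("inner window must lie in (0, 2*pi)")
        if not 0.0 < self.arch_angle <= 2.0 * np.pi:
            raise ValueError("arch angle must lie in (0, 2*pi]")


def make_arch_mesh(spec: ArchSpec
                   ) -> tuple[SurfaceMesh, dict[str, RegionMask]]:
    """Build the arch surface and its named region masks.

    Returns the mesh and masks ``inner_arch``, ``outer_arch`` and
    ``whole_wall``; inner and outer masks partition the wall nodes. The
    tube ends are left open (no caps), so every node is a wall node.
    """
    Rc = spec.centerline_radius_mm
    rt = spec.vessel_radius_mm
    n_ax, n_c = spec.n_axial, spec.n_circ
    theta = np.linspace(0.0, spec.arch_angle, n_ax + 1)  # along the arch
    phi = np.arange(n_c) * 2.0 * np.pi / n_c             # around the tube

    th, ph = np.meshgrid(theta, phi, indexing="ij")
    # phi = pi faces the centre of curvature: the inner (lesser) curvature
    rad = Rc + rt * np.cos(ph)
    verts = np.stack([rad * np.cos(th), rt * np.sin(ph), rad * np.sin(th)],
                     axis=-1).reshape(-1, 3)

    def vid(i: int, j: int) -> int:
        return i * n_c + (j % n_c)

    tris = []
    for i in range(n_ax):
        for j in range(n_c):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            tris.append([a, b, d])
            tris.append([a, d, c])
    mesh = SurfaceMesh(verts, np.array(tris, dtype=np.int64))

    # circumferential distance from the inner line (phi = pi)
    dist = np.abs(np.angle(np.exp(1j * (ph.reshape(-1) - np.pi))))
    inner = np.flatnonzero(dist <= spec.inner_window / 2.0)
    outer = np.flatnonzero(dist > spec.inner_window / 2.0)
    masks = {
        "inner_arch": RegionMask("inner_arch", inner),
        "outer_arch": RegionMask("outer_arch", outer),
        "whole_wall": mesh.whole_wall_mask(),
    }
    return mesh, masks


def inner_distance(mesh: SurfaceMesh, spec: ArchSpec) -> np.ndarray:
    """Circumferential angular distance of each node from the inner line."""
    y = mesh.vertices[:, 1] / spec.vessel_radius_mm
    r_in_plane = np.hypot(mesh.vertices[:, 0], mesh.vertices[:, 2])
    x = (r_in_plane - spec.centerline_radius_mm) / spec.vessel_radius_mm
    phi = np.arctan2(y, x)
    return np.abs(np.angle(np.exp(1j * (phi - np.pi))))


def make_waveform(heart_rate: float, peak_velocity: float,
                  seed: int | None = 0, n_samples: int = 100,
                  kind: str = "velocity") -> Waveform:
    """Rat-like single-cycle velocity waveform.

    A raised-cosine systolic pulse over the first ~35% of the cycle on top
    of a small diastolic baseline flow; period is ``60 / heart_rate``
    seconds and the waveform maximum equals ``peak_velocity`` exactly.  The
    seed jitters the pulse width and diastolic level slightly (animal-to-
    animal variation); the peak constraint is enforced after jitter.
    """
    if heart_rate <= 0 or peak_velocity <= 0:
        raise ValueError("heart rate and peak velocity must be positive")
    period = 60.0 / heart_rate
    rng = np.random.default_rng(seed)
    sys_frac = 0.35 * (1.0 + 0.05 * rng.standard_normal())
    sys_frac = float(np.clip(sys_frac, 0.2, 0.5))
    dia_level = 0.05 * (1.0 + 0.1 * rng.standard_normal())
    dia_level = float(np.clip(dia_level, 0.01, 0.15))

    t = np.arange(n_samples) * period / n_samples
    x = t / (sys_frac * period)
    pulse = np.where(x < 1.0, 0.5 * (1.0 - np.cos(2.0 * np.pi * x)), 0.0)
    v = dia_level + (1.0 - dia_level) * pulse
    v *= peak_velocity / v.max()
    return Waveform(t, v, period, kind=kind)


@dataclass(frozen=True)
class PlantedFieldSpec:
    """Fixed-axis reversing WSS field with inner-concentrated oscillation.

    Per node, ``tau(t) = (a + b sin(2 pi t / T)) e`` with ``a`` the steady
    baseline magnitude and ``b = ratio * a`` the oscillatory amplitude. The
    amplitude ratio equals ``inner_ratio`` on the inner-arch line and decays
    as a Gaussian of the circumferential distance with scale ``decay``
    (radians); the steady baseline simultaneously *dips* by ``baseline_dip``
    with the same spatial profile, reproducing the low-and-oscillatory shear
    environment of the inner curvature.  ``jitter`` adds a seeded
    multiplicative perturbation to the baseline so nodes are not identical.
    When ``osc_amplitude_pa`` is set the oscillatory amplitude is absolute
    (Pa, same spatial decay) instead of relative to the baseline — this
    expresses fields with zero steady component (pure reversal, OSI = 0.5).

    Defaults place the whole-wall statistics in the regime reported for
    hypertensive rat aortas: most of the wall below 20 Pa mean shear, a few
    percent of the area with OSI > 0.2 concentrated at the inner arch where
    the regional OSI approaches ~0.4, and a small high-RRT patch.
    """

    baseline_pa: float = 19.0
    baseline_dip: float = 0.95
    inner_ratio: float = 30.0
    decay: float = 0.12
    period_s: float = 0.16
    n_samples: int = 100
    jitter: float = 0.1
    seed: int = 0
    osc_amplitude_pa: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_pa < 0 or self.inner_ratio < 0 or self.decay <= 0:
            raise ValueError("magnitudes must be nonnegative, decay positive")
        if not 0.0 <= self.baseline_dip < 1.0:
            raise ValueError("baseline dip must be in [0, 1)")
        if self.osc_amplitude_pa is not None and self.osc_amplitude_pa < 0:
            raise ValueError("oscillatory amplitude must be nonnegative")
        if self.period_s <= 0 or self.n_samples < 4:
            raise ValueError("need positive period and >= 4 samples")
        if self.jitter < 0 or self.jitter >= 1:
            raise ValueError("jitter must be in [0, 1)")


def planted_osi(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closed-form OSI of ``tau(t) = a + b sin(w t)`` along a fixed axis.

    For b <= a the shear never reverses and OSI = 0.  For b > a the cycle
    mean of |a + b sin| is ``(2/pi)(a asin(a/b) + sqrt(b^2 - a^2))`` and
    OSI = (1 - a / that) / 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    osi = np.zeros(np.broadcast(a, b).shape)
    a, b = np.broadcast_arrays(a, b)
    rev = b > a
    m1 = (2.0 / np.pi) * (a[rev] * np.arcsin(a[rev] / b[rev])
                          + np.sqrt(b[rev] ** 2 - a[rev] ** 2))
    osi[rev] = 0.5 * (1.0 - a[rev] / m1)
    return osi


def planted_tawss(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closed-form TAWSS of ``tau(t) = a + b sin(w t)`` along a fixed axis."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = np.broadcast_arrays(a, b)
    out = a.astype(float).copy()
    rev = b > a
    out[rev] = (2.0 / np.pi) * (a[rev] * np.arcsin(a[rev] / b[rev])
                                + np.sqrt(b[rev] ** 2 - a[rev] ** 2))
    return out


def make_wss_field(mesh: SurfaceMesh, spec: PlantedFieldSpec,
                   arch: ArchSpec) -> tuple[WSSField, dict[str, np.ndarray]]:
    """Plant a reversing WSS field on an arch mesh.

    Returns the field and a ground-truth dict with per-node ``a``, ``b``,
    ``osi`` and ``tawss`` computed in closed form from the planted
    amplitudes — the oracle against which pipeline output is checked.
    """
    rng = np.random.default_rng(spec.seed)
    n = mesh.n_nodes
    dist = inner_distance(mesh, arch)
    shape = np.exp(-0.5 * (dist / spec.decay) ** 2)
    a = spec.baseline_pa * (1.0 - spec.baseline_dip * shape) * (
        1.0 + spec.jitter * rng.uniform(-1.0, 1.0, n))
    if spec.osc_amplitude_pa is not None:
        b = spec.osc_amplitude_pa * shape * np.ones(n)
    else:
        b = spec.inner_ratio * shape * a

    times = np.arange(spec.n_samples) * spec.period_s / spec.n_samples
    # axial direction of the arch at each node
    th = np.arctan2(mesh.vertices[:, 2], mesh.vertices[:, 0])
    e = np.stack([-np.sin(th), np.zeros(n), np.cos(th)], axis=1)
    signal = (a[:, None]
              + b[:, None] * np.sin(2.0 * np.pi * times / spec.period_s))
    tau = signal[:, :, None] * e[:, None, :]
    field = WSSField(mesh, times, tau, spec.period_s)
    truth = {"a": a, "b": b, "osi": planted_osi(a, b),
             "tawss": planted_tawss(a, b)}
    return field, truth


@dataclass(frozen=True)
class PlantedStudySpec:
    """Linear metric-to-remodelling relationship with Gaussian noise.

    Wall thickness (mm) = ``intercept + slope * metric + N(0, noise_sd)``.
    When ``target_r`` is set, ``noise_sd`` is ignored and derived from the
    sample SD of the supplied metric so the *population* Pearson correlation
    equals ``target_r``.  Defaults are rat-scale: regional OSI near 0.4 maps
    to wall thickness near 0.3 mm.
    """

    n_per_group: int = 6
    slope: float = 3.0
    intercept: float = -0.9
    noise_sd: float = 0.03
    target_r: float | None = None
    elastin_scale: float = 0.4
    seed: int = 0
    groups: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")
        if self.target_r is not None and not 0 < abs(self.target_r) < 1:
            raise ValueError("target_r must be in (-1, 1), nonzero")


def noise_sd_for_r(slope: float, x_sd: float, r: float) -> float:
    """Noise SD giving population Pearson r for y = slope*x + noise.

    r = slope*sd(x) / sqrt(slope^2 sd(x)^2 + sd^2)  =>
    sd = |slope| sd(x) sqrt(1/r^2 - 1).
    """
    if not 0 < abs(r) < 1:
        raise ValueError("r must be in (-1, 1), nonzero")
    return abs(slope) * x_sd * np.sqrt(1.0 / r**2 - 1.0)


def sample_regional_metrics(group_means, group_sd: float, n_per_group: int,
                            seed: int | None = 0) -> np.ndarray:
    """Draw per-animal regional metric values around group means."""
    rng = np.random.default_rng(seed)
    means = np.asarray(group_means, dtype=float)
    return np.concatenate([
        m + group_sd * rng.standard_normal(n_per_group) for m in means])


def make_study_table(spec: PlantedStudySpec, regional_osi,
                     regional_rrt=None) -> pd.DataFrame:
    """Build a per-animal study table with planted remodelling outcomes.

    ``regional_osi`` supplies one value per animal (group-major order,
    ``n_per_group`` per group).  Wall thickness is linear in regional OSI
    plus seeded Gaussian noise; elastin-layer thickness is a scaled copy
    with independent noise of the same SD.
    """
    x = np.asarray(regional_osi, dtype=float)
    n_total = spec.n_per_group * len(spec.groups)
    if x.size != n_total:
        raise ValueError(
            f"expected {n_total} regional metric values, got {x.size}")
    if regional_rrt is not None:
        rrt = np.asarray(regional_rrt, dtype=float)
        if rrt.size != n_total:
            raise ValueError("regional_rrt length mismatch")
    else:
        rrt = np.full(n_total, np.nan)
    sd = spec.noise_sd
    if spec.target_r is not None:
        sd = noise_sd_for_r(spec.slope, float(np.std(x, ddof=1)),
                            spec.target_r)
    rng = np.random.default_rng(spec.seed)
    thickness = (spec.intercept + spec.slope * x
                 + sd * rng.standard_normal(n_total))
    elastin = spec.elastin_scale * (
        spec.intercept + spec.slope * x) + spec.elastin_scale * sd * \
        rng.standard_normal(n_total)
    return pd.DataFrame({
        "animal_id": [f"{g}-{i + 1}" for g in spec.groups
                      for i in range(spec.n_per_group)],
        "group": np.repeat(list(spec.groups), spec.n_per_group),
        "regional_osi": x,
        "regional_rrt": rrt,
        "wall_thickness_mm": thickness,
        "elastin_thickness_mm": elastin,
    })
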