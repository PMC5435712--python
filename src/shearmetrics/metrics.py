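"""Wall-shear-stress derived metrics on vessel surfaces.

Given a per-node wall shear *vector* time series over one cardiac cycle
(period T), three scalar fields characterise the local flow environment:

* **TAWSS** (Pa) — time-averaged magnitude, ``(1/T) \\int_0^T |tau| dt``.
* **OSI** (dimensionless, 0 to 0.5) — oscillatory shear index,
  ``0.5 (1 - |\\int tau dt| / \\int |tau| dt)``; 0 for unidirectional shear,
  0.5 for purely oscillatory (zero-mean) shear.  The numerator integrates
  the vector first and then takes the magnitude.
* **RRT** (Pa⁻¹) — relative residence time, ``1 / ((1 - 2 OSI) TAWSS)``,
  a surrogate for near-wall particle stagnation; it diverges where the
  cycle-mean shear vector vanishes (OSI -> 0.5), which is recorded with a
  ``+inf`` sentinel and a degenerate flag rather than NaN so that area
  statistics stay defined.

All cycle integrals use the periodic trapezoidal rule: if the last sample
time is short of T, a closing sample at t = T is synthesised from the t = 0
sample.  Area statistics are weighted by the mesh's lumped node areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import RegionMask, SurfaceMesh

log = logging.getLogger(__name__)

DEGENERATE_EPS = 1e-12

TAWSS_BIN_WIDTH = 20.0  # Pa
TAWSS_N_BINS = 7


@dataclass
class WSSField:
    """Per-node wall shear vector time series over one cardiac cycle.

    tau has shape (n_nodes, n_times, 3) in Pa; times in seconds within
    [0, period].
    """

    mesh: SurfaceMesh
    times: np.ndarray
    tau: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.times.size < 3:
            raise ValueError("need at least 3 time samples per cycle")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] > self.period:
            raise ValueError("times must lie within [0, period]")
        if self.tau.shape != (self.mesh.n_nodes, self.times.size, 3):
            raise ValueError(
                f"tau shape {self.tau.shape} does not match "
                f"(n_nodes={self.mesh.n_nodes}, n_times={self.times.size}, 3)")
        if not np.all(np.isfinite(self.tau)):
            raise ValueError("tau contains non-finite values")

    def closed(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and tau with the periodic closure sample at t = T appended."""
        if self.times[-1] == self.period:
            return self.times, self.tau
        t = np.concatenate([self.times, [self.period]])
        tau = np.concatenate([self.tau, self.tau[:, :1, :]], axis=1)
        return t, tau


@dataclass
class MetricMap:
    """Per-node scalar metric bound to a mesh; ``flags`` marks degenerate
    nodes (zero shear all cycle, or vanishing mean-shear denominator)."""

    mesh: SurfaceMesh
    name: str
    values: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.size != self.mesh.n_nodes:
            raise ValueError("metric length must match mesh node count")
        if self.flags is None:
            self.flags = np.zeros(self.values.size, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": np.arange(self.values.size),
                             self.name: self.values,
                             "degenerate": self.flags.astype(int)})


def _cycle_integrals(field_: WSSField) -> tuple[np.ndarray, np.ndarray]:
    """(|∫tau dt|, ∫|tau| dt) per node, periodic trapezoid."""
    t, tau = field_.closed()
    vec = np.trapezoid(tau, t, axis=1)            # (n, 3)
    mag = np.trapezoid(np.linalg.norm(tau, axis=2), t, axis=1)  # (n,)
    return np.linalg.norm(vec, axis=1), mag


def compute_tawss(field_: WSSField) -> MetricMap:
    """Time-averaged WSS magnitude (Pa). Zero-shear nodes are flagged."""
    _, mag = _cycle_integrals(field_)
    tawss = mag / field_.period
    flags = mag < DEGENERATE_EPS
    if flags.any():
        log.warning("TAWSS: %d degenerate (zero-shear) nodes", flags.sum())
    return MetricMap(field_.mesh, "TAWSS", tawss, flags)


def compute_osi(field_: WSSField) -> MetricMap:
    """Oscillatory shear index in [0, 0.5].

    Nodes whose total shear exposure ``∫|tau| dt`` is below 1e-12 Pa·s have
    no defined direction; they get OSI = 0 and a degenerate flag.
    """
    num, den = _cycle_integrals(field_)
    flags = den < DEGENERATE_EPS
    if flags.any():
        log.warning("OSI: %d degenerate (zero-shear) nodes set to 0",
                    flags.sum())
    osi = np.zeros_like(den)
    ok = ~flags
    osi[ok] = 0.5 * (1.0 - num[ok] / den[ok])
    np.clip(osi, 0.0, 0.5, out=osi)  # guard fp drift
    return MetricMap(field_.mesh, "OSI", osi, flags)


def compute_rrt(tawss: MetricMap, osi: MetricMap) -> MetricMap:
    """Relative residence time 1/((1 - 2 OSI) TAWSS), Pa⁻¹.

    Where the denominator (the magnitude of the cycle-mean shear vector)
    falls below 1e-12, RRT is +inf and the node is flagged.
    """
    if tawss.mesh is not osi.mesh:
        raise ValueError("TAWSS and OSI maps must share a mesh")
    if tawss.name != "TAWSS" or osi.name != "OSI":
        raise ValueError("expected a TAWSS map and an OSI map")
    denom = (1.0 - 2.0 * osi.values) * tawss.values
    flags = (denom < DEGENERATE_EPS) | tawss.flags | osi.flags
    rrt = np.full_like(denom, np.inf)
    rrt[~flags] = 1.0 / denom[~flags]
    if flags.any():
        log.warning("RRT: %d nodes with vanishing mean shear set to +inf",
                    flags.sum())
    return MetricMap(tawss.mesh, "RRT", rrt, flags)


def area_fraction(metric: MetricMap, mask: RegionMask, threshold: float,
                  direction: str = "above") -> float:
    """Area-weighted fraction of a region beyond a threshold.

    Strict inequalities are used (value > threshold / value < threshold);
    ties fall on the non-qualifying side. ``+inf`` sentinel values count as
    above any finite threshold.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    mask.validate(metric.mesh)
    v = metric.values[mask.node_ids]
    a = metric.mesh.node_areas[mask.node_ids]
    hit = v > threshold if direction == "above" else v < threshold
    return float(a[hit].sum() / a.sum())


def tawss_histogram(metric: MetricMap, mask: RegionMask,
                    bin_width: float = TAWSS_BIN_WIDTH,
                    n_bins: int = TAWSS_N_BINS) -> np.ndarray:
    """Area fractions of TAWSS in ``n_bins`` ranges of ``bin_width`` Pa.

    Bins are [0, 20), [20, 40), ..., with the last bin open above
    (>= 120 Pa by default). Fractions sum to 1.
    """
    if metric.name != "TAWSS":
        raise ValueError("tawss_histogram requires a TAWSS map")
    mask.validate(metric.mesh)
    v = metric.values[mask.node_ids]
    a = metric.mesh.node_areas[mask.node_ids]
    idx = np.minimum((v // bin_width).astype(int), n_bins - 1)
    fractions = np.zeros(n_bins)
    np.add.at(fractions, idx, a)
    return fractions / a.sum()


def regional_mean(metric: MetricMap, mask: RegionMask) -> float:
    """Area-weighted mean of a metric over a region.

    Non-finite (sentinel) nodes are excluded with a warning; if every node
    in the region is degenerate the mean is undefined.
    """
    mask.validate(metric.mesh)
    v = metric.values[mask.node_ids]
    a = metric.mesh.node_areas[mask.node_ids]
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError(
            f"all nodes in region {mask.name!r} are degenerate")
    if not ok.all():
        log.warning("regional_mean(%s): excluding %d non-finite nodes",
                    mask.name, (~ok).sum())
    return float((v[ok] * a[ok]).sum() / a[ok].sum())


# ---------------------------------------------------------------------------
# I/O

def field_to_csv(field_: WSSField, path) -> None:
    """Write a WSS field as long-format CSV (node_id,time_s,tx,ty,tz)."""
    n, nt = field_.mesh.n_nodes, field_.times.size
    df = pd.DataFrame({
        "node_id": np.repeat(np.arange(n), nt),
        "time_s": np.tile(field_.times, n),
        "tx": field_.tau[:, :, 0].ravel(),
        "ty": field_.tau[:, :, 1].ravel(),
        "tz": field_.tau[:, :, 2].ravel(),
    })
    df.to_csv(path, index=False, float_format="%.9g")


def field_from_csv(mesh: SurfaceMesh, path, period: float) -> WSSField:
    """Read a long-format WSS CSV back onto ``mesh``."""
    df = pd.read_csv(path)
    required = {"node_id", "time_s", "tx", "ty", "tz"}
    if not required.issubset(df.columns):
        raise ValueError(f"WSS CSV must have columns {sorted(required)}")
    times = np.unique(df["time_s"].to_numpy())
    n = mesh.n_nodes
    df = df.sort_values(["node_id", "time_s"])
    if len(df) != n * times.size:
        raise ValueError("WSS CSV is not a complete node x time grid")
    tau = df[["tx", "ty", "tz"]].to_numpy().reshape(n, times.size, 3)
    return WSSField(mesh, times, tau, period)
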