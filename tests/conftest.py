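import numpy as np
import pytest
import trimesh

from shearmetrics.mesh import SurfaceMesh
from shearmetrics.metrics import WSSField
from shearmetrics.synthetic import ArchSpec, make_arch_mesh


@pytest.fixture
def cube_mesh() -> SurfaceMesh:
    """Unit cube surface: 12 triangles, total area 6 mm²."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture
def small_arch():
    """Coarse quarter-torus arch used where geometry details don't matter."""
    spec = ArchSpec(centerline_radius_mm=10.0, vessel_radius_mm=1.0,
                    arch_angle=np.pi / 2, n_axial=16, n_circ=16)
    mesh, masks = make_arch_mesh(spec)
    return spec, mesh, masks


def single_node_field(signal_xyz: np.ndarray, period: float) -> WSSField:
    """WSS field on a one-triangle mesh whose 3 nodes share one signal."""
    mesh = SurfaceMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
    nt = signal_xyz.shape[0]
    times = np.arange(nt) * period / nt
    tau = np.broadcast_to(signal_xyz, (3, nt, 3)).copy()
    return WSSField(mesh, times, tau, period)
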