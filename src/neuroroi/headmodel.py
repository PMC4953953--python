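"""Synthetic spherical head model: mesh, lead field, smoothing kernel, simulation.

The forward model is the standard instantaneous linear one,

    X = M J + eps,

with ``X`` the C x T sensor data, ``J`` the D x T cortical dipole currents
(one dipole per mesh vertex, oriented along the outward surface normal)
and ``M`` the C x D lead field.  The module builds a fully synthetic
stand-in for an anatomical pipeline: a recursively subdivided icosphere
cortex, a hemispheric sensor cap, an infinite-homogeneous-medium dipole
lead field, the mesh graph Laplacian and its matrix exponential (a local
smoothing kernel whose columns define compact cortical patches), and
seeded patch-source / noisy-EEG simulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import trimesh

__all__ = [
    "CorticalMesh", "SensorArray", "LeadField", "GraphLaplacian",
    "GreensFunction", "SimulatedRecording",
    "make_cortical_mesh", "make_sensor_cap", "make_lead_field",
    "graph_laplacian", "greens_function", "simulate_sources", "simulate_eeg",
]


@dataclass(frozen=True)
class CorticalMesh:
    """Triangulated cortical surface hosting one dipole per vertex.

    Attributes
    ----------
    vertices : (D, 3) float array
        Vertex positions in millimetres.
    faces : (F, 3) int array
        Triangle vertex-index triples (0-based).
    normals : (D, 3) float array
        Unit outward normals; each dipole is oriented along its normal.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def vertex_adjacency(self) -> sp.csr_matrix:
        """0/1 vertex adjacency from shared triangle edges (symmetric CSR)."""
        f = self.faces
        i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        a = sp.coo_matrix(
            (np.ones(i.size), (i, j)), shape=(self.n_vertices, self.n_vertices)
        )
        a = a + a.T
        a.data[:] = 1.0
        return a.tocsr()


@dataclass(frozen=True)
class SensorArray:
    """EEG sensor positions (mm) with channel labels."""

    positions: np.ndarray
    labels: list[str]

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class LeadField:
    """Gain matrix M (C x D): sensor potential per unit dipole moment."""

    M: np.ndarray


@dataclass(frozen=True)
class GraphLaplacian:
    """Mesh graph Laplacian G = A - diag(degree) (rows sum to zero)."""

    G: np.ndarray


@dataclass(frozen=True)
class GreensFunction:
    """Smoothing kernel Q_G = expm(sigma * G); columns are cortical patches.

    ``sigma`` rules the spatial extent of the patches: each column is a
    bump centred at one vertex that decays with graph distance.  Q_G is
    symmetric positive definite and row-stochastic (rows sum to one).
    """

    Q: np.ndarray
    sigma: float


@dataclass(frozen=True)
class SimulatedRecording:
    """A simulated EEG trial with its ground-truth source currents."""

    X: np.ndarray
    J_true: np.ndarray
    active_centers: list[int]
    fs: float
    snr_db: float | None
    seed: int
    noise: np.ndarray = field(repr=False, default=None)


def make_cortical_mesh(n_subdivisions: int, radius_mm: float) -> CorticalMesh:
    """Build an icosphere cortex of ``10 * 4**n + 2`` vertices.

    Parameters
    ----------
    n_subdivisions : int
        Recursive icosahedron subdivision level, between 1 and 5.
    radius_mm : float
        Sphere radius in millimetres (positive).
    """
    if not 1 <= int(n_subdivisions) <= 5:
        raise ValueError(
            f"n_subdivisions must be in [1, 5], got {n_subdivisions!r}"
        )
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    m = trimesh.creation.icosphere(subdivisions=int(n_subdivisions), radius=1.0)
    verts = np.asarray(m.vertices, dtype=float)
    # project exactly onto the sphere; normals of a sphere are radial
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return CorticalMesh(
        vertices=verts * float(radius_mm),
        faces=np.asarray(m.faces, dtype=np.int64),
        normals=verts.copy(),
    )


def make_sensor_cap(
    n_sensors: int, radius_mm: float, coverage: float = 0.75
) -> SensorArray:
    """Place ``n_sensors`` on a spherical cap of the given radius.

    A Fibonacci lattice on the upper portion of the sphere (fraction
    ``coverage`` of its area, measured from the vertex z = +radius) gives
    a near-uniform montage resembling an EEG cap.
    """
    if n_sensors < 2:
        raise ValueError("need at least 2 sensors")
    k = np.arange(n_sensors)
    # z descends from the pole through the cap
    z = 1.0 - coverage * (k + 0.5) / n_sensors * 2.0
    z = np.clip(z, -1.0, 1.0)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = k * golden
    r_xy = np.sqrt(1.0 - z**2)
    pos = radius_mm * np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
    labels = [f"CH{c + 1:02d}" for c in range(n_sensors)]
    return SensorArray(positions=pos, labels=labels)


def make_lead_field(mesh: CorticalMesh, sensors: SensorArray,
                    conductivity: float = 0.33) -> LeadField:
    """Quasi-static dipole lead field in an infinite homogeneous medium.

    Entry (c, d) is the electric potential at sensor c of a unit current
    dipole at vertex d oriented along the vertex normal,

        V = p . (r_s - r_d) / (4 pi kappa |r_s - r_d|^3),

    with ``kappa`` the medium conductivity (S/m).  Sensors are
    common-average referenced: each column is centred across sensors, so
    columns sum to zero.
    """
    r_s = sensors.positions * 1e-3          # mm -> m for physical units
    r_d = mesh.vertices * 1e-3
    diff = r_s[:, None, :] - r_d[None, :, :]          # C x D x 3
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist < 1e-12):
        raise ValueError("a sensor coincides with a mesh vertex")
    proj = np.einsum("cdk,dk->cd", diff, mesh.normals)
    M = proj / (4.0 * np.pi * conductivity * dist**3)
    M = M - M.mean(axis=0, keepdims=True)              # common-average ref
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite lead field entries")
    return LeadField(M=M)


def graph_laplacian(mesh: CorticalMesh) -> GraphLaplacian:
    """G = A - diag(degree) with A the 0/1 mesh vertex adjacency."""
    a = mesh.vertex_adjacency().toarray()
    return GraphLaplacian(G=a - np.diag(a.sum(axis=1)))


def greens_function(G: GraphLaplacian | np.ndarray, sigma: float) -> GreensFunction:
    """Matrix exponential Q_G = expm(sigma * G) of the scaled Laplacian.

    Because G is symmetric with zero row sums, Q_G is symmetric positive
    definite and row-stochastic; its columns are local smoothing bumps
    whose spatial extent grows with ``sigma``.
    """
    Gm = G.G if isinstance(G, GraphLaplacian) else np.asarray(G, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not np.allclose(Gm, Gm.T, atol=1e-10):
        raise ValueError("graph Laplacian must be symmetric")
    # symmetric eigendecomposition: exact symmetry of the result by construction
    w, V = np.linalg.eigh(Gm)
    Q = (V * np.exp(sigma * w)) @ V.T
    Q = 0.5 * (Q + Q.T)
    return GreensFunction(Q=Q, sigma=float(sigma))


def _graph_distances(mesh: CorticalMesh, sources: np.ndarray) -> np.ndarray:
    """Unweighted (edge-count) graph distances from the given vertices."""
    return csgraph.shortest_path(
        mesh.vertex_adjacency(), method="D", unweighted=True, indices=sources
    )


def simulate_sources(
    mesh: CorticalMesh,
    Q_G: GreensFunction,
    n_patches: int,
    fs: float,
    duration_s: float,
    band_hz: tuple[float, float] = (8.0, 13.0),
    amplitude: float = 1.0,
    seed: int = 0,
    min_separation: int = 4,
    candidate_vertices: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Simulate patch sources: smooth spatial profiles x band-limited tones.

    Picks ``n_patches`` centre vertices uniformly at random (seeded,
    without replacement, pairwise graph distance >= ``min_separation``
    edges), optionally restricted to ``candidate_vertices`` — e.g. the
    part of the cortex a sensor montage actually covers.  Each patch's spatial profile is the corresponding column of
    Q_G rescaled to unit maximum; its time course is a sinusoid at a
    frequency drawn uniformly in ``band_hz`` with random phase, scaled by
    ``amplitude``.  Returns (J_true, active_centers).
    """
    T = int(round(duration_s * fs))
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if T < 2:
        raise ValueError("duration_s * fs must be >= 2 samples")
    rng = np.random.default_rng(seed)
    if candidate_vertices is None:
        order = rng.permutation(mesh.n_vertices)
    else:
        candidate_vertices = np.asarray(candidate_vertices)
        order = candidate_vertices[rng.permutation(candidate_vertices.size)]
    centers: list[int] = []
    for v in order:
        if centers:
            d = _graph_distances(mesh, np.asarray(centers))[:, v]
            if d.min() < min_separation:
                continue
        centers.append(int(v))
        if len(centers) == n_patches:
            break
    else:
        raise ValueError(
            f"cannot place {n_patches} patch centers at pairwise graph "
            f"distance >= {min_separation} on this mesh"
        )
    t = np.arange(T) / fs
    J = np.zeros((mesh.n_vertices, T))
    for c in centers:
        prof = Q_G.Q[:, c]
        prof = prof / prof.max()
        f0 = rng.uniform(*band_hz)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        J += amplitude * np.outer(prof, np.sin(2.0 * np.pi * f0 * t + phase))
    return J, centers


def simulate_eeg(
    M: LeadField | np.ndarray,
    J_true: np.ndarray,
    snr_db: float | None,
    seed: int = 0,
    fs: float = 128.0,
    active_centers: list[int] | None = None,
) -> SimulatedRecording:
    """Project sources to sensors and add white Gaussian noise at a target SNR.

    ``snr_db`` is the ratio of total signal power to total noise power
    over all channels and samples, in dB; ``None`` disables noise.
    """
    Mm = M.M if isinstance(M, LeadField) else np.asarray(M, dtype=float)
    J_true = np.asarray(J_true, dtype=float)
    if not (np.all(np.isfinite(Mm)) and np.all(np.isfinite(J_true))):
        raise ValueError("non-finite inputs")
    if Mm.shape[1] != J_true.shape[0]:
        raise ValueError("lead-field column count must match source row count")
    signal = Mm @ J_true
    if snr_db is None:
        noise = np.zeros_like(signal)
    else:
        rng = np.random.default_rng(seed)
        p_sig = np.mean(signal**2)
        if p_sig == 0.0:
            sd = 1.0   # pure-noise recording: unit-variance noise
        else:
            sd = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
        noise = sd * rng.standard_normal(signal.shape)
    return SimulatedRecording(
        X=signal + noise,
        J_true=J_true,
        active_centers=list(active_centers or []),
        fs=float(fs),
        snr_db=snr_db,
        seed=int(seed),
        noise=noise,
    )
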