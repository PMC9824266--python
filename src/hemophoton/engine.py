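"""Monte Carlo photon-packet transport through a voxel tissue grid.

The transport loop per packet is: resolve the material at the current
position (composite skin resolves its sublayer from depth), sample a step
``-ln(xi)/mu_t``, move with voxel traversal, handle label-boundary crossings
by relocating to the ray/face intersection and reflecting or refracting
there, deposit ``dW = W mu_a / mu_t`` at the interaction site, redirect with
the Henyey-Greenstein phase function, and terminate by exit to ambient,
Russian roulette below the weight cutoff, a maximum elapsed time, or an
interaction-count cap.

Reflectance at interfaces is Schlick's approximation squared (``as_printed``,
the default); ``schlick_direct`` and the exact unpolarized Fresnel average
are selectable.  Total internal reflection forces R = 1 under every model.
At a boundary the unused remainder of the sampled step is resampled in the
new medium by default; an MCML-style dimensionless-step carry is available.

The module also exposes the individual transport operations on a
:class:`PhotonPacket` for testing and didactic use; :func:`run` drives the
compiled kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from . import _kernels
from ._kernels import C_MM_NS
from .phantoms import AMBIENT, MATERIAL_LABELS, SKIN, CompositeRegion, VoxelGrid
from .tissue_optics import (
    MATERIAL_NAMES,
    SKIN_SUBLAYERS,
    BloodState,
    material_properties,
)

REFLECTANCE_MODELS = {
    "as_printed": _kernels.MODEL_AS_PRINTED,
    "schlick_direct": _kernels.MODEL_SCHLICK_DIRECT,
    "fresnel_exact": _kernels.MODEL_FRESNEL_EXACT,
}
STEP_RULES = {"resample": _kernels.STEP_RESAMPLE, "carry": _kernels.STEP_CARRY}


@dataclass
class PhotonPacket:
    """State of one photon packet."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    elapsed_time: float = 0.0  # ns
    path_length: float = 0.0  # mm
    material: int = AMBIENT
    alive: bool = True
    out: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, float).copy()
        d = np.asarray(self.direction, float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("photon direction must be a nonzero vector")
        self.direction = d / norm


@dataclass(frozen=True)
class EngineConfig:
    """Engine knobs.

    ``n_photons`` defaults to 1e5 (a desk-scale photon budget; raise it for
    production-grade noise floors).  Roulette fires below ``roulette_cutoff``
    and survives with probability ``1/roulette_constant`` at amplified
    weight.  Times are in ns.
    """

    n_photons: int = 100_000
    seed: int = 0
    roulette_cutoff: float = 0.001
    roulette_constant: float = 10.0
    max_time_ns: float = 1.0
    time_bin_ns: float = 0.01
    reflectance_model: str = "as_printed"
    step_rule: str = "resample"
    max_interactions: int = 1_000_000

    def __post_init__(self):
        if not 0.0 < self.roulette_cutoff < 1.0:
            raise ValueError("roulette cutoff must lie in (0, 1)")
        if self.roulette_constant <= 1.0:
            raise ValueError("roulette constant must exceed 1")
        if self.time_bin_ns <= 0:
            raise ValueError("time bin width must be positive")
        if self.reflectance_model not in REFLECTANCE_MODELS:
            raise ValueError(f"unknown reflectance model {self.reflectance_model!r}")
        if self.step_rule not in STEP_RULES:
            raise ValueError(f"unknown step rule {self.step_rule!r}")

    @property
    def n_time_bins(self) -> int:
        return max(1, int(np.ceil(self.max_time_ns / self.time_bin_ns)))


@dataclass
class DetectionResult:
    """Accumulated output of one transport run."""

    exit_weight: np.ndarray  # (nx, ny, nz) total exit weight per boundary voxel
    exit_weight_sq: np.ndarray  # (nx, ny, nz) sum of squared exit weights
    exit_weight_t: np.ndarray  # (nx, ny, nz, n_bins) time-resolved exit weight
    absorbed_weight: np.ndarray  # (nx, ny, nz)
    time_edges_ns: np.ndarray  # (n_bins + 1,)
    totals: dict[str, float]
    seed: int
    config: EngineConfig
    pitch: float = 0.5
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def launched(self) -> float:
        return self.totals["launched"]

    @property
    def total_exited(self) -> float:
        return self.totals["exited"]

    @property
    def total_absorbed(self) -> float:
        return self.totals["absorbed"]

    def energy_balance(self) -> float:
        """Launched weight minus all termination tallies (0 up to roundoff)."""
        t = self.totals
        return t["launched"] - (
            t["exited"] + t["absorbed"] + t["roulette_killed"] + t["timeout"] + t["cap_killed"]
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("exit_weight", data=self.exit_weight, compression="gzip")
            f.create_dataset("exit_weight_sq", data=self.exit_weight_sq, compression="gzip")
            f.create_dataset("exit_weight_t", data=self.exit_weight_t, compression="gzip")
            f.create_dataset("absorbed_weight", data=self.absorbed_weight, compression="gzip")
            f.create_dataset("time_edges_ns", data=self.time_edges_ns)
            f.attrs["seed"] = self.seed
            f.attrs["pitch"] = self.pitch
            f.attrs["origin"] = self.origin
            for k, v in self.totals.items():
                f.attrs[f"total_{k}"] = v
            for k, v in vars(self.config).items():
                f.attrs[f"config_{k}"] = v

    @classmethod
    def load(cls, path) -> "DetectionResult":
        with h5py.File(path, "r") as f:
            totals = {
                k[len("total_"):]: float(f.attrs[k])
                for k in f.attrs
                if k.startswith("total_")
            }
            cfg_kwargs = {
                k[len("config_"):]: f.attrs[k] for k in f.attrs if k.startswith("config_")
            }
            for key in ("n_photons", "seed", "max_interactions"):
                cfg_kwargs[key] = int(cfg_kwargs[key])
            for key in ("reflectance_model", "step_rule"):
                cfg_kwargs[key] = str(cfg_kwargs[key])
            return cls(
                exit_weight=f["exit_weight"][()],
                exit_weight_sq=f["exit_weight_sq"][()],
                exit_weight_t=f["exit_weight_t"][()],
                absorbed_weight=f["absorbed_weight"][()],
                time_edges_ns=f["time_edges_ns"][()],
                totals=totals,
                seed=int(f.attrs["seed"]),
                config=EngineConfig(**cfg_kwargs),
                pitch=float(f.attrs["pitch"]),
                origin=np.asarray(f.attrs["origin"]),
            )


# --- unit operations (Python-level, mirrored by the kernel) ---------------


def launch_photon(position, direction, grid: VoxelGrid | None = None) -> PhotonPacket:
    """A fresh packet with W = 1 and the material resolved at the position."""
    p = PhotonPacket(position=position, direction=direction)
    if grid is not None:
        idx = grid.world_to_index(p.position)
        if grid.contains_index(idx):
            p.material = int(grid.labels[idx])
        else:
            p.material = AMBIENT
            p.out = True
            p.alive = False
    return p


def sample_step(mu_t: float, xi: float) -> float:
    """Free-path step -ln(xi)/mu_t, mm."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive in a sampling medium")
    if not 0.0 < xi <= 1.0:
        raise ValueError("xi must lie in (0, 1]")
    return -np.log(xi) / mu_t

def move_photon(packet: PhotonPacket, step: float, n_medium: float = 1.0) -> PhotonPacket:
    """Advance the packet; elapsed time grows by step * n / c."""
    packet.position = packet.position + packet.direction * step
    packet.path_length += step
    packet.elapsed_time += step * n_medium / C_MM_NS
    return packet


def detect_boundary_crossing(grid: VoxelGrid, position, direction, step: float):
    """Ray/voxel-face intersection of a move that may change material label.

    Returns ``None`` when the full step stays within the starting label,
    otherwise a dict with the intersection point, the outward (axis-aligned)
    face normal of the entered region, the distance to the face, and the
    previous/next voxel indices.
    """
    pos = np.asarray(position, float)
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    ix, iy, iz = grid.world_to_index(pos)
    if not grid.contains_index((ix, iy, iz)):
        raise ValueError("starting position outside the grid")
    flag, d, axis, pix, piy, piz, nix, niy, niz = _kernels.traverse(
        grid.labels, ix, iy, iz, pos[0], pos[1], pos[2], u[0], u[1], u[2],
        grid.pitch, grid.origin[0], grid.origin[1], grid.origin[2], float(step),
    )
    if flag == 0:
        return None
    normal = np.zeros(3)
    normal[axis] = -np.sign(u[axis])  # outward from the entered region
    return {
        "point": pos + u * d,
        "normal": normal,
        "distance": float(d),
        "axis": int(axis),
        "prev_voxel": (pix, piy, piz),
        "next_voxel": (nix, niy, niz),
        "left_grid": flag == 2,
    }


def reflectance(theta_incident: float, n1: float, n2: float, model: str = "as_printed") -> float:
    """Power reflectance R in [0, 1]; TIR returns 1 under every model."""
    if not 0.0 <= theta_incident <= np.pi / 2:
        raise ValueError("incidence angle must lie in [0, pi/2]")
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices must be >= 1")
    return float(
        _kernels.reflectance_coeff(np.cos(theta_incident), n1, n2, REFLECTANCE_MODELS[model])
    )


def reflect_or_refract(packet: PhotonPacket, normal, n1: float, n2: float,
                       R: float, xi: float) -> PhotonPacket:
    """Specular reflection with probability R, vector-Snell refraction otherwise."""
    nvec = np.asarray(normal, float)
    nvec = nvec / np.linalg.norm(nvec)
    u = packet.direction
    if xi < R:
        packet.direction = u - 2.0 * np.dot(u, nvec) * nvec
    else:
        if np.dot(u, nvec) > 0:
            nvec = -nvec  # orient against propagation
        eta = n1 / n2
        cosi = -np.dot(u, nvec)
        sint2 = eta * eta * (1.0 - cosi * cosi)
        if sint2 >= 1.0:
            packet.direction = u - 2.0 * np.dot(u, nvec) * nvec  # forced TIR
        else:
            cost = np.sqrt(1.0 - sint2)
            packet.direction = eta * u + (eta * cosi - cost) * nvec
    packet.direction = packet.direction / np.linalg.norm(packet.direction)
    return packet


def absorb(packet: PhotonPacket, mu_a: float, mu_t: float) -> float:
    """Deposit and return dW = W mu_a / mu_t."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive")
    dW = packet.weight * mu_a / mu_t
    packet.weight -= dW
    return dW


def hg_cosines(g: float, xi) -> np.ndarray | float:
    """Deflection cosines from the HG inverse CDF (vectorized over xi)."""
    if abs(g) >= 1.0:
        raise ValueError("|g| must be < 1")
    xi = np.asarray(xi, float)
    if g == 0.0:
        out = 1.0 - 2.0 * xi
    else:
        f = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
        out = np.clip((1.0 + g * g - f * f) / (2.0 * g), -1.0, 1.0)
    return out if out.ndim else float(out)


def hg_scatter(packet: PhotonPacket, g: float, xi1: float, xi2: float) -> PhotonPacket:
    """Redirect the packet by an HG deflection and a uniform azimuth."""
    cost = hg_cosines(g, xi1)
    phi = 2.0 * np.pi * xi2
    packet.direction = np.array(
        _kernels.rotate_direction(*packet.direction, cost, phi)
    )
    return packet


def roulette(packet: PhotonPacket, xi: float, cutoff: float = 0.001,
             rc: float = 10.0) -> PhotonPacket:
    """Russian roulette: survive with probability 1/rc at weight rc * W."""
    if packet.weight >= cutoff:
        return packet
    if xi <= 1.0 / rc:
        packet.weight *= rc
    else:
        packet.weight = 0.0
        packet.alive = False
    return packet


# --- full run --------------------------------------------------------------


def _build_property_rows(state: BloodState, wavelength_nm: float,
                         overrides: dict | None = None):
    """Flatten material properties into kernel rows.

    Row layout: one row per static label in MATERIAL_NAMES order, then the six
    skin sublayer rows.  ``label_row[label]`` maps a label to its row; the skin
    label instead resolves a sublayer row at run time.  ``overrides`` maps a
    material name (or ``skin/<sublayer index>``) to an OpticalProperties used
    verbatim — handy for idealized media in validation runs.
    """
    overrides = overrides or {}
    n_static = len(MATERIAL_NAMES)
    n_sub = len(SKIN_SUBLAYERS)
    props = np.zeros((n_static + n_sub, 4))
    label_row = np.arange(n_static, dtype=np.int64)
    for lab, name in enumerate(MATERIAL_NAMES):
        if name == "skin":
            continue
        p = overrides.get(name) or material_properties(name, state, wavelength_nm)
        props[lab] = (p.mu_a, p.mu_s, p.g, p.n)
    for s in range(n_sub):
        p = overrides.get(f"skin/{s}") or material_properties(
            "skin", state, wavelength_nm, sublayer=s
        )
        props[n_static + s] = (p.mu_a, p.mu_s, p.g, p.n)
    return props, label_row, n_static


def _candidate_csr(grid: VoxelGrid, region: CompositeRegion | None):
    """Per-voxel candidate reference points for composite depth lookups.

    Candidates are all reference points within (deepest edge + voxel diagonal)
    of the voxel centroid; any voxel whose list is empty is deeper than the
    last edge for every interior position and clamps to the deepest sublayer.
    """
    nvox = int(np.prod(grid.shape))
    if region is None:
        return (
            np.zeros((1, 3)),
            np.zeros(nvox + 1, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
        )
    skin_mask = grid.labels == region.label
    flat = np.flatnonzero(skin_mask.ravel())
    centroids = grid.centroids(skin_mask)
    radius = float(region.depth_edges_mm[-1]) + np.sqrt(3.0) * grid.pitch
    lists = region._tree.query_ball_point(centroids, r=radius)
    indptr = np.zeros(nvox + 1, dtype=np.int64)
    counts = np.array([len(l) for l in lists], dtype=np.int64)
    indptr_flat = np.zeros(nvox, dtype=np.int64)
    indptr_flat[flat] = counts
    indptr[1:] = np.cumsum(indptr_flat)
    idx = np.empty(int(counts.sum()), dtype=np.int64)
    for v, lst in zip(flat, lists):
        a = indptr[v]
        idx[a : a + len(lst)] = lst
    return region.reference_points.astype(float), indptr, idx


def run(
    grid: VoxelGrid,
    state: BloodState,
    wavelength_nm: float,
    source_position,
    source_direction,
    config: EngineConfig = EngineConfig(),
    region: CompositeRegion | None = None,
    material_overrides: dict | None = None,
) -> DetectionResult:
    """Propagate ``config.n_photons`` packets from a pencil source.

    ``region`` supplies runtime sublayer resolution for the composite skin
    label; it is required whenever the grid contains skin voxels.
    ``material_overrides`` maps material names to OpticalProperties, replacing
    the model-derived values (for idealized validation media).
    """
    if region is None and np.any(grid.labels == SKIN):
        raise ValueError("grid contains composite skin voxels: a CompositeRegion is required")

    props, label_row, n_static = _build_property_rows(state, wavelength_nm, material_overrides)
    refpts, indptr, cand_idx = _candidate_csr(grid, region)
    edges = (
        np.asarray(region.depth_edges_mm, float)
        if region is not None
        else np.asarray([np.inf])
    )
    composite_label = region.label if region is not None else -1

    src_pos = np.asarray(source_position, float)
    src_dir = np.asarray(source_direction, float)
    norm = np.linalg.norm(src_dir)
    if norm == 0:
        raise ValueError("source direction must be nonzero")
    src_dir = src_dir / norm

    nx, ny, nz = grid.shape
    n_bins = config.n_time_bins
    exit_w = np.zeros((nx, ny, nz))
    exit_sq = np.zeros((nx, ny, nz))
    exit_wt = np.zeros((nx, ny, nz, n_bins), dtype=np.float32)
    absorbed = np.zeros((nx, ny, nz))
    totals = np.zeros(_kernels.N_TOTALS)

    _kernels.run_kernel(
        grid.labels,
        label_row,
        composite_label,
        n_static,
        props,
        edges,
        refpts,
        indptr,
        cand_idx,
        grid.origin,
        grid.pitch,
        src_pos,
        src_dir,
        int(config.n_photons),
        int(config.seed),
        float(config.roulette_cutoff),
        float(config.roulette_constant),
        float(config.max_time_ns),
        float(config.time_bin_ns),
        REFLECTANCE_MODELS[config.reflectance_model],
        STEP_RULES[config.step_rule],
        int(config.max_interactions),
        exit_w,
        exit_sq,
        exit_wt,
        absorbed,
        totals,
    )

    totals_dict = {
        "launched": totals[_kernels.TOT_LAUNCHED],
        "exited": totals[_kernels.TOT_EXITED],
        "absorbed": totals[_kernels.TOT_ABSORBED],
        "roulette_killed": totals[_kernels.TOT_ROULETTE],
        "timeout": totals[_kernels.TOT_TIMEOUT],
        "cap_killed": totals[_kernels.TOT_CAP],
    }
    time_edges = np.arange(n_bins + 1) * config.time_bin_ns
    return DetectionResult(
        exit_weight=exit_w,
        exit_weight_sq=exit_sq,
        exit_weight_t=exit_wt,
        absorbed_weight=absorbed,
        time_edges_ns=time_edges,
        totals=totals_dict,
        seed=config.seed,
        config=config,
        pitch=grid.pitch,
        origin=grid.origin,
    )
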