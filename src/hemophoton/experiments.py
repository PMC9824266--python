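"""Source/detector layouts, physiological sweeps and ratio lookup tables.

Four layouts are supported: fingertip transmission (source on the soft
ventral side, detector on the nail), fingertip reflection (detector 2 mm
from the source on the same surface), wrist single-PD (one detector 2 mm
from the source, three wavelengths) and wrist multi-PD (three detectors at
increasing distance, one 615 nm source).

A sweep runs the transport engine over a (HbA1c, SpO2, phase) grid per
channel and produces a :class:`RatioLUT`.  Per channel, the pulsatile and
baseline components follow the standard PPG convention

    DC = I_diastolic,   AC = I_diastolic - I_systolic

(systole doubles the dermal blood volume, so absorbs more and transmits
less), and the ratio-of-ratios are

    R1 = (AC/DC)_525 / (AC/DC)_615,   R2 = (AC/DC)_465 / (AC/DC)_615

for wavelength channels, or sensor1/sensor3 and sensor2/sensor3 for the
multi-PD layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import DetectionResult, EngineConfig, run
from .phantoms import AMBIENT, NAIL, CompositeRegion, VoxelGrid
from .tissue_optics import BloodState

#: The HbA1c sweep values (fractions); densest where clinically most relevant.
HBA1C_VALUES = (
    0.03, 0.035, 0.04, 0.045, 0.05, 0.055, 0.056, 0.057, 0.058, 0.059,
    0.06, 0.061, 0.062, 0.063, 0.064, 0.065, 0.07, 0.075, 0.08, 0.085,
    0.09, 0.10, 0.11, 0.12, 0.13, 0.14,
)
#: The SpO2 sweep values (fractions); densest over the common 95-100 % range.
SPO2_VALUES = (0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.96, 0.97, 0.98, 0.99, 1.0)

PHASES = ("systolic", "diastolic")
WAVELENGTH_CHANNELS = (465.0, 525.0, 615.0)
SENSOR_CHANNELS = ("sensor1", "sensor2", "sensor3")
MULTI_PD_WAVELENGTH = 615.0

LAYOUT_KINDS = (
    "fingertip_transmission",
    "fingertip_reflection",
    "wrist_single_pd",
    "wrist_multi_pd",
)


@dataclass(frozen=True)
class DetectorSpec:
    """A circular collection region on the phantom surface."""

    position: tuple[float, float, float]  # mm, on the ambient-facing surface
    radius: float = 0.5  # mm
    label: str = "sensor1"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("detector radius must be positive")


@dataclass(frozen=True)
class SweepGrid:
    """The physiological grid of a sweep; defaults enumerate 572 configurations."""

    hba1c: tuple[float, ...] = HBA1C_VALUES
    spo2: tuple[float, ...] = SPO2_VALUES
    phases: tuple[str, ...] = PHASES
    wavelengths: tuple[float, ...] = WAVELENGTH_CHANNELS

    @property
    def n_configurations(self) -> int:
        return len(self.hba1c) * len(self.spo2) * len(self.phases)


@dataclass
class Layout:
    source_position: np.ndarray
    source_direction: np.ndarray
    detectors: tuple[DetectorSpec, ...]
    channels: tuple  # wavelengths (floats) or sensor labels (strs)
    kind: str


def _surface_voxel(grid: VoxelGrid, ix: int, iy: int, side: str) -> tuple[int, int, int]:
    """Outermost tissue voxel along z in column (ix, iy); side 'low' or 'high'."""
    column = grid.labels[ix, iy, :]
    tissue = np.flatnonzero(column != AMBIENT)
    if tissue.size == 0:
        raise ValueError(f"column ({ix}, {iy}) contains no tissue")
    k = tissue[0] if side == "low" else tissue[-1]
    return ix, iy, int(k)


def _surface_point(grid: VoxelGrid, ix: int, iy: int, side: str) -> np.ndarray:
    """World point on the ambient-facing face of the outermost tissue voxel."""
    i, j, k = _surface_voxel(grid, ix, iy, side)
    c = grid.index_to_world((i, j, k))
    c[2] += (-0.5 if side == "low" else 0.5) * grid.pitch
    return c


def layout(kind: str, grid: VoxelGrid, separation_mm: float = 2.0,
           detector_radius: float = 0.5,
           multi_pd_separations: tuple[float, ...] = (2.0, 4.0, 6.0)) -> Layout:
    """Source and detector placement for one of the four experiment kinds.

    Positions are derived from the phantom geometry: the fingertip source
    sits on the ventral (low-z) surface and the wrist source on the dorsal
    (high-z) surface; reflection detectors are offset along the limb axis
    (+y) so they stay on the surface.
    """
    if kind not in LAYOUT_KINDS:
        raise ValueError(f"unknown layout kind {kind!r}; choose from {LAYOUT_KINDS}")
    nx, ny, nz = grid.shape
    cxi, cyi = nx // 2, ny // 2
    tissue_y = np.flatnonzero(np.any(grid.labels != AMBIENT, axis=(0, 2)))
    if tissue_y.size == 0:
        raise ValueError("grid contains no tissue")

    if kind.startswith("fingertip"):
        src = _surface_point(grid, cxi, cyi, "low")
        src[2] -= 0.5 * grid.pitch  # just outside, aimed into the tissue
        direction = np.array([0.0, 0.0, 1.0])
        if kind == "fingertip_transmission":
            nail_mask = grid.labels == NAIL
            if not nail_mask.any():
                raise ValueError("transmission layout needs a nail patch on the phantom")
            nail_c = grid.centroids(nail_mask)
            top = nail_c[np.argmax(nail_c[:, 2])]
            # detector centred on the nail patch, on its outer surface
            det_pos = np.array([np.mean(nail_c[:, 0]), np.mean(nail_c[:, 1]), top[2]])
            dets = (DetectorSpec(tuple(det_pos), detector_radius, "sensor1"),)
        else:
            dyi = int(round(separation_mm / grid.pitch))
            det_pos = _surface_point(grid, cxi, cyi + dyi, "low")
            dets = (DetectorSpec(tuple(det_pos), detector_radius, "sensor1"),)
        return Layout(src, direction, dets, WAVELENGTH_CHANNELS, kind)

    # wrist: dorsal surface, source above the vessel midline; the source sits
    # near the proximal tissue edge so multi-PD offsets stay on the surface
    max_sep = max((separation_mm, *multi_pd_separations))
    syi = int(tissue_y[0]) + 2
    if syi + int(round(max_sep / grid.pitch)) > tissue_y[-1]:
        raise ValueError("wrist phantom too short for the detector separations")
    src = _surface_point(grid, cxi, syi, "high")
    src[2] += 0.5 * grid.pitch
    direction = np.array([0.0, 0.0, -1.0])
    if kind == "wrist_single_pd":
        dyi = int(round(separation_mm / grid.pitch))
        det_pos = _surface_point(grid, cxi, syi + dyi, "high")
        dets = (DetectorSpec(tuple(det_pos), detector_radius, "sensor1"),)
        return Layout(src, direction, dets, WAVELENGTH_CHANNELS, kind)
    dets = []
    for i, sep in enumerate(multi_pd_separations):
        dyi = int(round(sep / grid.pitch))
        det_pos = _surface_point(grid, cxi, syi + dyi, "high")
        dets.append(DetectorSpec(tuple(det_pos), detector_radius, f"sensor{i + 1}"))
    return Layout(src, direction, tuple(dets), SENSOR_CHANNELS, kind)


def extract_intensity(result: DetectionResult, det: DetectorSpec,
                      with_se: bool = False):
    """Summed exit weight over boundary voxels within the detector radius.

    All exit angles are accepted.  With ``with_se`` the Monte Carlo standard
    error (from the per-voxel sum of squared exit weights) is also returned.
    """
    nx, ny, nz = result.exit_weight.shape
    idx = np.indices((nx, ny, nz)).reshape(3, -1).T
    centroids = result.origin + (idx + 0.5) * result.pitch
    d2 = np.sum((centroids - np.asarray(det.position)) ** 2, axis=1)
    mask = (d2 <= det.radius**2).reshape(nx, ny, nz)
    if not mask.any():
        raise ValueError(
            f"detector {det.label!r} at {det.position} (r={det.radius} mm) "
            "covers no voxel centroids"
        )
    intensity = float(result.exit_weight[mask].sum())
    if not with_se:
        return intensity
    se = float(np.sqrt(result.exit_weight_sq[mask].sum()))
    return intensity, se


def select_multi_pd_positions(results: list[DetectionResult],
                              candidates: list[DetectorSpec],
                              source_position=None) -> tuple[DetectorSpec, ...]:
    """Pick the three candidate detectors with the highest intensity variance.

    ``results`` is a (possibly coarse) sweep over the physiological grid.
    Candidates are ranked by the variance of their extracted intensity across
    the sweep; ties break by ascending distance from the source.  The chosen
    three must be mutually non-overlapping circles.
    """
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate detector positions")
    intens = np.array(
        [[extract_intensity(res, det) for res in results] for det in candidates]
    )
    variances = intens.var(axis=1)
    if source_position is not None:
        dist = np.array(
            [np.linalg.norm(np.asarray(d.position) - np.asarray(source_position))
             for d in candidates]
        )
    else:
        dist = np.arange(len(candidates), dtype=float)
    order = np.lexsort((dist, -variances))
    chosen: list[DetectorSpec] = []
    for i in order:
        det = candidates[i]
        if all(
            np.linalg.norm(np.asarray(det.position) - np.asarray(c.position))
            >= det.radius + c.radius
            for c in chosen
        ):
            chosen.append(det)
        if len(chosen) == 3:
            return tuple(chosen)
    raise ValueError("fewer than 3 viable (non-overlapping) candidate positions")


LUT_COLUMNS = [
    "hba1c", "spo2", "channel", "i_systolic", "i_diastolic", "ac", "dc", "r1", "r2",
]


@dataclass
class RatioLUT:
    """Forward lookup table from physiological state to detector ratios.

    ``channels`` holds one row per (HbA1c, SpO2, channel) with the phase-pair
    intensities and AC/DC; ``ratios`` one row per (HbA1c, SpO2) with R1, R2.
    """

    channels: pd.DataFrame
    ratios: pd.DataFrame
    kind: str = "fingertip_reflection"

    def to_csv(self, path) -> None:
        df = self.channels.merge(self.ratios, on=["hba1c", "spo2"])
        df["kind"] = self.kind
        df[LUT_COLUMNS + ["kind"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RatioLUT":
        df = pd.read_csv(path)
        missing = set(LUT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"ratio LUT missing columns {sorted(missing)}")
        kind = str(df["kind"].iloc[0]) if "kind" in df.columns else "fingertip_reflection"
        channels = df[LUT_COLUMNS[:7]].copy()
        ratios = df[["hba1c", "spo2", "r1", "r2"]].drop_duplicates().reset_index(drop=True)
        return cls(channels=channels, ratios=ratios, kind=kind)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name, df in (("channels", self.channels), ("ratios", self.ratios)):
                grp = f.create_group(name)
                for col in df.columns:
                    data = df[col].to_numpy()
                    if data.dtype == object:
                        data = data.astype("S")
                    grp.create_dataset(col, data=data)
            f.attrs["kind"] = self.kind

    def row(self, hba1c: float, spo2: float) -> pd.DataFrame:
        sel = self.channels[
            np.isclose(self.channels.hba1c, hba1c) & np.isclose(self.channels.spo2, spo2)
        ]
        if sel.empty:
            raise KeyError(f"no LUT rows at HbA1c={hba1c}, SpO2={spo2}")
        return sel


def _ratio_pair(acdc: dict, kind: str) -> tuple[float, float]:
    """R1, R2 from per-channel AC/DC values keyed by channel."""
    if kind == "wrist_multi_pd":
        return acdc["sensor1"] / acdc["sensor3"], acdc["sensor2"] / acdc["sensor3"]
    return acdc[525.0] / acdc[615.0], acdc[465.0] / acdc[615.0]


def compute_ratios(acdc: dict, kind: str) -> tuple[float, float]:
    return _ratio_pair(acdc, kind)


def sweep(
    grid: VoxelGrid,
    region: CompositeRegion | None,
    lay: Layout,
    sweep_grid: SweepGrid = SweepGrid(),
    config: EngineConfig = EngineConfig(),
    ac_dc_convention: str = "diastolic",
    progress: bool = False,
) -> RatioLUT:
    """Run the engine over the physiological grid and build the ratio LUT.

    One engine run per (HbA1c, SpO2, phase) per wavelength channel; the
    multi-PD layout runs a single 615 nm simulation per state and extracts
    all three sensors from it.  Each (HbA1c, SpO2, wavelength) cell gets a
    distinct deterministic seed derived from ``config.seed``, shared by its
    systolic/diastolic pair: with common random numbers the paired
    AC = I_dia - I_sys difference is far less noisy than two independent
    runs would give.

    ``ac_dc_convention``: 'diastolic' (DC = I_dia, the default) or 'mean'
    (DC = (I_sys + I_dia)/2); AC = I_dia - I_sys in both.
    """
    if ac_dc_convention not in ("diastolic", "mean"):
        raise ValueError("ac_dc_convention must be 'diastolic' or 'mean'")
    multi_pd = lay.kind == "wrist_multi_pd"
    wavelengths = (MULTI_PD_WAVELENGTH,) if multi_pd else sweep_grid.wavelengths

    records = []
    cell_idx = 0
    for hba1c in sweep_grid.hba1c:
        for spo2 in sweep_grid.spo2:
            for lam in wavelengths:
                seed = (int(config.seed) + 9973 * cell_idx) % 2**31
                cell_idx += 1
                cfg = EngineConfig(**{**vars(config), "seed": seed})
                for phase in sweep_grid.phases:
                    state = BloodState(hba1c=hba1c, spo2_arterial=spo2, phase=phase)
                    res = run(grid, state, lam, lay.source_position,
                              lay.source_direction, cfg, region)
                    if multi_pd:
                        for det in lay.detectors:
                            records.append(
                                (hba1c, spo2, phase, det.label,
                                 extract_intensity(res, det))
                            )
                    else:
                        records.append(
                            (hba1c, spo2, phase, lam,
                             extract_intensity(res, lay.detectors[0]))
                        )
            if progress:  # pragma: no cover
                print(f"sweep: HbA1c={hba1c} SpO2={spo2} done")

    long = pd.DataFrame(records, columns=["hba1c", "spo2", "phase", "channel", "intensity"])
    wide = long.pivot_table(
        index=["hba1c", "spo2", "channel"], columns="phase", values="intensity"
    ).reset_index()
    wide = wide.rename(columns={"systolic": "i_systolic", "diastolic": "i_diastolic"})
    wide["ac"] = wide["i_diastolic"] - wide["i_systolic"]
    if ac_dc_convention == "diastolic":
        wide["dc"] = wide["i_diastolic"]
    else:
        wide["dc"] = 0.5 * (wide["i_diastolic"] + wide["i_systolic"])
    if (wide["dc"] == 0).any():
        bad = wide.loc[wide["dc"] == 0, ["hba1c", "spo2", "channel"]]
        raise ValueError(
            f"zero DC intensity at grid points:\n{bad}\n"
            "(undersampled: raise n_photons or enlarge the detector)"
        )

    rows = []
    for (h, s), sub in wide.groupby(["hba1c", "spo2"]):
        acdc = {row.channel: row.ac / row.dc for row in sub.itertuples()}
        r1, r2 = _ratio_pair(acdc, lay.kind)
        rows.append((h, s, r1, r2))
    ratios = pd.DataFrame(rows, columns=["hba1c", "spo2", "r1", "r2"])
    return RatioLUT(channels=wide, ratios=ratios, kind=lay.kind)
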