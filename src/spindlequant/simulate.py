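"""Synthetic cell populations with known ground truth.

The generator produces the three spindle-elongation phenotypes as piecewise
kinetic traces on the acquisition frame grid (formation-anchored: t = 0 is the
SPB-separation frame), sister-chromatid tracks with a separation-time offset
that may precede formation, and rendered fluorescence z-stacks in which each
focus is an anisotropic 3D Gaussian of known integrated counts and the
pericentric Cohesin signal is a cylindrical "barrel" between the SPBs at a
known enrichment over nuclear background.

Everything is driven by ``numpy.random.Generator``; the same seed and
parameters reproduce a cell bit-identically.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import erf

from .core import CellRecord, ImageStack, SisterTrack, SpindleTrajectory
from .params import OpticsParams, PhenotypeParams

RngLike = Union[int, np.random.Generator]

# Transient shortening events are kept inside the post-formation elongation
# phase and apart from each other so dips never stack (the class-conditional
# rule guarantees depend on a bounded dip amplitude).
_DIP_WINDOW = (8.0, 50.0)
_DIP_MIN_SEPARATION = 5.0


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    """Rejection-sampled normal truncated below at ``low``."""
    if sd == 0:
        return max(mean, low)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    return low + abs(rng.normal(0.0, sd))


def _frame_grid(optics: Optional[OpticsParams]) -> tuple[np.ndarray, float]:
    if optics is None:
        optics = OpticsParams()
    t = np.arange(optics.n_frames) * optics.frame_interval
    return t, optics.frame_interval


def simulate_trajectory(
    params: PhenotypeParams,
    cls: str,
    seed: RngLike,
    optics: Optional[OpticsParams] = None,
) -> tuple[SpindleTrajectory, dict]:
    """Simulate one spindle-length trace of a given phenotype class.

    Returns the trajectory and a dict of ground-truth kinetics (anaphase onset
    for normal cells, elongation rate for immediate cells).

    normal
        Forms at ``formation_length_mean``, drifts at ``metaphase_drift_rate``
        for a sampled metaphase duration, then elongates at ``anaphase_rate``
        to the anaphase plateau.
    immediate
        Elongates continuously from formation at a rate drawn uniformly from
        ``immediate_rate_range``, with Poisson-sampled transient shortening
        dips (exponential recovery, 2–4 min time scale).
    failed
        Drifts slowly and never exceeds ``failed_max_length`` (< 6 μm) within
        the observation window.
    """
    if cls not in ("normal", "immediate", "failed"):
        raise ValueError(f"unknown phenotype class {cls!r}")
    rng = _as_rng(seed)
    t, dt = _frame_grid(optics)
    L0 = params.formation_length_mean
    truth: dict = {"class": cls}

    if cls == "normal":
        dur = _truncated_normal(
            rng, params.metaphase_duration_mean, params.metaphase_duration_sd,
            params.metaphase_duration_min,
        )
        meta = L0 + params.metaphase_drift_rate * t
        ana = (L0 + params.metaphase_drift_rate * dur) + params.anaphase_rate * (t - dur)
        lengths = np.where(t <= dur, meta, ana)
        lengths = np.minimum(lengths, params.anaphase_plateau)
        truth["anaphase_onset"] = dur
    elif cls == "immediate":
        lo, hi = params.immediate_rate_range
        rate = float(rng.uniform(lo, hi))
        lengths = np.minimum(L0 + rate * t, params.anaphase_plateau)
        n_events = rng.poisson(params.shortening_event_rate * (_DIP_WINDOW[1] - _DIP_WINDOW[0]))
        event_times: list[float] = []
        for te in np.sort(rng.uniform(*_DIP_WINDOW, size=n_events)):
            if not event_times or te - event_times[-1] >= _DIP_MIN_SEPARATION:
                event_times.append(float(te))
        for te in event_times:
            tau = float(rng.uniform(2.0, 4.0))
            dip = params.shortening_depth * np.exp(-(t - te) / tau)
            lengths = lengths - np.where(t >= te, dip, 0.0)
        truth["rate"] = rate
        truth["shortening_events"] = event_times
    else:  # failed
        lengths = np.minimum(L0 + params.metaphase_drift_rate * t, params.failed_max_length)

    if params.length_noise_sd > 0:
        lengths = lengths + rng.normal(0.0, params.length_noise_sd, size=lengths.shape)
    lengths = np.clip(lengths, 0.05, None)
    return SpindleTrajectory(times=t, lengths=lengths, frame_interval=dt), truth


def simulate_sister_track(
    params: PhenotypeParams,
    trajectory: SpindleTrajectory,
    seed: RngLike,
) -> SisterTrack:
    """Simulate the lacO/lacI-GFP sister-chromatid readout for one cell.

    The separation time is drawn from a normal offset distribution relative to
    spindle formation and may be negative (separation before SPB separation).
    The fate is "failed" (both sisters to one pole) with probability
    ``missegregation_prob``.  The inter-sister distance trace is ~0 while
    cohesed, then tracks a fraction of spindle length after separation for
    accurate cells, or collapses back near zero for failed cells.
    """
    rng = _as_rng(seed)
    offset = float(rng.normal(params.separation_offset_mean, params.separation_offset_sd))
    failed = bool(rng.random() < params.missegregation_prob)
    t = trajectory.times
    sep = np.zeros_like(t)
    after = t >= offset
    if failed:
        # transient opening (~0.4 μm) that collapses back to one pole
        dt_after = np.where(after, t - offset, 0.0)
        sep = np.where(after, 0.4 * np.exp(-dt_after / 5.0) + 0.1, 0.08)
    else:
        sep = np.where(after, np.minimum(0.3 * (t - offset) + 0.2, 0.8 * trajectory.lengths), 0.08)
    sep = np.clip(sep, 0.0, None)
    return SisterTrack(
        separation_time=offset,
        fate="failed" if failed else "accurate",
        times=t.copy(),
        inter_sister_distance=sep,
    )


def simulate_cell(
    params: PhenotypeParams,
    seed: RngLike,
    cls: Optional[str] = None,
    optics: Optional[OpticsParams] = None,
    cell_id: str = "cell",
    barrel_ratio_true: Optional[float] = 1.5,
) -> CellRecord:
    """Simulate one complete cell: class draw, trajectory, sister track, geometry."""
    rng = _as_rng(seed)
    if cls is None:
        names = list(params.class_probs)
        probs = np.array([params.class_probs[k] for k in names])
        cls = str(names[rng.choice(len(names), p=probs / probs.sum())])
    traj, truth = simulate_trajectory(params, cls, rng, optics=optics)
    sister = simulate_sister_track(params, traj, rng)
    azimuth = float(rng.uniform(0.0, 2 * np.pi))
    tilt = float(rng.uniform(-np.deg2rad(20), np.deg2rad(20)))  # spindles lie near the focal plane
    return CellRecord(
        cell_id=cell_id,
        trajectory=traj,
        sister_track=sister,
        true_class=cls,
        true_anaphase_onset=truth.get("anaphase_onset"),
        barrel_ratio_true=barrel_ratio_true,
        orientation=(azimuth, tilt),
        rng_seed=seed if isinstance(seed, int) else None,
    )


def simulate_population(
    params: PhenotypeParams,
    n_cells: int,
    seed: int,
    optics: Optional[OpticsParams] = None,
    cls: Optional[str] = None,
) -> list[CellRecord]:
    """Simulate ``n_cells`` independent cells from one master seed.

    Per-cell generators are spawned from a ``SeedSequence`` so the population
    is reproducible and cells are independent.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cells)
    cells = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        cells.append(
            simulate_cell(params, rng, cls=cls, optics=optics, cell_id=f"cell{i:04d}")
        )
        cells[-1].rng_seed = int(child.generate_state(1)[0] % (2**31))
    return cells


# ---------------------------------------------------------------------------
# Rendering


def _axis_fractions(n: int, step: float, mu: float, sigma: float) -> np.ndarray:
    """Fraction of a unit 1D Gaussian (mean ``mu``, sigma) integrated over each
    voxel [i*step - step/2, i*step + step/2]; pixel centers sit at integer
    multiples of ``step``."""
    edges = (np.arange(n + 1) - 0.5) * step
    c = erf((edges - mu) / (np.sqrt(2.0) * sigma))
    return 0.5 * np.diff(c)


def add_gaussian_focus(
    volume: np.ndarray,
    position_um: Sequence[float],
    counts: float,
    optics: OpticsParams,
) -> None:
    """Add a voxel-integrated anisotropic 3D Gaussian focus in place.

    ``position_um`` is (x, y, z) in μm; the focus integrates to ``counts``
    over an infinite grid, so the rendered sum falls short only by the mass
    truncated outside the field of view (≤ ~1% for in-bounds foci).
    """
    nz, ny, nx = volume.shape
    x, y, z = position_um
    fx = _axis_fractions(nx, optics.pixel_size_xy, x, optics.psf_sigma_xy)
    fy = _axis_fractions(ny, optics.pixel_size_xy, y, optics.psf_sigma_xy)
    fz = _axis_fractions(nz, optics.z_step, z, optics.psf_sigma_z)
    volume += counts * fz[:, None, None] * fy[None, :, None] * fx[None, None, :]


def focus_positions(cell: CellRecord, optics: OpticsParams, frame: int) -> dict:
    """World coordinates (μm) of SPB and sister foci for one frame.

    The spindle is centered in the field, oriented by the cell's stored
    (azimuth, z-tilt) angles; sisters sit symmetrically about the center at
    the simulated inter-sister distance along the spindle axis.
    """
    center = np.array(
        [
            (optics.n_x - 1) * optics.pixel_size_xy / 2.0,
            (optics.n_y - 1) * optics.pixel_size_xy / 2.0,
            (optics.n_slices - 1) * optics.z_step / 2.0,
        ]
    )
    az, tilt = cell.orientation
    axis = np.array(
        [np.cos(tilt) * np.cos(az), np.cos(tilt) * np.sin(az), np.sin(tilt)]
    )
    L = float(cell.trajectory.lengths[frame])
    spb_a = center - axis * (L / 2.0)
    spb_b = center + axis * (L / 2.0)
    out = {"spb": [spb_a, spb_b], "spindle_length": L, "center": center, "axis": axis}
    if cell.sister_track is not None and cell.sister_track.inter_sister_distance is not None:
        d = float(cell.sister_track.inter_sister_distance[frame])
        out["sister"] = [center - axis * (d / 2.0), center + axis * (d / 2.0)]
        out["sister_distance"] = d
    return out


def _render_cohesin_volume(
    optics: OpticsParams,
    spb_a: np.ndarray,
    spb_b: np.ndarray,
    center: np.ndarray,
    barrel_ratio: float,
    nuclear_level: float,
    nuclear_radius: float,
    barrel_radius: float,
) -> np.ndarray:
    """Nuclear sphere at ``nuclear_level`` counts/voxel with a cylindrical
    barrel between the SPBs at ``barrel_ratio`` × nuclear level."""
    zc = np.arange(optics.n_slices) * optics.z_step
    yc = np.arange(optics.n_y) * optics.pixel_size_xy
    xc = np.arange(optics.n_x) * optics.pixel_size_xy
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)  # world order (x, y, z)

    r_nuc = np.linalg.norm(pts - center, axis=-1)
    vol = np.where(r_nuc <= nuclear_radius, nuclear_level, 0.0)

    ab = spb_b - spb_a
    ab_len = np.linalg.norm(ab)
    if ab_len > 1e-9:
        u = ab / ab_len
        rel = pts - spb_a
        along = rel @ u
        radial = np.linalg.norm(rel - along[..., None] * u, axis=-1)
        margin = 0.1  # barrel stops short of the poles
        in_barrel = (
            (along >= margin)
            & (along <= ab_len - margin)
            & (radial <= barrel_radius)
            & (r_nuc <= nuclear_radius)
        )
        vol = np.where(in_barrel, nuclear_level * barrel_ratio, vol)
    return vol


def render_stack(
    cell: CellRecord,
    optics: OpticsParams,
    channels: Sequence[str] = ("spb",),
    seed: RngLike = 0,
    frames: Optional[Sequence[int]] = None,
    nuclear_level: float = 200.0,
    nuclear_radius: float = 0.9,
    barrel_radius: float = 0.35,
) -> ImageStack:
    """Render fluorescence z-stacks for a simulated cell.

    Supported channels: ``spb`` (two SPB foci), ``sister`` (two lacO/lacI
    foci) and ``cohesin`` (nuclear sphere plus Cohesin barrel between SPBs at
    the cell's ``barrel_ratio_true``).  Ground-truth coordinates per frame are
    embedded in the returned stack's sidecar metadata.
    """
    rng = _as_rng(seed)
    if frames is None:
        frames = range(min(cell.trajectory.times.size, optics.n_frames))
    frames = list(frames)
    shape = (len(channels), len(frames), optics.n_slices, optics.n_y, optics.n_x)
    data = np.full(shape, float(optics.background_level))
    fov = np.array(
        [
            (optics.n_x - 1) * optics.pixel_size_xy,
            (optics.n_y - 1) * optics.pixel_size_xy,
            (optics.n_slices - 1) * optics.z_step,
        ]
    )
    truth_frames = []
    for fi, frame in enumerate(frames):
        pos = focus_positions(cell, optics, frame)
        for p in pos["spb"]:
            if np.any(p < 0) or np.any(p > fov):
                raise ValueError(f"focus outside field of view at frame {frame}: {p}")
        record = {
            "frame": int(frame),
            "spindle_length_um": pos["spindle_length"],
            "spb_um": [list(map(float, p)) for p in pos["spb"]],
        }
        if "sister" in pos:
            record["sister_um"] = [list(map(float, p)) for p in pos["sister"]]
            record["sister_distance_um"] = pos["sister_distance"]
        truth_frames.append(record)
        for ci, ch in enumerate(channels):
            if ch == "spb":
                for p in pos["spb"]:
                    add_gaussian_focus(data[ci, fi], p, optics.focus_counts, optics)
            elif ch == "sister":
                for p in pos.get("sister", []):
                    add_gaussian_focus(data[ci, fi], p, optics.focus_counts, optics)
            elif ch == "cohesin":
                ratio = cell.barrel_ratio_true if cell.barrel_ratio_true is not None else 1.0
                data[ci, fi] += _render_cohesin_volume(
                    optics, pos["spb"][0], pos["spb"][1], pos["center"],
                    ratio, nuclear_level, nuclear_radius, barrel_radius,
                )
            else:
                raise ValueError(f"unknown channel {ch!r}")

    if optics.noise_model == "poisson":
        data = rng.poisson(np.clip(data, 0.0, None)).astype(np.float64)
    elif optics.noise_model == "gaussian":
        data = data + rng.normal(0.0, optics.gaussian_sd, size=data.shape)

    ground_truth = {
        "cell_id": cell.cell_id,
        "true_class": cell.true_class,
        "barrel_ratio_true": cell.barrel_ratio_true,
        "frames": truth_frames,
    }
    return ImageStack(
        data=data,
        pixel_size_xy=optics.pixel_size_xy,
        z_step=optics.z_step,
        frame_interval=optics.frame_interval,
        channel_map={ch: i for i, ch in enumerate(channels)},
        ground_truth=ground_truth,
    )
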