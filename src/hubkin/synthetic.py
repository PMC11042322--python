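"""Seeded synthetic-data generators with exported ground truth.

The raw live-embryo microscopy this package's analyses were designed for is
not publicly deposited, so every analysis stage is validated against movies
and track tables produced here, whose statistical structure matches the
assumptions of the downstream methods:

* photoswitched single-molecule trajectories with bound / intermediate / free
  diffusive states, localization error, and exponential photobleaching, at
  slow (500 ms) and fast (~12.5 ms) frame cadences;
* nuclei (uniform-intensity ellipsoids, optionally drifting) containing
  transient 3D-Gaussian "hubs" whose lifetimes follow a two-component
  exponential mixture;
* a second channel containing a single diffraction-limited transcription-site
  spot with prescribed hub-interaction events.

All generators are deterministic given (seed, config) and return the ground
truth alongside the data. Optical realism (PSF anisotropy, excitation
patterns, gain maps) and chromatin polymer motion are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SimConfig, rng_for

__all__ = [
    "KineticSpec",
    "HubSpec",
    "Hub",
    "Nucleus",
    "InteractionSpec",
    "gen_smt_tracks",
    "gen_hub_movie",
    "gen_locus_movie",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "intensity"]

#: Diffusion-coefficient bin edges (μm²/s) the analyses use: bound ≤ 0.08,
#: 0.08 < intermediate < 0.5, free ≥ 0.5.
D_BOUND_MAX = 0.08
D_FREE_MIN = 0.5

STATES = ("bound", "intermediate", "free")


# ---------------------------------------------------------------------------
# Single-molecule tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticSpec:
    """Ground-truth kinetic parameters for single-molecule track generation.

    ``fractions`` are the (bound, intermediate, free) state probabilities and
    must sum to 1. ``D`` gives the true diffusion coefficient of each state in
    μm²/s and must respect the analysis bins (bound ≤ 0.08, intermediate in
    (0.08, 0.5), free ≥ 0.5). Bound molecules unbind at ``unbind_rate`` (1/s)
    and photobleach at ``bleach_rate`` (1/s); the observed track end is the
    earlier of the two competing exponentials (the censoring that the k_bias
    correction targets). Non-bound molecules are lost to bleaching and
    defocalization at ``transient_loss_rate`` (free) and
    ``intermediate_loss_rate`` (defaults to the free rate; chromatin-sampling
    molecules typically stay in focus longer than freely diffusing ones).
    """

    fractions: tuple[float, float, float] = (0.3, 0.3, 0.4)
    D: tuple[float, float, float] = (0.02, 0.2, 3.0)
    unbind_rate: float = 0.2
    bleach_rate: float = 0.1
    transient_loss_rate: float = 2.0
    intermediate_loss_rate: float | None = None
    localization_error: float = 0.02
    field_size_um: float = 10.0
    # optional spatial clustering of bound molecules
    cluster_centers: tuple[tuple[float, float], ...] = ()
    cluster_sigma: float = 0.08
    clustered_fraction: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")
        if min(self.fractions) < 0:
            raise ValueError("state fractions must be non-negative")
        for rate in (self.unbind_rate, self.bleach_rate, self.transient_loss_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        db, di, df = self.D
        if not (db <= D_BOUND_MAX and D_BOUND_MAX < di < D_FREE_MIN and df >= D_FREE_MIN):
            raise ValueError(
                "state diffusion coefficients must fall in the analysis bins "
                f"(bound ≤ {D_BOUND_MAX}, intermediate in ({D_BOUND_MAX}, {D_FREE_MIN}), "
                f"free ≥ {D_FREE_MIN})"
            )
        if self.clustered_fraction and not self.cluster_centers:
            raise ValueError("clustered_fraction > 0 requires cluster_centers")


def _exp_draw(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    """n exponential draws with the given rate; +inf where rate == 0."""
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


def gen_smt_tracks(
    config: SimConfig,
    spec: KineticSpec,
    n_tracks: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate single-molecule trajectories with per-track ground truth.

    Each track draws a kinetic state from ``spec.fractions``, then performs a
    2D Brownian walk with per-axis, per-frame displacement variance
    2·D·Δt, observed through independent Gaussian localization noise of
    ``spec.localization_error`` μm per axis. Bound tracks end at the earlier
    of exponential unbinding and exponential photobleaching; non-bound tracks
    end after an exponential observation span. Every track spans ≥ 2 frames.

    Returns
    -------
    tracks : DataFrame
        Columns ``track_id, frame, x_um, y_um, intensity``; frames within a
        track are strictly consecutive.
    truth : DataFrame
        One row per track: ``track_id, state, D_true, dwell_true_s,
        bleach_time_s, observed_span_s, censored_by_bleach, n_frames,
        cluster_id, x0_um, y0_um``.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = rng_for(config.seed, "smt_tracks")
    dt = config.frame_interval

    states = rng.choice(3, size=n_tracks, p=np.asarray(spec.fractions))
    d_true = np.asarray(spec.D)[states]

    dwell = np.full(n_tracks, np.inf)
    bleach = np.full(n_tracks, np.inf)
    bound = states == 0
    inter = states == 1
    free = states == 2
    dwell[bound] = _exp_draw(rng, spec.unbind_rate, int(bound.sum()))
    bleach[bound] = _exp_draw(rng, spec.bleach_rate, int(bound.sum()))
    i_rate = (spec.transient_loss_rate if spec.intermediate_loss_rate is None
              else spec.intermediate_loss_rate)
    dwell[inter] = _exp_draw(rng, i_rate, int(inter.sum()))
    dwell[free] = _exp_draw(rng, spec.transient_loss_rate, int(free.sum()))
    observed = np.minimum(dwell, bleach)
    # cap unbleachable, never-unbinding molecules at the movie length
    observed = np.minimum(observed, config.n_frames * dt)
    n_frames = np.maximum(2, np.ceil(observed / dt).astype(int))
    n_frames = np.minimum(n_frames, config.n_frames)

    # starting positions: uniform over the field, except clustered bound tracks
    x0 = rng.uniform(0, spec.field_size_um, size=n_tracks)
    y0 = rng.uniform(0, spec.field_size_um, size=n_tracks)
    cluster_id = np.full(n_tracks, -1)
    if spec.clustered_fraction > 0:
        centers = np.asarray(spec.cluster_centers, dtype=float)
        # bound and intermediate (chromatin-sampling) molecules cluster;
        # freely diffusing ones do not
        in_cluster = (states != 2) & (rng.uniform(size=n_tracks) < spec.clustered_fraction)
        idx = np.flatnonzero(in_cluster)
        which = rng.integers(0, len(centers), size=idx.size)
        cluster_id[idx] = which
        x0[idx] = centers[which, 0] + rng.normal(0, spec.cluster_sigma, size=idx.size)
        y0[idx] = centers[which, 1] + rng.normal(0, spec.cluster_sigma, size=idx.size)

    start_frame = rng.integers(0, np.maximum(1, config.n_frames - n_frames + 1))

    rows_id, rows_f, rows_x, rows_y = [], [], [], []
    sigma_step = np.sqrt(2.0 * d_true * dt)
    for i in range(n_tracks):
        nf = n_frames[i]
        steps = rng.normal(0.0, sigma_step[i], size=(nf - 1, 2))
        pos = np.vstack([[x0[i], y0[i]], steps]).cumsum(axis=0)
        loc = pos + rng.normal(0.0, spec.localization_error, size=pos.shape)
        rows_id.append(np.full(nf, i))
        rows_f.append(start_frame[i] + np.arange(nf))
        rows_x.append(loc[:, 0])
        rows_y.append(loc[:, 1])

    intensity_rng = rng_for(config.seed, "smt_intensity")
    tracks = pd.DataFrame(
        {
            "track_id": np.concatenate(rows_id),
            "frame": np.concatenate(rows_f),
            "x_um": np.concatenate(rows_x),
            "y_um": np.concatenate(rows_y),
        }
    )
    tracks["intensity"] = intensity_rng.gamma(5.0, 20.0, size=len(tracks))

    truth = pd.DataFrame(
        {
            "track_id": np.arange(n_tracks),
            "state": np.asarray(STATES)[states],
            "D_true": d_true,
            "dwell_true_s": dwell,
            "bleach_time_s": bleach,
            "observed_span_s": observed,
            "censored_by_bleach": bleach < dwell,
            "n_frames": n_frames,
            "cluster_id": cluster_id,
            "x0_um": x0,
            "y0_um": y0,
        }
    )
    return tracks, truth


def gen_confined_tracks(
    config: SimConfig,
    D: float = 0.5,
    trap_radius_um: float = 0.3,
    n_tracks: int = 500,
    track_len: int = 20,
    localization_error: float = 0.0,
) -> pd.DataFrame:
    """2D Brownian tracks confined to a reflecting circular trap.

    Confinement makes molecules retrace their steps, producing an excess of
    backward jump angles — the compact-exploration signature probed by the
    fold-anisotropy statistic. Each track starts at the trap centre;
    candidate steps ~ N(0, 2·D·Δt) per axis are reflected at the boundary.
    """
    rng = rng_for(config.seed, "confined_tracks")
    dt = config.frame_interval
    sigma = math.sqrt(2.0 * D * dt)
    rows_id, rows_f, rows_x, rows_y = [], [], [], []
    for i in range(n_tracks):
        pos = np.zeros(2)
        xs = np.empty((track_len, 2))
        for t in range(track_len):
            if t > 0:
                pos = pos + rng.normal(0.0, sigma, size=2)
                r = np.linalg.norm(pos)
                if r > trap_radius_um:  # reflect across the boundary
                    pos = pos * (2.0 * trap_radius_um - r) / r
            xs[t] = pos
        if localization_error > 0:
            xs = xs + rng.normal(0.0, localization_error, size=xs.shape)
        rows_id.append(np.full(track_len, i))
        rows_f.append(np.arange(track_len))
        rows_x.append(xs[:, 0] + trap_radius_um)
        rows_y.append(xs[:, 1] + trap_radius_um)
    return pd.DataFrame({
        "track_id": np.concatenate(rows_id),
        "frame": np.concatenate(rows_f),
        "x_um": np.concatenate(rows_x),
        "y_um": np.concatenate(rows_y),
        "intensity": 1.0,
    })


def render_smt_movie(
    config: SimConfig,
    tracks: pd.DataFrame,
    field_size_um: float,
    psf_sigma_px: float = 1.0,
    spot_amplitude: float = 200.0,
) -> np.ndarray:
    """Render a 2D+t single-molecule movie from a track table.

    Each localization becomes a 2D Gaussian of ``psf_sigma_px`` pixels and
    ``spot_amplitude`` photons peak on a flat background; noise follows
    ``config.noise_model``. Used to exercise detection/localization/linking
    against known track identities.
    """
    n_px = int(np.ceil(field_size_um / config.pixel_size))
    movie = np.full((config.n_frames, n_px, n_px), config.background_level, dtype=np.float64)
    half = int(np.ceil(4 * psf_sigma_px))
    for row in tracks.itertuples():
        t = int(row.frame)
        if not 0 <= t < config.n_frames:
            continue
        cy = row.y_um / config.pixel_size
        cx = row.x_um / config.pixel_size
        ylo, yhi = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        xlo, xhi = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        ylo, yhi = max(ylo, 0), min(yhi, n_px)
        xlo, xhi = max(xlo, 0), min(xhi, n_px)
        if ylo >= yhi or xlo >= xhi:
            continue
        yy = np.arange(ylo, yhi)[:, None] - cy
        xx = np.arange(xlo, xhi)[None, :] - cx
        movie[t, ylo:yhi, xlo:xhi] += spot_amplitude * np.exp(
            -(yy**2 + xx**2) / (2 * psf_sigma_px**2))
    rng = rng_for(config.seed, "smt_movie_noise")
    out = np.empty_like(movie, dtype=np.float32)
    for t in range(config.n_frames):
        out[t] = _apply_noise(movie[t], config, rng)
    return out


# ---------------------------------------------------------------------------
# Hub movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hub:
    """One ground-truth hub: a transient 3D Gaussian intensity accumulation.

    ``amplitude`` is the peak height added at the hub centre, expressed as a
    multiple of the nuclear base intensity (so the noise-free peak voxel is
    ≈ base·(1 + amplitude)). ``sigma_um`` is (σz, σy, σx) in μm. The hub is
    present in frames ``birth_frame ≤ t < death_frame``.
    """

    center_um: tuple[float, float, float]  # (z, y, x)
    birth_frame: int
    death_frame: int
    amplitude: float
    sigma_um: tuple[float, float, float] = (0.35, 0.25, 0.25)
    lifetime_class: str = "short"
    nucleus_label: int = 1
    lifetime_s: float | None = None  # continuous drawn value, pre-discretization

    def __post_init__(self) -> None:
        if self.death_frame <= self.birth_frame:
            raise ValueError("death_frame must exceed birth_frame")


@dataclass(frozen=True)
class HubSpec:
    """Random-hub generation parameters.

    Lifetimes (seconds) are drawn from a two-component exponential mixture:
    with probability ``f_long`` the mean is ``tau_long``, otherwise
    ``tau_short``; the drawing component is recorded as the hub's
    ``lifetime_class``. Hub centres are placed uniformly inside the nucleus
    (margin ``edge_margin_um`` from its boundary) and birth frames uniformly
    over the movie.
    """

    n_hubs_per_nucleus: int = 6
    tau_short: float = 5.0
    tau_long: float = 60.0
    f_long: float = 0.5
    amplitude: float = 1.5
    sigma_um: tuple[float, float, float] = (0.35, 0.25, 0.25)
    edge_margin_um: float = 0.8
    min_lifetime_frames: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_long <= 1.0:
            raise ValueError("f_long must be in [0, 1]")
        if self.tau_short <= 0 or self.tau_long <= 0:
            raise ValueError("lifetime scales must be positive")


@dataclass(frozen=True)
class Nucleus:
    """Ellipsoidal nucleus: centre and semi-axes in μm (z, y, x order)."""

    label: int
    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    velocity_um_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    base_intensity: float = 60.0

    def center_at(self, frame: int) -> np.ndarray:
        return np.asarray(self.center_um) + frame * np.asarray(self.velocity_um_per_frame)

    def contains(self, point_um: np.ndarray, frame: int = 0, margin_um: float = 0.0) -> bool:
        rel = (np.asarray(point_um) - self.center_at(frame)) / (
            np.asarray(self.semi_axes_um) - margin_um
        )
        return bool(np.sum(rel**2) <= 1.0)


def _grid_um(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nz, ny, nx = config.image_shape
    z = np.arange(nz) * config.voxel_z
    y = np.arange(ny) * config.pixel_size
    x = np.arange(nx) * config.pixel_size
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _ellipsoid_mask(config: SimConfig, nuc: Nucleus, frame: int) -> np.ndarray:
    z, y, x = _grid_um(config)
    c = nuc.center_at(frame)
    a = np.asarray(nuc.semi_axes_um)
    return ((z - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((x - c[2]) / a[2]) ** 2 <= 1.0


def _add_gaussian(
    vol: np.ndarray, config: SimConfig, center_um: Sequence[float],
    sigma_um: Sequence[float], peak: float,
) -> None:
    """Add a 3D Gaussian (in place), evaluated on a ±4σ bounding box."""
    sizes = config.voxel_sizes_um
    c_vox = np.asarray(center_um) / sizes
    half = 4.0 * np.asarray(sigma_um) / sizes
    lo = np.maximum(0, np.floor(c_vox - half).astype(int))
    hi = np.minimum(vol.shape, np.ceil(c_vox + half).astype(int) + 1)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * sizes[0] - center_um[0]) / sigma_um[0]
    yy = (np.arange(lo[1], hi[1]) * sizes[1] - center_um[1]) / sigma_um[1]
    xx = (np.arange(lo[2], hi[2]) * sizes[2] - center_um[2]) / sigma_um[2]
    g = np.exp(-0.5 * (zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2))
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += peak * g


def _apply_noise(stack: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(np.maximum(stack, 0.0)).astype(np.float32)
    if config.noise_model == "gaussian":
        return (stack + rng.normal(0.0, config.gaussian_sigma, size=stack.shape)).astype(np.float32)
    return stack.astype(np.float32)


def _default_nuclei(config: SimConfig, n_nuclei: int, rng: np.random.Generator,
                    drift_um_per_frame: float = 0.0) -> list[Nucleus]:
    """Lay out n ellipsoidal nuclei on a jittered grid that fits the stack."""
    nz, ny, nx = config.image_shape
    ext = np.array([nz * config.voxel_z, ny * config.pixel_size, nx * config.pixel_size])
    n_side = math.ceil(math.sqrt(n_nuclei))
    rxy = min(2.2, min(ext[1], ext[2]) / (2 * n_side) - 0.35)
    semi = (min(2.2, ext[0] / 2 - 0.4), rxy, rxy)
    nuclei = []
    for i in range(n_nuclei):
        gy, gx = divmod(i, n_side)
        cy = (gy + 0.5) * ext[1] / n_side
        cx = (gx + 0.5) * ext[2] / n_side
        cz = ext[0] / 2
        vel = (0.0, 0.0, 0.0)
        if drift_um_per_frame > 0:
            ang = rng.uniform(0, 2 * np.pi)
            vel = (0.0, drift_um_per_frame * math.sin(ang), drift_um_per_frame * math.cos(ang))
        nuclei.append(Nucleus(label=i + 1, center_um=(cz, cy, cx), semi_axes_um=semi,
                              velocity_um_per_frame=vel))
    return nuclei


def _draw_hubs(config: SimConfig, nuclei: list[Nucleus], spec: HubSpec,
               rng: np.random.Generator) -> list[Hub]:
    hubs: list[Hub] = []
    dt = config.frame_interval
    for nuc in nuclei:
        for _ in range(spec.n_hubs_per_nucleus):
            # rejection-sample a centre inside the (frame-0) nucleus
            for _attempt in range(1000):
                u = rng.uniform(-1.0, 1.0, size=3)
                cand = nuc.center_at(0) + u * (np.asarray(nuc.semi_axes_um) - spec.edge_margin_um)
                if nuc.contains(cand, frame=0, margin_um=spec.edge_margin_um):
                    break
            else:  # pragma: no cover - geometry always admits a centre
                raise RuntimeError("could not place hub inside nucleus")
            long_lived = rng.uniform() < spec.f_long
            tau = spec.tau_long if long_lived else spec.tau_short
            lifetime_s = rng.exponential(tau)
            nf = max(spec.min_lifetime_frames, int(round(lifetime_s / dt)))
            birth = int(rng.integers(0, max(1, config.n_frames - 1)))
            death = min(birth + nf, config.n_frames)
            if death <= birth:
                death = birth + 1
            hubs.append(Hub(center_um=tuple(cand), birth_frame=birth, death_frame=death,
                            amplitude=spec.amplitude, sigma_um=spec.sigma_um,
                            lifetime_class="long" if long_lived else "short",
                            nucleus_label=nuc.label, lifetime_s=float(lifetime_s)))
    return hubs


def gen_hub_movie(
    config: SimConfig,
    n_nuclei: int = 1,
    hub_spec: HubSpec | None = None,
    hubs: Sequence[Hub] | None = None,
    nuclei: Sequence[Nucleus] | None = None,
    drift_um_per_frame: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, list[Hub], list[Nucleus]]:
    """Render a TZYX hub movie plus per-frame nuclear label maps.

    Either pass ``hubs`` explicitly (phantom construction) or a ``hub_spec``
    from which hubs are drawn at random. Hubs move rigidly with their nucleus.

    Returns ``(stack [T,Z,Y,X] float32, labels [T,Z,Y,X] uint16, hubs,
    nuclei)``.
    """
    rng = rng_for(config.seed, "hub_movie")
    if nuclei is None:
        nuclei = _default_nuclei(config, n_nuclei, rng, drift_um_per_frame)
    else:
        nuclei = list(nuclei)
    if hubs is None:
        hubs = _draw_hubs(config, nuclei, hub_spec or HubSpec(), rng)
    else:
        hubs = list(hubs)
        by_label = {n.label: n for n in nuclei}
        for h in hubs:
            nuc = by_label.get(h.nucleus_label)
            if nuc is None or not nuc.contains(np.asarray(h.center_um), frame=0):
                raise ValueError(f"hub at {h.center_um} lies outside every nucleus")

    nz, ny, nx = config.image_shape
    stack = np.empty((config.n_frames, nz, ny, nx), dtype=np.float32)
    labels = np.zeros((config.n_frames, nz, ny, nx), dtype=np.uint16)
    by_label = {n.label: n for n in nuclei}
    noise_rng = rng_for(config.seed, "hub_movie_noise")
    for t in range(config.n_frames):
        vol = np.full((nz, ny, nx), config.background_level, dtype=np.float64)
        for nuc in nuclei:
            mask = _ellipsoid_mask(config, nuc, t)
            vol[mask] = nuc.base_intensity
            labels[t][mask] = nuc.label
        for h in hubs:
            if h.birth_frame <= t < h.death_frame:
                nuc = by_label[h.nucleus_label]
                offset = nuc.center_at(t) - nuc.center_at(0)
                _add_gaussian(vol, config, np.asarray(h.center_um) + offset,
                              h.sigma_um, h.amplitude * nuc.base_intensity)
        stack[t] = _apply_noise(vol, config, noise_rng)
    return stack, labels, hubs, nuclei


# ---------------------------------------------------------------------------
# Two-colour locus movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionSpec:
    """Prescription for hub–locus interaction events in a two-colour movie.

    Either ``events`` gives explicit, non-overlapping ``(start_frame,
    n_frames)`` pairs, or ``frequency_per_min`` prescribes
    ``round(frequency × movie_minutes)`` events placed at random with a
    minimum gap. During an event a hub Gaussian sits within
    ``event_offset_um`` (< 0.5 μm) of the locus for exactly ``n_frames``
    consecutive frames; outside events every decoy hub keeps
    ``decoy_min_dist_um`` away from the locus so no spurious overlap occurs.
    """

    events: tuple[tuple[int, int], ...] | None = None
    frequency_per_min: float | None = None
    event_frames_range: tuple[int, int] = (2, 12)
    min_gap_frames: int = 3
    event_offset_um: float = 0.2
    hub_amplitude: float = 2.0
    hub_sigma_um: tuple[float, float, float] = (0.35, 0.25, 0.25)
    n_decoy_hubs: int = 3
    decoy_min_dist_um: float = 1.6
    locus_step_um: float = 0.03
    spot_amplitude: float = 400.0
    spot_sigma_um: tuple[float, float, float] = (0.3, 0.15, 0.15)
    edge_margin_um: float = 0.8

    def __post_init__(self) -> None:
        if self.events is not None:
            ev = sorted(self.events)
            for (s1, n1), (s2, _n2) in zip(ev, ev[1:]):
                if s1 + n1 > s2:
                    raise ValueError("events overlap in time")
            for _s, n in ev:
                if n < 1:
                    raise ValueError("every event needs n_frames >= 1")


def _place_events(config: SimConfig, spec: InteractionSpec,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    if spec.events is not None:
        return sorted(spec.events)
    minutes = config.n_frames * config.frame_interval / 60.0
    n_events = int(round((spec.frequency_per_min or 0.0) * minutes))
    lo, hi = spec.event_frames_range
    lengths = rng.integers(lo, hi + 1, size=n_events)
    # random non-overlapping placement with min_gap spacing, by gap allocation
    total = int(lengths.sum()) + spec.min_gap_frames * max(0, n_events - 1)
    slack = config.n_frames - total
    if slack < 0:
        raise ValueError("prescribed events do not fit in the movie")
    cuts = np.sort(rng.integers(0, slack + 1, size=n_events))
    events, base = [], 0
    for i, ln in enumerate(lengths):
        events.append((int(cuts[i]) + base, int(ln)))
        base += int(ln) + spec.min_gap_frames
    return events


def gen_locus_movie(
    config: SimConfig,
    spec: InteractionSpec,
    nucleus: Nucleus | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Render a two-colour single-nucleus movie with prescribed interactions.

    Channel 1 carries the transcription-factor signal (nucleus + hubs);
    channel 2 carries one diffraction-limited transcription-site spot that
    performs a small random walk well inside the nucleus.

    Returns ``(ch1 [T,Z,Y,X], ch2 [T,Z,Y,X], labels [T,Z,Y,X], truth)`` where
    ``truth`` holds the locus path (μm), the event list, and the prescribed
    frequency.
    """
    rng = rng_for(config.seed, "locus_movie")
    nz, ny, nx = config.image_shape
    ext = np.array([nz * config.voxel_z, ny * config.pixel_size, nx * config.pixel_size])
    if nucleus is None:
        semi = (ext[0] / 2 - 0.35, ext[1] / 2 - 0.35, ext[2] / 2 - 0.35)
        nucleus = Nucleus(label=1, center_um=tuple(ext / 2), semi_axes_um=semi)

    events = _place_events(config, spec, rng)
    for s, n in events:
        if s + n > config.n_frames:
            raise ValueError("event extends past the movie end")

    # locus path: reflected random walk, kept >= edge_margin + 0.3 μm inside
    margin = spec.edge_margin_um + 0.3
    locus = np.empty((config.n_frames, 3))
    pos = np.asarray(nucleus.center_um, dtype=float)
    for t in range(config.n_frames):
        step = rng.normal(0.0, spec.locus_step_um, size=3)
        cand = pos + step
        if nucleus.contains(cand, frame=0, margin_um=margin):
            pos = cand
        locus[t] = pos

    # decoy hubs: always-on, far from every locus position
    decoys = []
    for _ in range(spec.n_decoy_hubs):
        for _attempt in range(2000):
            u = rng.uniform(-1.0, 1.0, size=3)
            cand = np.asarray(nucleus.center_um) + u * (
                np.asarray(nucleus.semi_axes_um) - spec.edge_margin_um)
            if not nucleus.contains(cand, frame=0, margin_um=spec.edge_margin_um):
                continue
            if np.min(np.linalg.norm(locus - cand, axis=1)) >= spec.decoy_min_dist_um:
                decoys.append(cand)
                break
    in_event = np.zeros(config.n_frames, dtype=bool)
    for s, n in events:
        in_event[s:s + n] = True

    event_dirs = rng.normal(size=(len(events), 3))
    event_dirs /= np.linalg.norm(event_dirs, axis=1, keepdims=True)

    ch1 = np.empty((config.n_frames, nz, ny, nx), dtype=np.float32)
    ch2 = np.empty_like(ch1)
    labels = np.zeros((config.n_frames, nz, ny, nx), dtype=np.uint16)
    noise_rng = rng_for(config.seed, "locus_movie_noise")
    nuc_mask = _ellipsoid_mask(config, nucleus, 0)
    for t in range(config.n_frames):
        vol1 = np.full((nz, ny, nx), config.background_level, dtype=np.float64)
        vol1[nuc_mask] = nucleus.base_intensity
        labels[t][nuc_mask] = nucleus.label
        for c in decoys:
            _add_gaussian(vol1, config, c, spec.hub_sigma_um,
                          spec.hub_amplitude * nucleus.base_intensity)
        if in_event[t]:
            k = next(i for i, (s, n) in enumerate(events) if s <= t < s + n)
            center = locus[t] + event_dirs[k] * spec.event_offset_um
            _add_gaussian(vol1, config, center, spec.hub_sigma_um,
                          spec.hub_amplitude * nucleus.base_intensity)
        vol2 = np.full((nz, ny, nx), config.background_level, dtype=np.float64)
        _add_gaussian(vol2, config, locus[t], spec.spot_sigma_um, spec.spot_amplitude)
        ch1[t] = _apply_noise(vol1, config, noise_rng)
        ch2[t] = _apply_noise(vol2, config, noise_rng)

    minutes = config.n_frames * config.frame_interval / 60.0
    truth = {
        "locus_um": locus,
        "events": events,
        "frequency_true_per_min": len(events) / minutes if minutes > 0 else 0.0,
        "nucleus": nucleus,
        "decoy_centers_um": [tuple(c) for c in decoys],
    }
    return ch1, ch2, labels, truth
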