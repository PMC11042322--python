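"""Single-molecule tracking kinetics.

Two acquisition regimes are analysed:

* **slow (500 ms/frame)** — long exposures blur fast molecules, so surviving
  tracks report chromatin-bound molecules. Track-duration survival curves are
  fit with a double exponential ``F·exp(−k_ns·t) + (1−F)·exp(−k_s·t)``; the
  slow off-rate ``k_s`` is corrected for photobleaching and chromatin motion
  by subtracting ``k_bias``, the slow rate measured on a stably bound histone
  control, giving the residence time ``1/(k_s − k_bias)``.
* **fast (~12.5 ms/frame)** — per-track diffusion coefficients are inferred
  from a posterior over a log-spaced grid (0.01–100 μm²/s), assigned by the
  occupancy-weighted geometric mean, and segregated into bound
  (D ≤ 0.08 μm²/s), intermediate (0.08–0.5) and free (≥ 0.5) kinetic bins.
  Mean track positions are clustered with DBSCAN (ε = 0.2 μm, min 10 points)
  and target-search behaviour is summarized by the fold-anisotropy of
  jump angles: P(backward, 180°±30°) / P(forward, 0°±30°).

Detection/localization/linking is a deliberately simple re-implementation
(band-pass + Gaussian least squares in a 9 px window; per-frame-pair globally
optimal Euclidean linking, no blinking, no gap closing) adequate for the
synthetic movies this package is validated on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

__all__ = [
    "SurvivalCurve",
    "DoubleExpFit",
    "ResidenceEstimate",
    "DiffusionAssignment",
    "AnisotropySummary",
    "detect_and_localize",
    "link_tracks",
    "mask_filter_tracks",
    "track_durations",
    "survival_curve",
    "fit_double_exponential",
    "correct_bias",
    "assign_diffusion",
    "dbscan_labels",
    "cluster_tracks",
    "jump_angles",
    "fold_anisotropy",
    "bootstrap_stat",
    "KINETIC_BINS",
]

#: (bound upper edge, free lower edge) in μm²/s.
KINETIC_BINS = (0.08, 0.5)


# ---------------------------------------------------------------------------
# Detection, localization, linking
# ---------------------------------------------------------------------------

def _gauss2d(params: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    amp, y0, x0, sigma, off = params
    return off + amp * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2.0 * sigma**2))


def detect_and_localize(
    frame_image: np.ndarray,
    pixel_size: float = 0.108,
    frame: int = 0,
    sigma_psf: float = 1.0,
    snr_threshold: float = 4.0,
    window: int = 9,
    min_distance: int = 3,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in one 2D frame and localize them.

    A difference-of-Gaussians band-pass isolates spot-scale structure; pixels
    exceeding ``snr_threshold`` robust noise sigmas seed local maxima, each of
    which is refined by least-squares 2D Gaussian fitting in a
    ``window × window`` px region. Failed fits (non-convergent, negative
    amplitude, or centre escaping the window) are dropped.

    Returns a DataFrame with columns ``frame, y_um, x_um, y_px, x_px,
    intensity, fit_ok`` (only rows with ``fit_ok`` are returned).
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_and_localize expects a single 2D frame")
    bp = ndimage.gaussian_filter(img, sigma_psf) - ndimage.gaussian_filter(img, 4.0 * sigma_psf)
    noise = 1.4826 * np.median(np.abs(bp - np.median(bp)))
    thr = max(snr_threshold * noise, 1e-9)

    # local maxima above threshold, non-maximum suppressed over min_distance
    maxed = ndimage.maximum_filter(bp, size=2 * min_distance + 1, mode="nearest")
    cand = np.argwhere((bp >= maxed) & (bp > thr))

    half = window // 2
    rows = []
    for cy, cx in cand:
        y0 = int(np.clip(cy, half, img.shape[0] - half - 1))
        x0 = int(np.clip(cx, half, img.shape[1] - half - 1))
        patch = img[y0 - half:y0 + half + 1, x0 - half:x0 + half + 1]
        yy, xx = np.mgrid[y0 - half:y0 + half + 1, x0 - half:x0 + half + 1].astype(float)
        off0 = float(np.median(patch))
        amp0 = float(patch.max() - off0)
        if amp0 <= 0 or np.ptp(patch) == 0:
            continue
        p0 = np.array([amp0, float(cy), float(cx), sigma_psf, off0])
        try:
            res = optimize.least_squares(
                lambda p: (_gauss2d(p, yy, xx) - patch).ravel(), p0,
                bounds=([0, y0 - half, x0 - half, 0.3, -np.inf],
                        [np.inf, y0 + half, x0 + half, half, np.inf]),
                max_nfev=200,
            )
        except ValueError:
            continue
        amp, fy, fx, sig, off = res.x
        fit_ok = bool(res.success and amp > 0)
        if not fit_ok:
            continue
        rows.append((frame, fy * pixel_size, fx * pixel_size, fy, fx,
                     float(2 * np.pi * sig**2 * amp), True))
    df = pd.DataFrame(rows, columns=["frame", "y_um", "x_um", "y_px", "x_px",
                                     "intensity", "fit_ok"])
    if len(df) > 1:
        # merge duplicate fits converging to the same spot
        tree = cKDTree(df[["y_px", "x_px"]].to_numpy())
        pairs = tree.query_pairs(r=float(min_distance))
        drop = {max(i, j) if df.intensity.iloc[i] >= df.intensity.iloc[j] else min(i, j)
                for i, j in pairs}
        df = df.drop(df.index[list(drop)]).reset_index(drop=True)
    return df


def link_tracks(
    detections: pd.DataFrame,
    search_radius: float,
    max_blinking: int = 0,
) -> pd.DataFrame:
    """Link detections into trajectories by per-frame-pair optimal assignment.

    Consecutive-frame detections are matched by minimising the total Euclidean
    distance (Hungarian assignment); any link longer than ``search_radius``
    (μm) is forbidden. Unlinked detections start new tracks; there is no gap
    closing (``max_blinking`` must be 0, matching the analysis settings).

    Returns a track table ``track_id, frame, x_um, y_um, intensity`` sorted by
    (track_id, frame).
    """
    if max_blinking != 0:
        raise NotImplementedError("blinking/gap closing is not supported (max_blinking=0)")
    need = {"frame", "x_um", "y_um"}
    if not need.issubset(detections.columns):
        raise ValueError(f"detections need columns {sorted(need)}")
    det = detections.sort_values("frame", kind="stable").reset_index(drop=True)
    if "intensity" not in det.columns:
        det["intensity"] = np.nan

    track_id = np.full(len(det), -1, dtype=int)
    next_id = 0
    frames = det["frame"].to_numpy()
    idx_by_frame = {f: np.flatnonzero(frames == f) for f in np.unique(frames)}
    prev_idx: np.ndarray | None = None
    prev_frame = None
    for f in sorted(idx_by_frame):
        cur = idx_by_frame[f]
        if prev_idx is not None and prev_frame == f - 1 and len(prev_idx) and len(cur):
            p = det.loc[prev_idx, ["x_um", "y_um"]].to_numpy()
            c = det.loc[cur, ["x_um", "y_um"]].to_numpy()
            dist = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2)
            big = 1e6
            cost = np.where(dist <= search_radius, dist, big)
            ri, ci = optimize.linear_sum_assignment(cost)
            for a, b in zip(ri, ci):
                if dist[a, b] <= search_radius:
                    track_id[cur[b]] = track_id[prev_idx[a]]
        for i in cur:
            if track_id[i] == -1:
                track_id[i] = next_id
                next_id += 1
        prev_idx, prev_frame = cur, f

    out = det.assign(track_id=track_id)[["track_id", "frame", "x_um", "y_um", "intensity"]]
    return out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


def mask_filter_tracks(
    tracks: pd.DataFrame, nuclear_mask: np.ndarray, pixel_size: float = 0.108
) -> pd.DataFrame:
    """Keep tracks whose mean position lies inside a 2D nuclear mask.

    The mask is a boolean (or label) image from a maximum projection; a track
    belongs to the nucleus if its mean (x, y) position, converted to pixel
    indices, falls on a nonzero mask pixel.
    """
    mask = np.asarray(nuclear_mask) != 0
    if not mask.any():
        raise ValueError("nuclear mask is empty")
    mean_pos = tracks.groupby("track_id")[["y_um", "x_um"]].mean()
    iy = np.clip((mean_pos["y_um"] / pixel_size).round().astype(int), 0, mask.shape[0] - 1)
    ix = np.clip((mean_pos["x_um"] / pixel_size).round().astype(int), 0, mask.shape[1] - 1)
    keep = mean_pos.index[mask[iy, ix]]
    return tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Residence times
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Empirical survival probability of track durations.

    ``t`` is the grid of sorted unique durations (s) of the retained tracks
    (duration ≥ ``min_duration``), restricted to points with ``S ≥ floor``;
    ``S[i]`` is the fraction of retained tracks with duration ≥ ``t[i]``, so
    ``S[0] == 1`` and S is non-increasing.
    """

    t: np.ndarray
    S: np.ndarray
    n_tracks: int
    min_duration: float
    floor: float
    low_statistics: bool = False


def track_durations(tracks: pd.DataFrame, frame_interval: float) -> np.ndarray:
    """Observed duration of each track in seconds (n_frames × Δt)."""
    counts = tracks.groupby("track_id")["frame"].size().to_numpy()
    return counts * frame_interval


def survival_curve(
    durations_or_tracks,
    frame_interval: float | None = None,
    min_duration: float = 2.0,
    floor: float = 1e-3,
) -> SurvivalCurve:
    """Survival probability curve of track durations.

    Accepts either a track table (with ``frame_interval``) or a 1D array of
    durations in seconds. Tracks shorter than ``min_duration`` (default 2 s,
    removing tracking errors and slowly diffusing molecules) are excluded
    before normalization; grid points with survival below ``floor`` (default
    10⁻³) are excluded from the returned fit range.
    """
    if isinstance(durations_or_tracks, pd.DataFrame):
        if frame_interval is None:
            raise ValueError("frame_interval required with a track table")
        durations = track_durations(durations_or_tracks, frame_interval)
    else:
        durations = np.asarray(durations_or_tracks, dtype=float)
    retained = durations[durations >= min_duration]
    if retained.size == 0:
        raise ValueError("no tracks at or above the minimum duration")
    t = np.unique(retained)
    s = (retained[None, :] >= t[:, None]).mean(axis=1)
    keep = s >= floor
    return SurvivalCurve(
        t=t[keep], S=s[keep], n_tracks=int(retained.size),
        min_duration=min_duration, floor=floor,
        low_statistics=bool(retained.size < 50),
    )


@dataclass
class DoubleExpFit:
    """Double-exponential survival model ``F·e^(−k_ns·t′) + (1−F)·e^(−k_s·t′)``.

    ``F`` is the fast (non-specific) fraction, ``k_ns ≥ k_s > 0`` the fast
    and slow off-rates (1/s). ``t0`` is the time origin of the fit: the
    curve's first grid point, so the model is evaluated at ``t′ = t − t0``
    (exact for exponential mixtures by memorylessness; a no-op for curves
    starting at 0). Standard errors come from the weighted-fit covariance.
    """

    F: float
    k_ns: float
    k_s: float
    se_F: float
    se_k_ns: float
    se_k_s: float
    t0: float = 0.0
    sse: float = np.nan
    at_bound: bool = False
    collapsed_single: bool = False


def _double_exp(t: np.ndarray, F: float, k_ns: float, k_s: float) -> np.ndarray:
    return F * np.exp(-k_ns * t) + (1.0 - F) * np.exp(-k_s * t)


_K_BOUNDS = (1e-6, 1e3)


def _fit_sigma(curve: SurvivalCurve, min_tail_tracks: int = 10) -> np.ndarray:
    """curve_fit ``sigma`` implementing w ∝ 1/S with a small-count floor.

    Weights proportional to 1/S match the binomial variance of the empirical
    survival (Var Ŝ ≈ S/n) and emphasize the tail; flooring S at
    ``min_tail_tracks``/n keeps grid points supported by only a handful of
    tracks from dominating the objective.
    """
    floor = max(curve.floor, min_tail_tracks / max(curve.n_tracks, 1))
    return np.sqrt(np.maximum(curve.S, floor))


def fit_double_exponential(
    curve: SurvivalCurve, n_starts: int = 5, ratio_min: float = 3.0
) -> DoubleExpFit:
    """Weighted nonlinear least-squares fit of the double-exponential model.

    Weights ``w(tᵢ) ∝ 1/S(tᵢ)`` emphasize the tail so the slow off-rate is
    estimated properly. Initialization is multi-start from log-spaced
    (k_ns, k_s) pairs bracketing the curve's gross decay rate; the best
    weighted SSE wins, and k_ns ≥ k_s is enforced by ordering after the fit
    (swapping F ↔ 1−F if needed).

    Two exponentials whose rates differ by less than ``ratio_min`` are not
    separable on a finite noisy curve — the flexible model then splits a
    single decay into two arbitrary nearby rates. When the best double fit
    lands in that regime (or puts F at a boundary), the fit collapses to the
    single-exponential model (``F = 0``, ``collapsed_single=True``), whose
    slow rate is stable.
    """
    if curve.t.size < 5:
        raise ValueError("need at least 5 survival grid points to fit")
    t = curve.t - curve.t[0]
    s = curve.S
    sigma = _fit_sigma(curve)

    # gross rate scale from the endpoints
    with np.errstate(divide="ignore"):
        span = t[-1] if t[-1] > 0 else 1.0
        k_scale = max(-np.log(max(s[-1], 1e-6)) / span, 1e-3)

    best = None
    ratios = np.logspace(0.5, 2.5, n_starts)
    for r in ratios:
        p0 = [0.5, min(k_scale * r, _K_BOUNDS[1] * 0.9), max(k_scale / 2, _K_BOUNDS[0] * 10)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    _double_exp, t, s, p0=p0, sigma=sigma, absolute_sigma=False,
                    bounds=([0.0, _K_BOUNDS[0], _K_BOUNDS[0]],
                            [1.0, _K_BOUNDS[1], _K_BOUNDS[1]]),
                    maxfev=20000,
                )
        except RuntimeError:
            continue
        resid = (_double_exp(t, *popt) - s) / sigma
        sse = float(resid @ resid)
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise RuntimeError(f"double-exponential fit failed on curve with {t.size} points")
    popt, pcov, sse = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    F, k_ns, k_s = popt
    se_F, se_ns, se_s = se
    if k_ns < k_s:  # order the rates; swap the fractions accordingly
        F, k_ns, k_s = 1.0 - F, k_s, k_ns
        se_ns, se_s = se_s, se_ns

    if F < 0.02 or F > 0.98 or k_ns / max(k_s, _K_BOUNDS[0]) < ratio_min:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p1, c1 = optimize.curve_fit(
                    lambda tt, k: np.exp(-k * tt), t, s, p0=[k_scale],
                    sigma=sigma, bounds=([_K_BOUNDS[0]], [_K_BOUNDS[1]]),
                    maxfev=20000)
            k1 = float(p1[0])
            se1 = float(np.sqrt(max(c1[0, 0], 0.0)))
            resid = (np.exp(-k1 * t) - s) / sigma
            return DoubleExpFit(F=0.0, k_ns=k1, k_s=k1, se_F=0.0, se_k_ns=se1,
                                se_k_s=se1, t0=float(curve.t[0]),
                                sse=float(resid @ resid),
                                at_bound=bool(k1 <= _K_BOUNDS[0] * 2),
                                collapsed_single=True)
        except RuntimeError:
            pass  # keep the double fit

    at_bound = bool(k_s <= _K_BOUNDS[0] * 2)
    return DoubleExpFit(F=float(F), k_ns=float(k_ns), k_s=float(k_s),
                        se_F=float(se_F), se_k_ns=float(se_ns), se_k_s=float(se_s),
                        t0=float(curve.t[0]), sse=sse, at_bound=at_bound)


@dataclass
class ResidenceEstimate:
    """Bias-corrected residence time: ``1/(k_s − k_bias)``.

    ``k_bias`` is the slow off-rate of a stably bound histone control under
    identical imaging; it captures photobleaching and chromatin motion.
    ``residence_err_s`` propagates both fits' standard errors to first order.
    """

    k_s: float
    k_bias: float
    k_s_true: float
    residence_s: float
    residence_err_s: float


def correct_bias(fit: DoubleExpFit, control_fit: DoubleExpFit) -> ResidenceEstimate:
    """Subtract the histone-control slow rate and invert to a residence time."""
    k_true = fit.k_s - control_fit.k_s
    if k_true <= 0:
        raise ValueError(
            f"bias exceeds signal: k_s={fit.k_s:.4g} <= k_bias={control_fit.k_s:.4g}"
        )
    var_k = fit.se_k_s**2 + control_fit.se_k_s**2
    residence = 1.0 / k_true
    return ResidenceEstimate(
        k_s=fit.k_s, k_bias=control_fit.k_s, k_s_true=k_true,
        residence_s=residence, residence_err_s=float(np.sqrt(var_k) / k_true**2),
    )


# ---------------------------------------------------------------------------
# Fast-tracking: diffusion, clustering, anisotropy
# ---------------------------------------------------------------------------

@dataclass
class DiffusionAssignment:
    """Per-track diffusion-grid occupancies and kinetic-bin assignment.

    ``occupancy[i]`` is track i's posterior over ``D_grid`` (rows sum to 1);
    ``D_assigned`` is the occupancy-weighted geometric mean
    ``exp(Σ occᵢⱼ·ln Dⱼ)``; ``kinetic_bin`` applies the bound/intermediate/
    free thresholds (0.08 and 0.5 μm²/s).
    """

    table: pd.DataFrame           # track_id, n_jumps, D_assigned, kinetic_bin
    D_grid: np.ndarray
    occupancy: np.ndarray
    n_excluded: int = 0
    prior: np.ndarray | None = None

    def bin_fractions(self) -> dict[str, float]:
        n = len(self.table)
        frac = self.table["kinetic_bin"].value_counts(normalize=True)
        return {b: float(frac.get(b, 0.0)) for b in ("bound", "intermediate", "free")} if n else \
            {"bound": 0.0, "intermediate": 0.0, "free": 0.0}


def _kinetic_bin(d: np.ndarray) -> np.ndarray:
    lo, hi = KINETIC_BINS
    out = np.where(d <= lo, "bound", np.where(d < hi, "intermediate", "free"))
    return out


def assign_diffusion(
    tracks: pd.DataFrame,
    frame_interval: float,
    loc_error: float = 0.03,
    D_grid: np.ndarray | None = None,
    empirical_prior: bool = False,
) -> DiffusionAssignment:
    """Per-track diffusion coefficients from a grid posterior.

    For each track the likelihood of every grid diffusion coefficient D is
    evaluated under 2D Brownian motion with per-axis jump variance
    ``2·(D·Δt + loc_error²)`` and normalized into an occupancy vector. With
    ``empirical_prior`` a one-pass shared prior — the average of the
    normalized per-track likelihoods — multiplies the likelihoods before
    renormalization, pooling statistical strength across tracks (a desk-scale
    simplification of variational state-array inference). The assigned D is
    the occupancy-weighted geometric mean.

    Tracks with zero jumps are excluded and counted in ``n_excluded``.
    """
    if D_grid is None:
        D_grid = np.logspace(-2, 2, 100)
    dt = frame_interval
    ids, ssd, nj = [], [], []
    for tid, g in tracks.groupby("track_id"):
        d = g[["x_um", "y_um"]].to_numpy()
        if len(d) < 2:
            continue
        jumps = np.diff(d, axis=0)
        ids.append(tid)
        ssd.append(float((jumps**2).sum()))
        nj.append(len(jumps))
    n_excluded = tracks["track_id"].nunique() - len(ids)
    if not ids:
        raise ValueError("no tracks with at least one jump")
    ssd_a = np.asarray(ssd)[:, None]
    nj_a = np.asarray(nj, dtype=float)[:, None]
    var = 2.0 * (D_grid[None, :] * dt + loc_error**2)
    loglik = -ssd_a / (2.0 * var) - nj_a * np.log(var)
    loglik -= loglik.max(axis=1, keepdims=True)
    lik = np.exp(loglik)
    lik /= lik.sum(axis=1, keepdims=True)
    prior = None
    occ = lik
    if empirical_prior:
        prior = lik.mean(axis=0)
        occ = lik * prior[None, :]
        occ /= occ.sum(axis=1, keepdims=True)
    d_assigned = np.exp(occ @ np.log(D_grid))
    table = pd.DataFrame({
        "track_id": ids,
        "n_jumps": np.asarray(nj, dtype=int),
        "D_assigned": d_assigned,
        "kinetic_bin": _kinetic_bin(d_assigned),
    })
    return DiffusionAssignment(table=table, D_grid=D_grid, occupancy=occ,
                               n_excluded=int(n_excluded), prior=prior)


def dbscan_labels(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Deterministic, permutation-invariant DBSCAN labels.

    Core points (≥ ``min_samples`` neighbours within ``eps``, self included)
    are clustered as connected components of the core-core ε-graph; border
    points join the cluster of their nearest core point (ties broken toward
    the smaller coordinate tuple), making the partition independent of input
    order. Noise points get label −1; cluster ids are assigned in order of
    each cluster's lexicographically smallest member coordinate.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    tree = cKDTree(pts)
    neigh = tree.query_ball_tree(tree, r=eps)
    counts = np.array([len(nb) for nb in neigh])
    core = counts >= min_samples
    core_idx = np.flatnonzero(core)
    if core_idx.size == 0:
        return labels
    # connected components over core points
    comp = {}
    seen = set()
    comps = []
    core_set = set(core_idx.tolist())
    for start in core_idx:
        if start in seen:
            continue
        stack, members = [int(start)], []
        seen.add(int(start))
        while stack:
            i = stack.pop()
            members.append(i)
            for j in neigh[i]:
                if j in core_set and j not in seen:
                    seen.add(j)
                    stack.append(j)
        comps.append(sorted(members))
    # canonical ordering: by lexicographically smallest member coordinate
    def comp_key(members):
        coords = pts[members]
        order = np.lexsort(coords.T[::-1])
        return tuple(coords[order[0]])
    comps.sort(key=comp_key)
    for cid, members in enumerate(comps):
        for i in members:
            comp[i] = cid
            labels[i] = cid
    # border points: nearest core within eps, ties toward smaller coord tuple
    for i in np.flatnonzero(~core):
        cands = [j for j in neigh[i] if j in core_set]
        if not cands:
            continue
        d = np.linalg.norm(pts[cands] - pts[i], axis=1)
        best = min(zip(d, [tuple(pts[j]) for j in cands], cands))
        labels[i] = comp[best[2]]
    return labels


def cluster_tracks(
    tracks: pd.DataFrame, max_distance: float = 0.2, min_samples: int = 10
) -> pd.DataFrame:
    """DBSCAN on mean track positions (ε = ``max_distance`` μm).

    Returns one row per track: ``track_id, x_mean, y_mean, cluster_id``
    (−1 = noise).
    """
    mean_pos = tracks.groupby("track_id")[["x_um", "y_um"]].mean().reset_index()
    labels = dbscan_labels(mean_pos[["x_um", "y_um"]].to_numpy(), max_distance, min_samples)
    return pd.DataFrame({
        "track_id": mean_pos["track_id"],
        "x_mean": mean_pos["x_um"],
        "y_mean": mean_pos["y_um"],
        "cluster_id": labels,
    })


@dataclass
class AnisotropySummary:
    """Distribution of angles between consecutive jumps, in degrees [0, 180].

    0° is a forward continuation, 180° a full reversal. ``hist`` is
    normalized to unit mass over ``bin_edges`` (10° bins by default).
    """

    angles_deg: np.ndarray
    bin_edges: np.ndarray
    hist: np.ndarray
    n_angles: int
    scope: str = "overall"
    empty: bool = False


def jump_angles(
    tracks: pd.DataFrame,
    min_jump: float = 0.2,
    exclude_track_ids=None,
    include_track_ids=None,
    scope: str = "overall",
    n_bins: int = 18,
) -> AnisotropySummary:
    """Angles between consecutive displacement vectors of each track.

    Jumps shorter than ``min_jump`` μm (including exactly repeated
    coordinates) are excluded; an angle is emitted for every pair of
    consecutive qualifying jumps. Bound-bin tracks are removed upstream by
    passing ``exclude_track_ids`` (they would bias the distribution), or the
    analysis restricted to cluster members with ``include_track_ids``.
    """
    df = tracks
    if exclude_track_ids is not None:
        df = df[~df["track_id"].isin(set(exclude_track_ids))]
    if include_track_ids is not None:
        df = df[df["track_id"].isin(set(include_track_ids))]
    angles = []
    for _tid, g in df.groupby("track_id"):
        p = g.sort_values("frame")[["x_um", "y_um"]].to_numpy()
        if len(p) < 3:
            continue
        v = np.diff(p, axis=0)
        norms = np.linalg.norm(v, axis=1)
        ok = norms >= min_jump
        for i in range(len(v) - 1):
            if ok[i] and ok[i + 1]:
                cosang = np.dot(v[i], v[i + 1]) / (norms[i] * norms[i + 1])
                angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    angles = np.asarray(angles, dtype=float)
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    if angles.size:
        hist, _ = np.histogram(angles, bins=edges)
        hist = hist / hist.sum()
    else:
        hist = np.zeros(n_bins)
    return AnisotropySummary(angles_deg=angles, bin_edges=edges, hist=hist,
                             n_angles=int(angles.size), scope=scope,
                             empty=bool(angles.size == 0))


def fold_anisotropy(summary: AnisotropySummary) -> float:
    """Backward/forward jump-angle probability ratio.

    Mass of angles in [150°, 180°] divided by mass in [0°, 30°]; > 1 means
    compact, revisiting exploration. Returns ``inf`` if the forward mass is
    zero (flagged by the caller's own check on ``summary.empty``).
    """
    a = summary.angles_deg
    if a.size == 0:
        raise ValueError("empty anisotropy summary")
    backward = float(np.mean((a >= 150.0) & (a <= 180.0)))
    forward = float(np.mean((a >= 0.0) & (a <= 30.0)))
    if forward == 0.0:
        return np.inf
    return backward / forward


def bootstrap_stat(values, stat_fn, fraction: float = 0.5, n_rep: int = 20,
                   seed: int = 0) -> tuple[float, float]:
    """Subsampling error bar: ``stat_fn`` on ``fraction`` of the data × ``n_rep``.

    Returns ``(stat on the full data, std of the statistic across
    replicates)``; replicates subsample without replacement.
    """
    vals = np.asarray(values)
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    m = max(1, int(round(fraction * vals.shape[0])))
    reps = [stat_fn(vals[rng.choice(vals.shape[0], size=m, replace=False)])
            for _ in range(n_rep)]
    return float(stat_fn(vals)), float(np.std(reps))
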