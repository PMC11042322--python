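"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force (full distance
matrices, dense grid searches) so they share no code path with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize

from hubkin.config import SimConfig
from hubkin import synthetic as syn


# ---------------------------------------------------------------------------
# Brute-force DBSCAN oracle (O(n²), full distance matrix + BFS)
# ---------------------------------------------------------------------------

def dbscan_oracle(pts: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Reference DBSCAN: core graph components + nearest-core border rule."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    dmat = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    neigh = [np.flatnonzero(dmat[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neigh])
    labels = np.full(n, -1)
    seen = np.zeros(n, bool)
    comps = []
    for i in range(n):
        if not core[i] or seen[i]:
            continue
        stack, members = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            members.append(j)
            for k in neigh[j]:
                if core[k] and not seen[k]:
                    seen[k] = True
                    stack.append(k)
        comps.append(sorted(members))

    def canon_key(members):
        coords = pts[members]
        order = np.lexsort(coords.T[::-1])
        return tuple(coords[order[0]])

    comps.sort(key=canon_key)
    for cid, members in enumerate(comps):
        for j in members:
            labels[j] = cid
    for i in range(n):
        if core[i]:
            continue
        cands = [j for j in neigh[i] if core[j]]
        if cands:
            best = min((dmat[i, j], tuple(pts[j]), j) for j in cands)
            labels[i] = labels[best[2]]
    return labels


# ---------------------------------------------------------------------------
# Dense grid-search + refinement oracle for the double-exponential fit
# ---------------------------------------------------------------------------

def double_exp_oracle(t: np.ndarray, s: np.ndarray, sigma: np.ndarray):
    """Global grid search over (F, k_ns, k_s) + Nelder–Mead refinement.

    Minimizes the same weighted SSE as the production fit but through an
    entirely independent optimisation route.
    """
    def model(F, kns, ks):
        return F * np.exp(-np.outer(kns, t)) + (1 - F) * np.exp(-np.outer(ks, t))

    f_grid = np.linspace(0.0, 1.0, 21)
    k_grid = np.logspace(-3, 1.7, 45)
    best = (np.inf, None)
    for F in f_grid:
        for kns in k_grid:
            resid = (F * np.exp(-kns * t)[None, :]
                     + (1 - F) * np.exp(-np.outer(k_grid, t)) - s[None, :]) / sigma[None, :]
            sse = (resid**2).sum(axis=1)
            j = int(np.argmin(sse))
            if sse[j] < best[0]:
                best = (float(sse[j]), (F, kns, float(k_grid[j])))
    F0, kns0, ks0 = best[1]

    def objective(p):
        F, lkns, lks = p
        F = np.clip(F, 0.0, 1.0)
        m = F * np.exp(-np.exp(lkns) * t) + (1 - F) * np.exp(-np.exp(lks) * t)
        return float((((m - s) / sigma) ** 2).sum())

    x = np.array([F0, np.log(kns0), np.log(ks0)])
    for _restart in range(3):  # NM converges tighter when restarted
        res = optimize.minimize(
            objective, x, method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-18, "maxiter": 20000,
                     "maxfev": 20000})
        x = res.x
    F, kns, ks = np.clip(res.x[0], 0, 1), np.exp(res.x[1]), np.exp(res.x[2])
    if kns < ks:
        F, kns, ks = 1 - F, ks, kns
    return float(F), float(kns), float(ks), float(res.fun)


# ---------------------------------------------------------------------------
# Interval-aligned hub "ladder" movies for lifetime experiments
# ---------------------------------------------------------------------------

LADDER_SLOTS = ((1.8, 2.2, 2.2), (1.8, 2.2, 4.7), (1.8, 4.7, 2.2), (1.8, 4.7, 4.7))


def ladder_movie(seed, lifetimes_by_interval, interval=20, trim=20, dt=5.53,
                 amplitude=1.5, classes_by_interval=None):
    """Movie in which hubs are born exactly at analysis-interval starts.

    ``lifetimes_by_interval[k][s]`` is the on-time (seconds, capped at the
    interval length) of the hub occupying slot ``s`` in interval ``k``.
    Returns (config, stack, labels, truth list of (start, center, lifetime,
    class)).
    """
    K = len(lifetimes_by_interval)
    n_frames = trim + K * interval + trim
    cfg = SimConfig(seed=seed, frame_interval=dt, n_frames=n_frames,
                    image_shape=(12, 64, 64), noise_model="none")
    nuc = syn.Nucleus(label=1, center_um=(1.8, 3.456, 3.456),
                      semi_axes_um=(1.5, 2.8, 2.8))
    hubs, truth = [], []
    for k, lifetimes in enumerate(lifetimes_by_interval):
        start = trim + k * interval
        for s, life in enumerate(lifetimes):
            cls = (classes_by_interval[k][s] if classes_by_interval is not None
                   else "short")
            nf = max(1, min(int(round(life / dt)), interval))
            hubs.append(syn.Hub(center_um=LADDER_SLOTS[s], birth_frame=start,
                                death_frame=start + nf, amplitude=amplitude,
                                lifetime_class=cls))
            truth.append((start, np.asarray(LADDER_SLOTS[s]), float(life), cls))
    stack, labels, _, _ = syn.gen_hub_movie(cfg, nuclei=[nuc], hubs=hubs)
    return cfg, stack, labels, truth


def match_ladder_records(records, truth):
    """Pair lifetime records with ladder ground truth by interval + slot."""
    out = []
    for r in records.itertuples():
        c = np.array([r.centroid_z_um, r.centroid_y_um, r.centroid_x_um])
        cands = [(np.linalg.norm(c - tc), life, cls)
                 for (st, tc, life, cls) in truth if st == r.interval_start]
        if not cands:
            continue
        d, life, cls = min(cands)
        if d < 0.6:
            out.append((life, cls, r.zero_crossing_s, bool(r.censored)))
    return out


@pytest.fixture(scope="session")
def slow_residence_data():
    """500 ms-cadence tracks with 5 s true bound residence + histone control."""
    import dataclasses

    cfg = SimConfig(seed=1, frame_interval=0.5, n_frames=400)
    spec = syn.KineticSpec(fractions=(0.6, 0.4, 0.0), unbind_rate=0.2,
                           bleach_rate=0.1, transient_loss_rate=2.0)
    tracks, truth = syn.gen_smt_tracks(cfg, spec, 4000)
    ctracks, _ = syn.gen_smt_tracks(
        dataclasses.replace(cfg, seed=1001),
        dataclasses.replace(spec, unbind_rate=0.0), 4000)
    return cfg, tracks, truth, ctracks
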