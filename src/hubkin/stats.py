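"""Rank-based statistical testing shared by the analysis stages.

The measured distributions (lifetimes, durations, frequencies) are skewed
and not normal, so comparisons use a Kruskal–Wallis omnibus test (when more
than two groups) followed by pairwise two-sided Mann–Whitney U tests, with a
Kolmogorov–Smirnov normality screen reported alongside. Pairwise p-values
are reported raw; a Bonferroni-adjusted column is emitted for reference but
not used for the headline significance flags.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sstats

__all__ = ["rank_tests"]


def rank_tests(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Omnibus + pairwise rank tests across named groups.

    Parameters
    ----------
    groups
        Mapping of group name → 1D array of values; at least two groups of
        n ≥ 3 each.

    Returns
    -------
    dict with keys ``omnibus`` (Kruskal–Wallis, only when > 2 groups),
    ``pairwise`` (list of dicts with raw and Bonferroni p-values),
    ``normality`` (per-group KS test against a fitted normal), and ``n``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 3:
            raise ValueError(f"group {k!r} has fewer than 3 values")

    report: dict = {"n": {k: int(v.size) for k, v in arrays.items()}}

    if len(names) > 2:
        if all(np.ptp(np.concatenate(list(arrays.values()))) == 0 for _ in (0,)):
            report["omnibus"] = {"test": "kruskal", "statistic": 0.0, "p": 1.0}
        else:
            try:
                stat, p = sstats.kruskal(*arrays.values())
            except ValueError:  # all values identical
                stat, p = 0.0, 1.0
            report["omnibus"] = {"test": "kruskal", "statistic": float(stat), "p": float(p)}

    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = []
    for a, b in combinations(names, 2):
        va, vb = arrays[a], arrays[b]
        if np.ptp(np.concatenate([va, vb])) == 0:
            stat, p = float(va.size * vb.size / 2.0), 1.0
        else:
            stat, p = sstats.mannwhitneyu(va, vb, alternative="two-sided")
        pairwise.append({
            "a": a, "b": b, "test": "mannwhitneyu",
            "statistic": float(stat), "p": float(p),
            "p_bonferroni": float(min(1.0, p * n_pairs)),
            "significant": bool(p < alpha),
        })
    report["pairwise"] = pairwise

    normality = {}
    for k, v in arrays.items():
        sd = v.std(ddof=1)
        if sd == 0:
            normality[k] = {"test": "ks", "p": 0.0, "normal": False}
        else:
            _stat, p = sstats.kstest((v - v.mean()) / sd, "norm")
            normality[k] = {"test": "ks", "p": float(p), "normal": bool(p >= alpha)}
    report["normality"] = normality
    return report
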