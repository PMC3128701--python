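"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — complete enumeration, per-voxel
loops, dictionary grouping — and shares no code with the package's
implementation paths it checks.
"""

import itertools

import numpy as np
from scipy.stats import rankdata


def ranksum_exact_p(a, b) -> float:
    """Two-sided rank-sum p by complete enumeration of group assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, n1 = len(pooled), len(a)
    ranks = rankdata(pooled)

    def u_of(pos):
        return ranks[list(pos)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(n), n1)])
    p = 2 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / len(us)
    return min(p, 1.0)


def signed_rank_exact_p(d) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for s, r in zip(signs, ranks) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ])
    p = 2 * min((ws <= w_obs).sum(), (ws >= w_obs).sum()) / len(ws)
    return min(p, 1.0)


def holm_reject(p_values, alpha=0.05) -> np.ndarray:
    """Reject the i-th smallest p iff all j <= i pass alpha/(m-j+1)."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    rejected = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):  # i is the 0-based rank
        ok = all(p[order[j]] <= alpha / (m - j) for j in range(i + 1))
        if not ok:
            break
        rejected[idx] = True
    return rejected


def group_voxels_by_membership(masks, min_overlap):
    """Partition voxels by their lesion-membership vector, dict-of-tuples.

    ``masks`` is a list of (subject_id, bool ndarray).  Returns a dict
    mapping frozenset(subject ids) -> sorted list of voxel index tuples,
    keeping only voxels covered by at least ``min_overlap`` masks.
    """
    dims = masks[0][1].shape
    groups = {}
    for idx in np.ndindex(dims):
        members = frozenset(sid for sid, data in masks if data[idx])
        if len(members) >= min_overlap:
            groups.setdefault(members, []).append(idx)
    return {k: sorted(v) for k, v in groups.items()}


def count_overlaps_at(masks, idx) -> int:
    return sum(bool(data[idx]) for _, data in masks)


def event_pm_window_matcher(onsets, target_flags, press_times):
    """Credit targets whose window [onset, next-next onset) holds a press."""
    credited = []
    for i, (t, is_target) in enumerate(zip(onsets, target_flags)):
        if not is_target:
            continue
        end = onsets[i + 2] if i + 2 < len(onsets) else float("inf")
        credited.append(any(t <= p < end for p in press_times))
    return credited
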