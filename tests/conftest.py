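"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import rankdata

from endomosaic.geometry import FieldRect, tessellate


def make_triangular_lattice(spacing: float, field: FieldRect, margin: float = 0.0):
    """Explicit triangular lattice inside ``field`` (independent of the
    package generator), optionally keeping ``margin`` clear of the edges."""
    row_h = spacing * math.sqrt(3.0) / 2.0
    pts = []
    j = 0
    y = row_h / 2.0
    while y < field.height - margin:
        if y > margin:
            x = spacing / 2.0 + (spacing / 2.0 if j % 2 else 0.0)
            while x < field.width - margin:
                if x > margin:
                    pts.append((x, y))
                x += spacing
        j += 1
        y = row_h / 2.0 + j * row_h
    return np.array(pts)


def random_mosaic(rng: np.random.Generator, n: int = 50, field: FieldRect | None = None):
    field = field or FieldRect(100.0, 80.0)
    pts = rng.uniform(
        (0.02 * field.width, 0.02 * field.height),
        (0.98 * field.width, 0.98 * field.height),
        size=(n, 2),
    )
    return tessellate(pts, field)


def bisector_adjacency_oracle(
    centers: np.ndarray, field: FieldRect, n_samples: int = 801
) -> set[frozenset]:
    """Adjacency by brute force: for each pair, sample the perpendicular
    bisector segment inside the field and test whether some sampled point
    has the pair as its (joint) nearest centers.

    A coarse scan of the clearance margin (distance advantage of the pair
    over every other center) is refined around its best candidates, so
    edges far shorter than the coarse sample spacing are still found.
    """
    n = len(centers)

    def margin(i, j, s_vals, mid, t):
        """max over samples of min_k d_k - d_ij, restricted to the field."""
        pts = mid[None, :] + s_vals[:, None] * t[None, :]
        inside = (
            (pts[:, 0] > 0)
            & (pts[:, 0] < field.width)
            & (pts[:, 1] > 0)
            & (pts[:, 1] < field.height)
        )
        if not inside.any():
            return None, None
        pts = pts[inside]
        s_in = s_vals[inside]
        dists = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        dij = dists[:, i]
        others = np.delete(dists, [i, j], axis=1)
        if others.shape[1] == 0:
            return np.inf, s_in[0]
        gap = others.min(axis=1) - dij
        k = int(np.argmax(gap))
        return float(gap[k]), float(s_in[k])

    edges: set[frozenset] = set()
    for i in range(n):
        for j in range(i + 1, n):
            mid = (centers[i] + centers[j]) / 2.0
            d = centers[j] - centers[i]
            t = np.array([-d[1], d[0]])
            t = t / np.linalg.norm(t)
            # clip the bisector line mid + s*t to the field rectangle
            s_lo, s_hi = -np.inf, np.inf
            for axis, lim in ((0, field.width), (1, field.height)):
                if abs(t[axis]) > 1e-15:
                    a = (0.0 - mid[axis]) / t[axis]
                    b = (lim - mid[axis]) / t[axis]
                    s_lo, s_hi = max(s_lo, min(a, b)), min(s_hi, max(a, b))
            if s_hi <= s_lo:
                continue
            coarse = np.linspace(s_lo, s_hi, n_samples)
            best, s_best = margin(i, j, coarse, mid, t)
            if best is None:
                continue
            step = (s_hi - s_lo) / (n_samples - 1)
            for _ in range(4):  # refine around the best candidate
                if best > 1e-9:
                    break
                # the margin is 2-Lipschitz in s, so the true maximum
                # cannot exceed the sampled maximum by more than `step`
                if best <= 1e-9 - step:
                    break
                fine = np.linspace(s_best - step, s_best + step, n_samples)
                got, s_got = margin(i, j, fine, mid, t)
                if got is None:
                    break
                best, s_best = got, s_got
                step = 2 * step / (n_samples - 1)
            if best is not None and best > 1e-9:
                edges.add(frozenset((i, j)))
    return edges


def closure_components_oracle(member_ids, adjacency) -> list[set[int]]:
    """Connected components by boolean reachability-matrix closure."""
    members = sorted(set(member_ids))
    idx = {m: k for k, m in enumerate(members)}
    n = len(members)
    if n == 0:
        return []
    reach = np.eye(n, dtype=bool)
    for m in members:
        for nbr in adjacency[m]:
            if nbr in idx:
                reach[idx[m], idx[nbr]] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    comps = []
    seen = set()
    for k in range(n):
        if k in seen:
            continue
        comp = {members[q] for q in np.nonzero(reach[k])[0]}
        seen |= {idx[m] for m in comp}
        comps.append(comp)
    comps.sort(key=lambda g: (-len(g), min(g)))
    return comps


def literal_grade_oracle(flags, adjacency) -> str:
    """Grade categories applied literally from the decision rules, using
    the closure-based component oracle (independent of the package BFS)."""
    countable = {f.cell_id for f in flags if f.countable}
    distinct = {f.cell_id for f in flags if f.border_distinct}
    comps = closure_components_oracle(countable, adjacency)
    qualifying = [c for c in comps if len(c) >= 15]
    n_q = sum(len(c) for c in qualifying)
    n_d = sum(len(c & distinct) for c in qualifying)
    if any(len(c) >= 50 and c <= distinct for c in comps):
        return "excellent"
    if n_q >= 50 and n_d == n_q:
        return "good"
    if n_q >= 50 and (n_q - n_d) * 4 <= n_q:
        return "fair"
    return "unanalyzable"


def wilcoxon_enumeration_oracle(differences) -> tuple[float, float]:
    """Exact signed-rank two-tailed p by full 2^n enumeration."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    w_all = []
    for mask in range(2**n):
        signs = [(mask >> k) & 1 for k in range(n)]
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    lower = np.mean(w_all <= w_obs + 1e-9)
    upper = np.mean(w_all >= w_obs - 1e-9)
    return w_obs, float(min(1.0, 2.0 * min(lower, upper)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240515)
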