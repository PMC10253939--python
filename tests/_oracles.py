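"""Independent brute-force reference implementations used as test oracles.

Every function here applies the declared definition of an operation with
plain Python loops (or an exhaustive search), sharing no code with the
package's vectorised implementations.
"""

from __future__ import annotations

import numpy as np


def brute_boxcar(pixels: np.ndarray, space_cutoff: int, time_cutoff: int) -> np.ndarray:
    """Per-pixel mean over a (space_cutoff x time_cutoff) window with
    symmetric (reflect) edge handling."""
    padded = np.pad(
        pixels, ((space_cutoff // 2,), (time_cutoff // 2,)), mode="symmetric"
    )
    out = np.empty_like(pixels, dtype=float)
    for i in range(pixels.shape[0]):
        for j in range(pixels.shape[1]):
            out[i, j] = padded[i : i + space_cutoff, j : j + time_cutoff].mean()
    return out


def brute_normalize(pixels: np.ndarray, half_window: int) -> np.ndarray:
    """Divide each point by the mean of its temporal neighbours within
    half_window lines on each side, centre excluded, shrunken at edges."""
    n_space, n_time = pixels.shape
    out = np.empty_like(pixels, dtype=float)
    for i in range(n_space):
        for j in range(n_time):
            lo = max(0, j - half_window)
            hi = min(n_time - 1, j + half_window)
            neighbors = [pixels[i, k] for k in range(lo, hi + 1) if k != j]
            out[i, j] = pixels[i, j] / (sum(neighbors) / len(neighbors))
    return out


def brute_erode_cross(bits: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Min over the 3x3 cross at each pixel; outside the grid counts as 0."""
    out = bits.astype(np.uint8).copy()
    n_space, n_time = bits.shape
    for _ in range(iterations):
        nxt = np.zeros_like(out)
        for i in range(n_space):
            for j in range(n_time):
                vals = [out[i, j]]
                vals.append(out[i - 1, j] if i > 0 else 0)
                vals.append(out[i + 1, j] if i < n_space - 1 else 0)
                vals.append(out[i, j - 1] if j > 0 else 0)
                vals.append(out[i, j + 1] if j < n_time - 1 else 0)
                nxt[i, j] = min(vals)
        out = nxt
    return out


def brute_components(bits: np.ndarray, min_area: int) -> list[frozenset]:
    """8-connected components by flood fill, keeping area >= min_area."""
    n_space, n_time = bits.shape
    seen = np.zeros_like(bits, dtype=bool)
    comps = []
    for i in range(n_space):
        for j in range(n_time):
            if bits[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = set()
                while stack:
                    ci, cj = stack.pop()
                    comp.add((ci, cj))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = ci + di, cj + dj
                            if (
                                0 <= ni < n_space
                                and 0 <= nj < n_time
                                and bits[ni, nj]
                                and not seen[ni, nj]
                            ):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                if len(comp) >= min_area:
                    comps.append(frozenset(comp))
    return comps


def brute_centroid(
    member_pixels: np.ndarray, norm_values: np.ndarray
) -> tuple[float, float]:
    """Weighted mean of member coordinates, weights max(value - 1, 0)."""
    total = 0.0
    si = 0.0
    sj = 0.0
    for i, j in member_pixels:
        w = max(norm_values[i, j] - 1.0, 0.0)
        total += w
        si += w * i
        sj += w * j
    if total == 0:
        pts = np.asarray(member_pixels, float)
        return float(pts[:, 0].mean()), float(pts[:, 1].mean())
    return si / total, sj / total


def brute_percentile(values, q: float) -> float:
    """Linear-interpolation percentile: h = (n-1) * q/100 between the order
    statistics floor(h) and floor(h)+1."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    h = (n - 1) * q / 100.0
    lo = int(np.floor(h))
    if lo >= n - 1:
        return vals[-1]
    frac = h - lo
    return vals[lo] + frac * (vals[lo + 1] - vals[lo])


def optimal_match_count(
    detected: np.ndarray, truth: np.ndarray, tol_x: float, tol_t: float
) -> int:
    """Maximum number of one-to-one pairs within tolerance, by optimal
    assignment (scipy Hungarian on a penalised cost matrix)."""
    from scipy.optimize import linear_sum_assignment

    det = np.asarray(detected, float).reshape(-1, 2)
    tru = np.asarray(truth, float).reshape(-1, 2)
    if det.size == 0 or tru.size == 0:
        return 0
    dx = np.abs(det[:, None, 0] - tru[None, :, 0]) / tol_x
    dt = np.abs(det[:, None, 1] - tru[None, :, 1]) / tol_t
    dist = np.maximum(dx, dt)
    cost = np.where(dist <= 1.0, dist, 1e6)
    rows, cols = linear_sum_assignment(cost)
    return int(np.sum(cost[rows, cols] <= 1.0))
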