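"""Independent brute-force oracles.

Everything here is written from the definitions, without touching the package
internals (direct exponential-weight sums, explicit summation loops, a
monotone-chain hull with the shoelace formula, normal-equation least squares,
exhaustive subset enumeration), so agreement with the package is evidence,
not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- exponentially weighted statistics (causal, span-parameterized,
#     weights renormalized over present entries only) -----------------------

def ewm_mean_std(x: np.ndarray, span: int) -> tuple[np.ndarray, np.ndarray]:
    alpha = 2.0 / (span + 1)
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = np.full(n, np.nan)
    std = np.full(n, np.nan)
    for i in range(n):
        present = [j for j in range(i + 1) if math.isfinite(x[j])]
        if not present:
            continue
        k = len(present)
        w = np.array([(1 - alpha) ** (k - 1 - r) for r in range(k)])
        vals = x[present]
        sw = w.sum()
        m = float((w * vals).sum() / sw)
        mean[i] = m
        if k >= 2:
            var_biased = float((w * (vals - m) ** 2).sum() / sw)
            correction = sw**2 / (sw**2 - (w**2).sum())
            std[i] = math.sqrt(var_biased * correction)
    return mean, std


def ewm_outlier_mask(x: np.ndarray, span: int, multiplier: float) -> np.ndarray:
    """One rejection pass from the definitions: flag where |x - EMA| > m*sigma."""
    x = np.asarray(x, dtype=float)
    mean, std = ewm_mean_std(x, span)
    out = ~np.isfinite(x)
    for i in range(x.size):
        if np.isfinite(x[i]) and np.isfinite(std[i]) and std[i] > 0:
            if abs(x[i] - mean[i]) > multiplier * std[i]:
                out[i] = True
    return out


# --- index definitions by explicit loops -----------------------------------

def spb1_direct(limb_points: np.ndarray, t: float) -> float:
    n = limb_points.shape[0]
    total = 0.0
    for k in range(4):
        acc = 0.0
        for i in range(n - 1):
            dx = limb_points[i + 1, k, 0] - limb_points[i, k, 0]
            dy = limb_points[i + 1, k, 1] - limb_points[i, k, 1]
            acc += math.hypot(dx, dy) / t
        total += acc / (n - 1)
    return total / 4.0


def spb2_direct(limb_points: np.ndarray, t: float) -> float:
    n = limb_points.shape[0]
    best = -math.inf
    for i in range(n - 1):
        D = 0.0
        for k in range(4):
            dx = limb_points[i + 1, k, 0] - limb_points[i, k, 0]
            dy = limb_points[i + 1, k, 1] - limb_points[i, k, 1]
            D += math.hypot(dx, dy) / t
        best = max(best, D)
    return best


def hull_area_direct(points: np.ndarray) -> float:
    """Monotone-chain convex hull + shoelace area; 0 for degenerate sets."""
    pts = sorted(set(map(tuple, np.asarray(points, dtype=float))))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        return 0.0
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def spb3_direct(limb_points: np.ndarray, t: float) -> float:
    n = limb_points.shape[0]
    return sum(hull_area_direct(limb_points[:, k, :]) for k in range(4)) / (t**2 * n)


def _angle_deg(u, v) -> float:
    nu, nv = math.hypot(*u), math.hypot(*v)
    if nu == 0 or nv == 0:
        return math.nan
    c = (u[0] * v[0] + u[1] * v[1]) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def ag_direct(shoulder, hip, elbow, wrist, knee, ankle) -> tuple[float, float, float]:
    """(AG1, AG2, AG3) by explicit per-frame loops from the definitions."""
    n = shoulder.shape[0]
    mid_arm = 0.5 * (elbow + wrist)
    mid_leg = 0.5 * (knee + ankle)
    sx_arm = -1.0 if np.nanmean(mid_arm[:, 0] - shoulder[:, 0]) < 0 else 1.0
    sx_leg = -1.0 if np.nanmean(mid_leg[:, 0] - hip[:, 0]) < 0 else 1.0
    thetas, Phis = [], []
    for i in range(n):
        th1 = _angle_deg(mid_arm[i] - shoulder[i], (sx_arm, 0.0))
        th2 = _angle_deg(mid_leg[i] - hip[i], (sx_leg, 0.0))
        if math.isfinite(th1) and math.isfinite(th2):
            thetas.append(th1 + th2)
        up = shoulder[i] - hip[i]
        p1 = 0.0 if elbow[i, 1] < shoulder[i, 1] else _angle_deg(up, elbow[i] - shoulder[i])
        p2 = 0.0 if knee[i, 1] < hip[i, 1] else _angle_deg(-up, knee[i] - hip[i])
        p3 = _angle_deg(elbow[i] - shoulder[i], wrist[i] - elbow[i])
        p4 = _angle_deg(knee[i] - hip[i], ankle[i] - knee[i])
        Phi = p1 + p2 + p3 + p4
        if math.isfinite(Phi):
            Phis.append(Phi)
    return (
        float(np.mean(thetas)),
        float(np.mean(Phis)),
        float(np.max(Phis)),
    )


# --- least squares, AIC and subset selection -------------------------------

def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """(beta incl. intercept first, RSS) via the normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def aic_gaussian(rss: float, n: int, k_mean: int, include_scale: bool = True) -> float:
    """AIC from the maximized Gaussian log-likelihood, written out in full."""
    llf = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1)
    return -2 * llf + 2 * (k_mean + (1 if include_scale else 0))


def best_subset_aic(X: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[tuple[str, ...], float]:
    """Exhaustive enumeration of all predictor subsets; best (subset, AIC)."""
    X = np.asarray(X, dtype=float)
    best = None
    for r in range(len(names) + 1):
        for combo in itertools.combinations(range(len(names)), r):
            _, rss = ols_normal_equations(X[:, list(combo)], y)
            aic = aic_gaussian(rss, len(y), len(combo) + 1)
            key = (aic, tuple(names[i] for i in combo))
            if best is None or aic < best[1]:
                best = (key[1], aic)
    return best


def greedy_backward_path(X: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[tuple[str, ...], float]:
    """Independent replay of backward elimination (min-AIC drop, name-order ties)."""
    current = sorted(names)
    idx = {nm: i for i, nm in enumerate(names)}
    _, rss = ols_normal_equations(X[:, [idx[nm] for nm in current]], y)
    best_aic = aic_gaussian(rss, len(y), len(current) + 1)
    while current:
        options = []
        for nm in current:
            rest = [c for c in current if c != nm]
            _, rss = ols_normal_equations(X[:, [idx[c] for c in rest]], y)
            options.append((aic_gaussian(rss, len(y), len(rest) + 1), nm))
        aic, nm = min(options)
        if aic < best_aic:
            best_aic = aic
            current = [c for c in current if c != nm]
        else:
            break
    return tuple(current), best_aic
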