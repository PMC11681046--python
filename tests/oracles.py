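"""Independent brute-force oracles used to check the geometric code.

These deliberately share no code with the package: point-in-polygon is
classic even-odd ray casting, and ray-boundary distance is an O(edges)
exhaustive segment-intersection scan.
"""

from __future__ import annotations

import math

import numpy as np


def point_in_polygon_oracle(vertices: np.ndarray, p) -> bool:
    """Even-odd ray casting; points on an edge count as inside."""
    x, y = float(p[0]), float(p[1])
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-edge check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and \
               min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
                return True
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xin:
                inside = not inside
    return inside


def ray_distance_oracle(vertices: np.ndarray, centroid, p):
    """Distance from p back to the last polygon crossing of the centroid ray.

    Exhaustive per-edge parametric intersection; returns (d, hit) or
    None when no crossing exists.
    """
    c = np.asarray(centroid, dtype=float)
    p = np.asarray(p, dtype=float)
    u = p - c
    best_t = None
    n = len(vertices)
    for i in range(n):
        a = np.asarray(vertices[i], dtype=float)
        b = np.asarray(vertices[(i + 1) % n], dtype=float)
        e = b - a
        denom = u[0] * e[1] - u[1] * e[0]
        if abs(denom) < 1e-12:
            continue
        w = a - c
        t = (w[0] * e[1] - w[1] * e[0]) / denom
        s = (w[0] * u[1] - w[1] * u[0]) / denom
        if -1e-9 <= s <= 1 + 1e-9 and 1e-12 < t <= 1 + 1e-9:
            if best_t is None or t > best_t:
                best_t = t
    if best_t is None:
        return None
    hit = c + min(best_t, 1.0) * u
    return float(np.hypot(*(p - hit))), (float(hit[0]), float(hit[1]))


def quadrant_angle_oracle(p, c) -> float:
    """Angle in degrees in [-180, 180) via explicit quadrant cases."""
    dx, dy = p[0] - c[0], p[1] - c[1]
    if dx > 0:
        ang = math.degrees(math.atan(dy / dx))
    elif dx < 0 and dy >= 0:
        ang = math.degrees(math.atan(dy / dx)) + 180.0
    elif dx < 0:
        ang = math.degrees(math.atan(dy / dx)) - 180.0
    elif dy > 0:
        ang = 90.0
    elif dy < 0:
        ang = -90.0
    else:
        raise ValueError("undefined angle")
    if ang >= 180.0:
        ang -= 360.0
    return ang


def directional_moments_oracle(points, center, axis_angle_deg, dA):
    """Per-point rotate-then-sum second moments (I_x', I_y')."""
    a = math.radians(axis_angle_deg)
    I_x = I_y = 0.0
    for x, y in points:
        dx, dy = x - center[0], y - center[1]
        x_p = math.cos(a) * dx + math.sin(a) * dy
        y_p = -math.sin(a) * dx + math.cos(a) * dy
        I_x += y_p**2 * dA
        I_y += x_p**2 * dA
    return I_x, I_y


def mad_filter_oracle(values, k=3.0):
    v = sorted(values)
    n = len(v)
    med = (v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2]))
    dev = sorted(abs(x - med) for x in values)
    mad = (dev[n // 2] if n % 2 else 0.5 * (dev[n // 2 - 1] + dev[n // 2]))
    smad = 1.4826 * mad
    if smad == 0:
        return [x != med for x in values]
    return [abs(x - med) > k * smad for x in values]
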