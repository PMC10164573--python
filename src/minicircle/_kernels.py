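"""Numba kernels for the inner loops of writhe and steric evaluation.

These are the only hot spots of the Monte-Carlo shape search: the segment-pair
writhe sum (O(n^2) pairs with cross products) and the all-pairs steric scan
(~1e6 distance checks per energy evaluation).
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def polygon_writhe(pts):
    """Writhe of the closed polygon through ``pts`` (n, 3).

    Exact Gauss double integral for straight segment pairs via the solid-angle
    closed form (Levitt's singularity-free formulation).  Adjacent segments lie
    in a common plane and contribute zero, so they are skipped.
    """
    n = pts.shape[0]
    total = 0.0
    for i in range(n):
        i2 = (i + 1) % n
        p1 = pts[i]
        p2 = pts[i2]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # wrap-around neighbour
            j2 = (j + 1) % n
            p3 = pts[j]
            p4 = pts[j2]

            r13x = p3[0] - p1[0]; r13y = p3[1] - p1[1]; r13z = p3[2] - p1[2]
            r14x = p4[0] - p1[0]; r14y = p4[1] - p1[1]; r14z = p4[2] - p1[2]
            r23x = p3[0] - p2[0]; r23y = p3[1] - p2[1]; r23z = p3[2] - p2[2]
            r24x = p4[0] - p2[0]; r24y = p4[1] - p2[1]; r24z = p4[2] - p2[2]

            # n1 = r13 x r14, n2 = r14 x r24, n3 = r24 x r23, n4 = r23 x r13
            n1x = r13y * r14z - r13z * r14y
            n1y = r13z * r14x - r13x * r14z
            n1z = r13x * r14y - r13y * r14x
            n2x = r14y * r24z - r14z * r24y
            n2y = r14z * r24x - r14x * r24z
            n2z = r14x * r24y - r14y * r24x
            n3x = r24y * r23z - r24z * r23y
            n3y = r24z * r23x - r24x * r23z
            n3z = r24x * r23y - r24y * r23x
            n4x = r23y * r13z - r23z * r13y
            n4y = r23z * r13x - r23x * r13z
            n4z = r23x * r13y - r23y * r13x

            m1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            m2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
            m3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
            m4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
            if m1 < 1e-14 or m2 < 1e-14 or m3 < 1e-14 or m4 < 1e-14:
                continue

            d12 = (n1x * n2x + n1y * n2y + n1z * n2z) / (m1 * m2)
            d23 = (n2x * n3x + n2y * n3y + n2z * n3z) / (m2 * m3)
            d34 = (n3x * n4x + n3y * n4y + n3z * n4z) / (m3 * m4)
            d41 = (n4x * n1x + n4y * n1y + n4z * n1z) / (m4 * m1)
            d12 = min(1.0, max(-1.0, d12))
            d23 = min(1.0, max(-1.0, d23))
            d34 = min(1.0, max(-1.0, d34))
            d41 = min(1.0, max(-1.0, d41))

            omega = (np.arcsin(d12) + np.arcsin(d23)
                     + np.arcsin(d34) + np.arcsin(d41))

            # sign from (r34 x r12) . r13
            r12x = p2[0] - p1[0]; r12y = p2[1] - p1[1]; r12z = p2[2] - p1[2]
            r34x = p4[0] - p3[0]; r34y = p4[1] - p3[1]; r34z = p4[2] - p3[2]
            cx = r34y * r12z - r34z * r12y
            cy = r34z * r12x - r34x * r12z
            cz = r34x * r12y - r34y * r12x
            s = cx * r13x + cy * r13y + cz * r13z
            if s > 0.0:
                total += omega
            elif s < 0.0:
                total -= omega
    return total / (2.0 * np.pi)


@njit(cache=True, fastmath=True)
def steric_scan(pts, d_min, window):
    """Quadratic overlap penalty and minimum non-neighbour distance.

    Pairs with circular index separation <= ``window`` are skipped (contour
    neighbours are legitimately closer than the tube diameter).  Returns
    ``(sum of (1 - d/d_min)^2 over violating pairs, min distance found)``.
    """
    n = pts.shape[0]
    penalty = 0.0
    dmin_found = 1e300
    d2cut = d_min * d_min
    for i in range(n):
        for j in range(i + 1, n):
            gap = j - i
            if n - gap < gap:
                gap = n - gap
            if gap <= window:
                continue
            dx = pts[i, 0] - pts[j, 0]
            dy = pts[i, 1] - pts[j, 1]
            dz = pts[i, 2] - pts[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < dmin_found:
                dmin_found = d2
            if d2 < d2cut:
                d = np.sqrt(d2)
                viol = 1.0 - d / d_min
                penalty += viol * viol
    return penalty, np.sqrt(dmin_found)
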