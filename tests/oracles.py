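"""Independent oracles used by the tests.

Everything here deliberately avoids the package's own algebraic paths:
Voronoi vertices are found by generic root-finding over all 4-subsets, the
inscribed intersection circle by 1-D search and by direct constrained
maximisation over tilted circles, and union volumes by Monte-Carlo sampling.
"""

import itertools

import numpy as np
from scipy.optimize import fsolve, minimize


def brute_force_vertices(coords, radii, lo, hi, empty_tol=1e-9):
    """All empty tangent spheres of 4-subsets, by multi-start root finding."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    found = []
    for quad in itertools.combinations(range(len(coords)), 4):
        P = coords[list(quad)]
        R = radii[list(quad)]

        def eqs(u):
            v, c = u[:3], u[3]
            return [float(np.linalg.norm(v - P[i]) - R[i] - c) for i in range(4)]

        centroid = P.mean(axis=0)
        starts = [np.r_[centroid, c0] for c0 in (0.2, 1.0, 3.0, 8.0)]
        offs = np.array([[1, 1, 1], [-1, 1, -1], [1, -1, -1], [-1, -1, 1]], float)
        starts += [np.r_[centroid + 2.0 * o, 2.0] for o in offs]
        for g in starts:
            sol, info, ier, _ = fsolve(eqs, g, full_output=True)
            if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-9:
                continue
            v, c = sol[:3], sol[3]
            if np.any(v < lo) or np.any(v > hi):
                continue
            d = np.linalg.norm(coords - v, axis=1) - radii
            others = np.ones(len(coords), bool)
            others[list(quad)] = False
            if others.any() and (d[others] - c).min() < -empty_tol:
                continue
            if any(np.linalg.norm(v - w) < 1e-7 for w, _ in found):
                continue
            found.append((v, c))
    return found


def inscribed_circle_1d(r1, r2, d, n=200001):
    """Largest circle inside the lens, by 1-D search over axis positions.

    By rotational symmetry the optimal disk is perpendicular to the axis; its
    radius at axial position xi is min(sqrt(r1^2 - xi^2), sqrt(r2^2 - (xi-d)^2)).
    Returns None when the spheres are disjoint.
    """
    if d >= r1 + r2:
        return None
    lo = max(-r1, d - r2)
    hi = min(r1, d + r2)
    xi = np.linspace(lo, hi, n)
    f1 = np.sqrt(np.clip(r1 * r1 - xi * xi, 0.0, None))
    f2 = np.sqrt(np.clip(r2 * r2 - (xi - d) ** 2, 0.0, None))
    vals = np.minimum(f1, f2)
    k = int(np.argmax(vals))
    # local refinement
    for _ in range(60):
        span = (hi - lo) / (n - 1)
        xs = np.linspace(max(lo, xi[k] - span), min(hi, xi[k] + span), 101)
        g = np.minimum(
            np.sqrt(np.clip(r1 * r1 - xs * xs, 0.0, None)),
            np.sqrt(np.clip(r2 * r2 - (xs - d) ** 2, 0.0, None)),
        )
        j = int(np.argmax(g))
        if g[j] <= vals[k] + 1e-15:
            break
        xi = xs
        vals = g
        k = j
        n = 101
        lo, hi = xs[0], xs[-1]
    return float(vals[k])


def inscribed_circle_maximize(r1, r2, d, seed=0):
    """Largest circle inside the lens by direct constrained maximisation.

    Optimises over the circle center (3 dof), its normal direction (2 dof)
    and radius t: the circle lies inside sphere i iff
    sqrt(w_i^2 + (rho_i + t)^2) <= r_i with w_i, rho_i the axial and radial
    components of (center - c_i) w.r.t. the normal. Returns the best radius
    over several starts, or None when the spheres are disjoint.
    """
    if d >= r1 + r2:
        return None
    centers = [np.zeros(3), np.array([d, 0.0, 0.0])]
    rads = [r1, r2]

    def unpack(u):
        q = u[:3]
        th, ph = u[3], u[4]
        n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        return q, n, u[5]

    def constraint(u, i):
        q, n, t = unpack(u)
        dvec = q - centers[i]
        w = float(dvec @ n)
        rho = float(np.linalg.norm(dvec - w * n))
        return rads[i] ** 2 - (w * w + (rho + t) ** 2)

    cons = [{"type": "ineq", "fun": constraint, "args": (i,)} for i in range(2)]
    rng = np.random.default_rng(seed)
    best = 0.0
    x_mid = 0.0 if d < 1e-12 else (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    x_small = 0.0 if r1 <= r2 else d  # center of the smaller sphere
    # canonical candidate configurations: the lens rim circle (disk on the
    # radical plane) and the smaller sphere's great circle
    rim2 = r1 * r1 - x_mid * x_mid
    rim = np.sqrt(rim2) if rim2 > 0 else 0.1 * min(r1, r2)
    starts = [
        np.array([x_mid, 1e-4, -1e-4, np.pi / 2, 1e-3, 0.95 * rim]),
        np.array([x_mid, 1e-4, -1e-4, np.pi / 2, 1e-3, 0.1 * min(r1, r2)]),
        np.array([x_small, 1e-4, 1e-4, np.pi / 2, -1e-3, 0.95 * min(r1, r2)]),
        np.array([x_small, 1e-4, 1e-4, np.pi / 2, -1e-3, 0.5 * min(r1, r2)]),
    ]
    base = x_mid if rng.random() < 0.5 else x_small
    starts.append(
        np.r_[
            np.array([base, 0, 0]) + rng.normal(scale=0.15 * min(r1, r2), size=3),
            np.pi / 2 + rng.normal(scale=0.3),
            rng.normal(scale=0.3),
            rng.uniform(0.05, 0.5) * min(r1, r2),
        ]
    )
    for u0 in starts:
        for _ in range(40):  # shrink the start onto a feasible point
            if all(constraint(u0, i) > 1e-10 for i in range(2)):
                break
            u0[5] *= 0.5
        else:
            continue
        res = minimize(
            lambda u: -u[5],
            u0,
            method="SLSQP",
            constraints=cons,
            options={"maxiter": 300, "ftol": 1e-12},
        )
        if -res.fun > best and all(constraint(res.x, i) > -1e-5 for i in range(2)):
            best = -res.fun
    return best


def monte_carlo_union_volume(centers, radii, n_points, rng):
    """Monte-Carlo estimate (value, sigma) of a sphere-union volume."""
    centers = np.asarray(centers, float)
    radii = np.asarray(radii, float)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    box = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    inside = np.zeros(n_points, bool)
    for c, r in zip(centers, radii):
        inside |= np.sum((pts - c) ** 2, axis=1) < r * r
    p = inside.mean()
    return box * p, box * np.sqrt(p * (1 - p) / n_points)


def lens_volume(r1, r2, d):
    """Closed-form volume of the intersection of two spheres."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * np.pi * r ** 3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d * d + 2 * d * r1 - 3 * r1 * r1 + 2 * d * r2 + 6 * r1 * r2 - 3 * r2 * r2)
        / (12.0 * d)
    )
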