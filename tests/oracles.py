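"""Independent oracles shared by the unit and acceptance tests.

Everything here is deliberately naive: brute-force pair counting, direct
1-D quadrature of the restrained configurational integral, closed-form
references.  The oracles never import the implementation's estimator code
paths beyond plain data types.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

KB_KCAL = 0.0019872041  # kcal/mol/K


def kendall_tau_b_brute(x, y) -> float:
    """Tie-corrected Kendall tau-b by explicit O(n^2) pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif (dx > 0) == (dy > 0):
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    if denom == 0:
        return float("nan")
    return (nc - nd) / denom


def _tie_term(v) -> float:
    """sum over tied groups of t*(t-1)/2."""
    _, counts = np.unique(np.asarray(v), return_counts=True)
    return float((counts * (counts - 1) // 2).sum())


def boresch_quadrature_dG(
    restraint, temperature: float = 298.15, v_standard: float = 1660.54
) -> float:
    """Exact factorised 1-D quadrature of the restrained configurational
    integral (with the r^2 and sin(theta) Jacobians), as the reference for
    the stiff-spring closed form.

    DG(c->d) = -kT ln[ 8 pi^2 V0 / (Z_r Z_thetaA Z_thetaB Z_phiA Z_phiB Z_phiC) ]
    with Z_r = int r^2 exp(-beta K_r (r-r0)^2/2) dr over (0, r0+20),
    Z_theta = int sin(theta) exp(-beta K (theta-theta0)^2/2) dtheta over (0, pi),
    Z_phi = int exp(-beta K (phi-phi0)^2/2) dphi over (phi0-pi, phi0+pi).
    """
    kt = KB_KCAL * temperature
    beta = 1.0 / kt

    def z_r(k, r0):
        return quad(
            lambda r: r * r * math.exp(-beta * k * (r - r0) ** 2 / 2.0),
            0.0,
            r0 + 20.0,
            limit=200,
        )[0]

    def z_theta(k, t0):
        return quad(
            lambda t: math.sin(t) * math.exp(-beta * k * (t - t0) ** 2 / 2.0),
            0.0,
            math.pi,
            limit=200,
        )[0]

    def z_phi(k, p0):
        return quad(
            lambda p: math.exp(-beta * k * (p - p0) ** 2 / 2.0),
            p0 - math.pi,
            p0 + math.pi,
            limit=200,
        )[0]

    z = (
        z_r(restraint.k_r, restraint.r0)
        * z_theta(restraint.k_theta_a, restraint.theta_a0)
        * z_theta(restraint.k_theta_b, restraint.theta_b0)
        * z_phi(restraint.k_phi_a, restraint.phi_a0)
        * z_phi(restraint.k_phi_b, restraint.phi_b0)
        * z_phi(restraint.k_phi_c, restraint.phi_c0)
    )
    return -kt * math.log(8.0 * math.pi**2 * v_standard / z)


def candidate_score_brute(candidates) -> list[float]:
    """Recompute the documented selection score by explicit loops.

    score = sum over the six coordinates of sigma / median(sigma of the
    coordinate's class across all candidates); classes are bond (r),
    angle (theta_a, theta_b) and dihedral (phi_a, phi_b, phi_c).
    """
    classes = {
        "r": "bond",
        "theta_a": "angle",
        "theta_b": "angle",
        "phi_a": "dihedral",
        "phi_b": "dihedral",
        "phi_c": "dihedral",
    }
    med = {}
    for cls in ("bond", "angle", "dihedral"):
        pool = [
            c.stds[name]
            for c in candidates
            for name in classes
            if classes[name] == cls
        ]
        m = float(np.median(pool))
        med[cls] = m if m > 0 else 1.0
    return [
        sum(c.stds[name] / med[classes[name]] for name in classes) for c in candidates
    ]


def frame_metric_brute(candidate) -> np.ndarray:
    """Exhaustive reference-frame metric: sum over coordinates of
    ((value - mean)/sigma)^2 with dihedral deviations wrapped."""
    classes = {"phi_a", "phi_b", "phi_c"}
    n = len(next(iter(candidate.series.values())))
    metric = np.zeros(n)
    for name, series in candidate.series.items():
        sigma = candidate.stds[name]
        if sigma <= 0 or not np.isfinite(sigma):
            continue
        dev = np.asarray(series) - candidate.means[name]
        if name in classes:
            dev = np.mod(dev + np.pi, 2 * np.pi) - np.pi
            dev[dev == -np.pi] = np.pi
        metric += (dev / sigma) ** 2
    return metric
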