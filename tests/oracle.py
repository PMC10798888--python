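"""Naive reference implementations used only as test oracles.

Everything here is written with plain Python loops, ``math.fsum`` and the
textbook definitions, independently of the package's vectorized code paths.
"""

from __future__ import annotations

import math
import statistics


def ols(xs, ys):
    """Closed-form simple linear regression; returns
    (slope, intercept, r_squared, mean_y, n)."""
    n = len(xs)
    mx = math.fsum(xs) / n
    my = math.fsum(ys) / n
    sxx = math.fsum((x - mx) ** 2 for x in xs)
    sxy = math.fsum((x - mx) * (y - my) for x, y in zip(xs, ys))
    syy = math.fsum((y - my) ** 2 for y in ys)
    slope = sxy / sxx
    r2 = 0.0 if syy == 0 else 1.0 - (syy - slope * sxy) / syy
    return slope, my - slope * mx, r2, my, n


def ols_ci(xs, ys, tppf):
    """Slope with a 95% CI half-width computed from first principles;
    ``tppf`` is the 0.975 t quantile with n - 2 df."""
    n = len(xs)
    slope, intercept, _, _, _ = ols(xs, ys)
    mx = math.fsum(xs) / n
    residuals = [y - (intercept + slope * x) for x, y in zip(xs, ys)]
    ss_res = math.fsum(r * r for r in residuals)
    sxx = math.fsum((x - mx) ** 2 for x in xs)
    stderr = math.sqrt(ss_res / (n - 2) / sxx)
    return slope, slope - tppf * stderr, slope + tppf * stderr


def kde_argmax(values, grid_points=10_001):
    """Mode of a Gaussian KDE with Scott bandwidth via a direct kernel sum."""
    n = len(values)
    mean = math.fsum(values) / n
    sd = math.sqrt(math.fsum((v - mean) ** 2 for v in values) / (n - 1))
    h = n ** (-1 / 5) * sd
    lo = min(values) - 3 * h
    hi = max(values) + 3 * h
    best_x, best_d = lo, -1.0
    for i in range(grid_points):
        x = lo + (hi - lo) * i / (grid_points - 1)
        d = math.fsum(
            math.exp(-((x - v) ** 2) / (2 * h * h)) for v in values
        )
        if d > best_d:
            best_x, best_d = x, d
    return best_x


def dbscan_noise(points, eps, min_samples):
    """Noise flags per the DBSCAN definition via brute-force neighbourhood
    counting: a point is noise iff it is neither a core point nor within eps
    of one."""
    n = len(points)

    def dist(i, j):
        return math.dist(points[i], points[j])

    core = [
        sum(1 for j in range(n) if dist(i, j) <= eps) >= min_samples
        for i in range(n)
    ]
    return [
        not core[i]
        and not any(core[j] and dist(i, j) <= eps for j in range(n))
        for i in range(n)
    ]


def match_ages(shorter_ages, longer_ages, shorter_lifespan):
    """Brute-force age-range matching; returns
    (matched_short, matched_long) or None."""
    tol = min(0.02 * shorter_lifespan, 1.0)
    for a in sorted(set(shorter_ages), reverse=True):
        best = min(longer_ages, key=lambda la: (abs(la - a), la))
        if abs(best - a) <= tol:
            return a, best
    return None


def naive_chain(panels, traits, r2_threshold, min_cpgs):
    """Loop-based reimplementation of the full comparison chain.

    ``panels`` maps species -> (cpg_ids, ages, betas) with betas a list of
    per-CpG value lists. Returns (species, cumulative_ratios) or raises
    ValueError when a comparison selects too few CpGs.
    """
    eligible = []
    for species in sorted(panels):
        cpgs, ages, betas = panels[species]
        t = traits[species]
        if len(ages) < 20:
            continue
        if max(ages) + t.age_sexual_maturity < 0.25 * t.max_lifespan:
            continue
        eligible.append(species)
    ordered = sorted(
        eligible, key=lambda s: (max(panels[s][1]), s)
    )

    def restrict(species, max_age):
        cpgs, ages, betas = panels[species]
        keep = [i for i, a in enumerate(ages) if a <= max_age]
        return (
            cpgs,
            [ages[i] for i in keep],
            [[row[i] for i in keep] for row in betas],
        )

    def cpg_fits(cpgs, ages, betas):
        fits = {}
        for cid, row in zip(cpgs, betas):
            pairs = [
                (a, b) for a, b in zip(ages, row) if not math.isnan(b)
            ]
            if len(pairs) < 3:
                continue
            xs = [p[0] for p in pairs]
            ys = [p[1] for p in pairs]
            if len(set(xs)) < 2:
                continue
            fits[cid] = ols(xs, ys)
        return fits

    retained = [ordered[0]]
    cumulative = [1.0]
    current = ordered[0]
    for species in ordered[1:]:
        match = match_ages(
            panels[current][1], panels[species][1],
            traits[current].max_lifespan,
        )
        if match is None:
            continue
        a_short, a_long = match
        short = restrict(current, a_short)
        long_ = restrict(species, a_long)
        if len(short[1]) < 15 or len(long_[1]) < 15:
            continue
        t_s, t_l = traits[current], traits[species]
        if max(short[1]) + t_s.age_sexual_maturity < 0.25 * t_s.max_lifespan:
            continue
        if max(long_[1]) + t_l.age_sexual_maturity < 0.25 * t_l.max_lifespan:
            continue
        fits_s = cpg_fits(*short)
        fits_l = cpg_fits(*long_)
        ratios = []
        for cid in short[0]:
            if cid not in fits_s or cid not in fits_l:
                continue
            s_slope, _, s_r2, s_mean, _ = fits_s[cid]
            l_slope, _, l_r2, l_mean, _ = fits_l[cid]
            if s_r2 < r2_threshold or l_r2 < r2_threshold:
                continue
            if s_slope == 0 or l_slope == 0:
                continue
            if (s_slope > 0) != (l_slope > 0):
                continue
            if not (0.1 <= s_mean <= 0.9 and 0.1 <= l_mean <= 0.9):
                continue
            ratios.append(l_slope / s_slope)
        if len(ratios) < min_cpgs:
            raise ValueError("too few CpGs in a comparison")
        cumulative.append(cumulative[-1] * statistics.median(ratios))
        retained.append(species)
        current = species
    return retained, cumulative
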