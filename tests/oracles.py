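"""Independent brute-force oracles for the feature and filter computations.

Everything here is written as plain Python loops over event records, on
purpose: these implementations share no code path with the package and are
used only to cross-check it.
"""

import math
from statistics import mean, stdev


def oracle_assign_aoi(x, y, grid):
    """Rectangle-by-rectangle search over all margin-expanded cells."""
    hits = []
    for idx in range(grid.n_cells):
        x0, y0, x1, y1 = grid.cell_rect(idx)
        if x0 <= x < x1 and y0 <= y < y1:
            hits.append(idx)
    return hits[0] if hits else None


def oracle_duration_filter(durations, floor, z_max):
    """Two-pass filter: drop below floor, then drop z >= z_max (sample sd)."""
    survivors = [d for d in durations if d >= floor]
    if len(survivors) < 2:
        return survivors
    m = mean(survivors)
    sd = stdev(survivors)
    if sd == 0:
        return survivors
    return [d for d in survivors if (d - m) / sd < z_max]


def oracle_regressions(fixations, grid):
    x_reg = 0
    y_reg = 0
    for a, b in zip(fixations, fixations[1:]):
        row_a = a.aoi // grid.cols
        row_b = b.aoi // grid.cols
        if row_b == row_a and b.x < a.x:
            x_reg += 1
        if b.y < a.y:
            y_reg += 1
    return x_reg, y_reg


def oracle_fixation_features(trial, grid):
    fixs = trial.fixations
    if not fixs:
        return {"n_fix": 0.0}
    durs = [f.duration for f in fixs]
    span = (fixs[-1].t_start + fixs[-1].duration) - fixs[0].t_start
    x_reg, y_reg = oracle_regressions(fixs, grid)
    return {
        "n_fix": float(len(fixs)),
        "fix_mean": sum(durs) / len(durs),
        "fix_max": max(durs),
        "norm_fix_mean": (sum(durs) / len(durs)) / span,
        "norm_fix_max": max(durs) / span,
        "x_regressions": float(x_reg),
        "y_regressions": float(y_reg),
    }


def oracle_px_to_deg(d_px, geometry):
    mm = d_px * geometry.screen_width_mm / geometry.screen_width_px
    return math.degrees(2 * math.atan(mm / (2 * geometry.distance_mm)))


def oracle_saccade_features(trial, geometry):
    saccs = trial.saccades
    counts = {"up": 0, "down": 0, "left": 0, "right": 0}
    n_dir = 0
    durs, vels, ampls, angles, dists, slopes = [], [], [], [], [], []
    for s in saccs:
        dx = s.x_end - s.x_start
        dy = s.y_end - s.y_start
        if not (dx == 0 and dy == 0):
            n_dir += 1
            if abs(dx) >= abs(dy):
                counts["right" if dx > 0 else "left"] += 1
            else:
                counts["down" if dy > 0 else "up"] += 1
        durs.append(s.duration)
        vels.append(s.velocity)
        ampls.append(s.amplitude)
        angles.append(math.degrees(math.atan2(-dy, dx)) if (dx, dy) != (0, 0) else 0.0)
        dists.append(oracle_px_to_deg(math.sqrt(dx * dx + dy * dy), geometry))
        if dx == 0:
            slopes.append(0.0 if dy == 0 else math.copysign(1e6, dy))
        else:
            slopes.append(dy / dx)
    out = {f"{d}_freq": counts[d] / n_dir for d in counts}
    for name, vals in [("duration", durs), ("vel", vels), ("ampl", ampls),
                       ("angle", angles), ("distance", dists), ("slope", slopes)]:
        out[f"min_{name}"] = min(vals)
        out[f"avg_{name}"] = sum(vals) / len(vals)
        out[f"max_{name}"] = max(vals)
    return out
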