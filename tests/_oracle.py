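"""Independent straight-line Mamdani oracle for cross-checking the engine.

Deliberately simple: scalar membership arithmetic written from the
textbook trapezoid definition for fuzzification, linear interpolation
between breakpoint nodes (np.interp) for the output profiles,
rule-by-rule clipping, pointwise max aggregation on a dense
100,001-point grid, and a plain discrete centroid. No code shared with
fuzzpk.fis beyond reading the configuration data.
"""

import numpy as np

ORACLE_GRID = 100_001


def mf_degree(shape, params, x, open_left=False, open_right=False):
    """Scalar membership degree from the textbook definition."""
    if shape == "triangular":
        a, bl, d = params
        br = bl
    else:
        a, bl, br, d = params
    if open_left and x < bl:
        return 1.0
    if open_right and x > br:
        return 1.0
    if bl <= x <= br:
        return 1.0
    if x <= a or x >= d:  # zero-width edges fall in the plateau branch above
        return 0.0
    if x < bl:
        return (x - a) / (bl - a)
    return (d - x) / (d - br)


def _profile(mf, grid, open_left, open_right):
    """Output-term profile by interpolation between breakpoint nodes."""
    if mf.shape == "triangular":
        a, b, c = mf.params
        nodes = [(a, 0.0), (b, 1.0), (c, 0.0)]
    else:
        a, b, c, d = mf.params
        nodes = [(a, 0.0), (b, 1.0), (c, 1.0), (d, 0.0)]
    # collapse zero-width edges (a==b or c==d): the plateau value wins
    if open_left or nodes[0][0] == nodes[1][0]:
        nodes = nodes[1:]
    if open_right or nodes[-1][0] == nodes[-2][0]:
        nodes = nodes[:-1]
    xp = [n[0] for n in nodes]
    fp = [n[1] for n in nodes]
    return np.interp(grid, xp, fp)


def fuzzify_var(var, x, policy):
    """Per-term degrees for one linguistic variable under the policy."""
    names = var.term_names
    if policy == "clamp_to_universe":
        x = min(max(x, var.universe[0]), var.universe[1])
    out = {}
    for i, name in enumerate(names):
        mf = var.terms[name]
        ol = mf.open_left or (policy == "saturate_extremes" and i == 0)
        orr = mf.open_right or (policy == "saturate_extremes" and i == len(names) - 1)
        out[name] = mf_degree(mf.shape, mf.params, x, ol, orr)
    return out


def evaluate(fis, values, n_grid=ORACLE_GRID):
    """Brute-force Mamdani max-min evaluation with a discrete centroid.

    Returns NaN when no rule fires.
    """
    policy = fis.options.out_of_range
    fuzz = {v.name: fuzzify_var(v, values[v.name], policy) for v in fis.inputs}
    lo, hi = fis.output.universe
    grid = np.linspace(lo, hi, n_grid)
    aggregated = np.zeros(n_grid)
    fired_any = False
    for rule in fis.rules:
        strength = min(fuzz[var][term] for var, term in rule.antecedent)
        if strength <= 0.0:
            continue
        fired_any = True
        out_mf = fis.output.terms[rule.consequent]
        profile = _profile(out_mf, grid, out_mf.open_left, out_mf.open_right)
        aggregated = np.maximum(aggregated, np.minimum(profile, strength))
    if not fired_any or aggregated.sum() <= 0:
        return float("nan")
    return float((grid * aggregated).sum() / aggregated.sum())
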