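"""Independent naive reference implementations of the merging statistics.

Pure-Python loops over grouped observation lists, sharing no code with the
package's vectorised engine.  Observation lists are
``{key: [(intensity, sigma, sign), ...]}``.  For the half-set correlation
statistics the (seeded) half assignment is an explicit input, so the
reference recomputes the statistic independently from the same split.
"""

import math


def ref_r_factors(groups):
    num_merge = num_meas = den = 0.0
    any_multi = False
    for obs in groups.values():
        if len(obs) < 2:
            continue
        any_multi = True
        vals = [o[0] for o in obs]
        mean = sum(vals) / len(vals)
        dev = sum(abs(v - mean) for v in vals)
        num_merge += dev
        num_meas += dev * math.sqrt(len(vals) / (len(vals) - 1.0))
        den += sum(vals)
    if not any_multi or den == 0:
        return None, None
    return num_merge / den, num_meas / den


def ref_i_over_sigma(groups):
    total = 0.0
    n = 0
    for obs in groups.values():
        sw = sum(1.0 / (o[1] ** 2) for o in obs)
        swi = sum(o[0] / (o[1] ** 2) for o in obs)
        i_hat = swi / sw
        s_hat = 1.0 / math.sqrt(sw)
        total += i_hat / s_hat
        n += 1
    return total / n if n else None


def ref_multiplicity(groups):
    n_obs = sum(len(v) for v in groups.values())
    return n_obs / len(groups) if groups else None


def ref_completeness(groups, reference_keys):
    ref = set(reference_keys)
    return len(set(groups) & ref) / len(ref)


def ref_sig_ano(groups):
    total = 0.0
    n = 0
    for obs in groups.values():
        plus = [o for o in obs if o[2] > 0]
        minus = [o for o in obs if o[2] < 0]
        if not plus or not minus:
            continue
        vals = []
        for side in (plus, minus):
            sw = sum(1.0 / (o[1] ** 2) for o in side)
            swi = sum(o[0] / (o[1] ** 2) for o in side)
            vals.append((swi / sw, 1.0 / sw))
        (ip, vp), (im, vm) = vals
        total += abs(ip - im) / math.sqrt(vp + vm)
        n += 1
    return total / n if n else None


def _pearson(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx == 0 or syy == 0:
        return None
    return sxy / math.sqrt(sxx * syy)


def ref_cc_half(groups, halves):
    """``halves``: {key: [0/1 per observation, same order as groups[key]]}."""
    xs, ys = [], []
    for key, obs in groups.items():
        if len(obs) < 2:
            continue
        h = halves[key]
        h0 = [o[0] for o, hh in zip(obs, h) if hh == 0]
        h1 = [o[0] for o, hh in zip(obs, h) if hh == 1]
        if not h0 or not h1:
            continue
        xs.append(sum(h0) / len(h0))
        ys.append(sum(h1) / len(h1))
    if len(xs) < 3:
        return None
    return _pearson(xs, ys)


def ref_cc_anom(groups, halves):
    """Half labels per (key, sign): halves[key] aligned with groups[key]."""
    d0, d1 = [], []
    for key, obs in groups.items():
        h = halves[key]
        cells = {}
        for o, hh in zip(obs, h):
            cells.setdefault((o[2] > 0, hh), []).append(o[0])
        if not all((s, hh) in cells for s in (True, False) for hh in (0, 1)):
            continue
        mean = {k: sum(v) / len(v) for k, v in cells.items()}
        d0.append(mean[(True, 0)] - mean[(False, 0)])
        d1.append(mean[(True, 1)] - mean[(False, 1)])
    if len(d0) < 3:
        return None
    return _pearson(d0, d1)
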