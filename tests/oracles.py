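"""Independent brute-force transcriptions of the grey relational equations.

Deliberately written with plain Python loops and the classical discrete
sum formula for the incidence integrals, sharing no code with the
package implementation, so the two can serve as mutual checks.
"""

from __future__ import annotations


def deng_grade_oracle(ref, comparatives, j, zeta=0.5, scope="panel_wide"):
    """gamma(Y_i, Y_j): mean over epochs of the point coefficient.

    coefficient(l) = (d_min + zeta*d_max) / (|Y_i(l) - Y_j(l)| + zeta*d_max)
    with d_min/d_max the extreme absolute deviations over all comparatives
    and epochs (panel_wide) or over the single pair (per_pair).
    """
    ref = list(ref)
    comparatives = [list(c) for c in comparatives]
    h = len(ref)
    if scope == "panel_wide":
        all_devs = []
        for comp in comparatives:
            for l in range(h):
                all_devs.append(abs(ref[l] - comp[l]))
    else:
        all_devs = [abs(ref[l] - comparatives[j][l]) for l in range(h)]
    d_min = min(all_devs)
    d_max = max(all_devs)
    total = 0.0
    for l in range(h):
        d = abs(ref[l] - comparatives[j][l])
        if d_max == 0.0:
            coeff = 1.0
        else:
            coeff = (d_min + zeta * d_max) / (d + zeta * d_max)
        total += coeff
    return total / h


def _incidence_sum(series):
    """Classical discrete incidence quantity: sum(x0[2..h-1]) + x0[h]/2."""
    x0 = [v - series[0] for v in series]
    s = 0.0
    for l in range(1, len(x0) - 1):
        s += x0[l]
    s += 0.5 * x0[-1]
    return s


def absolute_grade_oracle(ref, cmp):
    """epsilon = (1 + |r_i| + |r_j|) / (1 + |r_i| + |r_j| + |r_i - r_j|)."""
    ref = list(ref)
    cmp = list(cmp)
    r_i = _incidence_sum(ref)
    r_j = _incidence_sum(cmp)
    diff = [a - b for a, b in zip(ref, cmp)]
    r_diff = _incidence_sum(diff)
    top = 1.0 + abs(r_i) + abs(r_j)
    return top / (top + abs(r_diff))
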