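"""Independent reference implementations used only as test oracles.

These deliberately recompute results from the raw domain records with
plain Python (no vault queries, no scipy shortcuts shared with the
implementation under test).
"""

from fractions import Fraction
from math import comb
from typing import Dict, List, Sequence, Tuple

_LEVEL_ORDER = ["Not detected", "Low", "Medium", "High"]


def brute_force_rank(proteins, tms, healthy, cancer, cancer_type,
                     min_frac=0.5, apply_tm_filter=True) -> List[Tuple]:
    """Stable 4-key lexicographic sort of the candidate table.

    Returns [(protein_id, (k1, k2, k3, k4)), ...] in rank order.
    """
    symbol = {p.protein_id: p.gene_symbol for p in proteins}
    tm_by_pid: Dict[str, list] = {}
    for t in tms:
        tm_by_pid.setdefault(t.protein_id, []).append(t)
    tissue_max: Dict[str, Dict[str, int]] = {}
    for o in healthy:
        lvl = _LEVEL_ORDER.index(o.level)
        d = tissue_max.setdefault(o.protein_id, {})
        if lvl > d.get(o.tissue, -1):
            d[o.tissue] = lvl
    rows = []
    for s in cancer:
        if s.cancer_type != cancer_type:
            continue
        total = s.n_high + s.n_medium + s.n_low + s.n_not_detected
        frac = (s.n_high + s.n_medium) / total
        if not frac > min_frac:
            continue
        agreeing = sum(p.n_segments == 1 for p in tm_by_pid.get(s.protein_id, []))
        if apply_tm_filter and agreeing < 5:
            continue
        maxima = tissue_max.get(s.protein_id, {})
        k2 = sum(v == 3 for v in maxima.values())
        k3 = sum(v == 2 for v in maxima.values())
        rows.append(((k2 + k3, k2, k3, -frac, symbol[s.protein_id]),
                     (s.protein_id, (k2 + k3, k2, k3, frac))))
    rows.sort(key=lambda r: r[0])
    return [r[1] for r in rows]


def hypergeom_upper_tail_exact(k: int, N: int, m: int, q: int) -> Fraction:
    """P[X >= k] for X ~ Hypergeometric(N, m, q), exact rational.

    Direct summation of C(m, i) C(N-m, q-i) / C(N, q) over i = k..min(m, q)
    via the pmf recurrence (exact integer arithmetic throughout).
    """
    lo, hi = max(0, m + q - N), min(m, q)
    k = max(k, lo)
    if k > hi:
        return Fraction(0)
    pmf = Fraction(comb(m, k) * comb(N - m, q - k), comb(N, q))
    total = pmf
    for i in range(k, hi):
        pmf = pmf * (m - i) * (q - i) / ((i + 1) * (N - m - q + i + 1))
        total += pmf
    return total


def bh_step_up(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg adjusted values, written out longhand."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p_values[i] * n / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def rk4_association(t_grid, ka, kd, C, Rmax, h=0.01):
    """RK4 integration of dR/dt = ka*C*(Rmax - R) - kd*R from R(0) = 0.

    Returns R at each t in t_grid (t_grid must be sorted, start >= 0).
    """

    def f(r):
        return ka * C * (Rmax - r) - kd * r

    out = []
    t, r = 0.0, 0.0
    for target in t_grid:
        while t < target - 1e-12:
            step = min(h, target - t)
            k1 = f(r)
            k2 = f(r + step * k1 / 2)
            k3 = f(r + step * k2 / 2)
            k4 = f(r + step * k3)
            r += step * (k1 + 2 * k2 + 2 * k3 + k4) / 6
            t += step
        out.append(r)
    return out
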