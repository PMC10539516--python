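"""Independent brute-force evaluators used as test oracles.

Everything here is written in plain Python with exact rational arithmetic,
deliberately sharing no code with the package implementation.
"""

from fractions import Fraction
from itertools import product


def enumerate_count_configs(n_per_sex):
    """All (counts_m, counts_f) with per-sex called totals <= n_per_sex."""
    singles = [
        (a, b, c)
        for a, b, c in product(range(n_per_sex + 1), repeat=3)
        if a + b + c <= n_per_sex
    ]
    return [(cm, cf) for cm in singles for cf in singles]


def brute_force_hit(counts_m, counts_f, n_males, n_females, method, system):
    """Threshold evaluation of one detection method on exact fractions."""
    if system == "ZW":
        counts_m, counts_f = counts_f, counts_m
        n_males, n_females = n_females, n_males
    cm, cf = counts_m, counts_f
    nm, nf = sum(cm), sum(cf)
    if nm == 0 or nf == 0:
        return False
    if Fraction(nm, n_males) < Fraction(3, 5) or Fraction(nf, n_females) < Fraction(3, 5):
        return False

    het_m = Fraction(cm[1], nm)
    het_f = Fraction(cf[1], nf)
    if method == 2:
        return cf[1] == 0 and het_m >= Fraction(1, 2)

    # orientation: X allele = major allele among called female genotypes
    ref_f = 2 * cf[0] + cf[1]
    alt_f = cf[1] + 2 * cf[2]
    if ref_f > alt_f:
        orientations = [0]
    elif alt_f > ref_f:
        orientations = [2]
    else:
        orientations = [0, 2]

    for hx in orientations:
        hy = 2 - hx
        xf_f = Fraction(2 * cf[hx] + cf[1], 2 * nf)
        xf_m = Fraction(2 * cm[hx] + cm[1], 2 * nm)
        homx_f = Fraction(cf[hx], nf)
        homy_f = Fraction(cf[hy], nf)
        if method == 1:
            if (
                xf_f > Fraction(19, 20)
                and Fraction(2, 5) <= xf_m <= Fraction(3, 5)
            ):
                return True
        elif method == 4:
            if (
                het_m > Fraction(3, 4)
                and homx_f > Fraction(4, 5)
                and het_f < Fraction(1, 5)
                and homy_f < Fraction(1, 10)
            ):
                return True
        elif method == 5:
            if (
                het_m > Fraction(11, 20)
                and homx_f > Fraction(4, 5)
                and het_f < Fraction(1, 5)
                and cf[hy] == 0
            ):
                return True
        else:
            raise ValueError(method)
    return False


def bh_stepup(p_values):
    """Benjamini-Hochberg by the literal step-up definition."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    q = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p_values[i] * n / rank)
        q[i] = val
        prev = val
    return q
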