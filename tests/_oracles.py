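"""Independent reference implementations used only as test oracles.

These deliberately take different computational routes from the package:
the Fst oracle runs the ANOVA sums-of-squares over individual allele
copies (the textbook derivation of the variance components), and the
window oracle loops over positions in pure Python.
"""

from __future__ import annotations

import numpy as np


def wc_theta_anova(gts_f: list[int], gts_m: list[int]) -> float:
    """Weir-Cockerham per-site theta via the allele-copy ANOVA route.

    Genotypes are 0/1/2 copies of the alternate allele... here coded as
    hom_ref=0, het=1, hom_alt=2.  Each individual contributes two 0/1
    allele indicators; mean squares among populations (MSP), among
    individuals within populations (MSI) and within individuals (MSG) give
    the variance components a = (MSP - MSI) / (2 n_c), b = (MSI - MSG) / 2,
    c = MSG, and theta = a / (a + b + c).  NaN when monomorphic.
    """
    groups = [list(gts_f), list(gts_m)]
    r = len(groups)
    n = [len(g) for g in groups]
    n_tot = sum(n)
    # per-individual indicator pairs for the reference allele
    copies = {0: (1, 1), 1: (1, 0), 2: (0, 0)}
    p_i = []
    for g in groups:
        p_i.append(sum(sum(copies[x]) for x in g) / (2 * len(g)))
    pbar = sum(ni * pi for ni, pi in zip(n, p_i)) / n_tot
    nc = (n_tot - sum(ni ** 2 for ni in n) / n_tot) / (r - 1)

    msp = sum(2 * ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_i)) / (r - 1)
    ssi = ssg = 0.0
    for g, pi in zip(groups, p_i):
        for x in g:
            y = copies[x]
            pij = sum(y) / 2
            ssi += 2 * (pij - pi) ** 2
            ssg += sum((yk - pij) ** 2 for yk in y)
    msi = ssi / sum(ni - 1 for ni in n)
    msg = ssg / n_tot

    c = msg
    b = (msi - msg) / 2
    a = (msp - msi) / (2 * nc)
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return a / denom


def naive_window_table(depth_f: np.ndarray, depth_m: np.ndarray,
                       mask_f: np.ndarray, mask_m: np.ndarray,
                       window: int) -> list[dict]:
    """Pure-Python per-position window means, standardization and ratios
    for a single chromosome."""
    def cbar(depth, mask):
        vals = [d for d, m in zip(depth, mask) if not m]
        return sum(vals) / len(vals)

    cbar_f = cbar(depth_f, mask_f)
    cbar_m = cbar(depth_m, mask_m)
    rows = []
    length = len(depth_f)
    start = 0
    while start < length:
        end = min(start + window, length)
        def mean(depth, mask):
            vals = [int(d) for d, m in zip(depth[start:end], mask[start:end])
                    if not m]
            return sum(vals) / len(vals) if vals else float("nan")
        c_f = mean(depth_f, mask_f)
        c_m = mean(depth_m, mask_m)
        z_f = c_f / cbar_f
        z_m = c_m / cbar_m
        ratio = z_f / z_m if c_m and not np.isnan(c_m) else float("nan")
        rows.append({"start": start + 1, "end": end, "c_F": c_f, "c_M": c_m,
                     "z_F": z_f, "z_M": z_m, "ratio": ratio})
        start += window
    return rows


def enumerate_genotype_configs(n_f: int = 3, n_m: int = 3):
    """All (female genotypes, male genotypes) configurations over
    {hom_ref, het, hom_alt}."""
    import itertools
    for cfg in itertools.product([0, 1, 2], repeat=n_f + n_m):
        yield cfg[:n_f], cfg[n_f:]
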