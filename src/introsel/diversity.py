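"""Windowed diversity and differentiation statistics.

Implements missing-data-aware nucleotide diversity (pi), between-population
divergence (d_xy), two F_ST estimators (Hudson ratio-of-sums and
Weir-Cockerham theta), haplotype diversity with Nei's sampling variance, and
a label-permutation significance test.

All per-site quantities are computed from allele counts over *called*
alleles only, so missing genotypes reduce the local sample size rather than
biasing the estimate.  Window denominators for pi/d_xy are switchable
between window length (needs the window to be fully accessible/invariant
elsewhere) and genotyped-SNP counts (flagged as variant-only).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

from .io import GenotypeDataset
from .windows import WindowStat, iter_bp_windows

logger = logging.getLogger(__name__)

__all__ = [
    "nucleotide_diversity",
    "dxy",
    "fst_hudson",
    "fst_wc",
    "haplotype_diversity",
    "permutation_test",
    "site_pi",
    "hudson_site_components",
    "wc_site_components",
]


def _window_iter(ds: GenotypeDataset, windows):
    """Accept (size, step) tuples or explicit (chrom,start,end) triples."""
    if isinstance(windows, tuple) and len(windows) == 2 and all(
            isinstance(w, int) for w in windows):
        size, step = windows
        yield from iter_bp_windows(ds.chrom, ds.pos, size, step, ds.sequence_length)
    else:
        for chrom, start, end in windows:
            m = (ds.chrom == chrom) & (ds.pos >= start) & (ds.pos < end)
            yield str(chrom), int(start), int(end), np.flatnonzero(m)


def site_pi(ds: GenotypeDataset, pop: str, sample_idx=None) -> np.ndarray:
    """Per-site unbiased heterozygosity 2p(1-p) * n/(n-1) over called alleles.

    Equals the fraction of mismatching pairs among the n called alleles at
    the site; NaN where fewer than 2 alleles are called.
    """
    alt, n = ds.alt_counts(pop, sample_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(n, 1)
        pi = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1)
    pi[n < 2] = np.nan
    return pi


def nucleotide_diversity(ds: GenotypeDataset, pop: str, windows,
                         denominator: str = "length") -> list[WindowStat]:
    """Windowed nucleotide diversity pi for one population.

    ``denominator="length"`` divides the per-site heterozygosity sum by the
    window length in bp (treating non-SNP positions as invariant);
    ``denominator="sites"`` divides by the number of usable SNP sites in the
    window (flagged ``variant_only``).  Windows with no usable site are
    flagged ``no_data`` with value 0.
    """
    if pop not in ds.populations:
        raise ValueError(f"unknown population {pop!r}")
    if denominator not in ("length", "sites"):
        raise ValueError("denominator must be 'length' or 'sites'")
    pi = site_pi(ds, pop)
    out = []
    for chrom, start, end, idx in _window_iter(ds, windows):
        vals = pi[idx]
        ok = np.isfinite(vals)
        n_used = int(ok.sum())
        if n_used == 0:
            out.append(WindowStat(chrom, start, end, 0, "pi", 0.0,
                                  n_sites=0, flag="no_data"))
            continue
        total = float(vals[ok].sum())
        if denominator == "length":
            value, n_sites, flag = total / (end - start), end - start, ""
        else:
            value, n_sites, flag = total / n_used, n_used, "variant_only"
        out.append(WindowStat(chrom, start, end, n_used, "pi", value,
                              n_sites=n_sites, flag=flag))
    return out


def site_dxy(ds: GenotypeDataset, popA: str, popB: str):
    """Per-site (mismatch count, comparison count) between two populations.

    Mismatches are counted over all nA*nB between-population allele pairs.
    """
    aA, nA = ds.alt_counts(popA)
    aB, nB = ds.alt_counts(popB)
    mism = aA * (nB - aB) + (nA - aA) * aB
    comp = nA * nB
    return mism.astype(np.float64), comp.astype(np.float64)


def dxy(ds: GenotypeDataset, popA: str, popB: str, windows,
        denominator: str = "length") -> list[WindowStat]:
    """Windowed between-population divergence d_xy.

    ``denominator="length"``: sum of per-site mismatch *rates* divided by
    window length (non-SNP positions treated as invariant, contributing 0);
    ``denominator="sites"``: ratio of summed mismatch counts to summed valid
    comparison counts over the window's SNP sites (flagged ``variant_only``).
    Windows without a valid comparison are flagged.
    """
    mism, comp = site_dxy(ds, popA, popB)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(comp > 0, mism / np.maximum(comp, 1), np.nan)
    out = []
    for chrom, start, end, idx in _window_iter(ds, windows):
        ok = comp[idx] > 0
        n_used = int(ok.sum())
        if n_used == 0:
            out.append(WindowStat(chrom, start, end, 0, "dxy", 0.0,
                                  n_sites=0, flag="no_data"))
            continue
        if denominator == "length":
            value = float(rate[idx][ok].sum()) / (end - start)
            n_sites, flag = end - start, ""
        else:
            value = float(mism[idx][ok].sum() / comp[idx][ok].sum())
            n_sites, flag = n_used, "variant_only"
        out.append(WindowStat(chrom, start, end, n_used, "dxy", value,
                              n_sites=n_sites, flag=flag))
    return out


def hudson_site_components(aA, nA, aB, nB):
    """Per-site Hudson F_ST numerator and denominator from allele counts.

    numerator = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
    denominator = pA(1-pB) + pB(1-pA)

    Sites with fewer than 2 called alleles in either population get NaN and
    are excluded from window sums.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = aA / np.maximum(nA, 1)
        pB = aB / np.maximum(nB, 1)
        num = ((pA - pB) ** 2
               - pA * (1 - pA) / np.maximum(nA - 1, 1)
               - pB * (1 - pB) / np.maximum(nB - 1, 1))
        den = pA * (1 - pB) + pB * (1 - pA)
    bad = (nA < 2) | (nB < 2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def fst_hudson(ds: GenotypeDataset, popA: str, popB: str, windows) -> list[WindowStat]:
    """Windowed Hudson F_ST as a ratio of sums across usable sites.

    Negative window estimates are reported as-is (no clamping), so that
    averages over windows remain unbiased.
    """
    aA, nA = ds.alt_counts(popA)
    aB, nB = ds.alt_counts(popB)
    num, den = hudson_site_components(aA, nA, aB, nB)
    return _ratio_windows(ds, windows, num, den, "fst_hudson")


def wc_site_components(ds: GenotypeDataset, popA: str, popB: str,
                       idxA=None, idxB=None):
    """Weir-Cockerham (1984) per-site a and b+c components for two populations."""
    r = 2
    comps = []
    for pop, idx in ((popA, idxA), (popB, idxB)):
        if idx is None:
            idx = ds.populations[pop]
        sub = ds.gt[:, idx]
        called = sub != -1
        n_ind = called.sum(axis=1)                      # individuals with calls
        alt = np.where(called, sub, 0).sum(axis=1)
        het = np.where(called, sub == 1, False).sum(axis=1)
        comps.append((n_ind.astype(float), alt.astype(float), het.astype(float)))
    (n1, a1, h1), (n2, a2, h2) = comps
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = a1 / np.maximum(2 * n1, 1)
        p2 = a2 / np.maximum(2 * n2, 1)
        h1f = h1 / np.maximum(n1, 1)
        h2f = h2 / np.maximum(n2, 1)
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1f + n2 * h2f) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (n1 < 2) | (n2 < 2)
    a = np.where(bad, np.nan, a)
    abc = np.where(bad, np.nan, a + b + c)
    return a, abc


def fst_wc(ds: GenotypeDataset, popA: str, popB: str, windows) -> list[WindowStat]:
    """Windowed Weir-Cockerham theta, ratio of summed variance components."""
    a, abc = wc_site_components(ds, popA, popB)
    return _ratio_windows(ds, windows, a, abc, "fst_wc")


def _ratio_windows(ds, windows, num, den, name) -> list[WindowStat]:
    out = []
    for chrom, start, end, idx in _window_iter(ds, windows):
        ok = np.isfinite(num[idx]) & np.isfinite(den[idx])
        n_used = int(ok.sum())
        dsum = float(den[idx][ok].sum()) if n_used else 0.0
        if n_used == 0 or dsum == 0.0:
            out.append(WindowStat(chrom, start, end, n_used, name, np.nan,
                                  n_sites=n_used, flag="undefined"))
            continue
        out.append(WindowStat(chrom, start, end, n_used, name,
                              float(num[idx][ok].sum()) / dsum, n_sites=n_used))
    return out


def whole_locus_fst(ds: GenotypeDataset, popA: str, popB: str,
                    estimator: str = "wc", idxA=None, idxB=None) -> float:
    """Single F_ST value over all sites (ratio of sums), for permutation tests."""
    if estimator == "wc":
        num, den = wc_site_components(ds, popA, popB, idxA, idxB)
    elif estimator == "hudson":
        aA, nA = ds.alt_counts(popA, idxA)
        aB, nB = ds.alt_counts(popB, idxB)
        num, den = hudson_site_components(aA, nA, aB, nB)
    else:
        raise ValueError("estimator must be 'wc' or 'hudson'")
    ok = np.isfinite(num) & np.isfinite(den)
    dsum = den[ok].sum()
    return float(num[ok].sum() / dsum) if ok.any() and dsum != 0 else math.nan


def haplotype_diversity(multiplicities: Sequence[int]) -> tuple[float, float]:
    """Unbiased haplotype diversity h and its sampling standard deviation.

    h = n/(n-1) * (1 - sum p_i^2) over haplotype frequencies p_i = c_i/n.
    The standard deviation is Nei's (1987) large-sample variance:

        V(h) = 2/(n(n-1)) * ( 2(n-2) * (sum p^3 - (sum p^2)^2)
                              + sum p^2 - (sum p^2)^2 )

    Returns ``(h, sd)``.
    """
    c = np.asarray(multiplicities, dtype=float)
    if len(c) == 0 or (c < 1).any():
        raise ValueError("multiplicities must be positive integers")
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 sequences")
    p = c / n
    s2 = float((p ** 2).sum())
    s3 = float((p ** 3).sum())
    h = n / (n - 1) * (1 - s2)
    var = 2 / (n * (n - 1)) * (2 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2)
    return float(h), math.sqrt(max(var, 0.0))


def count_haplotypes(sequences: Sequence[str]) -> list[int]:
    """Multiplicity spectrum of a set of aligned sequences (exact identity)."""
    counts: dict[str, int] = {}
    for s in sequences:
        counts[s] = counts.get(s, 0) + 1
    return sorted(counts.values(), reverse=True)


def permutation_test(ds: GenotypeDataset, statistic, popA: str, popB: str,
                     n_perm: int = 1000, seed: int = 0,
                     alternative: str = "greater"):
    """Label-permutation p-value for a two-population statistic.

    ``statistic`` is either ``"fst_wc"``/``"fst_hudson"`` or a callable
    ``f(ds, popA, popB, idxA, idxB) -> float``.  Permutations shuffle the
    population labels over the pooled samples (sizes preserved); the p-value
    uses the add-one estimator p = (1 + #{perm >= obs}) / (n_perm + 1), so it
    is never exactly 0.  Returns ``(observed, p, flag)``; the result is
    flagged ``degenerate`` when the statistic is undefined on more than half
    of the permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if callable(statistic):
        fun = statistic
    elif statistic in ("fst_wc", "fst_hudson"):
        est = statistic.split("_")[1]
        def fun(d, pA, pB, iA, iB):
            return whole_locus_fst(d, pA, pB, estimator=est, idxA=iA, idxB=iB)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    idxA, idxB = ds.populations[popA], ds.populations[popB]
    obs = fun(ds, popA, popB, idxA, idxB)
    pool = np.concatenate([idxA, idxB])
    nA = len(idxA)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pool)
        null[i] = fun(ds, popA, popB, perm[:nA], perm[nA:])
    ok = np.isfinite(null)
    flag = "degenerate" if ok.sum() < n_perm / 2 else ""
    if alternative == "greater":
        exceed = int((null[ok] >= obs).sum())
    elif alternative == "less":
        exceed = int((null[ok] <= obs).sum())
    else:
        exceed = int((np.abs(null[ok]) >= abs(obs)).sum())
    p = (1 + exceed) / (int(ok.sum()) + 1)
    return obs, float(p), flag
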