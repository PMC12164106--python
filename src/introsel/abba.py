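"""Four-taxon introgression statistics on derived-allele frequencies.

Implements Patterson's D with block-jackknife significance, the f4-ratio
admixture-fraction estimator with a split donor population, the windowed
f_dM statistic (50-SNP windows, 25-SNP step by default), and the rules that
turn f_dM windows plus a genome-wide D into called introgressed regions.

For the trio (P1, P2; P3) with outgroup O and per-site derived frequencies
p1, p2, p3, pO:

    D = sum (p2-p1)(p3-pO) / sum (p2+p1-2 p1 p2)(p3+pO-2 p3 pO)

D > 0 indicates an excess of P2-P3 derived-allele sharing (ABBA) over P1-P3
sharing (BABA).  f_dM bounds the per-window introgressed fraction in
[-1, 1], positive for P2-P3 sharing and negative for P1-P3 sharing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .io import AlleleFrequencyTable, GenotypeDataset, polarize, split_donor
from .regions import RegionSet
from .windows import WindowStat, iter_snp_windows

logger = logging.getLogger(__name__)

__all__ = [
    "TrioSpec",
    "DStatResult",
    "d_statistic",
    "jackknife",
    "f4_ratio",
    "fdm_windows",
    "call_introgressed_windows",
]


@dataclass(frozen=True)
class TrioSpec:
    """Populations of the four-taxon arrangement (((P1, P2), P3), O)."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self):
        names = [self.p1, self.p2, self.p3, self.outgroup]
        if len(set(names)) != 4:
            raise ValueError(f"trio populations must be distinct: {names}")

    @property
    def pops(self) -> tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.outgroup)


@dataclass
class DStatResult:
    """Genome-wide D with block-jackknife uncertainty (and optional f4-ratio)."""

    d: float
    se: float
    z: float
    p: float
    n_sites: int
    n_blocks: int
    f4_ratio: Optional[float] = None
    flag: str = ""


def _terms(freqs: AlleleFrequencyTable, trio: TrioSpec):
    mask = freqs.informative_mask(trio.pops)
    m = freqs.matrix(trio.pops, mask)
    p1, p2, p3, po = m.T
    num = (p2 - p1) * (p3 - po)
    den = (p2 + p1 - 2 * p1 * p2) * (p3 + po - 2 * p3 * po)
    # sites with a zero denominator term contribute 0 to both sums
    num = np.where(den == 0, 0.0, num)
    return num, den, mask


def d_statistic(freqs: AlleleFrequencyTable, trio: TrioSpec) -> float:
    """Genome-wide Patterson's D over all informative polarized sites."""
    num, den, _ = _terms(freqs, trio)
    dsum = den.sum()
    if len(num) == 0 or dsum == 0:
        return np.nan
    return float(num.sum() / dsum)


def jackknife(freqs: AlleleFrequencyTable, trio: TrioSpec, n_blocks: int = 20,
              alternative: str = "two-sided") -> DStatResult:
    """Block-jackknife standard error and Z-test for Patterson's D.

    The informative sites (genome-ordered) are partitioned into ``n_blocks``
    contiguous blocks of (near-)equal site counts; delete-one-block
    estimates give the jackknife SE and Z = D/SE.  The p-value uses a
    Student-t reference with g-1 degrees of freedom (g = usable blocks),
    which calibrates the test at the small block counts typical here — a
    normal reference is visibly anti-conservative at 20 blocks (two-sided
    by default; ``alternative="greater"`` for the one-sided excess-ABBA
    test).  Blocks without usable sites are dropped and logged.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    num, den, _ = _terms(freqs, trio)
    n = len(num)
    if n == 0 or den.sum() == 0:
        return DStatResult(np.nan, np.nan, np.nan, np.nan, 0, 0, flag="undefined")
    d = float(num.sum() / den.sum())
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    bnum = np.add.reduceat(num, edges[:-1])
    bden = np.add.reduceat(den, edges[:-1])
    keep = bden != 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d jackknife blocks with no informative sites", dropped)
    bnum, bden = bnum[keep], bden[keep]
    g = len(bnum)
    if g < 2:
        return DStatResult(d, np.nan, np.nan, np.nan, n, g, flag="too_few_blocks")
    loo = (num.sum() - bnum) / (den.sum() - bden)
    se = float(np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum()))
    if se == 0:
        return DStatResult(d, 0.0, np.nan, np.nan, n, g, flag="zero_variance")
    z = d / se
    if alternative == "greater":
        p = float(sps.t.sf(z, df=g - 1))
    else:
        p = float(2 * sps.t.sf(abs(z), df=g - 1))
    return DStatResult(d, se, z, p, n, g)


def f4_ratio(freqs: AlleleFrequencyTable, trio: TrioSpec,
             split: tuple[str, str] = ("P3a", "P3b"),
             form: str = "printed") -> float:
    """f4-ratio admixture-fraction estimate with a split donor population.

    ``split`` names the two donor subsets carried in ``freqs.split_freq``
    (built by passing the :func:`introsel.io.split_donor` bipartition to
    :func:`introsel.io.polarize` as ``extra_groups``).

    ``form="printed"`` evaluates

        sum (p3a - pO)(p2 - p1) / sum (p3a - pO)(p3b - p1),

    the formulation this pipeline standardises on; ``form="f4"`` evaluates
    the same quantity written as explicit four-population statistics,
    f4(P1,P2;P3a,O) / f4(P1,P3b;P3a,O) — the two agree term-by-term (each
    is the other with numerator and denominator negated), so the flag is a
    cross-check, not a correction.  Returns NaN (with a log note) on a zero
    denominator.
    """
    a, b = split
    pops = [trio.p1, trio.p2, trio.outgroup]
    mask = freqs.informative_mask(pops + [a, b])
    p1, p2, po = freqs.matrix(pops, mask).T
    p3a = freqs._get(a)[mask]
    p3b = freqs._get(b)[mask]
    if form == "printed":
        num = ((p3a - po) * (p2 - p1)).sum()
        den = ((p3a - po) * (p3b - p1)).sum()
    elif form == "f4":
        num = ((p1 - p2) * (p3a - po)).sum()
        den = ((p1 - p3b) * (p3a - po)).sum()
    else:
        raise ValueError("form must be 'printed' or 'f4'")
    if den == 0:
        logger.warning("f4-ratio denominator is zero; returning NaN")
        return np.nan
    return float(num / den)


def d_and_f4(ds: GenotypeDataset, trio: TrioSpec, n_blocks: int = 20,
             seed: int = 0, alternative: str = "two-sided") -> DStatResult:
    """Convenience: polarize, split the donor, and compute D + jackknife + f4-ratio."""
    ia, ib = split_donor(ds, trio.p3, seed)
    freqs = polarize(ds, trio.outgroup, extra_groups={"P3a": ia, "P3b": ib})
    res = jackknife(freqs, trio, n_blocks=n_blocks, alternative=alternative)
    res.f4_ratio = f4_ratio(freqs, trio)
    return res


def _fdm_site_terms(p1, p2, p3, po):
    """Per-site f_dM numerator and dynamic-donor denominator terms."""
    s_num = (1 - p1) * p2 * p3 * (1 - po) - p1 * (1 - p2) * p3 * (1 - po)
    pos = p2 >= p1  # site supports P2-P3 sharing
    pd_pos = np.maximum(p2, p3)
    den_pos = (1 - p1) * pd_pos * pd_pos * (1 - po) - p1 * (1 - pd_pos) * pd_pos * (1 - po)
    pd_neg = np.maximum(p1, p3)
    den_neg = -((1 - pd_neg) * p2 * pd_neg * (1 - po) - pd_neg * (1 - p2) * pd_neg * (1 - po))
    return s_num, np.where(pos, den_pos, den_neg)


def fdm_windows(freqs: AlleleFrequencyTable, trio: TrioSpec,
                window: int = 50, step: int = 25) -> list[WindowStat]:
    """Sliding-window f_dM over SNP-count windows of informative sites.

    Per window, f_dM = S(P1,P2,P3,O) / S(P1,Pd,Pd,O), where the dynamic
    donor Pd takes, per site, the larger of the two relevant derived-allele
    frequencies: the P2/P3 branch when derived alleles in P2 are at least as
    frequent as in P1 (positive, P2-P3 sharing), and the P1/P3 branch
    otherwise (negative, P1-P3 sharing).  Values are bounded in [-1, 1];
    windows with a zero denominator are flagged and excluded from ranking.
    """
    mask = freqs.informative_mask(trio.pops)
    m = freqs.matrix(trio.pops, mask)
    chrom = freqs.chrom[mask]
    pos = freqs.pos[mask]
    s_num, s_den = _fdm_site_terms(*m.T)
    out = []
    for c, idx in iter_snp_windows(chrom, window, step):
        dsum = s_den[idx].sum()
        start, end = int(pos[idx[0]]), int(pos[idx[-1]]) + 1
        if dsum == 0:
            out.append(WindowStat(c, start, end, len(idx), "fdm", np.nan,
                                  flag="undefined"))
            continue
        out.append(WindowStat(c, start, end, len(idx), "fdm",
                              float(s_num[idx].sum() / dsum)))
    return out


def call_introgressed_windows(stats: list[WindowStat], genome_wide_d: float,
                              mode: str = "quantile", alpha: float = 0.05,
                              quantile: float = 0.05) -> RegionSet:
    """Call introgressed regions from f_dM windows gated by genome-wide D.

    ``mode="ztest"``: Z-transform f_dM across windows and call windows with
    one-tailed (upper) p < ``alpha``; ``mode="quantile"``: call the top
    ``quantile`` fraction of windows by f_dM.  In both modes nothing is
    called unless the genome-wide D is positive; called windows are merged.
    """
    valid = [s for s in stats if s.flag == "" and np.isfinite(s.value)]
    if not np.isfinite(genome_wide_d) or genome_wide_d <= 0:
        return RegionSet()
    if mode == "ztest":
        vals = np.array([s.value for s in valid])
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        if sd == 0:
            logger.warning("f_dM windows have zero variance; nothing called")
            return RegionSet()
        z = (vals - vals.mean()) / sd
        called = [s for s, zi in zip(valid, z) if sps.norm.sf(zi) < alpha]
    elif mode == "quantile":
        if len(valid) < 20:
            raise ValueError(
                f"quantile calling needs >= 20 valid windows, got {len(valid)}")
        cut = np.quantile([s.value for s in valid], 1 - quantile)
        called = [s for s in valid if s.value > cut]
    else:
        raise ValueError("mode must be 'ztest' or 'quantile'")
    return RegionSet((s.chrom, s.start, s.end) for s in called)
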