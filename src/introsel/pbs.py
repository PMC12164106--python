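"""Population branch statistic (PBS) selection scan with permutation nulls.

PBS isolates allele-frequency change on a focal branch S against two
reference populations M and G:

    PBS = (T_SM + T_SG - T_MG) / 2,   T = -ln(1 - F_ST)

Window F_ST values are Hudson ratio-of-sums over SNP-count windows (50 SNPs
with a 25-SNP step by default); significance comes from a Monte-Carlo
permutation of individuals across the three populations (2000 cycles by
default), and selected regions are the top 1% of window PBS values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .diversity import hudson_site_components
from .io import GenotypeDataset
from .regions import RegionSet
from .windows import iter_snp_windows

logger = logging.getLogger(__name__)

__all__ = [
    "PBSResult",
    "pbs_from_fst",
    "pbs_scan",
    "pbs_permutation_p",
    "call_selected_regions",
]

_CAP = 1 - 1e-9


@dataclass
class PBSResult:
    """One PBS window: pairwise F_ST values, branch lengths, PBS, p-value."""

    chrom: str
    start: int
    end: int
    n_snps: int
    fst_sm: float
    fst_sg: float
    fst_mg: float
    pbs: float
    p: Optional[float] = None
    flag: str = ""


def _branch_length(fst: float) -> float:
    """T = -ln(1 - F_ST), with F_ST floored at 0 and capped below 1."""
    if not np.isfinite(fst):
        raise ValueError("non-finite F_ST")
    if fst < 0:
        fst = 0.0
    if fst >= 1:
        fst = _CAP
    return float(-np.log1p(-fst))


def pbs_from_fst(f_sm: float, f_sg: float, f_mg: float) -> float:
    """PBS of the focal branch from the three pairwise F_ST values.

    Negative F_ST estimates are floored at 0 and values >= 1 capped at
    1 - 1e-9 before the log (both logged); the natural log is used.
    """
    for f in (f_sm, f_sg, f_mg):
        if not np.isfinite(f):
            raise ValueError(f"non-finite F_ST input: {(f_sm, f_sg, f_mg)}")
    if min(f_sm, f_sg, f_mg) < 0 or max(f_sm, f_sg, f_mg) >= 1:
        logger.debug("F_ST outside [0,1) floored/capped: %s", (f_sm, f_sg, f_mg))
    return (_branch_length(f_sm) + _branch_length(f_sg) - _branch_length(f_mg)) / 2


def _window_pbs(counts, bounds):
    """Window PBS values from per-population (alt, n) count arrays.

    ``counts`` is {name: (alt, n)} for 'S', 'M', 'G'; ``bounds`` an
    (n_windows, 2) array of [start, end) indices into the site arrays
    (windows are contiguous site runs).  Returns (fst_sm, fst_sg, fst_mg,
    pbs) arrays with NaN where any pairwise F_ST is undefined.  Window sums
    use cumulative sums so overlapping windows cost O(sites + windows).
    """
    lo, hi = bounds[:, 0], bounds[:, 1]
    out = {}
    for key, (a, b) in {"sm": ("S", "M"), "sg": ("S", "G"), "mg": ("M", "G")}.items():
        num, den = hudson_site_components(counts[a][0], counts[a][1],
                                          counts[b][0], counts[b][1])
        ok = np.isfinite(num) & np.isfinite(den)
        cs_n = np.concatenate([[0.0], np.cumsum(np.where(ok, num, 0.0))])
        cs_d = np.concatenate([[0.0], np.cumsum(np.where(ok, den, 0.0))])
        wden = cs_d[hi] - cs_d[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[key] = np.where(wden != 0, (cs_n[hi] - cs_n[lo]) / np.where(wden != 0, wden, 1), np.nan)
    # raw (possibly negative) F_ST is kept: -log1p(-f) is well defined below 0,
    # and flooring would put a point mass at PBS = 0 that breaks permutation
    # calibration; only the upper end is capped below 1.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = {k: -np.log1p(-np.minimum(v, _CAP)) for k, v in out.items()}
    pbs = (t["sm"] + t["sg"] - t["mg"]) / 2
    return out["sm"], out["sg"], out["mg"], pbs


def pbs_scan(ds: GenotypeDataset, focal: str, ref1: str, ref2: str,
             window: int = 50, step: int = 25,
             polymorphic_only: bool = True) -> list[PBSResult]:
    """Sliding-window PBS scan for a focal population (or pooled group).

    Hudson F_ST is computed for the three population pairs as a ratio of
    sums within each SNP-count window; sites where any of the three
    populations has fewer than 2 called alleles are excluded so that all
    three pairwise estimates use the same sites, and (by default) so are
    sites monomorphic across the three populations jointly, which carry no
    information about their differentiation — windows then hold ``window``
    informative SNPs each.  Windows with an undefined pairwise F_ST are
    flagged and excluded from downstream quantiles.
    """
    counts = {"S": ds.alt_counts(focal), "M": ds.alt_counts(ref1),
              "G": ds.alt_counts(ref2)}
    usable = (counts["S"][1] >= 2) & (counts["M"][1] >= 2) & (counts["G"][1] >= 2)
    if polymorphic_only:
        tot_alt = sum(a for a, _ in counts.values())
        tot_n = sum(n for _, n in counts.values())
        usable &= (tot_alt > 0) & (tot_alt < tot_n)
    site_idx = np.flatnonzero(usable)
    sub = {k: (a[usable], n[usable]) for k, (a, n) in counts.items()}
    chrom = ds.chrom[usable]
    pos = ds.pos[usable]
    wins = list(iter_snp_windows(chrom, window, step))
    bounds = np.array([[idx[0], idx[-1] + 1] for _, idx in wins], dtype=np.int64)
    fsm, fsg, fmg, pbs = _window_pbs(sub, bounds)
    out = []
    for w, (c, idx) in enumerate(wins):
        start, end = int(pos[idx[0]]), int(pos[idx[-1]]) + 1
        flag = "" if np.isfinite(pbs[w]) else "undefined"
        out.append(PBSResult(c, start, end, len(idx), float(fsm[w]), float(fsg[w]),
                             float(fmg[w]), float(pbs[w]), flag=flag))
    # remember the usable-site mapping for permutations
    for r in out:
        r._site_index = site_idx  # type: ignore[attr-defined]
    return out


def pbs_permutation_p(ds: GenotypeDataset, results: list[PBSResult],
                      focal: str, ref1: str, ref2: str,
                      window: int = 50, step: int = 25,
                      n_cycles: int = 2000, seed: int = 0,
                      null: str = "global", batch: int = 50) -> list[PBSResult]:
    """Monte-Carlo permutation p-values for a PBS scan.

    Individuals are permuted jointly across the three populations (group
    sizes preserved) and window PBS recomputed each cycle.  With
    ``null="global"`` every window is compared against the pooled null over
    all windows and cycles; ``null="window"`` compares each window against
    its own null values only.  Empirical p-values use the add-one rule and
    are reproducible from ``seed``.
    """
    if n_cycles < 100:
        logger.warning("n_cycles=%d is low for a permutation null", n_cycles)
    idxS, idxM, idxG = (ds.populations[p] for p in (focal, ref1, ref2))
    pool = np.concatenate([idxS, idxM, idxG])
    nS, nM = len(idxS), len(idxM)
    rng = np.random.default_rng(seed)

    usable_sites = getattr(results[0], "_site_index", None)
    gt = ds.gt if usable_sites is None else ds.gt[usable_sites]
    chrom = ds.chrom if usable_sites is None else ds.chrom[usable_sites]
    bounds = np.array([[idx[0], idx[-1] + 1]
                       for _, idx in iter_snp_windows(chrom, window, step)],
                      dtype=np.int64)
    if len(bounds) != len(results):
        raise ValueError("scan results do not match the dataset/window spec")

    called = (gt != -1)
    g = np.where(called, gt, 0).astype(np.float64)
    called = called.astype(np.float64)

    obs = np.array([r.pbs for r in results])
    valid = np.isfinite(obs)
    null_all: list[np.ndarray] = []
    for lo in range(0, n_cycles, batch):
        nb = min(batch, n_cycles - lo)
        perms = np.stack([rng.permutation(pool) for _ in range(nb)])
        null_block = np.empty((nb, len(bounds)))
        for j in range(nb):
            part = {"S": perms[j, :nS], "M": perms[j, nS:nS + nM],
                    "G": perms[j, nS + nM:]}
            counts = {}
            for k, cols in part.items():
                counts[k] = (g[:, cols].sum(axis=1),
                             2 * called[:, cols].sum(axis=1))
            null_block[j] = _window_pbs(counts, bounds)[3]
        null_all.append(null_block)
    null_mat = np.concatenate(null_all, axis=0)  # (n_cycles, n_windows)

    out = []
    if null == "global":
        flat = null_mat[np.isfinite(null_mat)]
        n_null = len(flat)
        flat.sort()
        ge = n_null - np.searchsorted(flat, obs, side="left")
        for r, k, v in zip(results, ge, valid):
            p = (1 + int(k)) / (n_null + 1) if v and n_null else np.nan
            out.append(PBSResult(r.chrom, r.start, r.end, r.n_snps, r.fst_sm,
                                 r.fst_sg, r.fst_mg, r.pbs, p=p, flag=r.flag))
    elif null == "window":
        for w, r in enumerate(results):
            col = null_mat[:, w]
            col = col[np.isfinite(col)]
            p = ((1 + int((col >= obs[w]).sum())) / (len(col) + 1)
                 if valid[w] and len(col) else np.nan)
            out.append(PBSResult(r.chrom, r.start, r.end, r.n_snps, r.fst_sm,
                                 r.fst_sg, r.fst_mg, r.pbs, p=p, flag=r.flag))
    else:
        raise ValueError("null must be 'global' or 'window'")
    return out


def call_selected_regions(results: list[PBSResult], quantile: float = 0.01) -> RegionSet:
    """Merge the top-``quantile`` windows by PBS into selected regions.

    Requires at least 100 valid windows; refuses degenerate inputs where all
    PBS values are identical.  The call set depends only on PBS ranks, so it
    is invariant under any strictly monotone transform of the values.
    """
    valid = [r for r in results if r.flag == "" and np.isfinite(r.pbs)]
    if len(valid) < 100:
        raise ValueError(
            f"only {len(valid)} valid windows; the top-quantile call needs >= 100 "
            "(reduce the window/step or simulate a longer sequence)")
    vals = np.array([r.pbs for r in valid])
    if np.allclose(vals, vals[0]):
        raise ValueError("all PBS values identical; refusing degenerate quantile call")
    cut = np.quantile(vals, 1 - quantile)
    return RegionSet((r.chrom, r.start, r.end) for r in valid if r.pbs > cut)
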