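"""Window construction shared by the scan modules.

Two window schemes are used:

* SNP-count windows (e.g. 50 SNPs with a 25-SNP step) over the ordered sites
  of one chromosome — the scheme used for the f_dM and PBS scans;
* fixed base-pair windows (e.g. 2 Mb / 1 Mb step, or 20 kb / 2 kb step) —
  the scheme used for the diversity/differentiation scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd


@dataclass
class WindowStat:
    """One genomic window carrying a named statistic."""

    chrom: str
    start: int           # 0-based half-open
    end: int
    n_snps: int
    stat: str
    value: float
    n_sites: Optional[int] = None
    z: Optional[float] = None
    p: Optional[float] = None
    flag: str = ""


def stats_frame(stats: list[WindowStat]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_snps", "n_sites", "stat", "value", "z", "p", "flag"]
    return pd.DataFrame([[getattr(s, c) for c in cols] for s in stats], columns=cols)


def iter_snp_windows(chrom: np.ndarray, size: int, step: int) -> Iterator[tuple[str, np.ndarray]]:
    """Yield (chromosome, site-index array) for SNP-count windows.

    Windows are laid out per chromosome over the ordered site indices; a
    trailing window shorter than ``size`` is emitted only if no full window
    fits on that chromosome (so every chromosome yields at least one window).
    """
    if size < 1 or step < 1:
        raise ValueError("window size and step must be >= 1")
    chrom = np.asarray(chrom)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        n = len(idx)
        if n == 0:
            continue
        if n < size:
            yield str(c), idx
            continue
        for lo in range(0, n - size + 1, step):
            yield str(c), idx[lo:lo + size]


def iter_bp_windows(chrom: np.ndarray, pos: np.ndarray, size: int, step: int,
                    sequence_length: Optional[dict] = None
                    ) -> Iterator[tuple[str, int, int, np.ndarray]]:
    """Yield (chromosome, start, end, site-index array) for bp windows.

    Window grid starts at 0 and extends to the chromosome length when known
    (``sequence_length``), otherwise to the last SNP position.
    """
    if size < 1 or step < 1:
        raise ValueError("window size and step must be >= 1")
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    for c in pd.unique(chrom):
        m = chrom == c
        p = pos[m]
        idx = np.flatnonzero(m)
        L = int((sequence_length or {}).get(str(c), p.max() + 1 if len(p) else size))
        for start in range(0, max(L - size, 0) + step, step):
            end = min(start + size, L)
            if end <= start:
                break
            in_w = (p >= start) & (p < end)
            yield str(c), start, end, idx[in_w]
            if end >= L:
                break
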