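"""Five-taxon DFOIL site-pattern statistics and gene-flow direction inference.

Taxon order is (P1, P2, P3, P4, O) on the symmetric tree
(((P1,P2),(P3,P4)),O), with the P1-P2 split more recent than the P3-P4
split.  Sites are coded by which taxa carry the derived allele B (ancestral
A fixed by the outgroup); patterns with a derived outgroup are excluded.

Four D-like statistics (DFO, DIL, DFI, DOL) are each (L - R)/(L + R) over a
designated left/right group of eight site patterns, with a 1-df chi-squared
test on the (L, R) totals.  The resulting vector of significant signs
identifies both the taxa involved in gene flow and its direction.

The pattern groups are stored as data below so they are auditable; the
sign -> direction table is the standard five-taxon truth table (the P4 rows
follow from the P3 rows by the 3<->4 taxon-swap symmetry, which exchanges
DFI with DOL and negates DFO and DIL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import AlleleFrequencyTable

__all__ = [
    "PATTERN_GROUPS",
    "DIRECTION_TABLE",
    "SitePatternCounts",
    "DfoilResult",
    "count_patterns",
    "dfoil_statistics",
]

# Left/right site-pattern groups for each statistic.  A pattern string gives
# the derived(B)/ancestral(A) state of (P1, P2, P3, P4); the outgroup is A.
PATTERN_GROUPS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "DFO": (("BABAA", "BBBAA", "ABABA", "AAABA"),
            ("BAABA", "BBABA", "ABBAA", "AABAA")),
    "DIL": (("ABBAA", "BBBAA", "BAABA", "AAABA"),
            ("ABABA", "BBABA", "BABAA", "AABAA")),
    "DFI": (("BABAA", "BABBA", "ABABA", "ABAAA"),
            ("ABBAA", "ABBBA", "BAABA", "BAAAA")),
    "DOL": (("BAABA", "BABBA", "ABBAA", "ABAAA"),
            ("ABABA", "ABBBA", "BABAA", "BAAAA")),
}

# Sign vector (DFO, DIL, DFI, DOL) -> introgression class.  0 = not
# significant at the chi-squared test.
DIRECTION_TABLE: dict[tuple[int, int, int, int], str] = {
    (0, 0, 0, 0): "none",
    (1, 1, 0, 0): "P3<->P12 ancestral",
    (-1, -1, 0, 0): "P4<->P12 ancestral",
    (1, 1, 1, 0): "P1->P3",
    (1, 1, -1, 0): "P2->P3",
    (1, 0, 1, 1): "P3->P1",
    (0, 1, -1, -1): "P3->P2",
    (-1, -1, 0, 1): "P1->P4",
    (-1, -1, 0, -1): "P2->P4",
    (-1, 0, 1, 1): "P4->P1",
    (0, -1, -1, -1): "P4->P2",
}

@dataclass
class SitePatternCounts:
    """Weighted counts of the derived-allele presence patterns over 5 taxa.

    ``counts`` maps pattern strings like ``"BABAA"`` (order P1 P2 P3 P4 O) to
    summed weights; in binarized mode these are integer site counts, in
    frequency-weighted mode products of per-population derived/ancestral
    frequencies summed over sites.
    """

    counts: dict[str, float]
    n_sites: int
    n_skipped: int
    mode: str

    def __getitem__(self, pattern: str) -> float:
        return self.counts.get(pattern, 0.0)

    def scaled(self, k: float) -> "SitePatternCounts":
        return SitePatternCounts({p: v * k for p, v in self.counts.items()},
                                 self.n_sites, self.n_skipped, self.mode)


@dataclass
class DfoilResult:
    """The four DFOIL statistics, their chi-squared p-values, and a direction."""

    stats: dict[str, float]
    p_values: dict[str, float]
    totals: dict[str, tuple[float, float]]  # (L, R) per statistic
    signs: tuple[int, int, int, int]
    direction: str


def count_patterns(freqs: AlleleFrequencyTable,
                   taxa: tuple[str, str, str, str, str],
                   mode: str = "frequency",
                   threshold: float = 0.5) -> SitePatternCounts:
    """Accumulate five-taxon site-pattern weights from derived frequencies.

    ``taxa`` is (P1, P2, P3, P4, O); only sites where all five populations
    have called alleles are used (others are skipped and counted).

    ``mode="frequency"``: each pattern's weight at a site is the product of
    p (for B) or 1-p (for A) across the five populations — exactly the
    per-site contribution of frequency-weighted ABBA-BABA counting.
    ``mode="binarized"``: a population is scored B when its derived
    frequency is >= ``threshold``; the single matching pattern gains 1.
    The two modes agree whenever all frequencies are 0 or 1.
    """
    if len(set(taxa)) != 5:
        raise ValueError(f"need five distinct populations, got {taxa}")
    mask = freqs.informative_mask(taxa)
    m = freqs.matrix(taxa, mask)  # includes the outgroup column
    n_sites = m.shape[0]
    n_skipped = int((~mask).sum())
    counts: dict[str, float] = {}
    if mode == "frequency":
        for bits in np.ndindex(2, 2, 2, 2, 2):
            w = np.ones(n_sites)
            for j, b in enumerate(bits):
                w = w * (m[:, j] if b else (1 - m[:, j]))
            pat = "".join("AB"[b] for b in bits)
            counts[pat] = float(w.sum())
    elif mode == "binarized":
        b = (m >= threshold).astype(int)
        pats, c = np.unique(
            np.array(["".join("AB"[x] for x in row) for row in b]),
            return_counts=True)
        counts = {p: float(k) for p, k in zip(pats, c)}
    else:
        raise ValueError("mode must be 'frequency' or 'binarized'")
    return SitePatternCounts(counts, n_sites, n_skipped, mode)


def compatible_directions(signs: tuple[int, int, int, int]) -> list[str]:
    """Truth-table rows not contradicted by the observed significant signs.

    A row is compatible when every *significant* observed statistic matches
    it: same sign where the row is nonzero, and no significant sign where
    the row expects 0.  Non-significant observations are uninformative (a
    low-powered statistic cannot rule a row out), so a weak dataset may be
    compatible with several rows while a strong one pins down exactly one.
    """
    out = []
    for row, label in DIRECTION_TABLE.items():
        ok = all(s == 0 or (r != 0 and s == r) for s, r in zip(signs, row))
        if ok and label != "none":
            out.append(label)
    return out


def dfoil_statistics(counts: SitePatternCounts, alpha: float = 0.05) -> DfoilResult:
    """Compute DFO/DIL/DFI/DOL, chi-squared significance, and direction.

    Each statistic is (L - R)/(L + R) over its pattern groups; significance
    is a 1-df chi-squared test on the (L, R) totals.  The vector of
    significant signs is looked up in :data:`DIRECTION_TABLE`;
    a vector outside the table maps to ``"undetermined"``, and any
    statistic with L + R = 0 is undefined (NaN) and forces
    ``"undetermined"``.
    """
    stats, pvals, totals, signs = {}, {}, {}, []
    any_undefined = False
    for name, (left, right) in PATTERN_GROUPS.items():
        L = sum(counts[p] for p in left)
        R = sum(counts[p] for p in right)
        totals[name] = (L, R)
        if L + R == 0:
            stats[name] = np.nan
            pvals[name] = np.nan
            signs.append(0)
            any_undefined = True
            continue
        d = (L - R) / (L + R)
        chi2 = (L - R) ** 2 / (L + R)
        p = float(sps.chi2.sf(chi2, df=1))
        stats[name] = float(d)
        pvals[name] = p
        signs.append(0 if p >= alpha or d == 0 else (1 if d > 0 else -1))
    sign_vec = tuple(signs)
    if any_undefined:
        direction = "undetermined"
    else:
        direction = DIRECTION_TABLE.get(sign_vec, "undetermined")
    return DfoilResult(stats, pvals, totals, sign_vec, direction)
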