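"""Genomic interval algebra: merged region sets, multi-set intersection, annotation.

All coordinates are 0-based half-open internally.  BED files are read and
written natively in that convention; GFF3 (1-based closed) is converted on
read.  "Common" regions across several scans are computed at base-pair
resolution by coverage counting, so the input window grids need not align.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSet",
    "AnnotationHit",
    "read_bed",
    "write_bed",
    "read_gff3",
    "intersect_many",
    "selected_introgressed",
    "annotate",
]


class RegionSet:
    """A normalized (sorted, merged) set of genomic intervals.

    Parameters
    ----------
    records
        Iterable of ``(chrom, start, end)`` with 0-based half-open intervals.
        Overlapping or book-ended intervals on the same chromosome are merged
        during normalization.
    """

    def __init__(self, records: Iterable[tuple[str, int, int]] = ()):
        recs = [(str(c), int(s), int(e)) for c, s, e in records]
        for c, s, e in recs:
            if e <= s:
                raise ValueError(f"empty or inverted interval {c}:[{s},{e})")
        self._df = _merge(pd.DataFrame(recs, columns=["chrom", "start", "end"]))

    @classmethod
    def _from_merged(cls, df: pd.DataFrame) -> "RegionSet":
        out = cls.__new__(cls)
        out._df = df.reset_index(drop=True)
        return out

    @property
    def df(self) -> pd.DataFrame:
        """Normalized intervals as a DataFrame (chrom, start, end)."""
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        return iter(self._df.itertuples(index=False, name=None))

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.total_length} bp)"

    @property
    def total_length(self) -> int:
        return int((self._df["end"] - self._df["start"]).sum())

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(list(self) + list(other))

    def intersect(self, other: "RegionSet") -> "RegionSet":
        return intersect_many([self, other], min_support=2)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) on chrom overlaps any interval in the set."""
        sub = self._df[self._df["chrom"] == str(chrom)]
        return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def _merge(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"chrom": str, "start": np.int64, "end": np.int64}
        )
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out = []
    cur = None
    for chrom, start, end in df.itertuples(index=False, name=None):
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
        else:
            if cur is not None:
                out.append(tuple(cur))
            cur = [chrom, start, end]
    out.append(tuple(cur))
    return pd.DataFrame(out, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}
    )


def read_bed(path) -> RegionSet:
    """Read a BED3+ file into a RegionSet (extra columns ignored)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str},
    )
    return RegionSet(df.itertuples(index=False, name=None))


def write_bed(regions: RegionSet, path) -> None:
    """Write a RegionSet as sorted BED3."""
    regions.df.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3 features into a 0-based half-open feature table.

    Returns a DataFrame with columns chrom, start, end, feature_id, strand.
    Malformed lines are skipped with a logged count.  ``feature_id`` is taken
    from the ``ID=`` or ``Name=`` attribute, falling back to ``<type>:<row>``.
    """
    rows, bad = [], 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                bad += 1
                continue
            try:
                start, end = int(parts[3]) - 1, int(parts[4])
            except ValueError:
                bad += 1
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            fid = attrs.get("ID") or attrs.get("Name") or f"{parts[2]}:{i}"
            rows.append((parts[0], start, end, fid, parts[6]))
    if bad:
        logger.warning("skipped %d malformed GFF3 lines in %s", bad, path)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature_id", "strand"])


def read_features(path) -> pd.DataFrame:
    """Read a BED or GFF3 feature file into the annotation feature table.

    BED input may carry a name (column 4) and strand (column 6).
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return read_gff3(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    out = pd.DataFrame(
        {
            "chrom": df[0],
            "start": df[1].astype(np.int64),
            "end": df[2].astype(np.int64),
            "feature_id": df[3] if df.shape[1] > 3 else [f"feature:{i}" for i in range(len(df))],
            "strand": df[5] if df.shape[1] > 5 else ".",
        }
    )
    return out


def intersect_many(sets: Sequence[RegionSet], min_support: int = None) -> RegionSet:
    """Positions covered by at least ``min_support`` of the input sets.

    ``min_support=len(sets)`` gives the common region across all sets (the
    rule used to define shared introgression across recipient populations);
    ``min_support=1`` is the union.  Computed by a breakpoint sweep over
    per-set coverage, so results are base-pair exact regardless of the
    window grids the inputs came from.
    """
    if len(sets) == 0:
        raise ValueError("need at least one RegionSet")
    if min_support is None:
        min_support = len(sets)
    if not 1 <= min_support <= len(sets):
        raise ValueError(f"min_support must be in [1, {len(sets)}]")
    events: dict[str, list[tuple[int, int]]] = {}
    for rs in sets:
        for chrom, start, end in rs:
            events.setdefault(chrom, []).append((start, +1))
            events[chrom].append((end, -1))
    out: list[tuple[str, int, int]] = []
    for chrom, ev in events.items():
        ev.sort()
        cov = 0
        open_at = None
        for pos, delta in ev:
            prev = cov
            cov += delta
            if prev < min_support <= cov:
                open_at = pos
            elif prev >= min_support > cov:
                out.append((chrom, open_at, pos))
                open_at = None
    return RegionSet(out)


def selected_introgressed(introgressed: RegionSet, selected: RegionSet) -> RegionSet:
    """Intersection of introgression calls with selection calls.

    The result is the set of "selected introgressed regions": intervals
    supported by both the f_dM introgression scan and the top-quantile PBS
    selection scan.
    """
    return intersect_many([introgressed, selected], min_support=2)


@dataclass(frozen=True)
class AnnotationHit:
    """One region-to-feature relation.

    ``distance`` is 0 for overlaps; otherwise the signed gap in bp between
    region and feature (negative = feature ends before the region starts).
    """

    chrom: str
    start: int
    end: int
    feature_id: str
    relation: str  # "overlap" | "nearest"
    distance: int


def annotate(
    regions: RegionSet,
    features: pd.DataFrame,
    max_distance: int = 1_000_000,
) -> list[AnnotationHit]:
    """Annotate each region with overlapping features and its nearest feature.

    For every region, all overlapping features are reported with distance 0;
    if none overlap, the single nearest feature within ``max_distance`` bp is
    reported with a signed coordinate distance.  Ties are broken toward the
    feature with the smaller start coordinate.  Feature-file row order never
    affects the result.
    """
    feats = features.sort_values(["chrom", "start", "end", "feature_id"])
    hits: list[AnnotationHit] = []
    for chrom, start, end in regions:
        sub = feats[feats["chrom"] == chrom]
        if sub.empty:
            continue
        ov = sub[(sub["start"] < end) & (sub["end"] > start)]
        if len(ov):
            for f in ov.itertuples(index=False):
                hits.append(AnnotationHit(chrom, start, end, f.feature_id, "overlap", 0))
            continue
        # signed gap: negative when the feature lies left (upstream) of the region
        gap = np.where(
            sub["end"] <= start, sub["end"] - start, sub["start"] - end
        ).astype(np.int64)
        order = np.lexsort((sub["start"].to_numpy(), np.abs(gap)))
        best = order[0]
        if abs(int(gap[best])) <= max_distance:
            f = sub.iloc[best]
            hits.append(
                AnnotationHit(chrom, start, end, f["feature_id"], "nearest", int(gap[best]))
            )
    return hits


def annotation_table(hits: list[AnnotationHit]) -> pd.DataFrame:
    """AnnotationHit list as a TSV-ready DataFrame."""
    return pd.DataFrame([h.__dict__ for h in hits])
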