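"""Genotype I/O: VCF reading with site filters, population maps, polarization.

The internal model is a biallelic-SNP genotype matrix (sites x samples,
alt-allele dosage 0/1/2, -1 for missing) plus a population map.  Coordinates
are 0-based half-open internally; VCF is 1-based on disk and converted on
read/write.

Derived-allele polarization follows the outgroup-minor-allele rule: the
derived allele at a site is the allele at frequency < 0.5 in the outgroup;
sites where the outgroup is exactly 50/50, beyond a configurable
polymorphism threshold, or entirely missing are excluded from polarized
analyses (and counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "SiteFilterSpec",
    "PopulationMap",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "read_popmap",
    "read_vcf",
    "polarize",
    "split_donor",
    "pool_populations",
]


@dataclass(frozen=True)
class SiteFilterSpec:
    """Site-level filters applied on VCF read.

    ``max_missing`` keeps sites whose missing-call rate is strictly below the
    threshold; ``min_maf`` keeps sites whose minor-allele frequency (over
    called alleles in the mapped samples) is strictly above the threshold.
    Either may be None to disable (the unfiltered mode appropriate for
    ABBA-BABA statistics, where MAF filtering biases the site-pattern counts).
    """

    max_missing: Optional[float] = 0.1
    min_maf: Optional[float] = 0.05

    @classmethod
    def none(cls) -> "SiteFilterSpec":
        return cls(max_missing=None, min_maf=None)


class PopulationMap:
    """sample -> population assignment, with optional analysis role tags."""

    def __init__(self, samples: Sequence[str], populations: Sequence[str],
                 roles: Optional[Sequence[str]] = None):
        if len(set(samples)) != len(samples):
            dupes = pd.Series(samples)[pd.Series(samples).duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in population map: {dupes}")
        self.df = pd.DataFrame({
            "sample": list(samples),
            "population": list(populations),
            "role": list(roles) if roles is not None else [""] * len(samples),
        })

    @property
    def samples(self) -> list[str]:
        return self.df["sample"].tolist()

    def populations(self) -> dict[str, list[str]]:
        return {p: g["sample"].tolist() for p, g in self.df.groupby("population", sort=False)}

    def population_of(self, sample: str) -> str:
        row = self.df[self.df["sample"] == sample]
        if row.empty:
            raise KeyError(sample)
        return row["population"].iloc[0]


def read_popmap(path) -> PopulationMap:
    """Read a 2-3 column TSV: sample, population[, role]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    roles = df[2].fillna("") if df.shape[1] > 2 else None
    return PopulationMap(df[0], df[1], roles)


class GenotypeDataset:
    """Biallelic SNP calls for samples grouped into populations.

    Attributes
    ----------
    samples : list of sample ids
    chrom, pos : per-site chromosome id and 0-based position (positions
        strictly increasing within each chromosome)
    ref, alt : per-site alleles
    gt : (n_sites, n_samples) int8 alt-allele dosage, -1 = missing
    populations : population name -> array of sample column indices
    """

    def __init__(self, samples, chrom, pos, ref, alt, gt, populations,
                 sequence_length: Optional[dict] = None):
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.gt = np.asarray(gt, dtype=np.int8)
        self.populations = {k: np.asarray(v, dtype=np.intp) for k, v in populations.items()}
        self.sequence_length = sequence_length or {}
        self._validate()

    def _validate(self):
        n_sites, n_samples = self.gt.shape
        if n_samples != len(self.samples):
            raise ValueError("genotype matrix width != number of samples")
        if not (len(self.chrom) == len(self.pos) == n_sites):
            raise ValueError("site arrays inconsistent with genotype matrix")
        seen = np.zeros(n_samples, dtype=int)
        for name, idx in self.populations.items():
            seen[idx] += 1
        if (seen != 1).any():
            bad = [self.samples[i] for i in np.where(seen != 1)[0]]
            raise ValueError(f"samples not in exactly one population: {bad}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")
        if n_sites and (self.gt.max(axis=1) == MISSING).any():
            raise ValueError("site with all calls missing")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(self.samples, self.chrom.copy(), self.pos.copy(),
                               self.ref.copy(), self.alt.copy(), self.gt.copy(),
                               {k: v.copy() for k, v in self.populations.items()},
                               dict(self.sequence_length))

    def take_sites(self, mask_or_index) -> "GenotypeDataset":
        idx = np.asarray(mask_or_index)
        return GenotypeDataset(self.samples, self.chrom[idx], self.pos[idx],
                               self.ref[idx], self.alt[idx], self.gt[idx],
                               self.populations, dict(self.sequence_length))

    def alt_counts(self, pop: str, sample_idx=None):
        """(alt-allele count, called-allele count) per site for a population.

        ``sample_idx`` overrides the population's sample set (used for donor
        bipartitions and pooled groups).
        """
        if sample_idx is None:
            if pop not in self.populations:
                raise KeyError(f"unknown population {pop!r}")
            sample_idx = self.populations[pop]
        sub = self.gt[:, sample_idx]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)

    def alt_frequency(self, pop: str, sample_idx=None):
        """Per-site alt-allele frequency over called alleles (NaN if none)."""
        alt, n = self.alt_counts(pop, sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def to_vcf(self, path) -> None:
        """Write the dataset as an uncompressed VCF 4.2 text file."""
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c, L in self.sequence_length.items():
                fh.write(f"##contig=<ID={c},length={int(L)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            for i in range(self.n_sites):
                gts = "\t".join(code[int(g)] for g in self.gt[i])
                fh.write(f"{self.chrom[i]}\t{self.pos[i] + 1}\t.\t{self.ref[i]}\t"
                         f"{self.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")

    def write_popmap(self, path) -> None:
        rows = []
        for name, idx in self.populations.items():
            for i in idx:
                rows.append((self.samples[i], name))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_vcf(path, popmap: PopulationMap,
             filters: SiteFilterSpec = SiteFilterSpec()) -> GenotypeDataset:
    """Read a (plain or bgzipped) VCF into a filtered GenotypeDataset.

    Keeps biallelic SNPs passing the missing-rate and MAF thresholds in
    ``filters``; multiallelic sites and indels are skipped with a logged
    count.  Positions are converted to 0-based.  Samples are restricted to
    the population map; a popmap sample absent from the VCF is fatal.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = set(vcf.samples)
    unknown = [s for s in popmap.samples if s not in vcf_samples]
    if unknown:
        raise ValueError(f"popmap samples not present in VCF: {unknown}")
    if not popmap.samples:
        raise ValueError("empty intersection of popmap and VCF samples")
    vcf = VCF(str(path), gts012=True, samples=popmap.samples)
    order = vcf.samples  # cyvcf2 returns VCF order
    n = len(order)

    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_skipped = 0
    n_filtered = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        g = v.gt_types.astype(np.int8)  # 0=hom ref,1=het,2=hom alt,3=unknown
        g[g == 3] = MISSING
        called = g != MISSING
        n_called = int(called.sum())
        if n_called == 0:
            n_filtered += 1
            continue
        if filters.max_missing is not None and (n - n_called) / n >= filters.max_missing:
            n_filtered += 1
            continue
        if filters.min_maf is not None:
            ac = int(g[called].sum())
            an = 2 * n_called
            maf = min(ac, an - ac) / an
            if maf <= filters.min_maf:
                n_filtered += 1
                continue
        chrom.append(v.CHROM)
        pos.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(g)
    if n_skipped:
        logger.info("skipped %d multiallelic/indel sites", n_skipped)
    if n_filtered:
        logger.info("filtered %d sites (missing-rate/MAF thresholds)", n_filtered)

    pops = {}
    col = {s: i for i, s in enumerate(order)}
    for p, samps in popmap.populations().items():
        pops[p] = np.array([col[s] for s in samps], dtype=np.intp)
    gt = np.array(rows, dtype=np.int8) if rows else np.empty((0, n), dtype=np.int8)
    return GenotypeDataset(order, chrom, pos, ref, alt, gt, pops)


@dataclass
class AlleleFrequencyTable:
    """Per-site derived-allele frequencies for each population.

    Built by :func:`polarize`; carries only sites that could be polarized
    against the outgroup.  ``freq[pop]`` is NaN where the population has no
    called alleles; ``n_called[pop]`` counts called alleles.
    """

    chrom: np.ndarray
    pos: np.ndarray
    freq: dict[str, np.ndarray]
    n_called: dict[str, np.ndarray]
    derived_is_alt: np.ndarray
    outgroup: str
    n_excluded: int = 0
    split_freq: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @classmethod
    def from_frequencies(cls, rows, pops: Sequence[str] = ("P1", "P2", "P3", "O"),
                         pos=None, n_called: int = 10) -> "AlleleFrequencyTable":
        """Build a table directly from per-site derived-frequency rows.

        Convenient for worked examples and tests: ``rows`` is an
        (n_sites, len(pops)) array-like with the last column the outgroup.
        """
        a = np.asarray(rows, dtype=float)
        n = len(a)
        return cls(
            chrom=np.array(["1"] * n, dtype=object),
            pos=np.arange(n) if pos is None else np.asarray(pos),
            freq={p: a[:, j].copy() for j, p in enumerate(pops)},
            n_called={p: np.full(n, n_called) for p in pops},
            derived_is_alt=np.ones(n, dtype=bool),
            outgroup=pops[-1],
        )

    def informative_mask(self, pops: Sequence[str]) -> np.ndarray:
        """Sites where every listed population has at least one called allele."""
        m = np.ones(self.n_sites, dtype=bool)
        for p in pops:
            m &= np.isfinite(self._get(p))
        return m

    def _get(self, pop: str) -> np.ndarray:
        if pop in self.freq:
            return self.freq[pop]
        if pop in self.split_freq:
            return self.split_freq[pop]
        raise KeyError(f"unknown population {pop!r}")

    def matrix(self, pops: Sequence[str], mask=None) -> np.ndarray:
        """(n_sites, len(pops)) derived-frequency matrix, optionally masked."""
        cols = [self._get(p) for p in pops]
        m = np.column_stack(cols)
        return m if mask is None else m[mask]


def polarize(ds: GenotypeDataset, outgroup: str,
             max_outgroup_polymorphism: Optional[float] = None,
             extra_groups: Optional[dict[str, np.ndarray]] = None) -> AlleleFrequencyTable:
    """Polarize sites to derived-allele frequencies using an outgroup.

    The derived allele is the allele at minor frequency (< 0.5) in the
    outgroup.  Excluded (and counted in ``n_excluded``): sites with no
    called outgroup allele, an exact 50/50 outgroup, or outgroup minor
    frequency above ``max_outgroup_polymorphism`` when set.

    ``extra_groups`` maps extra group names (e.g. a donor bipartition from
    :func:`split_donor`) to sample index arrays; their derived frequencies
    are carried in ``split_freq``.
    """
    if outgroup not in ds.populations:
        raise ValueError(f"outgroup population {outgroup!r} not in dataset")
    og_f = ds.alt_frequency(outgroup)
    keep = np.isfinite(og_f) & (og_f != 0.5)
    if max_outgroup_polymorphism is not None:
        keep &= np.minimum(og_f, 1 - og_f) <= max_outgroup_polymorphism
    derived_is_alt = og_f < 0.5

    freq, n_called = {}, {}
    for p in ds.populations:
        f = ds.alt_frequency(p)
        freq[p] = np.where(derived_is_alt, f, 1 - f)[keep]
        n_called[p] = ds.alt_counts(p)[1][keep]
    split_freq = {}
    for name, idx in (extra_groups or {}).items():
        f = ds.alt_frequency(name, sample_idx=idx)
        split_freq[name] = np.where(derived_is_alt, f, 1 - f)[keep]
    return AlleleFrequencyTable(
        chrom=ds.chrom[keep], pos=ds.pos[keep], freq=freq, n_called=n_called,
        derived_is_alt=derived_is_alt[keep], outgroup=outgroup,
        n_excluded=int((~keep).sum()), split_freq=split_freq,
    )


def split_donor(ds: GenotypeDataset, donor: str, seed: int):
    """Random disjoint bipartition of the donor population's samples.

    Returns ``(idx_a, idx_b)`` sample-index arrays of sizes ceil(n/2) and
    floor(n/2), reproducible from ``seed``.  Used to form the P3a/P3b
    subpopulations of the f4-ratio.
    """
    if donor not in ds.populations:
        raise ValueError(f"unknown donor population {donor!r}")
    idx = ds.populations[donor]
    if len(idx) < 2:
        raise ValueError(
            f"donor {donor!r} has {len(idx)} sample(s); the f4-ratio needs at "
            "least 2 to form the P3a/P3b bipartition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(idx)
    half = (len(idx) + 1) // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def pool_populations(ds: GenotypeDataset, name: str, members: Sequence[str]) -> GenotypeDataset:
    """Return a dataset where ``members`` are merged into one population ``name``.

    Used for the PBS focal group, which pools the introgressed populations.
    """
    pops = {}
    pooled = []
    for p, idx in ds.populations.items():
        if p in members:
            pooled.append(idx)
        else:
            pops[p] = idx
    if not pooled:
        raise ValueError(f"no member populations found among {list(members)}")
    pops[name] = np.sort(np.concatenate(pooled))
    return GenotypeDataset(ds.samples, ds.chrom, ds.pos, ds.ref, ds.alt, ds.gt,
                           pops, dict(ds.sequence_length))
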