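"""Coalescent benchmark scenarios with known introgression and sweeps.

The default scenario emulates the wild/domestic sheep system the scan
pipeline is built for: an outgroup (bighorn-like), two wild subpopulations
(W1, W2 — the two Asiatic-mouflon lineages) splitting ~2,189 generations ago
(6,567 y at 3 y/generation), a domestic lineage splitting from the wild
lineage ~3,330 generations ago (9,991 y), a reference domestic population
(MEN) plus four candidate populations radiating ~1,000 generations ago, and
a single recent admixture pulse from W2 into a subset of the candidates.
Split times follow the published SMC++ estimates at 3 y/generation; N_e
values and the outgroup split are illustrative round numbers, not inferred
quantities.  Mutation rate defaults to 1e-8 per site per generation.

Ground truth: every sampled haplotype's donor-ancestry segments are
extracted exactly from the recorded migrations (tskit ``link_ancestors``),
so recovery tests can compare calls against known tracts.  An optional
"sweep" distorts in-interval derived-allele frequencies toward fixation in
one population, standing in for the selection signal a PBS scan detects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import GenotypeDataset
from .regions import RegionSet

__all__ = [
    "ScenarioParams",
    "TruthTract",
    "SweepSpec",
    "simulate",
    "inject_sweep",
    "make_haplotype_fixture",
    "truth_regions",
    "ancestry_fraction",
]

CHROM = "1"


@dataclass(frozen=True)
class ScenarioParams:
    """Demography, pulse, and sequence parameters for one simulated dataset.

    Times are in generations before present; sizes are diploid N_e.
    ``generation_time`` only converts generations to years in reports.
    """

    sequence_length: float = 10_000_000
    mutation_rate: float = 1e-8
    recombination_rate: float = 1e-8
    ne: float = 10_000
    ne_overrides: Optional[dict] = None     # per-population N_e, e.g. {"W2": 2000}
    n_diploid: int = 4                      # per population
    candidates: tuple[str, ...] = ("C1", "C2", "C3", "C4")
    reference: str = "MEN"
    wild: tuple[str, str] = ("W1", "W2")
    outgroup: str = "OUT"
    t_pulse: float = 500
    t_domestic_radiation: float = 1_000
    t_wild_split: float = 2_189             # W1/W2, 6,567.53 y / 3 y per gen
    t_wild_domestic_split: float = 3_330    # 9,991.41 y / 3 y per gen
    t_outgroup_split: float = 50_000        # illustrative, not inferred
    pulse_donor: str = "W2"
    pulse_recipients: tuple[str, ...] = ("C1", "C2")
    pulse_fraction: float = 0.2
    generation_time: float = 3.0
    seed: int = 1

    def validate(self) -> None:
        if not 0 <= self.pulse_fraction <= 1:
            raise ValueError("pulse fraction must be in [0, 1]")
        for r in (self.mutation_rate, self.recombination_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        order = (self.t_pulse, self.t_domestic_radiation, self.t_wild_split,
                 self.t_wild_domestic_split, self.t_outgroup_split)
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError(
                "event times must satisfy pulse < domestic radiation < wild "
                f"split < wild/domestic split < outgroup split, got {order}")
        if self.pulse_donor not in self.wild:
            raise ValueError(f"pulse donor {self.pulse_donor!r} must be a wild population")
        unknown = set(self.pulse_recipients) - set(self.candidates)
        if unknown and self.pulse_fraction > 0:
            raise ValueError(f"pulse recipients not among candidates: {sorted(unknown)}")

    @property
    def populations(self) -> tuple[str, ...]:
        return (self.outgroup, *self.wild, self.reference, *self.candidates)

    def years(self, generations: float) -> float:
        return generations * self.generation_time


@dataclass(frozen=True)
class TruthTract:
    """One donor-ancestry segment on one sampled haplotype of a recipient."""

    population: str
    chrom: str
    start: int          # 0-based half-open
    end: int
    haplotype: int      # tskit sample node id
    pulse_id: int = 0


@dataclass(frozen=True)
class SweepSpec:
    """Localized allele-frequency distortion emulating a selective sweep.

    ``strength`` in (0, 1] moves each in-interval site's derived-allele
    frequency in the target population the given fraction of the way to
    fixation; genotypes are resampled at the boosted frequency.
    """

    population: str
    chrom: str
    start: int
    end: int
    strength: float

    def __post_init__(self):
        if not 0 < self.strength <= 1:
            raise ValueError("sweep strength must be in (0, 1]")
        if self.end <= self.start:
            raise ValueError("empty sweep interval")


def _demography(params: ScenarioParams):
    import msprime

    dem = msprime.Demography()
    domestics = [params.reference, *params.candidates]
    overrides = params.ne_overrides or {}
    for name in (*params.populations, "DOM", "WILD", "ROOT", "ANC"):
        dem.add_population(name=name, initial_size=overrides.get(name, params.ne))
    dem.add_population_split(time=params.t_domestic_radiation,
                             derived=domestics, ancestral="DOM")
    dem.add_population_split(time=params.t_wild_split,
                             derived=list(params.wild), ancestral="WILD")
    dem.add_population_split(time=params.t_wild_domestic_split,
                             derived=["DOM", "WILD"], ancestral="ROOT")
    dem.add_population_split(time=params.t_outgroup_split,
                             derived=["ROOT", params.outgroup], ancestral="ANC")
    if params.pulse_fraction > 0:
        for rec in params.pulse_recipients:
            # backwards in time: recipient lineages jump into the donor
            dem.add_mass_migration(time=params.t_pulse, source=rec,
                                   dest=params.pulse_donor,
                                   proportion=params.pulse_fraction)
    dem.sort_events()
    return dem


def _truth_tracts(ts, params: ScenarioParams, pop_of_name: dict[str, int]
                  ) -> list[TruthTract]:
    donor_id = pop_of_name[params.pulse_donor]
    rec_ids = {pop_of_name[r]: r for r in params.pulse_recipients}
    mig = [m for m in ts.migrations()
           if m.dest == donor_id and m.source in rec_ids
           and math.isclose(m.time, params.t_pulse)]
    if not mig:
        return []
    # genome segments over which each sample descends from each migrant node
    samples_by_pop = {
        pid: [s for s in ts.samples() if ts.node(s).population == pid]
        for pid in rec_ids
    }
    all_rec_samples = sorted(s for ss in samples_by_pop.values() for s in ss)
    ancestors = sorted({m.node for m in mig} - set(all_rec_samples))
    descent: dict[int, list[tuple[int, float, float]]] = {}
    if ancestors:
        tab = ts.tables.link_ancestors(samples=all_rec_samples, ancestors=ancestors)
        for parent, child, left, right in zip(tab.parent, tab.child, tab.left, tab.right):
            descent.setdefault(int(parent), []).append((int(child), left, right))
    sample_pop = {s: rec_ids[ts.node(s).population] for s in all_rec_samples}

    def to_samples(node, lo, hi):
        """Resolve (node, interval) down to sample haplotypes; link_ancestors
        edges may chain through other migrant ancestors."""
        if node in sample_pop:
            yield node, lo, hi
            return
        for child, left, right in descent.get(node, ()):
            l, h = max(left, lo), min(right, hi)
            if h > l:
                yield from to_samples(child, l, h)

    segs: dict[tuple[str, int], list[tuple[float, float]]] = {}
    for m in mig:
        for hap, lo, hi in to_samples(m.node, m.left, m.right):
            segs.setdefault((sample_pop[hap], hap), []).append((lo, hi))
    out = []
    for (pop, hap), intervals in sorted(segs.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        intervals.sort()
        merged = [list(intervals[0])]
        for lo, hi in intervals[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            out.append(TruthTract(pop, CHROM, int(lo), int(math.ceil(hi)), hap))
    return out


def simulate(params: ScenarioParams) -> tuple[GenotypeDataset, list[TruthTract]]:
    """Simulate one dataset under the scenario and extract truth tracts.

    Returns a biallelic-SNP :class:`~introsel.io.GenotypeDataset` (one
    chromosome, ancestral allele as REF so ALT is the derived allele) and
    the per-haplotype donor-ancestry tracts in the pulse recipients.  Fully
    reproducible from ``params.seed``.
    """
    import msprime

    params.validate()
    dem = _demography(params)
    ts = msprime.sim_ancestry(
        {p: params.n_diploid for p in params.populations},
        demography=dem, sequence_length=params.sequence_length,
        recombination_rate=params.recombination_rate,
        record_migrations=params.pulse_fraction > 0,
        random_seed=params.seed,
    )
    ts = msprime.sim_mutations(ts, rate=params.mutation_rate,
                               random_seed=params.seed + 1)
    pop_of_name = {p.metadata["name"]: p.id for p in ts.populations()}

    samples, pops, cols = [], {}, []
    for ind in ts.individuals():
        pid = ts.node(ind.nodes[0]).population
        name = ts.population(pid).metadata["name"]
        label = f"{name}_{len([s for s in samples if s.startswith(name + '_')])}"
        pops.setdefault(name, []).append(len(samples))
        samples.append(label)
        cols.append(tuple(ind.nodes))

    keep_sites, pos, ref, alt, rows = [], [], [], [], []
    for v in ts.variants():
        if len(v.alleles) != 2:
            continue
        pos.append(int(v.site.position))
        ref.append(v.alleles[0])
        alt.append(v.alleles[1])
        g = v.genotypes
        rows.append([g[a] + g[b] for a, b in cols])
    gt = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    # discrete-genome mutations can stack at one position; keep the first
    pos = np.asarray(pos, dtype=np.int64)
    if len(pos):
        uniq = np.concatenate([[True], np.diff(pos) > 0])
        pos, gt = pos[uniq], gt[uniq]
        ref = [r for r, u in zip(ref, uniq) if u]
        alt = [a for a, u in zip(alt, uniq) if u]
    ds = GenotypeDataset(
        samples, np.full(len(pos), CHROM, dtype=object), pos, ref, alt, gt,
        {k: np.array(v) for k, v in pops.items()},
        sequence_length={CHROM: int(params.sequence_length)},
    )
    tracts = (_truth_tracts(ts, params, pop_of_name)
              if params.pulse_fraction > 0 else [])
    return ds, tracts


def truth_regions(tracts: Sequence[TruthTract],
                  population: Optional[str] = None) -> RegionSet:
    """Merged truth-tract regions, optionally for one recipient population."""
    return RegionSet((t.chrom, t.start, t.end) for t in tracts
                     if population is None or t.population == population)


def ancestry_fraction(tracts: Sequence[TruthTract], params: ScenarioParams,
                      population: str) -> float:
    """Mean donor-ancestry fraction per sampled haplotype of a recipient.

    The expectation of this quantity equals the pulse fraction f (the merged
    union across haplotypes is larger, approaching 1 - (1-f)^n).
    """
    total = sum(t.end - t.start for t in tracts if t.population == population)
    n_hap = 2 * params.n_diploid
    return total / (n_hap * params.sequence_length)


def inject_sweep(ds: GenotypeDataset, sweep: SweepSpec, seed: int) -> GenotypeDataset:
    """Return a copy with in-interval alt (derived) frequencies boosted.

    Inside the sweep interval, each site's alt frequency p in the target
    population becomes p + strength * (1 - p) and genotypes are resampled
    binomially at the new frequency (missing calls stay missing); strength 1
    fixes the derived allele.  Everything outside the interval is unchanged.
    """
    if sweep.population not in ds.populations:
        raise ValueError(f"unknown population {sweep.population!r}")
    L = ds.sequence_length.get(sweep.chrom)
    if L is not None and (sweep.start < 0 or sweep.end > L):
        raise ValueError(f"sweep interval outside simulated bounds [0, {L})")
    out = ds.copy()
    rng = np.random.default_rng(seed)
    idx = out.populations[sweep.population]
    in_w = np.flatnonzero((out.chrom == sweep.chrom)
                          & (out.pos >= sweep.start) & (out.pos < sweep.end))
    for i in in_w:
        row = out.gt[i, idx]
        called = row != -1
        if not called.any():
            continue
        p = row[called].sum() / (2 * called.sum())
        p_new = p + sweep.strength * (1 - p)
        draw = rng.binomial(2, p_new, size=called.sum()).astype(np.int8)
        row[called] = draw
        out.gt[i, idx] = row
    # resampling may leave a site with no alt copies anywhere; that is fine,
    # the site remains a biallelic record
    return out


def make_haplotype_fixture(multiplicities: Sequence[int], length: int,
                           seed: int = 0) -> list[str]:
    """Aligned sequences realizing a haplotype multiplicity spectrum.

    Returns ``sum(multiplicities)`` sequences of the given length over
    A/C/G/T in which two sequences are identical iff they belong to the
    same multiplicity class.  Distinctness is guaranteed by giving class k
    a unique base at alignment column k.
    """
    mult = list(multiplicities)
    if not mult or any(m < 1 for m in mult):
        raise ValueError("multiplicities must be a non-empty list of positive ints")
    if length < len(mult):
        raise ValueError("length must be >= number of distinct haplotypes")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    backbone = rng.integers(0, 4, size=length)
    seqs = []
    for k, m in enumerate(mult):
        hap = backbone.copy()
        hap[k] = (backbone[k] + 1 + k % 3) % 4
        seqs.extend(["".join(bases[hap])] * m)
    return seqs


def write_fasta(sequences: Sequence[str], path, prefix: str = "hap") -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sequences):
            fh.write(f">{prefix}{i}\n{s}\n")
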