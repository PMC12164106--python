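"""End-to-end orchestration: simulate/load -> D & f4 -> f_dM -> DFOIL -> PBS -> regions.

A candidate population is flagged "introgressed" iff all three hold:
genome-wide D > 0, f4-ratio > 0, and block-jackknife p < alpha.  Introgressed
regions are called per flagged candidate from the f_dM scan (top-quantile
windows gated by D > 0), their base-pair intersection across all flagged
candidates is the "common introgressed region", the PBS scan on the pooled
flagged candidates yields selected regions, and the intersection of the two
is the set of selected introgressed regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .abba import TrioSpec, call_introgressed_windows, d_and_f4, fdm_windows
from .dfoil import count_patterns, dfoil_statistics
from .io import (SiteFilterSpec, pool_populations, polarize, read_popmap,
                 read_vcf)
from .pbs import call_selected_regions, pbs_permutation_p, pbs_scan
from .regions import (RegionSet, annotate, annotation_table, intersect_many,
                      read_features, selected_introgressed, write_bed)
from .simulate import ScenarioParams, simulate, truth_regions
from .windows import stats_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, presets, and thresholds for one full scan.

    Exactly one of ``scenario`` (simulate) or ``vcf``+``popmap`` (load) must
    be set.  Population roles: ``p1`` is the non-introgressed reference,
    ``candidates`` the target (P2) populations, ``donor`` the wild donor
    (P3), ``donor_sister`` its sister lineage (P4 of the DFOIL arrangement
    and second PBS reference), ``outgroup`` the outgroup.
    """

    scenario: Optional[ScenarioParams] = None
    vcf: Optional[str] = None
    popmap: Optional[str] = None
    features: Optional[str] = None

    p1: str = "MEN"
    candidates: tuple[str, ...] = ("C1", "C2", "C3", "C4")
    donor: str = "W2"
    donor_sister: str = "W1"
    outgroup: str = "OUT"

    filters: SiteFilterSpec = field(default_factory=SiteFilterSpec.none)
    fdm_window: int = 50
    fdm_step: int = 25
    fdm_quantile: float = 0.05
    fdm_mode: str = "quantile"
    pbs_window: int = 50
    pbs_step: int = 25
    pbs_quantile: float = 0.01
    pbs_permutations: int = 2000
    n_blocks: int = 20
    alpha: float = 0.05
    bh_correction: bool = False
    max_annotation_distance: int = 1_000_000
    run_dfoil: bool = True
    run_pbs: bool = True
    seed: int = 1
    outdir: Optional[str] = None

    def validate(self) -> None:
        if (self.scenario is None) == (self.vcf is None):
            raise ValueError("set exactly one of scenario or vcf/popmap")
        for q in (self.fdm_quantile, self.pbs_quantile, self.alpha):
            if not 0 < q < 1:
                raise ValueError("thresholds must be in (0, 1)")


@dataclass
class PipelineResult:
    """Per-candidate statistics, called regions, and the run manifest."""

    dstats: pd.DataFrame                 # one row per candidate
    flagged: list[str]
    introgressed: dict[str, RegionSet]   # per flagged candidate
    common_introgressed: RegionSet
    dfoil: Optional[object] = None
    pbs: Optional[list] = None
    selected: Optional[RegionSet] = None
    selected_introgressed: Optional[RegionSet] = None
    annotation: Optional[pd.DataFrame] = None
    truth: Optional[RegionSet] = None
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def load_dataset(cfg: PipelineConfig):
    if cfg.scenario is not None:
        ds, tracts = simulate(cfg.scenario)
        return ds, truth_regions(tracts)
    ds = read_vcf(cfg.vcf, read_popmap(cfg.popmap), cfg.filters)
    return ds, None


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full scan; see the module docstring for the stage logic.

    With ``cfg.outdir`` set, per-stage TSV/BED outputs and a
    ``MANIFEST.json`` (version, seed, thresholds, per-stage counts) are
    written there; reruns with identical config and seed are byte-identical.
    """
    cfg.validate()
    ds, truth = _stage("load")(load_dataset)(cfg)

    rows, per_cand = [], {}
    for cand in cfg.candidates:
        trio = TrioSpec(cfg.p1, cand, cfg.donor, cfg.outgroup)
        res = _stage("dstat")(d_and_f4)(ds, trio, n_blocks=cfg.n_blocks,
                                        seed=cfg.seed)
        per_cand[cand] = res
        rows.append({"candidate": cand, "D": res.d, "se": res.se, "z": res.z,
                     "p": res.p, "f4_ratio": res.f4_ratio,
                     "n_sites": res.n_sites, "n_blocks": res.n_blocks})
    dstats = pd.DataFrame(rows)
    pcol = dstats["p"].to_numpy(dtype=float)
    if cfg.bh_correction:
        ok = np.isfinite(pcol)
        adj = pcol.copy()
        adj[ok] = sps.false_discovery_control(pcol[ok])
        dstats["p_adj"] = adj
        pcol = adj
    flagged = [c for c, p, r in zip(dstats["candidate"], pcol, rows)
               if np.isfinite(p) and p < cfg.alpha and r["D"] > 0
               and np.isfinite(r["f4_ratio"]) and r["f4_ratio"] > 0]
    dstats["introgressed"] = dstats["candidate"].isin(flagged)

    freqs = _stage("polarize")(polarize)(ds, cfg.outgroup)
    intro: dict[str, RegionSet] = {}
    fdm_frames = {}
    for cand in flagged:
        trio = TrioSpec(cfg.p1, cand, cfg.donor, cfg.outgroup)
        stats = _stage("fdm")(fdm_windows)(freqs, trio, cfg.fdm_window, cfg.fdm_step)
        fdm_frames[cand] = stats_frame(stats)
        intro[cand] = call_introgressed_windows(
            stats, per_cand[cand].d, mode=cfg.fdm_mode, alpha=cfg.alpha,
            quantile=cfg.fdm_quantile)
    common = (intersect_many(list(intro.values()), min_support=len(intro))
              if intro else RegionSet())

    result = PipelineResult(dstats=dstats, flagged=flagged, introgressed=intro,
                            common_introgressed=common, truth=truth)

    group = flagged if flagged else list(cfg.candidates)
    pooled = _stage("pool")(pool_populations)(ds, "__focal__", group)

    if cfg.run_dfoil:
        pooled_freqs = polarize(pooled, cfg.outgroup)
        taxa = ("__focal__", cfg.p1, cfg.donor, cfg.donor_sister, cfg.outgroup)
        counts = _stage("dfoil")(count_patterns)(pooled_freqs, taxa)
        result.dfoil = dfoil_statistics(counts, alpha=cfg.alpha)

    if cfg.run_pbs:
        scan = _stage("pbs")(pbs_scan)(pooled, "__focal__", cfg.p1,
                                       cfg.donor_sister, cfg.pbs_window,
                                       cfg.pbs_step)
        scan = _stage("pbs_perm")(pbs_permutation_p)(
            pooled, scan, "__focal__", cfg.p1, cfg.donor_sister,
            cfg.pbs_window, cfg.pbs_step, n_cycles=cfg.pbs_permutations,
            seed=cfg.seed)
        result.pbs = scan
        result.selected = call_selected_regions(scan, cfg.pbs_quantile)
        result.selected_introgressed = selected_introgressed(
            common, result.selected)

    if cfg.features and result.selected_introgressed is not None:
        feats = read_features(cfg.features)
        hits = _stage("annotate")(annotate)(result.selected_introgressed, feats,
                                            cfg.max_annotation_distance)
        result.annotation = annotation_table(hits)

    result.manifest = _manifest(cfg, result)
    if cfg.outdir:
        _write_outputs(cfg, result, fdm_frames)
    return result


def _manifest(cfg: PipelineConfig, res: PipelineResult) -> dict:
    m = {
        "introsel_version": __version__,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "fdm": {"window": cfg.fdm_window, "step": cfg.fdm_step,
                "mode": cfg.fdm_mode, "quantile": cfg.fdm_quantile},
        "pbs": {"window": cfg.pbs_window, "step": cfg.pbs_step,
                "quantile": cfg.pbs_quantile, "permutations": cfg.pbs_permutations},
        "n_blocks": cfg.n_blocks,
        "flagged": res.flagged,
        "common_introgressed_bp": res.common_introgressed.total_length,
    }
    if cfg.scenario is not None:
        m["scenario"] = asdict(cfg.scenario)
    if res.selected is not None:
        m["selected_bp"] = res.selected.total_length
        m["selected_introgressed_bp"] = res.selected_introgressed.total_length
    if res.dfoil is not None:
        m["dfoil"] = {"stats": res.dfoil.stats, "p": res.dfoil.p_values,
                      "direction": res.dfoil.direction}
    return m


def _write_outputs(cfg, res, fdm_frames):
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    res.dstats.to_csv(out / "dstats.tsv", sep="\t", index=False)
    for cand, frame in fdm_frames.items():
        frame.to_csv(out / f"fdm_{cand}.tsv", sep="\t", index=False)
    for cand, rs in res.introgressed.items():
        write_bed(rs, out / f"introgressed_{cand}.bed")
    write_bed(res.common_introgressed, out / "common_introgressed.bed")
    if res.pbs is not None:
        pd.DataFrame([r.__dict__ for r in res.pbs]).drop(
            columns=["_site_index"], errors="ignore").to_csv(
            out / "pbs.tsv", sep="\t", index=False)
        write_bed(res.selected, out / "selected.bed")
        write_bed(res.selected_introgressed, out / "selected_introgressed.bed")
    if res.annotation is not None:
        res.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    if res.truth is not None:
        write_bed(res.truth, out / "truth_tracts.bed")
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True, default=str)
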