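"""End-to-end orchestration of the analysis stages on synthetic cohorts.

Every stage is also callable on its own through the library API; this
module only sequences them (simulate -> paint -> segments -> date ->
selection scans -> intersect) and writes the text artifacts. Identical
seeds produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import ancestry, dating, haplostats, popstats, synthpop

log = logging.getLogger("admixscan")


@dataclass
class RunConfig:
    """Parameters of one synthetic end-to-end run.

    ``sim`` holds the SimConfig fields; stage parameters mirror the
    library defaults and are validated up front.
    """

    sim: dict = field(default_factory=dict)
    lambda_grid: tuple = ancestry.DEFAULT_LAMBDA_GRID
    f_min: float = 0.75
    len_min: int = 1000
    alpha: float = 0.01
    top_q: float = 0.01
    min_methods: int = 2
    win_fst: int = 50_000
    step_fst: int = 20_000
    win_scan: int = 50_000
    seed: int = 0
    outdir: str = "admixscan_out"

    def sim_config(self) -> synthpop.SimConfig:
        kw = dict(self.sim)
        kw.setdefault("seed", self.seed)
        return synthpop.SimConfig(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not (0 < cfg.top_q <= 0.5):
            raise ValueError("top_q must be in (0, 0.5]")
        if not (0 <= cfg.f_min <= 1):
            raise ValueError("f_min must be in [0, 1]")
        cfg.sim_config()  # validates the simulation block
        return cfg


DEMO_SIM = dict(K=4, F=0.2, n_ref=16, n_adm=10, L_bp=10_000_000,
                n_sites=4_000, cM_per_Mb=1.0, g=30.0, eps=0.001, n_chrom=2)


def demo_config(outdir, seed=0) -> RunConfig:
    """Desk-scale configuration used by the `demo` subcommand."""
    return RunConfig(sim=DEMO_SIM, seed=seed, outdir=str(outdir))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full synthetic pipeline; returns the summary dict."""
    os.makedirs(cfg.outdir, exist_ok=True)
    summary = {"seed": cfg.seed, "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        return _StageTimer(name, summary)

    scfg = cfg.sim_config()
    with stage("simulate"):
        panels = synthpop.make_panels(scfg)
        truth = synthpop.simulate_cohort(scfg, panels)
        truth.write(os.path.join(cfg.outdir, "sim"))

    with stage("paint"):
        paintings, positions, lengths = [], [], []
        for ci, pc in enumerate(panels.chroms):
            refs = np.concatenate([pc.haps[k] for k in range(scfg.K)], axis=0)
            labels = np.repeat(np.arange(scfg.K), scfg.n_ref)
            codes = ancestry.paint_cohort(truth.target_haps[ci], refs,
                                          labels, cfg.lambda_grid)
            paintings.append(codes)
            positions.append(pc.pos_bp)
            lengths.append(scfg.L_bp)
        props = ancestry.global_proportions(paintings, positions, lengths,
                                            K=scfg.K)
        _write_tracts_bed(os.path.join(cfg.outdir, "tracts.bed"),
                          panels, paintings, positions, lengths)
    summary["global_proportions"] = [round(float(p), 6) for p in props]
    summary["true_proportions"] = list(scfg.m)

    with stage("segments"):
        seg_frames = []
        for ci, pc in enumerate(panels.chroms):
            seg = ancestry.segment_and_test(
                paintings[ci], pc.pos_bp, scfg.L_bp, props,
                chrom=pc.chrom, f_min=cfg.f_min, len_min=cfg.len_min,
                alpha=cfg.alpha)
            seg_frames.append(seg)
        import pandas as pd

        segments = pd.concat(seg_frames, ignore_index=True)
        segments.to_csv(os.path.join(cfg.outdir, "excess_segments.tsv"),
                        sep="\t", index=False)
    summary["n_excess_segments"] = int(len(segments))

    with stage("date"):
        curve = None
        order = np.argsort(scfg.m)[::-1]
        kA, kB = int(order[0]), int(order[1])
        for ci, pc in enumerate(panels.chroms):
            gt = truth.target_haps[ci].reshape(scfg.n_adm, 2, -1).sum(axis=1)
            cm = pc.pos_bp / 1e6 * scfg.cM_per_Mb
            curve = dating.weighted_ld_curve(gt, pc.haps[kA], pc.haps[kB],
                                             cm, chrom=pc.chrom, curve=curve)
        fit = dating.fit_decay(curve)
    summary["admixture_generations"] = round(fit.n_generations, 4)
    summary["admixture_generations_se"] = (None if not np.isfinite(fit.se)
                                           else round(fit.se, 4))
    summary["dating_flag"] = fit.flag
    summary["true_generations"] = scfg.g

    with stage("selection_scans"):
        scans = {}
        st = truth.target_sitetable(0)
        pc = panels.chroms[0]
        ref_st = truth.panel_sitetable(0, ancestry=kB)
        scans["clr"] = haplostats.clr_scan(
            st, win=cfg.win_scan, L=scfg.L_bp,
            morgans_per_bp=scfg.cM_per_Mb / 1e8)
        ihs = haplostats.ehh_ihs(truth.target_haps[0], pc.pos_bp,
                                 pc.pos_bp / 1e6 * scfg.cM_per_Mb)
        scans["ihs"] = haplostats.ihs_windows(ihs, chrom=pc.chrom,
                                              win=cfg.win_scan, L=scfg.L_bp)
        merged = _merge_tables(st, ref_st)
        scans["fst"] = popstats.wc_fst_windows(
            merged, st.samples, ref_st.samples, win=cfg.win_fst,
            step=cfg.step_fst, L=scfg.L_bp)
        pi_t = popstats.pi_windows(st, win=cfg.win_fst, step=cfg.step_fst,
                                   L=scfg.L_bp)
        pi_r = popstats.pi_windows(ref_st, win=cfg.win_fst,
                                   step=cfg.step_fst, L=scfg.L_bp)
        scans["theta_pi_ratio"] = popstats.theta_pi_ratio(pi_t, pi_r)
        for name, df in scans.items():
            df.to_csv(os.path.join(cfg.outdir, f"scan_{name}.tsv"),
                      sep="\t", index=False)

    with stage("intersect"):
        candidates = haplostats.rank_and_intersect(
            scans, top_q=cfg.top_q, min_methods=cfg.min_methods,
            min_windows=min(100, min(len(s) for s in scans.values())))
        candidates.to_csv(os.path.join(cfg.outdir, "candidates.bed"),
                          sep="\t", index=False, header=False)
    summary["n_candidate_regions"] = int(len(candidates))

    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


class _StageTimer:
    def __init__(self, name, summary):
        self.name, self.summary = name, summary

    def __enter__(self):
        self.t0 = time.time()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            log.error("stage %s failed: %s", self.name, exc)
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs", self.name, time.time() - self.t0)
        self.summary["stages"][self.name] = "done"


def _write_tracts_bed(path, panels, paintings, positions, lengths):
    with open(path, "w") as fh:
        for pc, codes, pos, L in zip(panels.chroms, paintings, positions,
                                     lengths):
            for h, hap in enumerate(codes):
                for s, e, k in ancestry.tracts_from_codes(hap, pos, L):
                    fh.write(f"{pc.chrom}\t{s}\t{e}\thap{h}_anc{k}\n")


def _merge_tables(a, b):
    """Column-concatenate two SiteTables on identical site lists."""
    from .vcfio import SiteTable

    if not np.array_equal(a.pos, b.pos):
        raise ValueError("site lists differ; cannot merge")
    return SiteTable(
        chrom=a.chrom, pos=a.pos, ref=a.ref, alt=a.alt, info=a.info,
        gt=np.concatenate([a.gt, b.gt], axis=1),
        phased=(None if a.phased is None or b.phased is None
                else np.concatenate([a.phased, b.phased], axis=1)),
        samples=list(a.samples) + list(b.samples),
    )
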