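import numpy as np
import pytest

from admixscan import synthpop
from admixscan.vcfio import SiteTable


def make_sitetable(pos, gt, chrom="chr1", info=None, phased=None,
                   samples=None, ref=None, alt=None):
    """Build a small SiteTable from plain arrays (0-based positions)."""
    pos = np.asarray(pos, dtype=np.int64)
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    return SiteTable(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=pos,
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, dtype="U1"),
        alt=np.asarray(alt if alt is not None else ["G"] * n_sites, dtype="U1"),
        info={k: np.asarray(v, dtype=float) for k, v in (info or {}).items()},
        gt=gt,
        phased=None if phased is None else np.asarray(phased, dtype=np.int8),
        samples=samples or [f"s{i}" for i in range(n_samples)],
    )


def haps_to_sitetable(haps, pos, chrom="chr1", prefix="s"):
    """Phased SiteTable from a (n_hap, n_sites) haplotype matrix."""
    haps = np.asarray(haps, dtype=np.int8)
    n_hap, n_sites = haps.shape
    phased = haps.T.reshape(n_sites, n_hap // 2, 2)
    return make_sitetable(pos, phased.sum(axis=2), chrom=chrom,
                          phased=phased,
                          samples=[f"{prefix}{i}" for i in range(n_hap // 2)])


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-way admixed cohort small enough for per-test reuse."""
    cfg = synthpop.SimConfig(K=2, m=(0.6, 0.4), F=0.2, n_sites=3000,
                             L_bp=10_000_000, n_adm=10, n_ref=16, g=30,
                             eps=0.001, seed=101)
    panels = synthpop.make_panels(cfg)
    truth = synthpop.simulate_cohort(cfg, panels)
    return cfg, panels, truth


@pytest.fixture(scope="session")
def four_way_cohort():
    """A 4-way admixed cohort matching the generator defaults at reduced
    size, for painting and proportion tests."""
    cfg = synthpop.SimConfig(K=4, F=0.2, n_sites=4000, L_bp=10_000_000,
                             n_adm=8, n_ref=16, g=30, eps=0.001, seed=7)
    panels = synthpop.make_panels(cfg)
    truth = synthpop.simulate_cohort(cfg, panels)
    return cfg, panels, truth
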