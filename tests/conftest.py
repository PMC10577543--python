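import numpy as np
import pytest
from hypothesis import settings

from poolscan import poolio, simcohort as sc

settings.register_profile("ci", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced end-to-end study (400 variants, 800 haplotypes) shared by
    I/O and pipeline tests."""
    return sc.default_scenario(seed=11, n_variants=400, n_hap=800,
                               risk_group_size=30, protective_group_size=15)


@pytest.fixture(scope="session")
def small_freq(small_scenario):
    return poolio.estimate_frequencies(small_scenario.counts,
                                       small_scenario.design)


def make_design(n_case_pools=3, n_ctrl_pools=3, pool_size=25):
    """A minimal pool design without a backing cohort."""
    pools = []
    nxt = 0
    for k in range(n_case_pools):
        pools.append(sc.Pool(f"case{k}", "case",
                             tuple(range(nxt, nxt + pool_size))))
        nxt += pool_size
    for k in range(n_ctrl_pools):
        pools.append(sc.Pool(f"ctrl{k}", "control",
                             tuple(range(nxt, nxt + pool_size))))
        nxt += pool_size
    return sc.PoolDesign(pools=tuple(pools), pool_size=pool_size)


def make_freq(freqs, design, variant_ids=None):
    """Wrap a raw pools x variants frequency array in a FrequencyMatrix."""
    freqs = np.asarray(freqs, dtype=float)
    n_pools, n_var = freqs.shape
    ids = variant_ids or [f"v{j}" for j in range(n_var)]
    sizes = design.pool_sizes()
    w = (2.0 * sizes)[:, None] * np.isfinite(freqs)
    af = np.nansum(freqs * w, axis=0) / w.sum(axis=0)
    maf = np.minimum(af, 1 - af)
    mac = np.rint(maf * 2 * sizes.sum()).astype(int)
    return poolio.FrequencyMatrix(freqs=freqs, pool_ids=design.pool_ids,
                                  variant_ids=ids, pool_sizes=sizes,
                                  af=af, maf=maf, mac=mac)


def simulate_flag_cohort(seed, betas, afs, n_cases=450, n_controls=500,
                         mean_depth=30.0, error_rate=0.0, n_hap=2000,
                         risk_alleles=None):
    """One variant per LD block with a per-allele log-odds effect; pooled
    reads at the given depth.  The workhorse for calibration and power
    simulations of the tag-level tests."""
    n_var = len(afs)
    region = sc.RegionSpec("chr9", 21_950_000, 22_180_000)
    ld = sc.LDSpec(n_blocks=n_var, within_block_r2=0.0)
    lo = min(afs) * 0.999
    spectrum = sc.uniform_af_spectrum(max(lo, 1e-4), max(afs))
    rng = np.random.default_rng(seed)
    panel = sc.simulate_haplotypes(region, ld, n_hap=n_hap, n_variants=n_var,
                                   af_spectrum=spectrum, seed=seed,
                                   on_unattainable="clamp")
    # force exact target frequencies per column
    import dataclasses
    for j, af in enumerate(afs):
        col = np.zeros(n_hap, dtype=np.uint8)
        on = rng.choice(n_hap, size=int(round(af * n_hap)), replace=False)
        col[on] = 1
        panel.alleles[:, j] = col
        ra = (risk_alleles or ["alt"] * n_var)[j]
        panel.variants[j] = dataclasses.replace(
            panel.variants[j], id=f"tag{j}", true_af=float(col.mean()),
            risk_allele=ra, beta=betas[j], trait=f"trait{j}")
    model = sc.RiskModel(flag_effects={f"tag{j}": betas[j]
                                       for j in range(n_var)})
    cohort = sc.assign_phenotypes(panel, model, n_cases, n_controls,
                                  seed=seed + 1)
    design = sc.build_pool_design(cohort, 18, 20, 25, seed=seed + 2)
    counts = sc.simulate_pooled_reads(cohort, design, mean_depth=mean_depth,
                                      error_rate=error_rate, seed=seed + 3)
    freq = poolio.estimate_frequencies(counts, design)
    return panel, cohort, design, freq
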