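"""Windowed diversity, Tajima's D, ROH/F_ROH, LD decay and inbreeding F."""

import numpy as np
import pytest

from garrupop import popdiv, simdata, vario
from garrupop.popdiv import ROHSegment, tajima_constants
from garrupop.simdata import GroupSpec, ROHBlock, SexDesign, SimConfig
from garrupop.vario import Window, make_windows

from conftest import make_gm


# -- pi ---------------------------------------------------------------------


def test_pi_empty_and_single_site_windows():
    ws = [Window("scaffold_1", 0, 40_000)]
    empty = make_gm(np.empty((0, 4), dtype=int), positions=[], scaffold_length=40_000)
    assert popdiv.pi_windows(empty, ws)["pi"].iloc[0] == 0.0
    # one site, dosages (0, 2): p = 0.5, m = 4 -> 2*0.25*(4/3) / 40000
    gm = make_gm([[0, 2]], positions=[100], scaffold_length=40_000)
    pi = popdiv.pi_windows(gm, ws)["pi"].iloc[0]
    assert pi == pytest.approx(2 * 0.25 * (4 / 3) / 40_000, abs=1e-12)
    # monomorphic site contributes nothing
    gm0 = make_gm([[0, 0]], positions=[100], scaffold_length=40_000)
    assert popdiv.pi_windows(gm0, ws)["pi"].iloc[0] == 0.0


def test_pi_matches_pairwise_haplotype_oracle():
    """Window pi equals the mean pairwise difference over all chromosome pairs."""
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(25, 6))
    gm = make_gm(g, scaffold_length=10_000)
    ws = [Window("scaffold_1", 0, 10_000)]
    got = popdiv.pi_windows(gm, ws)["pi"].iloc[0]
    # oracle: per site, differing allele pairs / C(m,2), summed
    total = 0.0
    for row in g:
        alt = int(row.sum())
        m = 2 * len(row)
        total += alt * (m - alt) / (m * (m - 1) / 2)
    assert got == pytest.approx(total / 10_000, rel=1e-12)


def test_pi_invariant_to_allele_relabel():
    rng = np.random.default_rng(1)
    g = rng.integers(0, 3, size=(30, 8))
    ws = [Window("scaffold_1", 0, 5_000)]
    pi_a = popdiv.pi_windows(make_gm(g, scaffold_length=5_000), ws)["pi"].iloc[0]
    pi_b = popdiv.pi_windows(make_gm(2 - g, scaffold_length=5_000), ws)["pi"].iloc[0]
    assert pi_a == pytest.approx(pi_b, rel=1e-12)


def test_pi_concatenation_is_length_weighted_mean():
    rng = np.random.default_rng(2)
    g = rng.integers(0, 3, size=(40, 6))
    pos = np.sort(rng.choice(np.arange(1, 60_000), 40, replace=False))
    gm = make_gm(g, positions=pos, scaffold_length=60_000)
    parts = [Window("scaffold_1", 0, 20_000), Window("scaffold_1", 20_000, 60_000)]
    whole = [Window("scaffold_1", 0, 60_000)]
    pp = popdiv.pi_windows(gm, parts)
    pw = popdiv.pi_windows(gm, whole)["pi"].iloc[0]
    weighted = (pp["pi"] * (pp["end"] - pp["start"])).sum() / 60_000
    assert pw == pytest.approx(weighted, rel=1e-12)


# -- Tajima's D -------------------------------------------------------------


def _tajima_oracle(g: np.ndarray, window_size: int):
    """Independent brute-force evaluation of the 1989 formula."""
    seg = [row for row in g if 0 < row.sum() < 2 * len(row)]
    S = len(seg)
    if S < 3:
        return np.nan
    n = min(2 * len(row) for row in seg)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    pi_abs = 0.0
    for row in seg:
        alt = int(row.sum())
        m = 2 * len(row)
        pi_abs += alt * (m - alt) / (m * (m - 1) / 2)
    return (pi_abs - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajima_d_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    for trial in range(20):
        g = rng.integers(0, 3, size=(rng.integers(3, 40), rng.integers(2, 12)))
        gm = make_gm(g, scaffold_length=10_000)
        got = popdiv.tajima_d_windows(gm, [Window("scaffold_1", 0, 10_000)])["tajima_d"].iloc[0]
        exp = _tajima_oracle(g, 10_000)
        if np.isnan(exp):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(exp, abs=1e-10)


def test_tajima_d_undefined_below_three_segregating_sites():
    gm = make_gm([[0, 0, 0], [2, 2, 2]], scaffold_length=10_000)
    d = popdiv.tajima_d_windows(gm, [Window("scaffold_1", 0, 10_000)])["tajima_d"].iloc[0]
    assert np.isnan(d)


def test_tajima_d_negative_for_singleton_excess():
    """16 singleton sites among 10 chromosomes: strong low-frequency skew."""
    g = np.zeros((16, 5), dtype=int)
    for i in range(16):
        g[i, i % 5] = 1
    gm = make_gm(g, scaffold_length=10_000)
    d = popdiv.tajima_d_windows(gm, [Window("scaffold_1", 0, 10_000)])["tajima_d"].iloc[0]
    assert d < 0
    assert d == pytest.approx(_tajima_oracle(g, 10_000), abs=1e-10)


# -- heterozygosity ---------------------------------------------------------


def test_heterozygosity_rate():
    gm = make_gm([[1, 0], [1, 2], [0, 1]], scaffold_length=1000)
    assert popdiv.heterozygosity_rate(gm, "s0", 1_000_000) == pytest.approx(2e-6)
    assert popdiv.heterozygosity_rate(gm, "s1", 1000) == pytest.approx(1e-3)
    with pytest.raises(KeyError):
        popdiv.heterozygosity_rate(gm, "nope", 1000)


# -- ROH --------------------------------------------------------------------


def test_roh_fully_heterozygous_sample_has_none():
    gm = make_gm(np.ones((50, 1), dtype=int), positions=np.arange(50) * 2000 + 1)
    assert popdiv.call_roh(gm, "s0") == []


def test_roh_planted_run_recovered_and_short_run_rejected():
    cfg = SimConfig(
        seed=8,
        n_scaffolds=1,
        scaffold_length=500_000,
        roh_blocks=[
            ROHBlock("GCO_01", "scaffold_1", 100_000, 160_000),  # 60 kb
            ROHBlock("GCO_01", "scaffold_1", 300_000, 330_000),  # 30 kb < 40 kb
        ],
        sex_design=SexDesign(n_z=0, n_w=0),
    )
    gm, _, _ = simdata.simulate_cohort(cfg)
    segs = popdiv.call_roh(gm, "GCO_01")
    covering = [s for s in segs if s.start <= 101_000 and s.end >= 159_000]
    assert len(covering) == 1
    assert all(not (s.start >= 295_000 and s.end <= 335_000) for s in segs)
    # every reported segment satisfies both stated thresholds
    for s in segs:
        assert s.length >= 40_000 and s.n_snps >= 10


def test_roh_missing_budget():
    pos = np.arange(100) * 1000 + 1
    g = np.zeros((100, 1), dtype=int)
    g[40:44, 0] = -1  # 4 consecutive missing > max_missing=2 splits the run
    gm = make_gm(g, positions=pos)
    segs = popdiv.call_roh(gm, "s0", min_snps=10, min_kb=10, max_missing=2)
    assert len(segs) == 2


def test_bin_roh_and_conservation():
    def seg(kb):
        return ROHSegment("s", "c", 0, int(kb * 1000), 10, 0)

    segs = [seg(50), seg(150), seg(600), seg(1500)]
    counts = popdiv.bin_roh(segs)
    assert counts == {"<100kb": 1, "100-500kb": 1, "500-1000kb": 1, ">1000kb": 1}
    assert sum(counts.values()) == len(segs)
    assert popdiv.bin_roh([]) == {"<100kb": 0, "100-500kb": 0, "500-1000kb": 0, ">1000kb": 0}
    # boundary 100 kb is left-closed into the second bin
    assert popdiv.bin_roh([seg(100)])["100-500kb"] == 1


def test_f_roh_bounds_and_overlap_error():
    assert popdiv.f_roh([], 1e6) == 0.0
    whole = ROHSegment("s", "c", 0, 1_000_000, 100, 0)
    assert popdiv.f_roh([whole], 1_000_000) == 1.0
    a = ROHSegment("s", "c", 0, 100_000, 10, 0)
    b = ROHSegment("s", "c", 50_000, 150_000, 10, 0)
    with pytest.raises(ValueError):
        popdiv.f_roh([a, b], 1e6)


# -- LROH -------------------------------------------------------------------


def test_flag_lroh_strict_threshold_and_merge():
    import pandas as pd

    ws = pd.DataFrame(
        {
            "scaffold": "c",
            "start": [0, 40_000, 80_000, 120_000, 160_000],
            "end": [40_000, 80_000, 120_000, 160_000, 200_000],
            "pi": [2e-4, 9.9e-5, 5e-5, 8e-5, 3e-4],
        }
    )
    runs = popdiv.flag_lroh(ws)
    assert len(runs) == 1
    assert runs.iloc[0]["span"] == 120_000 and runs.iloc[0]["n_windows"] == 3
    none = popdiv.flag_lroh(ws.assign(pi=1e-3))
    assert none.empty
    # exactly at threshold is NOT flagged (strict <)
    at = popdiv.flag_lroh(ws.assign(pi=1e-4))
    assert at.empty


# -- LD decay ---------------------------------------------------------------


def test_ld_duplicate_site_r2_one():
    g = np.array([[0, 1, 2, 1, 0, 2], [0, 1, 2, 1, 0, 2]])
    gm = make_gm(g, positions=[100, 600])
    df, _ = popdiv.ld_decay(gm, max_dist=10_000, bin_bp=1000)
    assert df["mean_r2"].dropna().iloc[0] == pytest.approx(1.0)


def test_ld_independent_sites_finite_sample_bias():
    """E[r2] for independent sites is ~1/n with n diploid samples."""
    cfg = SimConfig(
        seed=2,
        n_scaffolds=1,
        scaffold_length=200_000,
        groups=[GroupSpec("G", 10, 1e-3, 0.0)],
        sex_design=SexDesign(n_z=0, n_w=0),
    )
    gm, _, _ = simdata.simulate_cohort(cfg)
    df, _ = popdiv.ld_decay(gm, max_dist=50_000, bin_bp=5000)
    mean = np.average(df["mean_r2"].dropna(), weights=df["n_pairs"][df["mean_r2"].notna()])
    assert mean == pytest.approx(1 / 10, abs=0.03)


def test_decay_length_interpolation():
    mids = np.array([500.0, 1500.0, 2500.0])
    means = np.array([0.8, 0.4, 0.2])
    # crosses 0.3 between 1500 and 2500: 1500 + (0.1/0.2)*1000 = 2000
    assert popdiv._decay_length(mids, means, 0.3) == pytest.approx(2000.0)
    assert np.isnan(popdiv._decay_length(mids, np.array([0.2, 0.1, 0.05]), 0.3))
    assert np.isnan(popdiv._decay_length(mids, np.array([0.9, 0.8, 0.7]), 0.3))


# -- inbreeding F -----------------------------------------------------------


def test_inbreeding_sign_for_het_excess():
    # 50/50 frequency sites, focal sample all heterozygous -> F < 0
    g = np.column_stack([np.ones(40, dtype=int), np.zeros(40, dtype=int), np.full(40, 2)])
    gm = make_gm(g)
    assert popdiv.inbreeding_f(gm, "s0") < 0


def test_inbreeding_recovers_planted_f():
    means = {}
    for f in (0.0, 0.1, 0.25, 0.5):
        cfg = SimConfig(
            seed=11,
            n_scaffolds=1,
            scaffold_length=600_000,
            groups=[GroupSpec("G", 12, 2e-3, f)],
            sex_design=SexDesign(n_z=0, n_w=0),
        )
        gm, _, _ = simdata.simulate_cohort(cfg)
        means[f] = np.mean([popdiv.inbreeding_f(gm, s) for s in gm.samples])
        assert means[f] == pytest.approx(f, abs=0.05)
    # recovery slope ~1 over the planted range
    fs = np.array(list(means))
    slope = np.polyfit(fs, np.array([means[f] for f in fs]), 1)[0]
    assert slope == pytest.approx(1.0, abs=0.1)
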