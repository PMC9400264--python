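"""Hp/zHp, Weir-Cockerham Fst, dual-threshold overlap, flanks, gene overlap."""

import numpy as np
import pandas as pd
import pytest

from garrupop import simdata, sweep, vario
from garrupop.simdata import GroupSpec, SexDesign, SimConfig, SweepSpec
from garrupop.vario import Window, make_windows

from conftest import make_gm


# -- Hp ---------------------------------------------------------------------


def test_hp_printed_formula_cases():
    assert sweep.hp_single_window([10, 10], [0, 0]) == 0.0
    assert sweep.hp_single_window([5], [5]) == pytest.approx(0.5)
    # counts (8,2) and (6,4): 2*14*6/20^2 = 0.42
    assert sweep.hp_single_window([8, 6], [2, 4]) == pytest.approx(0.42)


def test_hp_random_windows_match_direct_formula():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        k = rng.integers(1, 30)
        n_maj = rng.integers(1, 40, k)
        n_min = rng.integers(0, n_maj + 1)
        got = sweep.hp_single_window(n_maj, n_min)
        smaj, smin = n_maj.sum(), n_min.sum()
        exp = 2 * smaj * smin / (smaj + smin) ** 2
        assert got == pytest.approx(exp, abs=1e-12)


def test_hp_windows_invariant_to_allele_relabel():
    rng = np.random.default_rng(1)
    g = rng.integers(0, 3, size=(40, 10))
    ws = [Window("scaffold_1", 0, 10_000)]
    a = sweep.hp_windows(make_gm(g, scaffold_length=10_000), ws)["hp"].iloc[0]
    b = sweep.hp_windows(make_gm(2 - g, scaffold_length=10_000), ws)["hp"].iloc[0]
    assert a == pytest.approx(b, abs=1e-15)


def test_hp_window_eligibility_rule():
    g = np.tile([0, 1], (10, 5))  # 10 SNPs only -> not > 10
    gm = make_gm(g, scaffold_length=10_000)
    ws = [Window("scaffold_1", 0, 10_000)]
    assert np.isnan(sweep.hp_windows(gm, ws)["hp"].iloc[0])


# -- zHp --------------------------------------------------------------------


def test_zhp_standardization_properties():
    rng = np.random.default_rng(2)
    hp = rng.uniform(0, 0.5, 500)
    z = sweep.zhp_standardize(hp)
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
    # minimal Hp window carries the minimal zHp
    assert np.argmin(z) == np.argmin(hp)


def test_zhp_hand_case_and_degenerate():
    z = sweep.zhp_standardize(np.array([0.1, 0.2, 0.3]))
    assert z[0] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        sweep.zhp_standardize(np.array([0.2, 0.2, 0.2]))
    with pytest.raises(ValueError):
        sweep.zhp_standardize(np.array([0.2]))


# -- Weir-Cockerham Fst -----------------------------------------------------


def _wc_oracle(g1, g2):
    """Scalar brute-force Weir-Cockerham (1984) a, b, c for one site."""
    def stats(g):
        g = [x for x in g if x >= 0]
        n = len(g)
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        return n, p, h

    n1, p1, h1 = stats(g1)
    n2, p2, h2 = stats(g2)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def test_wc_components_match_bruteforce_oracle():
    rng = np.random.default_rng(3)
    for _ in range(100):
        na, nb = rng.integers(2, 12, 2)
        g1 = rng.integers(0, 3, na)
        g2 = rng.integers(0, 3, nb)
        gm = make_gm(np.concatenate([g1, g2]).reshape(1, -1))
        ids = gm.samples
        a, b, c = sweep.wc_site_components(
            gm, gm.sample_indices(ids[:na]), gm.sample_indices(ids[na:])
        )
        oa, ob, oc = _wc_oracle(g1, g2)
        assert a[0] == pytest.approx(oa, abs=1e-12)
        assert b[0] == pytest.approx(ob, abs=1e-12)
        assert c[0] == pytest.approx(oc, abs=1e-12)


def test_fst_reciprocally_fixed_is_one():
    g = np.tile([0] * 6 + [2] * 6, (15, 1))
    gm = make_gm(g, scaffold_length=10_000)
    ws = [Window("scaffold_1", 0, 10_000)]
    fst = sweep.wc_fst_windows(gm, gm.samples[:6], gm.samples[6:], ws)["fst"].iloc[0]
    assert fst == pytest.approx(1.0)


def test_fst_single_pool_near_zero():
    cfg = SimConfig(
        seed=17,
        n_scaffolds=1,
        scaffold_length=2_000_000,
        groups=[GroupSpec("POOL", 20, 2e-3, 0.0)],
        sex_design=SexDesign(n_z=0, n_w=0),
    )
    gm, samples, _ = simdata.simulate_cohort(cfg)
    ids = samples["sample"].tolist()
    ws = make_windows({"scaffold_1": 2_000_000}, 40_000)
    fst = sweep.wc_fst_windows(gm, ids[:10], ids[10:], ws)["fst"]
    assert np.nanmean(np.abs(fst)) < 0.05
    assert np.nanmax(fst) <= 1.0


# -- dual-threshold overlap -------------------------------------------------


def _stats_frames(n, rng):
    base = {
        "scaffold": "c",
        "start": np.arange(n) * 40_000,
        "end": (np.arange(n) + 1) * 40_000,
    }
    fst = pd.DataFrame({**base, "n_snps": 50, "fst": rng.uniform(0, 1, n)})
    zhp = pd.DataFrame({**base, "zhp": rng.normal(0, 1, n)})
    return fst, zhp


def test_overlap_quantile_boundary():
    rng = np.random.default_rng(4)
    fst, zhp = _stats_frames(200, rng)
    scan, thr = sweep.dual_threshold_overlap(fst, zhp, quantile=1.0)
    assert scan["is_overlap"].all()
    assert (scan["is_overlap"] == (scan["passes_fst"] & scan["passes_zhp"])).all()


def test_overlap_fraction_under_independence():
    """Independent statistics: overlap fraction concentrates near quantile^2."""
    rng = np.random.default_rng(5)
    total = hits = 0
    for _ in range(200):
        fst, zhp = _stats_frames(500, rng)
        scan, _ = sweep.dual_threshold_overlap(fst, zhp, quantile=0.05)
        hits += int(scan["is_overlap"].sum())
        total += len(scan)
    frac = hits / total
    # expected 0.05^2 = 2.5e-3; binomial 4-sigma band around it
    se = np.sqrt(2.5e-3 * (1 - 2.5e-3) / total)
    assert abs(frac - 2.5e-3) < 4 * se + 1e-4


def test_overlap_sorted_by_zhp_and_inclusive_thresholds():
    fst = pd.DataFrame(
        {
            "scaffold": "c",
            "start": [0, 40_000, 80_000, 120_000],
            "end": [40_000, 80_000, 120_000, 160_000],
            "n_snps": 50,
            "fst": [0.9, 0.8, 0.1, 0.2],
        }
    )
    zhp = fst[["scaffold", "start", "end"]].assign(zhp=[-4.0, -5.0, 0.0, 1.0])
    scan, thr = sweep.dual_threshold_overlap(fst, zhp, quantile=0.5)
    ov = scan[scan["is_overlap"]]
    assert list(ov["zhp"]) == sorted(ov["zhp"])
    # windows exactly at the thresholds pass (inclusive comparisons)
    assert ((ov["fst"] >= thr["fst_threshold"]) & (ov["zhp"] <= thr["zhp_threshold"])).all()


# -- flank profile ----------------------------------------------------------


def test_flank_clipping_and_tile_count():
    cfg = SimConfig(seed=19, n_scaffolds=1, scaffold_length=1_200_000,
                    sex_design=SexDesign(n_z=0, n_w=0))
    gm, samples, _ = simdata.simulate_cohort(cfg)
    pop = samples["sample"].tolist()[:5]
    prof = sweep.flank_profile(gm, pop, "scaffold_1", 0, 40_000, flank=500_000)
    assert prof["start"].iloc[0] == 0  # left flank clipped at scaffold start
    # region [0, 540000) -> 54 tiles
    assert len(prof) == 54
    prof2 = sweep.flank_profile(gm, pop, "scaffold_1", 500_000, 540_000)
    # 40 kb hit + 2x500 kb flank = 1.04 Mb -> 104 tiles
    assert len(prof2) == 104


def test_flank_pi_minimum_at_planted_sweep():
    cfg = SimConfig(
        seed=23,
        n_scaffolds=1,
        scaffold_length=2_000_000,
        sweep_regions=[SweepSpec("scaffold_1", 960_000, 1_040_000, 0.02, 0.0)],
        sex_design=SexDesign(n_z=0, n_w=0),
    )
    gm, samples, _ = simdata.simulate_cohort(cfg)
    gco = samples.loc[samples["group"] == "GCO", "sample"].tolist()
    prof = sweep.flank_profile(gm, gco, "scaffold_1", 960_000, 1_040_000, flank=300_000)
    hit = (prof["start"] >= 960_000) & (prof["end"] <= 1_040_000)
    assert prof.loc[hit, "pi"].mean() < 0.25 * prof.loc[~hit, "pi"].median()


# -- gene annotation --------------------------------------------------------


def test_gene_overlap_semantics(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text(
        "c\t100\t200\tgeneA\n"
        "c\t400\t500\tgeneB\n"
        "d\t100\t200\tgeneC\n"
    )
    genes = sweep.read_bed(bed)
    windows = pd.DataFrame(
        {"scaffold": ["c", "c"], "start": [0, 200], "end": [200, 400]}
    )
    out = sweep.annotate_genes(windows, genes)
    assert out["genes"].iloc[0] == ["geneA"]
    # gene starting exactly at window end is NOT reported (half-open)
    assert out["genes"].iloc[1] == []


def test_gene_overlap_matches_bruteforce(tmp_path):
    rng = np.random.default_rng(6)
    genes = pd.DataFrame(
        {
            "scaffold": "c",
            "start": rng.integers(0, 900, 6) * 100,
            "name": [f"g{i}" for i in range(6)],
        }
    )
    genes["end"] = genes["start"] + rng.integers(1, 300, 6) * 10
    windows = pd.DataFrame(
        {"scaffold": "c", "start": np.arange(5) * 20_000, "end": (np.arange(5) + 1) * 20_000}
    )
    out = sweep.annotate_genes(windows, genes)
    for _, w in out.iterrows():
        expected = sorted(
            g["name"]
            for _, g in genes.iterrows()
            if g["start"] < w["end"] and g["end"] > w["start"]
        )
        assert w["genes"] == expected


def test_malformed_bed_raises(tmp_path):
    bad = tmp_path / "bad.bed"
    bad.write_text("c\tnotanumber\t200\tg\n")
    with pytest.raises(ValueError):
        sweep.read_bed(bad)
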