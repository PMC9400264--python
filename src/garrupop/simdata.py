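"""Synthetic cohorts with planted, recorded truth.

Generates everything the downstream pipeline consumes — a multi-sample
genotype matrix (writable as VCF 4.2), per-sample per-scaffold depth
profiles, STR genotype tables, variant-effect labels and sample metadata —
for a two-species resequencing design: a high-diversity focal group and a
low-diversity, more inbred comparison group, with related pairs, planted
runs of homozygosity, a phenomenologically planted selective sweep, ZW
depth signatures (males ZZ, females ZW) and W-linked, female-restricted
STR markers.

Model
-----
Segregating-site counts per autosomal scaffold are Poisson(theta * L * a_n)
with a_n the Watterson harmonic number for 2n chromosomes; derived-allele
counts follow the neutral equilibrium frequency spectrum p(i) proportional
to 1/i over i = 1..2n-1.  For non-inbred groups genotypes are assigned by
randomly placing exactly i alt alleles among the group's 2n chromosomes,
so the sample carries the neutral spectrum exactly (this makes windowed pi
and Tajima's D analytically calibrated); inbred groups draw per-sample
genotypes with the standard inbreeding mixture
P(het) = 2pq(1-F).  There is no recombination model or demographic
history; sites are exchangeable within a scaffold.

Sweeps are planted phenomenologically: inside a sweep region the focal
group's sites are thinned and driven toward alt fixation
(``divergence_shift``) with heterozygosity suppressed by
``diversity_scale``, which is what a completed hard sweep looks like to
the downstream Hp/Fst scan.

Every planted feature is recorded in a :class:`TruthSet` so recovery can
be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .vario import GenotypeMatrix, SITE_COLUMNS, INFO_KEYS, MISSING

EFFECT_CATEGORIES = (
    "frameshift",
    "stopgain",
    "stoploss",
    "splicing",
    "missense",
    "synonymous",
    "other",
)

# Stage indices for the documented seed derivation: the single config seed
# expands into independent child streams via SeedSequence(seed, spawn_key).
_STAGE_GENO, _STAGE_DEPTH, _STAGE_STR, _STAGE_EFFECT = range(4)


class SimConfigError(ValueError):
    pass


@dataclass
class GroupSpec:
    """One population: name, diploid sample count, scaled mutation rate per bp,
    and inbreeding coefficient in [0, 1]."""

    name: str
    n_samples: int
    theta_per_bp: float
    inbreeding_f: float = 0.0


@dataclass
class SweepSpec:
    """Planted sweep: diversity_scale in (0,1] thins and de-heterozygoses the
    focal group inside [start, end); divergence_shift in [0,1] drives its
    allele frequencies toward alt fixation."""

    scaffold: str
    start: int
    end: int
    diversity_scale: float = 1.0
    divergence_shift: float = 0.0


@dataclass
class RelatedPair:
    """Planted relationship; kind in {parent_offspring, full_sib, half_sib}."""

    kind: str
    id_a: str
    id_b: str

    EXPECTED_PI_HAT = {"parent_offspring": 0.5, "full_sib": 0.5, "half_sib": 0.25}


@dataclass
class ROHBlock:
    """Forced homozygous interval [start, end) for one sample."""

    sample: str
    scaffold: str
    start: int
    end: int


@dataclass
class SexDesign:
    """ZW scaffold layout and per-sex copy ratios (males ZZ, females ZW)."""

    n_z: int = 1
    n_w: int = 1
    female_fraction: float = 4 / 14
    z_ratio_male: float = 1.0
    z_ratio_female: float = 0.5
    w_ratio_male: float = 0.0
    w_ratio_female: float = 0.5


@dataclass
class STRDesign:
    """STR panel layout: loci per scaffold class, unit lengths, allele range."""

    n_autosomal_loci: int = 8
    n_w_loci: int = 6
    unit_lengths: tuple = (2, 3, 4, 5, 6)
    n_alleles_range: tuple = (2, 8)
    n_kinship_loci: int = 4  # planted 4-bp, >=5 allele, complete-call loci per autosome


# Default effect-category mixture: a realistic exome-wide blend dominated by
# synonymous/missense with a small strongly deleterious tail.
DEFAULT_EFFECT_MIX = {
    "frameshift": 0.04,
    "stopgain": 0.03,
    "stoploss": 0.01,
    "splicing": 0.02,
    "missense": 0.38,
    "synonymous": 0.44,
    "other": 0.08,
}


@dataclass
class SimConfig:
    """Full description of a synthetic cohort; the seed determines everything.

    Defaults emulate the study conditions this package targets: a 14-bird
    focal group (10 males / 4 females) with high diversity, an 11-bird
    comparison group with ~10x lower diversity and more inbreeding, ~20x
    coverage, and a ZW sex system.
    """

    seed: int = 0
    n_scaffolds: int = 3
    scaffold_length: int = 1_000_000
    groups: list = field(
        default_factory=lambda: [
            GroupSpec("GCO", 14, 2.5e-3, 0.0),
            GroupSpec("GSA", 11, 3.0e-4, 0.1),
        ]
    )
    sweep_regions: list = field(default_factory=list)
    related_pairs: list = field(default_factory=list)
    roh_blocks: list = field(default_factory=list)
    sex_design: SexDesign = field(default_factory=SexDesign)
    coverage_mean: float = 20.0
    depth_cv: float = 0.1
    str_design: STRDesign = field(default_factory=STRDesign)
    effect_mix: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MIX))
    filter_fail_rate: float = 0.1

    def validate(self) -> None:
        if self.n_scaffolds < 1 or self.scaffold_length <= 0:
            raise SimConfigError("need >=1 autosomal scaffold with positive length")
        for g in self.groups:
            if g.theta_per_bp <= 0:
                raise SimConfigError(f"group {g.name}: non-positive theta")
            if g.n_samples < 2:
                raise SimConfigError(f"group {g.name}: need >=2 samples")
            if not 0 <= g.inbreeding_f <= 1:
                raise SimConfigError(f"group {g.name}: inbreeding_f outside [0,1]")
        for s in self.sweep_regions:
            if not (0 < s.diversity_scale <= 1):
                raise SimConfigError("diversity_scale must be in (0,1]")
            if not (0 <= s.divergence_shift <= 1):
                raise SimConfigError("divergence_shift must be in [0,1]")
        for u in self.str_design.unit_lengths:
            if u not in (2, 3, 4, 5, 6):
                raise SimConfigError(f"STR unit length {u} outside 2..6")
        per_group = self.effect_mix and isinstance(next(iter(self.effect_mix.values())), dict)
        for mix in (self.effect_mix.values() if per_group else [self.effect_mix]):
            tot = sum(mix.values())
            if abs(tot - 1.0) > 1e-9:
                raise SimConfigError(f"effect mix sums to {tot}, not 1")
            unknown = set(mix) - set(EFFECT_CATEGORIES)
            if unknown:
                raise SimConfigError(f"unknown effect categories {sorted(unknown)}")

    # -- scaffold layout ----------------------------------------------------

    def scaffold_names(self) -> dict[str, str]:
        """Ordered scaffold -> class ('autosome'|'Z'|'W') mapping."""
        out = {}
        i = 1
        for _ in range(self.n_scaffolds):
            out[f"scaffold_{i}"] = "autosome"
            i += 1
        for _ in range(self.sex_design.n_z):
            out[f"scaffold_{i}"] = "Z"
            i += 1
        for _ in range(self.sex_design.n_w):
            out[f"scaffold_{i}"] = "W"
            i += 1
        return out

    def scaffold_lengths(self) -> dict[str, int]:
        return {s: self.scaffold_length for s in self.scaffold_names()}

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class TruthSet:
    """Everything that was planted, for downstream recovery checks."""

    sweep_regions: list = field(default_factory=list)
    related_pairs: list = field(default_factory=list)
    expected_pi_hat: dict = field(default_factory=dict)
    roh_blocks: list = field(default_factory=list)
    scaffold_classes: dict = field(default_factory=dict)
    sample_sexes: dict = field(default_factory=dict)
    sample_groups: dict = field(default_factory=dict)
    group_expected_pi: dict = field(default_factory=dict)
    sex_marker_strs: list = field(default_factory=list)
    kinship_strs: list = field(default_factory=list)
    n_filter_violations: int = 0

    def sweep_windows(self, size: int = 40_000) -> list[tuple[str, int, int]]:
        """Windows of the given tiling fully inside a planted sweep region."""
        out = []
        for s in self.sweep_regions:
            start = (s.start + size - 1) // size * size
            while start + size <= s.end:
                out.append((s.scaffold, start, start + size))
                start += size
        return out

    def to_json(self, path) -> None:
        d = asdict(self)
        d["expected_pi_hat"] = {f"{a}|{b}": v for (a, b), v in self.expected_pi_hat.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# Cohort simulation


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for g in config.groups:
        n_f = int(round(config.sex_design.female_fraction * g.n_samples))
        n_f = min(max(n_f, 1), g.n_samples - 1)  # both sexes present
        for k in range(g.n_samples):
            rows.append(
                {
                    "sample": f"{g.name}_{k + 1:02d}",
                    "group": g.name,
                    "sex": "F" if k < n_f else "M",
                }
            )
    return pd.DataFrame(rows)


def _neutral_counts(rng, n_chrom: int, size: int) -> np.ndarray:
    """Derived-allele counts from p(i) ~ 1/i, i = 1..n_chrom-1."""
    i = np.arange(1, n_chrom)
    p = (1.0 / i) / np.sum(1.0 / i)
    return rng.choice(i, size=size, p=p)


def _place_exact(rng, counts: np.ndarray, n_chrom: int) -> np.ndarray:
    """Dosage matrix with exactly counts[s] alt alleles randomly placed among
    n_chrom chromosome slots per site (random-union HWE pairing)."""
    u = rng.random((len(counts), n_chrom))
    rank = u.argsort(axis=1).argsort(axis=1)
    chrom = rank < counts[:, None]
    return chrom.reshape(len(counts), n_chrom // 2, 2).sum(axis=2).astype(np.int8)


def _draw_hwe_f(rng, p: np.ndarray, n_dip: int, f: float) -> np.ndarray:
    """Per-sample genotype draws with inbreeding mixture.

    P(hom alt) = p^2 + f p q;  P(het) = 2pq(1-f);  P(hom ref) = q^2 + f p q.
    """
    q = 1 - p
    p_hom_alt = p * p + f * p * q
    p_het = 2 * p * q * (1 - f)
    u = rng.random((len(p), n_dip))
    g = np.zeros((len(p), n_dip), dtype=np.int8)
    g[u < (p_hom_alt + p_het)[:, None]] = 1
    g[u < p_hom_alt[:, None]] = 2
    return g


def _gamete(rng, parent_dosage: np.ndarray) -> np.ndarray:
    """One transmitted allele per site under Mendelian segregation."""
    allele = (parent_dosage // 2).astype(np.int8)  # 0 -> 0, 2 -> 1
    het = parent_dosage == 1
    allele[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return allele


def _info_fields(rng, n: int, fail_rate: float) -> tuple[np.ndarray, int]:
    """INFO columns drawn from pass/fail mixtures.

    Passing records draw comfortably inside the hard-filter bounds; a
    ``fail_rate`` fraction get exactly one violating field (uniform over
    the six criteria).  Returns (n x 6 array, number of violating records).
    """
    vals = np.column_stack(
        [
            rng.uniform(10, 35, n),  # QD pass >= 2
            rng.uniform(0, 10, n),  # FS pass <= 20
            rng.uniform(50, 60, n),  # MQ pass >= 40
            rng.uniform(0.5, 2.0, n),  # SOR pass <= 3
            rng.normal(0, 0.5, n),  # MQRankSum pass >= -2
            rng.normal(0, 1.0, n),  # ReadPosRankSum pass >= -5
        ]
    )
    vals[:, 4] = np.clip(vals[:, 4], -1.9, None)
    vals[:, 5] = np.clip(vals[:, 5], -4.9, None)
    bad = rng.random(n) < fail_rate
    which = rng.integers(0, 6, n)
    lows = {0: (0.1, 1.9), 2: (10.0, 39.0)}
    highs = {1: (21.0, 60.0), 3: (3.1, 6.0)}
    for k, (lo, hi) in lows.items():
        m = bad & (which == k)
        vals[m, k] = rng.uniform(lo, hi, int(m.sum()))
    for k, (lo, hi) in highs.items():
        m = bad & (which == k)
        vals[m, k] = rng.uniform(lo, hi, int(m.sum()))
    m = bad & (which == 4)
    vals[m, 4] = rng.uniform(-4.0, -2.01, int(m.sum()))
    m = bad & (which == 5)
    vals[m, 5] = rng.uniform(-8.0, -5.01, int(m.sum()))
    return vals, int(bad.sum())


def simulate_cohort(config: SimConfig):
    """Simulate genotypes for the whole cohort.

    Returns ``(GenotypeMatrix, sample_table DataFrame, TruthSet)``.
    SNVs are placed on autosomal scaffolds only; Z/W scaffolds exist for the
    depth and STR stages.
    """
    config.validate()
    rng = config.rng(_STAGE_GENO)
    samples = _sample_table(config)
    truth = TruthSet(
        sweep_regions=list(config.sweep_regions),
        related_pairs=list(config.related_pairs),
        roh_blocks=list(config.roh_blocks),
        scaffold_classes=config.scaffold_names(),
        sample_sexes=dict(zip(samples["sample"], samples["sex"])),
        sample_groups=dict(zip(samples["sample"], samples["group"])),
        group_expected_pi={g.name: g.theta_per_bp for g in config.groups},
    )
    truth.sweep_regions = [s for s in truth.sweep_regions
                           if s.diversity_scale < 1 or s.divergence_shift > 0]
    truth.expected_pi_hat = {
        (rp.id_a, rp.id_b): RelatedPair.EXPECTED_PI_HAT[rp.kind]
        for rp in config.related_pairs
    }

    group_cols = {
        g.name: np.flatnonzero((samples["group"] == g.name).to_numpy())
        for g in config.groups
    }
    n_total = len(samples)
    bases = np.array(list("ACGT"))

    site_frames = []
    geno_blocks = []
    autosomes = [s for s, c in config.scaffold_names().items() if c == "autosome"]
    for scaf in autosomes:
        L = config.scaffold_length
        sweeps = [s for s in config.sweep_regions if s.scaffold == scaf]

        # per-group segregating sites: position -> (group, derived count)
        per_group: dict[str, dict[int, int]] = {}
        for g in config.groups:
            n_chrom = 2 * g.n_samples
            a_n = np.sum(1.0 / np.arange(1, n_chrom))
            s_count = rng.poisson(g.theta_per_bp * L * a_n)
            pos = rng.integers(1, L + 1, size=s_count)
            pos = np.unique(pos)
            counts = _neutral_counts(rng, n_chrom, len(pos))
            per_group[g.name] = dict(zip(pos.tolist(), counts.tolist()))

        all_pos = np.array(sorted(set().union(*[set(d) for d in per_group.values()])), dtype=int)
        n_sites = len(all_pos)
        geno = np.zeros((n_sites, n_total), dtype=np.int8)
        # origin: the first group in which the site segregates (effect mixes
        # and provenance are per origin group)
        origin = np.empty(n_sites, dtype=object)
        for g in reversed(config.groups):
            has = np.array([int(p) in per_group[g.name] for p in all_pos])
            origin[has] = g.name

        for g in config.groups:
            cols = group_cols[g.name]
            n_chrom = 2 * g.n_samples
            cnt = np.array([per_group[g.name].get(int(p), 0) for p in all_pos])
            p_freq = cnt / n_chrom

            in_sweep = np.zeros(n_sites, dtype=bool)
            if g.name == config.groups[0].name and sweeps:
                for s in sweeps:
                    in_sweep |= (all_pos - 1 >= s.start) & (all_pos - 1 < s.end)
                    reg = (all_pos - 1 >= s.start) & (all_pos - 1 < s.end)
                    seg = reg & (cnt > 0)
                    # drive toward alt fixation, then thin surviving variation
                    p_new = s.divergence_shift + (1 - s.divergence_shift) * p_freq[seg]
                    drop = rng.random(int(seg.sum())) > s.diversity_scale
                    p_new[drop] = np.round(p_new[drop])
                    p_freq[seg] = p_new

            base = np.zeros((n_sites, len(cols)), dtype=np.int8)
            plain = ~in_sweep
            if g.inbreeding_f == 0:
                exact = plain & (cnt > 0)
                if exact.any():
                    base[exact] = _place_exact(rng, cnt[exact], n_chrom)
            else:
                seg = plain & (p_freq > 0)
                if seg.any():
                    base[seg] = _draw_hwe_f(rng, p_freq[seg], len(cols), g.inbreeding_f)
            if in_sweep.any():
                for s in sweeps:
                    reg = (all_pos - 1 >= s.start) & (all_pos - 1 < s.end)
                    m = reg & (p_freq > 0)
                    if m.any():
                        f_eff = min(1.0, max(g.inbreeding_f, 1 - s.diversity_scale))
                        base[m] = _draw_hwe_f(rng, p_freq[m], len(cols), f_eff)
                    fixed = reg & (p_freq >= 1)
                    base[fixed] = 2
            geno[:, cols] = base

        geno_blocks.append(geno)
        ref_i = rng.integers(0, 4, n_sites)
        alt_i = (ref_i + rng.integers(1, 4, n_sites)) % 4
        info, n_bad = _info_fields(rng, n_sites, config.filter_fail_rate)
        truth.n_filter_violations += n_bad
        frame = pd.DataFrame(
            {
                "scaffold": scaf,
                "pos": all_pos,
                "ref": bases[ref_i],
                "alt": bases[alt_i],
            }
        )
        for k, key in enumerate(INFO_KEYS):
            frame[key] = info[:, k]
        frame["origin_group"] = origin
        site_frames.append(frame)

    sites = pd.concat(site_frames, ignore_index=True) if site_frames else pd.DataFrame(columns=SITE_COLUMNS)
    geno = np.vstack(geno_blocks) if geno_blocks else np.empty((0, n_total), dtype=np.int8)
    gm = GenotypeMatrix(
        sites=sites,
        samples=samples["sample"].tolist(),
        geno=geno,
        scaffold_lengths=config.scaffold_lengths(),
    )

    _apply_relatedness(rng, gm, config, group_cols, samples)
    _apply_roh(rng, gm, config)
    return gm, samples, truth


def _apply_relatedness(rng, gm, config, group_cols, samples):
    """Overwrite planted relatives with Mendelian draws from (latent) parents."""
    sample_group = dict(zip(samples["sample"], samples["group"]))
    freqs_by_group = {}
    for g in config.groups:
        freqs_by_group[g.name] = gm.alt_freq(group_cols[g.name])

    def latent(group_name):
        p = np.nan_to_num(freqs_by_group[group_name])
        return _draw_hwe_f(rng, p, 1, 0.0)[:, 0]

    for rp in config.related_pairs:
        ga = sample_group[rp.id_a]
        ia, ib = gm.sample_index(rp.id_a), gm.sample_index(rp.id_b)
        if rp.kind == "parent_offspring":
            parent = gm.geno[:, ia]
            other = latent(ga)
            gm.geno[:, ib] = _gamete(rng, parent) + _gamete(rng, other)
        elif rp.kind == "full_sib":
            p1, p2 = latent(ga), latent(ga)
            gm.geno[:, ia] = _gamete(rng, p1) + _gamete(rng, p2)
            gm.geno[:, ib] = _gamete(rng, p1) + _gamete(rng, p2)
        elif rp.kind == "half_sib":
            shared, o1, o2 = latent(ga), latent(ga), latent(ga)
            gm.geno[:, ia] = _gamete(rng, shared) + _gamete(rng, o1)
            gm.geno[:, ib] = _gamete(rng, shared) + _gamete(rng, o2)
        else:
            raise SimConfigError(f"unknown relationship kind {rp.kind!r}")


def _apply_roh(rng, gm, config):
    """Force homozygosity inside planted ROH blocks (one allele drawn, doubled)."""
    if not config.roh_blocks:
        return
    scafs = gm.sites["scaffold"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    freqs = gm.alt_freq()
    for blk in config.roh_blocks:
        j = gm.sample_index(blk.sample)
        m = (scafs == blk.scaffold) & (pos0 >= blk.start) & (pos0 < blk.end)
        p = np.nan_to_num(freqs[m])
        allele = (rng.random(int(m.sum())) < p).astype(np.int8)
        gm.geno[m, j] = 2 * allele


# ---------------------------------------------------------------------------
# Depth profiles


def simulate_depth_profiles(config: SimConfig, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-sample per-scaffold mean depth, truncated-Normal around
    coverage_mean x copy ratio (CV = ``depth_cv``).

    Copy ratios: autosomes 1 both sexes; Z 1 in males / 0.5 in females;
    W 0 in males / 0.5 in females.
    """
    sexes = samples["sex"]
    if not {"M", "F"} <= set(sexes):
        raise SimConfigError("need at least one male and one female for depth design")
    rng = config.rng(_STAGE_DEPTH)
    sd = config.sex_design
    ratios = {
        ("autosome", "M"): 1.0,
        ("autosome", "F"): 1.0,
        ("Z", "M"): sd.z_ratio_male,
        ("Z", "F"): sd.z_ratio_female,
        ("W", "M"): sd.w_ratio_male,
        ("W", "F"): sd.w_ratio_female,
    }
    rows = []
    for _, srow in samples.iterrows():
        for scaf, cls in config.scaffold_names().items():
            mean = config.coverage_mean * ratios[(cls, srow["sex"])]
            d = max(0.0, rng.normal(mean, config.depth_cv * mean)) if mean > 0 else 0.0
            rows.append({"sample": srow["sample"], "scaffold": scaf, "mean_depth": d})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# STR table


def simulate_str_table(config: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """STR genotype table under a stepwise model (allele length = unit x k).

    Autosomal loci segregate in both sexes; W-linked loci are emitted as two
    equal allele lengths in females (hemizygous, recorded homozygous) and
    missing in males.  Planted kinship loci (4-bp unit, >=5 alleles,
    complete calls) are recorded in ``truth.kinship_strs``; all W-linked
    female-restricted loci go to ``truth.sex_marker_strs``.

    Columns: locus_id, scaffold, pos, unit, then one ``a1/a2`` (or ``./.``)
    column per sample.
    """
    for u in config.str_design.unit_lengths:
        if u not in (2, 3, 4, 5, 6):
            raise SimConfigError(f"STR unit length {u} outside 2..6")
    rng = config.rng(_STAGE_STR)
    des = config.str_design
    classes = config.scaffold_names()
    sample_ids = list(truth.sample_sexes)
    sexes = truth.sample_sexes
    lo, hi = des.n_alleles_range
    rows = []
    counter = 1

    def spectrum(unit, k):
        k0 = rng.integers(3, 10)
        lengths = unit * (k0 + np.arange(k))
        w = rng.dirichlet(np.ones(k) * 2.0)
        return lengths, w

    for scaf, cls in classes.items():
        if cls == "Z":
            continue
        n_loci = des.n_autosomal_loci if cls == "autosome" else des.n_w_loci
        n_kin = des.n_kinship_loci if cls == "autosome" else 0
        pos = np.sort(rng.integers(1, config.scaffold_length, n_loci + n_kin))
        for li in range(n_loci + n_kin):
            planted_kin = cls == "autosome" and li >= n_loci
            if planted_kin:
                unit = 4
                k = int(rng.integers(5, hi + 1))
            else:
                unit = int(rng.choice(list(des.unit_lengths)))
                k = int(rng.integers(lo, hi + 1))
            lengths, w = spectrum(unit, k)
            locus_id = f"STR_{counter:04d}"
            counter += 1
            row = {"locus_id": locus_id, "scaffold": scaf, "pos": int(pos[li]), "unit": unit}
            if cls == "W":
                for s in sample_ids:
                    if sexes[s] == "M":
                        row[s] = "./."
                    else:
                        a = int(rng.choice(lengths, p=w))
                        row[s] = f"{a}/{a}"
                truth.sex_marker_strs.append(locus_id)
            else:
                miss_rate = 0.0 if planted_kin else 0.05
                for s in sample_ids:
                    if rng.random() < miss_rate:
                        row[s] = "./."
                    else:
                        a1 = int(rng.choice(lengths, p=w))
                        a2 = int(rng.choice(lengths, p=w))
                        row[s] = f"{min(a1, a2)}/{max(a1, a2)}"
                if planted_kin:
                    # guarantee >=5 distinct observed alleles
                    seen = {int(x) for s in sample_ids for x in row[s].split("/")}
                    need = [int(x) for x in lengths if int(x) not in seen]
                    si = 0
                    while len(seen) < 5 and need:
                        a = need.pop(0)
                        other = int(row[sample_ids[si]].split("/")[1])
                        row[sample_ids[si]] = f"{min(a, other)}/{max(a, other)}"
                        seen.add(a)
                        si += 1
                    truth.kinship_strs.append(locus_id)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Effect labels


def simulate_effect_labels(config: SimConfig, gm: GenotypeMatrix) -> pd.DataFrame:
    """Assign each site one effect category from the configured multinomial.

    ``config.effect_mix`` is either one category->proportion dict applied to
    all sites, or a per-group dict of such dicts keyed by group name; in the
    per-group form each site draws from the mix of its origin group (the
    group it segregates in), which is how group differences in deleterious
    load are planted.

    Returns a DataFrame (scaffold, pos, category); empty matrix gives an
    empty table.
    """
    mixes = config.effect_mix
    per_group = mixes and isinstance(next(iter(mixes.values())), dict)
    for mix in (mixes.values() if per_group else [mixes]):
        tot = sum(mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise SimConfigError(f"effect mix sums to {tot}, not 1")
    rng = config.rng(_STAGE_EFFECT)
    if gm.n_sites == 0:
        return pd.DataFrame(columns=["scaffold", "pos", "category"])

    out = np.empty(gm.n_sites, dtype=object)
    if per_group:
        origin = gm.sites["origin_group"].to_numpy()
        for grp, mix in mixes.items():
            sel = np.flatnonzero(origin == grp)
            cats = list(mix)
            p = np.array([mix[c] for c in cats])
            draw = rng.choice(len(cats), size=len(sel), p=p / p.sum())
            out[sel] = [cats[i] for i in draw]
        missing = out == None  # noqa: E711 -- object array sentinel check
        if missing.any():
            raise SimConfigError("per-group effect_mix lacks a group present in the data")
    else:
        cats = list(mixes)
        p = np.array([mixes[c] for c in cats])
        draw = rng.choice(len(cats), size=gm.n_sites, p=p / p.sum())
        out[:] = [cats[i] for i in draw]
    return pd.DataFrame(
        {
            "scaffold": gm.sites["scaffold"].to_numpy(),
            "pos": gm.sites["pos"].to_numpy(),
            "category": out,
        }
    )


# ---------------------------------------------------------------------------
# Quartet frequencies for gene-flow testing


def simulate_quartet(
    seed: int,
    n_sites: int = 20_000,
    n_per_pop: int = 5,
    drift: float = 0.15,
    introgression: float = 0.0,
):
    """Four-population genotype matrix for ABBA-BABA testing.

    Allele frequencies drift along the asymmetric tree (((P1,P2),P3),O)
    under the Balding-Nichols model: each branch draws
    Beta(p(1-F)/F, (1-p)(1-F)/F) around its parent frequency, with
    F = ``drift`` per internal/tip branch (P3 and the outgroup get deeper
    divergence, 2F and 3F).  With ``introgression`` m > 0, a random
    fraction m of sites in P2 adopt P3's frequency (gene flow P3 -> P2),
    which produces D > 0 for the (P1, P2, P3, O) ordering used throughout.

    Returns (GenotypeMatrix, pops dict name -> sample id list).
    """
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, n_sites)

    def bn(p, f):
        return np.clip(rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f), 0.01, 0.99)

    p12 = bn(anc, drift)
    p1, p2 = bn(p12, drift), bn(p12, drift)
    p3 = bn(anc, min(2 * drift, 0.9))
    p4 = bn(anc, min(3 * drift, 0.9))
    if introgression > 0:
        m = rng.random(n_sites) < introgression
        p2 = np.where(m, p3, p2)

    pops = {}
    genos = []
    for name, p in (("P1", p1), ("P2", p2), ("P3", p3), ("OUT", p4)):
        pops[name] = [f"{name}_{k}" for k in range(n_per_pop)]
        genos.append(_draw_hwe_f(rng, p, n_per_pop, 0.0))
    geno = np.hstack(genos)
    sites = pd.DataFrame(
        {
            "scaffold": "scaffold_1",
            "pos": np.arange(1, n_sites + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    for k in INFO_KEYS:
        sites[k] = np.nan
    gm = GenotypeMatrix(
        sites=sites,
        samples=[s for v in pops.values() for s in v],
        geno=geno,
        scaffold_lengths={"scaffold_1": (n_sites + 1) * 100},
    )
    return gm, pops


# ---------------------------------------------------------------------------
# Table I/O helpers (TSV with header; plumbing for the pipeline stage)


def write_tables(outdir, gm, samples, truth, depth=None, strs=None, effects=None):
    """Write the full synthetic input bundle (VCF + TSVs + truth JSON)."""
    from pathlib import Path
    from .vario import write_vcf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(gm, out / "cohort.vcf")
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    if depth is not None:
        depth.to_csv(out / "depth.tsv", sep="\t", index=False)
    if strs is not None:
        strs.to_csv(out / "strs.tsv", sep="\t", index=False)
    if effects is not None:
        effects.to_csv(out / "effects.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
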