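"""Synthetic genotypes, trait architectures, reflectance, and field trials.

The generator emulates the statistical structure of a multi-environment
winter-wheat programme: a diversity training panel of ~450 inbred lines
scored at ~11,000 independent biallelic markers (MAF above 0.05), grain
yield with low entry-mean heritability, five spectral reflectance indices
at three growth stages with low-to-moderate heritability and moderate
genetic correlation with yield (negative for the water index), and an
augmented block design — replicated checks in every block, un-replicated
entries — across several environments with genotype-by-environment
interaction.

Traits follow an infinitesimal model: yield marker effects are i.i.d.
normal; each index's effects are u_x = r_G * u_y + sqrt(1 - r_G^2) * u_x'
with independent u_x', giving the target genetic correlation in
expectation. Breeding values are centered-dosage x effects, rescaled to
the trait's genotypic SD. Phenotype noise is sized from the target
entry-mean heritability via H2 = s2_G / (s2_G + s2_GEI/n + s2_eps/(n r)).

Test panels diverge from the training panel through one ``relatedness``
knob in [0, 1]: founder allele frequencies are blended toward an
independent pool and marker effects are correlated at ``relatedness``, so
both the allele-frequency distance and the cross-panel predictive signal
shrink together as relatedness drops.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` children, so each sub-stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenotypeMatrix,
    SpectralRecord,
    TrialTable,
    write_genotype_matrix,
    write_reflectance_table,
    write_trial_table,
)
from .sri import INDEX_BANDS


@dataclass
class TraitSpec:
    """Architecture of one simulated trait (yield or an index at a stage)."""

    name: str
    mean: float
    sigma_g: float           # genotypic SD on the trait scale
    h2: float                # target entry-mean heritability
    r_G: float = 1.0         # genetic correlation with yield (yield itself: 1)
    stage: str | None = None
    # explicit variance components override the h2-derived ones when set
    sigma2_GEI: float | None = None
    sigma2_eps: float | None = None

    def components(self, n_env: int, gei_fraction: float) -> tuple[float, float, float]:
        s2g = self.sigma_g**2
        if self.sigma2_GEI is not None and self.sigma2_eps is not None:
            return s2g, self.sigma2_GEI, self.sigma2_eps
        if not (0 < self.h2 < 1):
            raise ValueError(f"heritability must lie in (0,1), got {self.h2}")
        total = n_env * s2g * (1.0 / self.h2 - 1.0)  # s2_GEI + s2_eps, r = 1
        return s2g, gei_fraction * total, (1.0 - gei_fraction) * total


@dataclass
class SimScenario:
    """Study conditions for one simulated experiment."""

    seed: int = 0
    n_train: int = 456
    n_test: dict = field(default_factory=dict)   # panel name -> size
    m: int = 11089
    maf_range: tuple = (0.05, 0.5)
    dh: bool = True                              # fully homozygous lines
    yield_trait: TraitSpec = field(
        default_factory=lambda: TraitSpec("yield", mean=5.0, sigma_g=0.4, h2=0.19))
    index_traits: list = field(default_factory=list)
    n_env: int = 4
    blocks_per_env: int = 24
    checks: tuple = ("CHK1", "CHK2")
    gei_fraction: float = 0.4
    sigma2_block: float = 0.1                    # block-effect variance
    #: markers per linkage block (1 = independent loci); blocks share a
    #: latent founder haplotype, giving the within-block correlation that
    #: LD-kNN imputation exploits
    ld_block_size: int = 1
    ld_flip_prob: float = 0.02
    relatedness: dict = field(default_factory=dict)   # panel name -> [0, 1]
    test_h2: dict = field(default_factory=dict)       # panel name -> yield h2
    test_n_env: int = 1
    band_noise_sd: float = 0.01

    def __post_init__(self):
        if abs(self.yield_trait.r_G - 1.0) > 1e-12:
            raise ValueError("yield's genetic self-correlation must be 1")
        for t in self.index_traits:
            if not (-1 <= t.r_G <= 1):
                raise ValueError(f"|r_G| must be <= 1 for {t.name}")


@dataclass
class SimBundle:
    scenario: SimScenario
    g_train: GenotypeMatrix
    g_test: dict
    bv: dict            # panel -> DataFrame (lines x traits) of breeding values
    trials: dict        # panel -> {trait key -> TrialTable}
    reflectance: dict   # panel -> list[SpectralRecord]
    effects: dict       # trait key -> marker-effect vector (training panel)


def _rng(seed: int, *path: str) -> np.random.Generator:
    """Named child stream: the same (seed, path) always yields the same rng."""
    ints = [int.from_bytes(p.encode(), "little") % (2**32) for p in path]
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), *ints]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _draw_panel(freqs: np.ndarray, n: int, dh: bool, line_prefix: str,
                rng: np.random.Generator, ld_block_size: int = 1,
                ld_flip_prob: float = 0.02) -> GenotypeMatrix:
    m = freqs.size
    if ld_block_size > 1:
        # markers within a block copy a latent haplotype up to a small flip
        # probability, so neighbouring markers are strongly correlated
        n_blocks = int(np.ceil(m / ld_block_size))
        block_of = np.repeat(np.arange(n_blocks), ld_block_size)[:m]
        block_freq = np.array([freqs[block_of == b][0] for b in range(n_blocks)])

        def draw_haplotype():
            latent = (rng.random((n, n_blocks)) < block_freq[None, :]).astype(np.int8)
            alleles = latent[:, block_of]
            flips = rng.random((n, m)) < ld_flip_prob
            return np.where(flips, 1 - alleles, alleles)
        if dh:
            dosage = 2 * draw_haplotype()
        else:
            dosage = draw_haplotype() + draw_haplotype()
    elif dh:
        dosage = 2 * rng.binomial(1, freqs[None, :], size=(n, m))
    else:
        dosage = rng.binomial(2, freqs[None, :], size=(n, m))
    return GenotypeMatrix(
        line_ids=np.array([f"{line_prefix}{i:04d}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"M{j:05d}" for j in range(freqs.size)], dtype=object),
        dosage=dosage.astype(np.int8),
        chrom=np.array(["1"] * freqs.size, dtype=object),
        pos=np.arange(1, freqs.size + 1),
    )


def simulate_genotypes(scenario: SimScenario) -> tuple[GenotypeMatrix, dict]:
    """Training panel plus test panels sharing (part of) the founder pool."""
    lo, hi = scenario.maf_range
    if not (0 <= lo < hi <= 0.5):
        raise ValueError(f"infeasible maf_range {scenario.maf_range}")
    rng = _rng(scenario.seed, "genotypes")
    p_train = rng.uniform(lo, hi, size=scenario.m)
    g_train = _draw_panel(p_train, scenario.n_train, scenario.dh, "DP", rng,
                          scenario.ld_block_size, scenario.ld_flip_prob)
    g_test = {}
    for panel, n in scenario.n_test.items():
        rel = scenario.relatedness.get(panel, 1.0)
        rng_p = _rng(scenario.seed, "genotypes", panel)
        p_new = rng_p.uniform(0.05, 0.95, size=scenario.m)
        p_panel = np.clip(rel * p_train + (1.0 - rel) * p_new, 0.01, 0.99)
        g_test[panel] = _draw_panel(p_panel, n, scenario.dh, panel, rng_p,
                                    scenario.ld_block_size, scenario.ld_flip_prob)
    return g_train, g_test


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def _trait_key(t: TraitSpec) -> str:
    return t.name if t.stage is None else f"{t.name}:{t.stage}"


def simulate_traits(g: GenotypeMatrix, scenario: SimScenario,
                    effects: dict | None = None,
                    effect_correlation: float = 1.0):
    """True breeding values per trait for the lines of ``g``.

    When ``effects`` from the training panel are passed with
    ``effect_correlation`` rho < 1, each trait's effect vector is blended
    with fresh effects (rho*u + sqrt(1-rho^2)*u_new), modelling a test
    panel whose genetic architecture only partly overlaps the trainer's.
    Returns (breeding-value DataFrame, raw effect vectors).
    """
    rng = _rng(scenario.seed, "effects")
    traits = [scenario.yield_trait] + list(scenario.index_traits)
    if effects is None:
        u_y = rng.standard_normal(scenario.m)
        effects = {}
        for t in traits:
            if t.name == "yield":
                effects[_trait_key(t)] = u_y
            else:
                u_ind = rng.standard_normal(scenario.m)
                effects[_trait_key(t)] = t.r_G * u_y + np.sqrt(1 - t.r_G**2) * u_ind
    rho = effect_correlation
    if rho < 1.0:
        rng_new = _rng(scenario.seed, "effects", "panel", f"{rho:.6f}")
        u_y_new = rng_new.standard_normal(scenario.m)
        blended = {}
        for t in traits:
            key = _trait_key(t)
            if t.name == "yield":
                u_new = u_y_new
            else:
                u_new = t.r_G * u_y_new + np.sqrt(1 - t.r_G**2) * rng_new.standard_normal(scenario.m)
            blended[key] = rho * effects[key] + np.sqrt(1 - rho**2) * u_new
        effects = blended
    d = g.dosage_float()
    M = d - np.nanmean(d, axis=0)[None, :]
    bv = {}
    for t in traits:
        key = _trait_key(t)
        raw = M @ effects[key]
        sd = raw.std()
        bv[key] = raw / sd * t.sigma_g if sd > 0 else raw
    return pd.DataFrame(bv, index=list(g.line_ids)), effects


# ---------------------------------------------------------------------------
# field trials
# ---------------------------------------------------------------------------


def simulate_trial(bv: pd.Series, scenario: SimScenario, trait: TraitSpec,
                   panel: str = "DP", n_env: int | None = None) -> TrialTable:
    """One augmented trial for one trait: checks replicated once per block,
    entries un-replicated, block and GEI and residual noise added."""
    n_env = scenario.n_env if n_env is None else n_env
    s2g, s2ge, s2e = trait.components(n_env, scenario.gei_fraction)
    key = _trait_key(trait)
    rng = _rng(scenario.seed, "trial", panel, key, str(n_env))
    # field layout is a property of the panel, not the trait: every trait
    # is scored on the same plots, as in a real multi-trait trial
    layout_rng = _rng(scenario.seed, "layout", panel, str(n_env))
    entries = list(bv.index)
    n_blocks = max(scenario.blocks_per_env, 1)
    check_bv = {c: rng.normal(0.0, trait.sigma_g) for c in scenario.checks}
    rows = []
    for e in range(n_env):
        env = f"E{e + 1}"
        order = layout_rng.permutation(len(entries))
        block_of = np.array_split(order, n_blocks)
        ge = rng.normal(0.0, np.sqrt(s2ge), size=len(entries))
        ge_chk = {c: rng.normal(0.0, np.sqrt(s2ge)) for c in scenario.checks}
        benv = rng.normal(0.0, np.sqrt(scenario.sigma2_block), size=n_blocks)
        for b, idxs in enumerate(block_of):
            block = f"B{b + 1:02d}"
            for i in idxs:
                val = (trait.mean + bv.iloc[i] + ge[i] + benv[b]
                       + rng.normal(0.0, np.sqrt(s2e)))
                rows.append((entries[i], env, block, False, "", val))
            for c in scenario.checks:
                val = (trait.mean + check_bv[c] + ge_chk[c] + benv[b]
                       + rng.normal(0.0, np.sqrt(s2e)))
                rows.append((f"{c}@{env}:{block}", env, block, True, c, val))
    df = pd.DataFrame(rows, columns=["entry_id", "environment_id", "block_id",
                                     "is_check", "check_id", "value"])
    return TrialTable(df, response=key)


# ---------------------------------------------------------------------------
# reflectance synthesis
# ---------------------------------------------------------------------------

_BAND_ORDER = (800, 700, 750, 680, 900, 970)


def synthesize_reflectance(index_trials: dict, scenario: SimScenario,
                           panel: str = "DP") -> list[SpectralRecord]:
    """Invert the index formulas into per-plot band reflectances.

    Per plot and stage the five simulated index values determine the six
    bands given an anchor R800 = 0.5; Gaussian band noise (SD
    ``band_noise_sd``) is added and bands are clipped into (0, 1), so
    recomputed indices track the simulated values up to that noise.
    """
    rng = _rng(scenario.seed, "reflectance", panel)
    stages = sorted({t[1] for t in index_trials})
    records = []
    for stage in stages:
        frames = {}
        for (name, stg), trial in index_trials.items():
            if stg != stage:
                continue
            df = trial.data
            frames[name] = df.set_index(["entry_id", "environment_id", "block_id"])["value"]
        needed = set(INDEX_BANDS)
        if set(frames) != needed:
            continue  # band inversion needs all five indices at the stage
        plots = frames["NDVI"].index
        nd_clip = lambda v: float(np.clip(v, -0.95, 0.95))  # noqa: E731
        for key in plots:
            ndre1 = nd_clip(frames["NDRE1"].loc[key])
            ndre2 = nd_clip(frames["NDRE2"].loc[key])
            ndvi = nd_clip(frames["NDVI"].loc[key])
            nwi1 = nd_clip(frames["NWI1"].loc[key])
            sr = float(np.clip(frames["SR"].loc[key], 0.05, 50.0))
            r800 = 0.5
            bands = {
                800: r800,
                700: r800 * (1 - ndre1) / (1 + ndre1),
                750: r800 * (1 - ndre2) / (1 + ndre2),
                680: r800 * (1 - ndvi) / (1 + ndvi),
            }
            bands[900] = sr * bands[680]
            bands[970] = bands[900] * (1 + nwi1) / (1 - nwi1)
            noisy = {}
            for nm in _BAND_ORDER:
                v = bands[nm] + rng.normal(0.0, scenario.band_noise_sd)
                noisy[nm] = float(np.clip(v, 1e-3, 0.999))
            records.append(SpectralRecord(plot_key=key, stage=stage, reflectance=noisy))
    return records


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# index architecture patterned on the training panel's reported summaries:
# (index, stage, mean, H2, r_G with yield, genotypic SD)
_TABLE1_ARCHITECTURE = [
    ("NDRE1", "Hd", 0.75, 0.26, 0.64, 0.045),
    ("NDRE1", "Gf1", 0.71, 0.63, 0.65, 0.043),
    ("NDRE1", "Gf2", 0.51, 0.30, 0.59, 0.031),
    ("NDRE2", "Hd", 0.14, 0.42, 0.65, 0.020),
    ("NDRE2", "Gf1", 0.13, 0.53, 0.65, 0.020),
    ("NDRE2", "Gf2", 0.10, 0.30, 0.58, 0.020),
    ("NDVI", "Hd", 0.83, 0.24, 0.64, 0.050),
    ("NDVI", "Gf1", 0.80, 0.52, 0.66, 0.048),
    ("NDVI", "Gf2", 0.63, 0.37, 0.58, 0.038),
    ("NWI1", "Hd", -0.08, 0.23, -0.51, 0.020),
    ("NWI1", "Gf1", -0.07, 0.16, -0.42, 0.020),
    ("NWI1", "Gf2", -0.06, 0.26, -0.58, 0.020),
    ("SR", "Hd", 18.61, 0.41, 0.67, 1.12),
    ("SR", "Gf1", 15.81, 0.55, 0.57, 0.95),
    ("SR", "Gf2", 7.24, 0.31, 0.57, 0.43),
]

PRESETS = ("table1_like", "cv_like", "independent_like")


def _index_specs(subset: set | None = None) -> list[TraitSpec]:
    specs = []
    for name, stage, mean, h2, r_g, sigma_g in _TABLE1_ARCHITECTURE:
        if subset is not None and name not in subset:
            continue
        specs.append(TraitSpec(name=name, stage=stage, mean=mean, sigma_g=sigma_g,
                               h2=h2, r_G=r_g))
    return specs


def make_scenario(preset: str, seed: int, **overrides) -> SimScenario:
    if preset == "table1_like":
        sc = SimScenario(seed=seed, index_traits=_index_specs())
    elif preset == "cv_like":
        sc = SimScenario(
            seed=seed,
            index_traits=[t for t in _index_specs({"NDVI", "NWI1", "SR"})
                          if t.stage == "Gf1"],
        )
    elif preset == "independent_like":
        sc = SimScenario(
            seed=seed,
            n_test={"DH": 449, "F5": 501},
            relatedness={"DH": 0.7, "F5": 0.4},
            test_h2={"DH": 0.55, "F5": 0.14},
            index_traits=[t for t in _index_specs({"NDVI", "NWI1", "SR"})
                          if t.stage == "Gf1"],
        )
    else:
        raise ValueError(f"unknown preset {preset!r}; known: {PRESETS}")
    return replace(sc, **overrides) if overrides else sc


def generate_scenario(preset: str, seed: int, out_dir=None,
                      **overrides) -> SimBundle:
    """Full bundle for a preset: genotypes, breeding values, trials,
    reflectance; optionally written to ``out_dir`` as VCF + CSV fixtures
    (byte-identical for identical (preset, seed))."""
    scenario = make_scenario(preset, seed, **overrides)
    g_train, g_test = simulate_genotypes(scenario)
    bv_train, effects = simulate_traits(g_train, scenario)
    bv = {"DP": bv_train}
    trials = {"DP": {}}
    for t in [scenario.yield_trait] + list(scenario.index_traits):
        key = _trait_key(t)
        trials["DP"][key] = simulate_trial(bv_train[key], scenario, t, panel="DP")
    reflectance = {}
    if scenario.index_traits:
        idx_trials = {(t.name, t.stage): trials["DP"][_trait_key(t)]
                      for t in scenario.index_traits}
        reflectance["DP"] = synthesize_reflectance(idx_trials, scenario, panel="DP")
    for panel, g in g_test.items():
        rel = scenario.relatedness.get(panel, 1.0)
        h2 = scenario.test_h2.get(panel, scenario.yield_trait.h2)
        sc_panel = replace(scenario, yield_trait=replace(scenario.yield_trait, h2=h2))
        bv_panel, _ = simulate_traits(g, sc_panel, effects=effects,
                                      effect_correlation=rel)
        bv[panel] = bv_panel
        trials[panel] = {}
        for t in [sc_panel.yield_trait] + list(sc_panel.index_traits):
            key = _trait_key(t)
            trials[panel][key] = simulate_trial(
                bv_panel[key], sc_panel, t, panel=panel, n_env=scenario.test_n_env)
    bundle = SimBundle(scenario=scenario, g_train=g_train, g_test=g_test,
                       bv=bv, trials=trials, reflectance=reflectance,
                       effects=effects)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: SimBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_matrix(bundle.g_train, out / "geno_DP.vcf", "vcf")
    for panel, g in bundle.g_test.items():
        write_genotype_matrix(g, out / f"geno_{panel}.vcf", "vcf")
    for panel, tset in bundle.trials.items():
        for key, trial in tset.items():
            safe = key.replace(":", "_")
            write_trial_table(trial, out / f"trial_{panel}_{safe}.csv")
    for panel, recs in bundle.reflectance.items():
        write_reflectance_table(recs, out / f"reflectance_{panel}.csv")
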