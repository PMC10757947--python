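"""Synthetic leaf-lipidome generator with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
54-genotype x 2-treatment (OT/HT) x 2-run x 3-block factorial with
recurrent QC-pool samples; ~190 species across the headgroup classes with
galactolipid-dominated composition (MGDG ~49%, DGDG ~29% of total signal
at OT); multiplicative heat effects (18:3-containing diacyl membrane
species down 0.53-0.75x, 18:3-containing TGs up 1.9-2.2x, sterol esters
up 2.5-5.4x, sterol glycosides up slightly, oxidized and acylated-sterol
species down); per-genotype tolerance g_i in [0,1] scaling every HT
multiplier M to M**g_i; lognormal measurement noise; and planted QC
violations whose removal is checkable exactly.

Everything random flows from one seed; identical config + seed gives a
bit-identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_qc import DEFAULT_LOD, LipidomeTable
from .markers import GenomeLayout
from .nomenclature import AcylChain, LipidSpecies, contains_chain, parse_species

__all__ = [
    "RemodelConfig",
    "GroundTruth",
    "default_roster",
    "default_class_shares",
    "generate_lipidome",
    "generate_markers",
]

_CHAIN_183 = AcylChain(18, 3, 0)

#: default OT composition shares per headgroup class (fraction of total
#: signal); galactolipids dominate the leaf lipidome
_DEFAULT_SHARES = {
    "MGDG": 0.49, "DGDG": 0.29, "PC": 0.075, "PE": 0.04, "PG": 0.035,
    "PI": 0.02, "SQDG": 0.012, "PA": 0.006, "PS": 0.004, "DG": 0.008,
    "TG": 0.008, "SE": 0.002, "SG": 0.002, "ASG": 0.003,
    "LPC": 0.001, "LPE": 0.001, "MGMG": 0.0005, "DGMG": 0.0005,
    "TrGDG": 0.0005, "acMGDG": 0.0005, "PE-N": 0.0005, "GSL": 0.0005,
}

#: HT/OT multiplier ranges per effect rule (uniform draws)
_DEFAULT_MULTIPLIERS = {
    "membrane_18:3": (0.53, 0.75),
    "tg_18:3": (1.9, 2.2),
    "se": (2.5, 5.4),
    "sg": (1.05, 1.4),
    "ox": (0.4, 0.8),
    "asg": (0.4, 0.9),
    "neutral": (0.9, 1.1),
}

_ROSTER: dict[str, list[str]] = {
    "MGDG": ["18:3_18:3", "18:3_16:0", "18:3_18:2", "18:2_16:0", "18:2_18:2",
             "18:1_18:2", "16:0_18:1", "18:0_18:3", "20:1_18:3", "17:0_18:3",
             "34:4", "36:5", "34:1", "36:3", "34:2", "36:2", "36:1",
             "18:3_18:4;O", "16:0_18:3;O", "18:3_18:3;O", "18:2_18:3;O",
             "16:0_18:2;O"],
    "DGDG": ["18:3_18:3", "18:3_16:0", "18:3_16:1", "18:3_18:2", "16:0_18:2",
             "18:2_18:2", "18:0_18:3", "18:1_18:2", "16:0_18:1", "20:1_18:3",
             "20:2_18:3", "20:3_18:3", "36:5", "34:1", "36:2", "34:4", "36:1",
             "16:0_18:3;O", "18:3_18:3;O", "18:2_18:3;O", "18:3_18:4;O",
             "16:0_18:2;O", "18:3_18:2;O", "18:2_18:2;O", "16:0_18:4;O",
             "18:0_18:3;O", "18:1_18:3;O", "18:2_18:4;O", "16:1_18:3;O"],
    "SQDG": ["16:0_18:3", "18:3_18:3", "16:0_18:2", "16:0_16:0", "34:1",
             "32:0", "34:2", "16:0_18:4;O"],
    "PG": ["18:3_16:1", "18:2_16:1", "16:0_18:3", "16:0_18:2", "16:0_18:1",
           "18:0_18:3", "16:0_16:1", "18:1_16:1", "34:1", "32:0", "34:2"],
    "PC": ["16:0_18:3", "18:3_18:3", "18:2_18:3", "16:0_18:2", "18:2_18:2",
           "18:1_18:2", "16:0_18:1", "18:0_18:2", "18:1_18:3", "18:0_18:3",
           "18:2_20:0", "18:2_22:0", "18:2_22:1", "18:2_22:2", "18:2_20:1",
           "34:3", "36:4", "34:1", "36:2",
           "16:0_18:3;O", "18:2_18:3;O", "18:3_18:3;O", "16:0_18:2;O"],
    "PE": ["16:0_18:3", "18:2_18:3", "18:3_18:3", "16:0_18:2", "18:2_18:2",
           "18:1_18:2", "18:0_18:2", "16:0_18:1", "18:2_20:0", "18:2_20:2",
           "18:2_20:3", "18:2_22:0", "18:2_24:0", "18:2_24:1", "34:1", "34:2",
           "16:0_18:3;O", "18:2_18:3;O", "16:0_18:2;O"],
    "PI": ["16:0_18:3", "16:0_18:2", "18:2_18:3", "18:0_18:2", "18:1_18:2",
           "16:0_18:1", "18:3_18:3", "34:1", "36:5", "32:0", "34:2"],
    "PS": ["16:0_18:2", "18:0_18:2", "18:2_22:1", "18:2_24:0", "16:0_18:3",
           "42:2", "40:2", "34:1"],
    "PA": ["16:0_18:3", "18:3_18:3", "16:0_18:2", "18:2_18:2", "16:0_18:1",
           "18:2_18:3", "34:1", "36:5"],
    "LPC": ["16:0", "18:2", "18:3"],
    "LPE": ["16:0", "18:2", "18:3"],
    "MGMG": ["18:3", "16:0"],
    "DGMG": ["18:3", "16:0"],
    "TrGDG": ["36:6", "34:3"],
    "acMGDG": ["16:0_18:3_18:3", "18:3_18:3_18:3", "52:7"],
    "PE-N": ["42:2", "40:2"],
    "DG": ["18:3_18:3", "16:0_18:3", "18:2_18:3", "16:0_18:2", "18:2_18:2",
           "16:0_18:1", "34:1"],
    "TG": ["18:3_18:3_18:3", "18:3_18:3_18:2", "18:2_18:3_18:2",
           "16:0_18:3_18:3", "16:0_18:3_18:2", "18:2_18:2_18:2",
           "16:0_18:2_18:2", "16:0_16:0_18:2", "18:1_18:2_18:2",
           "16:0_18:1_18:2", "52:3", "54:5", "54:4"],
    "GSL": ["40:1;O2", "42:2;O2"],
}


def default_roster() -> list[str]:
    """The default ~190-species roster, generated from the classes and
    acyl chains reported for heat-stressed peanut leaves (representative,
    not an exact reproduction of any one study's analyte list)."""
    names: list[str] = []
    for cls, comps in _ROSTER.items():
        names += [f"{cls} {c}" for c in comps]
    names += ["sitosterol 18:2", "sitosterol 18:3"]                     # SE
    names += [f"{s.capitalize()}-Glc"
              for s in ("sitosterol", "stigmasterol", "campesterol")]   # SG
    names += [f"{s.capitalize()}-Glc {c}"
              for s in ("sitosterol", "stigmasterol", "campesterol")
              for c in ("16:0", "18:2", "18:3")]                        # ASG
    return names


def default_class_shares() -> dict[str, float]:
    return dict(_DEFAULT_SHARES)


@dataclass(frozen=True)
class RemodelConfig:
    """Stated world of the generator; defaults mirror the experimental
    design and the reported effect magnitudes."""

    n_genotypes: int = 54
    n_runs: int = 2
    n_blocks: int = 3
    n_qc_pool: int = 8
    roster: tuple[str, ...] = field(default_factory=lambda: tuple(default_roster()))
    class_shares: tuple[tuple[str, float], ...] = field(
        default_factory=lambda: tuple(_DEFAULT_SHARES.items()))
    multiplier_ranges: tuple[tuple[str, tuple[float, float]], ...] = field(
        default_factory=lambda: tuple(_DEFAULT_MULTIPLIERS.items()))
    total_signal: float = 10.0        # grand-total signal/mg at OT
    dominant_weight: float = 0.6      # within-class weight of a leading di-18:3 species
    noise_sd: float = 0.15            # residual lognormal sd (log scale)
    # per-genotype global-abundance effect: small because signals are
    # normalized to internal standard and mg dry weight, which cancels most
    # genotype-level global variation
    genotype_sd: float = 0.02
    run_sd: float = 0.05
    block_sd: float = 0.05
    qc_cv: float = 0.10               # QC-pool coefficient of variation
    n_planted_cv: int = 3             # analytes planted with QC CV 0.5 (> 0.3)
    planted_cv: float = 0.5
    n_planted_lod: int = 2            # analytes planted below the LOD
    n_strong: int = 5                 # strong remodelers, g = 1 (full remodeling)
    n_weak: int = 5                   # weak remodelers, g = 0 (no response)
    # background genotypes draw g ~ U(0.3, 0.7): the planted strong/weak
    # groups are separated from the population, which is what makes
    # "programmed tolerant/susceptible" a recoverable ground-truth category
    g_values: Optional[tuple[float, ...]] = None  # explicit override

    def shares_dict(self) -> dict[str, float]:
        d = dict(self.class_shares)
        if abs(sum(d.values()) - 1.0) > 1e-9:
            raise ValueError("class shares must sum to 1")
        return d

    def multiplier_dict(self) -> dict[str, tuple[float, float]]:
        d = dict(self.multiplier_ranges)
        for lo, hi in d.values():
            if lo <= 0 or hi < lo:
                raise ValueError("multiplier ranges must be positive and ordered")
        return d


@dataclass
class GroundTruth:
    """Everything needed to verify parameter recovery on a generated table."""

    multipliers: pd.Series        # per-analyte programmed HT multiplier M
    effect_rule: pd.Series        # which multiplier rule produced M
    expected_fold: pd.Series      # population-level expected HT/OT ratio
    base_abundance: pd.Series     # per-analyte OT expectation (signal/mg)
    g: pd.Series                  # per-genotype tolerance parameter
    genotype_effects: pd.Series   # per-genotype log-scale abundance effect
    strong_genotypes: list[str]
    weak_genotypes: list[str]
    planted_cv: list[str]
    planted_lod: list[str]
    config: RemodelConfig
    seed: int


def _effect_rule(sp: LipidSpecies) -> str:
    """Map a species to its HT-multiplier rule."""
    cls = sp.headgroup.name
    if cls == "GSL":  # sphingolipid oxygens are structural, not ox-lipid marks
        return "neutral"
    if sp.total_extra_oxygens > 0:
        return "ox"
    if cls == "SE":
        return "se"
    if cls == "SG":
        return "sg"
    if cls == "ASG":
        return "asg"
    has_183 = False
    if sp.acyl_resolved and sp.chains:
        has_183 = contains_chain(sp, _CHAIN_183)
    elif sp.headgroup.n_acyl_positions == 2 and sp.total_double_bonds == 6 \
            and sp.total_carbons == 36:
        has_183 = True  # 36:6 must be di-18:3 (each chain caps at 3 DB per 18 C)
    if cls == "TG":
        return "tg_18:3" if has_183 else "neutral"
    if sp.headgroup.is_membrane_diacyl and has_183:
        return "membrane_18:3"
    return "neutral"


def _within_class_weights(n: int, lead: bool, cfg: RemodelConfig) -> np.ndarray:
    """Fixed within-class species weights: optional dominant first species
    (the di-18:3 galactolipid) plus a harmonic (Zipf-like) tail, so even the
    rarest roster species stays well above the detection limit."""
    if n == 1:
        return np.ones(1)
    tail = 1.0 / (1.0 + np.arange(n - 1 if lead else n))
    tail = tail / tail.sum()
    if lead:
        return np.concatenate([[cfg.dominant_weight],
                               (1 - cfg.dominant_weight) * tail])
    return tail


def _standardized_pattern(n: int) -> np.ndarray:
    """Deterministic zero-mean, unit-sample-SD (ddof=1) vector used to plant
    exact QC CVs."""
    u = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
    if n % 2 == 1:
        u[-1] = 0.0
    u = u - u.mean()
    return u / u.std(ddof=1)


def generate_lipidome(config: Optional[RemodelConfig] = None,
                      seed: int = 0) -> tuple[LipidomeTable, GroundTruth]:
    """Generate a lipidome table plus its ground truth.

    amount(sample, analyte) = base(class share x species weight)
    x exp(genotype effect) x M ** (1[HT] * g_i) x exp(run + block effects)
    x lognormal noise; QC pools are drawn around the grand-mean composition
    with the configured CV; planted QC violations are injected last and
    hold exactly in the realized table.
    """
    cfg = config or RemodelConfig()
    rng = np.random.default_rng(seed)
    shares = cfg.shares_dict()
    mranges = cfg.multiplier_dict()

    species = {name: parse_species(name) for name in cfg.roster}
    by_class: dict[str, list[str]] = {}
    for name in cfg.roster:
        by_class.setdefault(species[name].headgroup.name, []).append(name)
    unknown = set(by_class) - set(shares)
    if unknown:
        raise ValueError(f"roster classes without a share: {sorted(unknown)}")

    analytes: list[str] = []
    base = []
    for cls, members in by_class.items():
        lead = (cls in ("MGDG", "DGDG")
                and species[members[0]].total_double_bonds == 6)
        w = _within_class_weights(len(members), lead, cfg)
        for name, wi in zip(members, w):
            analytes.append(name)
            base.append(cfg.total_signal * shares[cls] * wi)
    base = pd.Series(base, index=analytes, dtype=float)

    rule = pd.Series({a: _effect_rule(species[a]) for a in analytes})
    mult = pd.Series(
        {a: rng.uniform(*mranges[rule[a]]) for a in analytes}, dtype=float)

    # genotype tolerance parameters
    genotypes = [f"G{i + 1:02d}" for i in range(cfg.n_genotypes)]
    if cfg.g_values is not None:
        if len(cfg.g_values) != cfg.n_genotypes:
            raise ValueError("g_values length must equal n_genotypes")
        g = np.asarray(cfg.g_values, dtype=float)
        strong_idx: list[int] = []
        weak_idx: list[int] = []
    else:
        if cfg.n_strong + cfg.n_weak > cfg.n_genotypes:
            raise ValueError("n_strong + n_weak exceeds n_genotypes")
        g = rng.uniform(0.3, 0.7, size=cfg.n_genotypes)
        picks = rng.choice(cfg.n_genotypes, size=cfg.n_strong + cfg.n_weak,
                           replace=False)
        strong_idx = list(picks[:cfg.n_strong])
        weak_idx = list(picks[cfg.n_strong:])
        g[strong_idx] = 1.0
        g[weak_idx] = 0.0
    if ((g < 0) | (g > 1)).any():
        raise ValueError("g values must lie in [0, 1]")
    g = pd.Series(g, index=genotypes)

    geno_eff = pd.Series(rng.normal(0, cfg.genotype_sd, cfg.n_genotypes),
                         index=genotypes)
    run_eff = rng.normal(0, cfg.run_sd, cfg.n_runs)
    block_eff = rng.normal(0, cfg.block_sd, cfg.n_blocks)

    # planted violations: minor-class, neutral-rule analytes only
    eligible = [a for a in analytes
                if rule[a] == "neutral"
                and species[a].headgroup.name in
                ("PI", "PS", "LPC", "LPE", "MGMG", "DGMG", "TrGDG",
                 "acMGDG", "PE-N", "GSL", "DG", "PA")]
    n_planted = cfg.n_planted_cv + cfg.n_planted_lod
    picks = list(rng.choice(len(eligible), size=n_planted, replace=False))
    planted_cv = [eligible[i] for i in picks[:cfg.n_planted_cv]]
    planted_lod = [eligible[i] for i in picks[cfg.n_planted_cv:]]
    base[planted_lod] = DEFAULT_LOD / 10.0  # realized mean stays below LOD

    # expectation matrix over experimental samples
    meta_rows = []
    for gi, geno in enumerate(genotypes):
        for t in ("OT", "HT"):
            for r in range(1, cfg.n_runs + 1):
                for b in range(1, cfg.n_blocks + 1):
                    meta_rows.append((f"{geno}_{t}_R{r}_B{b}", geno, t, r, b,
                                      False))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "genotype", "treatment",
                                            "run", "block", "is_qc_pool"]
                        ).set_index("sample_id")

    bvec = base.to_numpy()
    mvec = mult.to_numpy()
    n_s, n_a = len(meta), len(analytes)
    expect = np.empty((n_s, n_a))
    for i, (sid, row) in enumerate(meta.iterrows()):
        e = math.exp(geno_eff[row["genotype"]]
                     + run_eff[row["run"] - 1] + block_eff[row["block"] - 1])
        if row["treatment"] == "HT":
            expect[i] = bvec * (mvec ** g[row["genotype"]]) * e
        else:
            expect[i] = bvec * e

    # lognormal noise with mean preserved: mu = ln(expect) - sd^2/2
    if cfg.noise_sd > 0:
        noise = rng.normal(0, cfg.noise_sd, size=expect.shape)
        amounts = expect * np.exp(noise - cfg.noise_sd ** 2 / 2)
    else:
        amounts = expect.copy()

    # QC pool around the grand-mean composition
    qc_base = expect.mean(axis=0)
    sigma_q = math.sqrt(math.log(1 + cfg.qc_cv ** 2))
    qn = rng.normal(0, sigma_q, size=(cfg.n_qc_pool, n_a))
    qc_amounts = qc_base * np.exp(qn - sigma_q ** 2 / 2)
    # plant exact-CV violations
    pat = _standardized_pattern(cfg.n_qc_pool)
    for a in planted_cv:
        j = analytes.index(a)
        m = qc_amounts[:, j].mean()
        qc_amounts[:, j] = m * (1 + cfg.planted_cv * pat)
    qc_meta = pd.DataFrame(
        {"genotype": "", "treatment": "", "run": 0, "block": 0,
         "is_qc_pool": True},
        index=[f"QC{i + 1:02d}" for i in range(cfg.n_qc_pool)])

    samples = pd.concat([meta, qc_meta])
    amount_df = pd.DataFrame(np.vstack([amounts, qc_amounts]),
                             index=samples.index, columns=analytes)
    table = LipidomeTable(samples, amount_df, dict(species))

    # exact population-level expected fold per analyte
    w = np.exp(geno_eff.to_numpy())
    gvec = g.to_numpy()
    exp_fold = pd.Series(
        {a: float((w * mult[a] ** gvec).sum() / w.sum()) for a in analytes})

    truth = GroundTruth(
        multipliers=mult, effect_rule=rule, expected_fold=exp_fold,
        base_abundance=base, g=g, genotype_effects=geno_eff,
        strong_genotypes=[genotypes[i] for i in strong_idx],
        weak_genotypes=[genotypes[i] for i in weak_idx],
        planted_cv=planted_cv, planted_lod=planted_lod,
        config=cfg, seed=seed)
    return table, truth


def generate_markers(layout: GenomeLayout, n: int,
                     enrichment: Optional[dict[str, float]] = None,
                     seed: int = 0) -> pd.DataFrame:
    """Multinomially allocate ``n`` markers to chromosomes proportionally
    to size x enrichment factor, with uniform positions within each
    chromosome (1-based)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    enrichment = enrichment or {}
    bad = [c for c, f in enrichment.items() if f <= 0]
    if bad:
        raise ValueError(f"enrichment factors must be positive: {bad}")
    rng = np.random.default_rng(seed)
    tab = layout.table
    weights = np.array([row.size_mb * enrichment.get(row.chrom, 1.0)
                        for row in tab.itertuples(index=False)])
    counts = rng.multinomial(n, weights / weights.sum())
    rows = []
    for row, c in zip(tab.itertuples(index=False), counts):
        if c == 0:
            continue
        pos = rng.integers(1, int(row.size_mb * 1e6) + 1, size=c)
        rows += [(row.chrom, int(p)) for p in np.sort(pos)]
    return pd.DataFrame(rows, columns=["chrom", "pos"])
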