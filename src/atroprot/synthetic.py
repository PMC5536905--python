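"""Synthetic study generator with known ground truth.

Emulates the statistical structure of the denervation study: a common heavy
spike-in standard shared by all expression samples, per-protein time profiles
of log2(den/ctrl) drawn from six archetypes, one-pool exponential label
incorporation with condition-dependent rate constants, diglycine-site
occupancy shifts superimposed on protein abundance, annotation terms with
shifted ratio distributions, and planted "atrogene-like" training profiles.

The generator is fully determined by ``GeneratorConfig.seed``; noise-free
mode (``noise_sd_log2=0`` and ``frac_missing=0``) makes downstream point
estimates recover the ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (AnnotationSet, ProteinQuantTable, SampleDesign,
                     SiteQuantTable)

__all__ = ["GeneratorConfig", "GroundTruth", "ARCHETYPE_TEMPLATES",
           "generate_expression_study", "generate_pulse_study",
           "generate_site_study", "generate_annotations"]

#: Piecewise-linear log2 fold-change templates (unit amplitude) anchored at
#: the four expression days.  Three shapes (step, ramp, peak-and-return) in
#: both directions.  After per-row z-scoring only the *shape* of a profile
#: survives (offset and scale are removed), so a constant-offset template
#: would be indistinguishable from the step template; the sixth default
#: archetype is therefore transient_down rather than a constant profile.
ARCHETYPE_TEMPLATES: dict[str, tuple[float, ...]] = {
    "early_up": (0.3, 1.0, 1.0, 1.0),
    "late_up": (0.0, 0.2, 0.6, 1.0),
    "transient_up": (0.5, 1.0, 0.3, 0.0),
    "early_down": (-0.3, -1.0, -1.0, -1.0),
    "late_down": (0.0, -0.2, -0.6, -1.0),
    "transient_down": (-0.5, -1.0, -0.3, 0.0),
}
TEMPLATE_DAYS = (1.0, 4.0, 7.0, 14.0)
UP_ARCHETYPES = ("early_up", "late_up")
DOWN_ARCHETYPES = ("early_down", "late_down")

LN2 = np.log(2.0)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the reference study design: triplicates, expression sampled at
    days 1/4/7/14, the label pulse at days 4/7/11, ~20% of the proteome
    regulated with |log2 FC| = 1, per-measurement log2 noise SD 0.33
    (calibrated so that roughly a tenth to two-fifths of regulated proteins
    reach significance at n=3), base turnover 0.05/day (median half-life
    ~2 weeks), a doubling of the synthesis rate for the rate-shifted subset,
    3.5 diglycine sites per modified protein and ~15% regulated sites.
    """

    n_proteins: int = 1000
    n_replicates: int = 3
    time_days_expression: tuple[float, ...] = (1.0, 4.0, 7.0, 14.0)
    time_days_pulse: tuple[float, ...] = (4.0, 7.0, 11.0)
    frac_regulated: float = 0.2
    effect_log2: float = 1.0
    noise_sd_log2: float = 0.33
    profile_archetypes: int = 6
    n_atrogene_up: int = 15
    n_atrogene_down: int = 12
    base_rate_k: float = 0.05
    rate_shift_factor: float = 2.0
    frac_rate_shifted: float = 0.05
    sites_per_protein_mean: float = 3.5
    frac_sites_regulated: float = 0.15
    frac_proteins_with_sites: float = 0.15
    site_effect_log2: float = 1.5
    frac_missing: float = 0.02
    templates: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(ARCHETYPE_TEMPLATES))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_regulated", "frac_rate_shifted", "frac_sites_regulated",
                     "frac_proteins_with_sites", "frac_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} not in [0, 1]")
        for name in ("time_days_expression", "time_days_pulse"):
            t = getattr(self, name)
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ConfigError(f"{name} must be strictly increasing")
            if any(x <= 0 for x in t):
                raise ConfigError(f"{name} must be positive")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ConfigError("n_proteins and n_replicates must be positive")
        if self.noise_sd_log2 < 0 or self.effect_log2 <= 0:
            raise ConfigError("effect_log2 must be > 0 and noise_sd_log2 >= 0")
        if self.base_rate_k <= 0 or self.rate_shift_factor <= 0:
            raise ConfigError("rates must be positive")
        n_reg = int(round(self.frac_regulated * self.n_proteins))
        if self.profile_archetypes > 0 and self.frac_regulated > 0 and n_reg < 1:
            raise ConfigError("frac_regulated * n_proteins < 1 with archetypes requested")
        if self.n_atrogene_up + self.n_atrogene_down > n_reg:
            raise ConfigError("more atrogenes requested than regulated proteins")


@dataclass
class GroundTruth:
    """The generator's true parameters, for downstream validation.

    ``proteins`` holds per-protein regulated flag, archetype, atrogene class
    (0 = none, 1 = up-training, 2 = down-training), true rate constants and
    the rate-shift factor gamma; ``delta`` holds the true log2(den/ctrl)
    profile per expression time point; ``sites`` (once the site study is
    generated) holds the true per-site occupancy shift u.
    """

    proteins: pd.DataFrame
    delta: pd.DataFrame
    sites: pd.DataFrame | None = None

    @property
    def regulated_ids(self) -> pd.Index:
        return self.proteins.index[self.proteins["regulated"]]

    def atrogene_ids(self, klass: int) -> pd.Index:
        return self.proteins.index[self.proteins["atrogene_class"] == klass]


def _protein_ids(n: int) -> pd.Index:
    return pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id")


def _assign_archetypes(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Regulated flags, archetype labels and atrogene classes per protein.

    The first ``n_atrogene_up`` regulated proteins cycle through the monotone
    up archetypes and carry class 1; the next ``n_atrogene_down`` cycle the
    monotone down archetypes (class 2); remaining regulated proteins cycle
    through the first ``profile_archetypes`` templates.
    """
    ids = _protein_ids(cfg.n_proteins)
    n_reg = int(round(cfg.frac_regulated * cfg.n_proteins))
    reg_pos = rng.choice(cfg.n_proteins, size=n_reg, replace=False)
    regulated = np.zeros(cfg.n_proteins, dtype=bool)
    regulated[reg_pos] = True

    archetype = np.array([""] * cfg.n_proteins, dtype=object)
    atro = np.zeros(cfg.n_proteins, dtype=int)
    names = list(cfg.templates)[: cfg.profile_archetypes]
    reg_pos = np.sort(reg_pos)
    for j, p in enumerate(reg_pos):
        if j < cfg.n_atrogene_up:
            archetype[p] = UP_ARCHETYPES[j % len(UP_ARCHETYPES)]
            atro[p] = 1
        elif j < cfg.n_atrogene_up + cfg.n_atrogene_down:
            k = j - cfg.n_atrogene_up
            archetype[p] = DOWN_ARCHETYPES[k % len(DOWN_ARCHETYPES)]
            atro[p] = 2
        else:
            archetype[p] = names[j % len(names)]
    return pd.DataFrame({"regulated": regulated, "archetype": archetype,
                         "atrogene_class": atro}, index=ids)


def _true_delta(cfg: GeneratorConfig, proteins: pd.DataFrame) -> pd.DataFrame:
    times = np.asarray(cfg.time_days_expression, dtype=float)
    delta = np.zeros((len(proteins), len(times)))
    for i, (pid, row) in enumerate(proteins.iterrows()):
        if row["regulated"]:
            tpl = np.asarray(cfg.templates[row["archetype"]], dtype=float)
            delta[i] = cfg.effect_log2 * np.interp(times, TEMPLATE_DAYS, tpl)
    return pd.DataFrame(delta, index=proteins.index, columns=times)


def _expression_design(cfg: GeneratorConfig) -> SampleDesign:
    rows = []
    for cond in ("control", "denervated"):
        for t in cfg.time_days_expression:
            for r in range(1, cfg.n_replicates + 1):
                rows.append((f"{cond[:3]}_d{t:g}_r{r}", cond, t, r, "expression"))
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_day", "replicate", "assay"]))


def generate_expression_study(cfg: GeneratorConfig
                              ) -> tuple[ProteinQuantTable, SampleDesign, GroundTruth]:
    """Spike-in expression study: common heavy standard, archetype profiles.

    The heavy intensity of a protein is identical across all samples (the
    shared spike-in standard); the light intensity is
    ``A_p * 2**(delta_p(t) * [denervated] + eps)`` with
    ``eps ~ Normal(0, noise_sd_log2)`` on the log2 scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    proteins = _assign_archetypes(cfg, rng)
    delta = _true_delta(cfg, proteins)
    design = _expression_design(cfg)

    abundance = 10.0 ** rng.normal(6.0, 0.8, size=cfg.n_proteins)
    heavy = {}
    light = {}
    counts = {}
    for _, s in design.frame.iterrows():
        sid = s["sample_id"]
        shift = delta[s["time_day"]].to_numpy() if s["condition"] == "denervated" else 0.0
        eps = (rng.normal(0.0, cfg.noise_sd_log2, size=cfg.n_proteins)
               if cfg.noise_sd_log2 > 0 else 0.0)
        light[sid] = abundance * 2.0 ** (shift + eps)
        heavy[sid] = abundance
        cnt = 2 + rng.poisson(6.0, size=cfg.n_proteins)
        if cfg.frac_missing > 0:
            dropout = rng.random(cfg.n_proteins) < cfg.frac_missing
            cnt = np.where(dropout, rng.integers(0, 2, size=cfg.n_proteins), cnt)
        counts[sid] = cnt

    idx = proteins.index
    lightf = pd.DataFrame(light, index=idx)
    heavyf = pd.DataFrame(heavy, index=idx)
    countf = pd.DataFrame(counts, index=idx)
    hl = heavyf / lightf
    meta = pd.DataFrame({"gene_name": [f"Gene{i}" for i in range(cfg.n_proteins)]},
                        index=idx)
    table = ProteinQuantTable(meta, lightf, heavyf, hl, countf, design)
    table = table.apply_min_ratio_count()

    truth_prot = proteins.copy()
    truth_prot["k_ctrl"] = np.nan
    truth_prot["k_den"] = np.nan
    truth_prot["gamma"] = np.nan
    return table, design, GroundTruth(truth_prot, delta)


def _pulse_design(cfg: GeneratorConfig) -> SampleDesign:
    rows = []
    for cond in ("control", "denervated"):
        for t in cfg.time_days_pulse:
            for r in range(1, cfg.n_replicates + 1):
                rows.append((f"{cond[:3]}_p{t:g}_r{r}", cond, t, r, "pulse"))
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_day", "replicate", "assay"]))


def generate_pulse_study(cfg: GeneratorConfig,
                         truth: GroundTruth | None = None
                         ) -> tuple[ProteinQuantTable, SampleDesign, GroundTruth]:
    """Pulse-labelling study under the one-pool model f(t) = 1 - exp(-k t).

    Heavy = newly synthesized (label taken up during the pulse), so the
    observed H/L is ``f/(1-f)`` perturbed by lognormal noise.  The denervated
    rate is ``gamma * k_ctrl`` with gamma != 1 only for the rate-shifted
    subset.  Pass the expression *truth* to keep one coherent protein universe
    across assays; otherwise a fresh one is created.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    if truth is None:
        proteins = _assign_archetypes(cfg, rng)
        delta = _true_delta(cfg, proteins)
        truth = GroundTruth(proteins.assign(k_ctrl=np.nan, k_den=np.nan, gamma=np.nan),
                            delta)
    n = len(truth.proteins)
    k_ctrl = cfg.base_rate_k * np.exp(rng.normal(0.0, 0.4, size=n))
    gamma = np.ones(n)
    n_shift = int(round(cfg.frac_rate_shifted * n))
    if n_shift:
        shifted = rng.choice(n, size=n_shift, replace=False)
        gamma[shifted] = cfg.rate_shift_factor
    k_den = gamma * k_ctrl
    truth.proteins["k_ctrl"] = k_ctrl
    truth.proteins["k_den"] = k_den
    truth.proteins["gamma"] = gamma

    design = _pulse_design(cfg)
    idx = truth.proteins.index
    hl = {}
    light = {}
    heavy = {}
    counts = {}
    abundance = 10.0 ** rng.normal(6.0, 0.8, size=n)
    for _, s in design.frame.iterrows():
        sid = s["sample_id"]
        k = k_den if s["condition"] == "denervated" else k_ctrl
        f = 1.0 - np.exp(-k * s["time_day"])
        ratio = f / (1.0 - f)
        eps = (rng.normal(0.0, cfg.noise_sd_log2, size=n)
               if cfg.noise_sd_log2 > 0 else 0.0)
        r_obs = ratio * 2.0 ** eps
        hl[sid] = r_obs
        light[sid] = abundance / (1.0 + r_obs)
        heavy[sid] = abundance - light[sid]
        cnt = 2 + rng.poisson(6.0, size=n)
        if cfg.frac_missing > 0:
            dropout = rng.random(n) < cfg.frac_missing
            cnt = np.where(dropout, rng.integers(0, 2, size=n), cnt)
        counts[sid] = cnt

    meta = pd.DataFrame({"gene_name": [f"Gene{i}" for i in range(n)]}, index=idx)
    table = ProteinQuantTable(meta, pd.DataFrame(light, index=idx),
                              pd.DataFrame(heavy, index=idx),
                              pd.DataFrame(hl, index=idx),
                              pd.DataFrame(counts, index=idx), design)
    return table.apply_min_ratio_count(), design, truth


def _site_design(cfg: GeneratorConfig) -> SampleDesign:
    # Site samples are den/ctrl ratio measurements per (time, replicate);
    # by convention they carry condition="denervated".
    rows = []
    for t in cfg.time_days_expression:
        for r in range(1, cfg.n_replicates + 1):
            rows.append((f"site_d{t:g}_r{r}", "denervated", t, r, "sites"))
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_day", "replicate", "assay"]))


def generate_site_study(cfg: GeneratorConfig, expression: ProteinQuantTable,
                        truth: GroundTruth) -> SiteQuantTable:
    """Diglycine-site study: site ratios ride on protein abundance.

    Per site and sample, the observed log2(den/ctrl) is
    ``delta_p(t) + u_j(t) + noise`` where u_j is the true occupancy shift
    (non-zero only for the regulated-site fraction, constant over time with a
    random sign).  Sites-per-protein is 1 + Poisson(mean - 1); positions are
    uniform on a per-protein length.  Updates ``truth.sites`` in place.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    n_prot = int(round(cfg.frac_proteins_with_sites * len(truth.proteins)))
    n_prot = max(n_prot, 1)
    prot_pos = np.sort(rng.choice(len(truth.proteins), size=n_prot, replace=False))
    pids = truth.proteins.index[prot_pos]
    lengths = rng.integers(200, 3000, size=n_prot)
    counts = 1 + rng.poisson(max(cfg.sites_per_protein_mean - 1.0, 0.0), size=n_prot)

    design = _site_design(cfg)
    rows = []
    u_list = []
    for pid, length, c in zip(pids, lengths, counts):
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(c, length),
                                 replace=False))
        for p in pos:
            reg = rng.random() < cfg.frac_sites_regulated
            u = cfg.site_effect_log2 * (1 if rng.random() < 0.5 else -1) if reg else 0.0
            rows.append((f"{pid}_K{p}", pid, int(p), True, int(length)))
            u_list.append(u)
    sites = pd.DataFrame(rows, columns=["site_id", "protein_id", "residue_position",
                                        "localization_ok", "protein_length"]
                         ).set_index("site_id")
    u = np.asarray(u_list)

    delta = truth.delta
    values = {}
    for _, s in design.frame.iterrows():
        sid = s["sample_id"]
        d = delta.loc[sites["protein_id"], s["time_day"]].to_numpy()
        eps = (rng.normal(0.0, cfg.noise_sd_log2, size=len(sites))
               if cfg.noise_sd_log2 > 0 else 0.0)
        values[sid] = d + u + eps
    log2_ratio = pd.DataFrame(values, index=sites.index)

    truth.sites = pd.DataFrame({"protein_id": sites["protein_id"],
                                "u": u,
                                "regulated_site": u != 0.0}, index=sites.index)
    return SiteQuantTable(sites, log2_ratio, design)


def generate_annotations(cfg: GeneratorConfig, truth: GroundTruth,
                         n_null_terms: int = 30, n_planted_up: int = 3,
                         n_planted_down: int = 3, term_size: int = 30,
                         purity: float = 1.0) -> AnnotationSet:
    """Null terms (random membership) plus planted up/down-enriched terms.

    A planted term draws ``purity * term_size`` members from the truly up-
    (or down-) regulated proteins and fills the remainder at random.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    ids = truth.proteins.index.to_numpy()
    mean_delta = truth.delta.mean(axis=1)
    up = ids[(truth.proteins["regulated"]) & (mean_delta > 0)]
    down = ids[(truth.proteins["regulated"]) & (mean_delta < 0)]

    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for i in range(n_null_terms):
        tid = f"NULL:{i:04d}"
        terms[tid] = set(rng.choice(ids, size=min(term_size, len(ids)), replace=False))
        names[tid] = f"null term {i}"

    def plant(pool: np.ndarray, tid: str, name: str) -> None:
        n_pure = int(round(purity * term_size))
        n_pure = min(n_pure, len(pool))
        members = set(rng.choice(pool, size=n_pure, replace=False))
        rest = np.setdiff1d(ids, np.asarray(sorted(members)))
        fill = term_size - n_pure
        if fill > 0:
            members |= set(rng.choice(rest, size=min(fill, len(rest)), replace=False))
        terms[tid] = members
        names[tid] = name

    for i in range(n_planted_up):
        plant(up, f"UP:{i:02d}", f"planted up term {i}")
    for i in range(n_planted_down):
        plant(down, f"DOWN:{i:02d}", f"planted down term {i}")
    return AnnotationSet(terms, names)
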