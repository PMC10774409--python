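"""Seeded synthetic experiment generator with exported ground truth.

Produces a full factorial warming x management experiment — design,
bacterial/fungal communities, isotope incubations, amino-sugar profiles and
soil measurements — such that every downstream stage is testable offline:

* communities evolve by geometric replacement toward a regional pool, giving
  a tunable, analytically checkable similarity decay with time lag;
* warmed plots under a drifting management additionally shift linearly in
  time toward a warm-specialist profile, so warmed and ambient communities
  separate linearly (divergence series);
* incubation raw values are constructed by inverting the physiology module's
  forward computation, so noise-free data recover latent growth/respiration
  exactly; amino sugars likewise invert the necromass equations;
* the SOC warming effect under conservation ramps in after an onset year and
  reaches the configured multiplier (default +3.1%) in the final year, and
  the injected CUE effect-size trajectory crosses zero mid-study.

Everything is deterministic for a fixed seed (integer-seeded generators,
purpose-keyed streams).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from warmsoil.datamodel import (
    MANAGEMENTS,
    WARMING_LEVELS,
    ConfigurationError,
    FeatureTable,
    Lineage,
    MeasurementTable,
    SampleMetadata,
    StudyDesign,
    TaxonomyMap,
    plot_id_for,
)
from warmsoil.necromass import (
    BACTERIAL_CONVERSION,
    FUNGAL_CONVERSION,
    GLUCOSAMINE_MOLAR_MASS,
    AminoSugarProfile,
    muramic_mass_to_mmol,
)
from warmsoil.physiology import IsotopeIncubation

import pandas as pd

DOMAINS = ("bacteria", "fungi")

# stable sub-stream tags so adding a stage never reshuffles earlier draws
_STREAMS = {
    "blocks": 1,
    "pool": 2,
    "initial": 3,
    "replacement": 4,
    "counts": 5,
    "incubation_noise": 6,
    "measurement_noise": 7,
    "necromass_noise": 8,
}


def _rng(seed: int, stream: str, *keys: int) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream], *keys])


def default_turnover() -> dict[str, float]:
    """rho per biennial step, keyed 'domain/management/warming'.

    Fungi turn over faster than bacteria; warming accelerates fungal turnover
    under conservation.
    """
    return {
        "bacteria/conservation/ambient": 0.06,
        "bacteria/conservation/warmed": 0.08,
        "bacteria/conventional/ambient": 0.06,
        "bacteria/conventional/warmed": 0.06,
        "fungi/conservation/ambient": 0.18,
        "fungi/conservation/warmed": 0.30,
        "fungi/conventional/ambient": 0.18,
        "fungi/conventional/warmed": 0.18,
    }


def default_drift() -> dict[str, float]:
    """Per-year directional shift of warmed communities, keyed 'domain/management'."""
    return {
        "bacteria/conservation": 0.01,
        "bacteria/conventional": 0.0,
        "fungi/conservation": 0.03,
        "fungi/conventional": 0.0,
    }


@dataclass
class SocParams:
    baseline: dict[str, float] = field(
        default_factory=lambda: {"conservation": 20.0, "conventional": 16.0}
    )  # mg C g-1
    annual_trend: dict[str, float] = field(
        default_factory=lambda: {"conservation": 0.25, "conventional": 0.05}
    )
    warming_multiplier: dict[str, float] = field(
        default_factory=lambda: {"conservation": 1.031, "conventional": 1.0}
    )
    onset_year: int = 2016  # multiplier ramps in from here, full in final year
    block_sd: float = 0.4


@dataclass
class CueParams:
    base: float = 0.4
    uptake: float = 100.0  # µg C g-1 per 48 h incubation
    block_sd: float = 0.02
    # injected warmed-vs-ambient Cohen's d trajectory: d(y) = a + b*(y - y0)
    d_intercept: dict[str, float] = field(
        default_factory=lambda: {"conservation": -1.0, "conventional": 0.0}
    )
    d_slope: dict[str, float] = field(
        default_factory=lambda: {"conservation": 0.2, "conventional": 0.0}
    )


@dataclass
class NecromassParams:
    bacterial_base: float = 900.0  # µg C g-1
    bacterial_annual_trend: float = 0.02  # relative per year
    fungal_base: float = 2500.0  # µg C g-1
    fungal_annual_trend: float = 0.05
    fungal_warming_trend: dict[str, float] = field(
        default_factory=lambda: {"conservation": 0.03, "conventional": 0.0}
    )  # extra relative increase per year when warmed
    block_sd_frac: float = 0.02


@dataclass
class IncubationParams:
    f_co: float = 2.0  # µg biomass C per µg new DNA-O (generator's convention)
    soil_dry_mass: float = 0.5  # g
    control_atpct: float = 0.2005  # natural abundance 18O
    water_label_atpct: float = 30.0
    headspace_volume: float = 0.02  # L
    headspace_temp: float = 293.15  # K
    headspace_pressure: float = 101325.0  # Pa


@dataclass
class NoiseParams:
    """Gaussian noise standard deviations; scale them all with noise_scale."""

    soc: float = 0.05  # mg C g-1
    doc: float = 2.0  # mg C kg-1
    biomass: float = 20.0  # g m-2
    dna_atpct: float = 0.01  # atom%
    co2_ppm: float = 5.0
    necromass_frac: float = 0.02  # relative on latent necromass


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_blocks: int = 4
    years: tuple[int, ...] = (2010, 2012, 2014, 2016, 2018, 2020)
    sequencing_blocks: int = 3
    n_taxa: int = 500  # per domain
    depth: int = 25000
    n_phyla: int = 8
    pool_concentration: float = 50.0  # Dirichlet concentration of pool draws
    burn_in_steps: int = 25  # replacement steps before year 0 (stationarity)
    turnover: dict[str, float] = field(default_factory=default_turnover)
    lineage_turnover: dict[str, float] | None = None  # phylum -> rho override
    divergence_drift: dict[str, float] = field(default_factory=default_drift)
    soc_params: SocParams = field(default_factory=SocParams)
    cue_params: CueParams = field(default_factory=CueParams)
    necromass_params: NecromassParams = field(default_factory=NecromassParams)
    incubation_params: IncubationParams = field(default_factory=IncubationParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    noise_scale: float = 1.0  # 0 => fully deterministic measurements

    def __post_init__(self) -> None:
        for key, rho in self.turnover.items():
            if not (0.0 <= rho < 1.0):
                raise ConfigurationError(f"turnover[{key}]={rho} must be in [0, 1)")
        for key, drift in self.divergence_drift.items():
            if drift < 0:
                raise ConfigurationError(f"divergence_drift[{key}] must be >= 0")
        if self.sequencing_blocks > self.n_blocks:
            raise ConfigurationError("sequencing_blocks cannot exceed n_blocks")
        if self.depth < 1:
            raise ConfigurationError("sequencing depth must be >= 1")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        for f in dataclasses.fields(NoiseParams):
            if getattr(self.noise, f.name) < 0:
                raise ConfigurationError(f"noise.{f.name} must be >= 0")

    def rho_for(self, domain: str, management: str, warming: str) -> float:
        return self.turnover[f"{domain}/{management}/{warming}"]

    def drift_for(self, domain: str, management: str) -> float:
        return self.divergence_drift.get(f"{domain}/{management}", 0.0)

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        """Build a config from a (YAML-derived) plain dict; nested sections
        override dataclass defaults field by field."""
        kwargs = dict(raw)
        nested = {
            "soc_params": SocParams,
            "cue_params": CueParams,
            "necromass_params": NecromassParams,
            "incubation_params": IncubationParams,
            "noise": NoiseParams,
        }
        for key, klass in nested.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                base = klass()
                for k, v in kwargs[key].items():
                    if not hasattr(base, k):
                        raise ConfigurationError(f"unknown field {key}.{k}")
                    setattr(base, k, v)
                kwargs[key] = base
        if "years" in kwargs:
            kwargs["years"] = tuple(int(y) for y in kwargs["years"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config fields: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Latent quantities every generated raw measurement derives from."""

    growth: dict[str, float]  # sample_id -> µg C g-1 per 48 h
    respiration: dict[str, float]
    cue: dict[str, float]
    soc: dict[str, float]  # latent (pre-noise) mg C g-1
    bacterial_necromass: dict[str, float]  # latent µg C g-1
    fungal_necromass: dict[str, float]
    turnover: dict[str, float]
    divergence_drift: dict[str, float]
    soc_warming_multiplier: dict[str, float]
    cue_d_trajectory: dict[str, dict[int, float]]  # management -> year -> d


class SyntheticExperiment(NamedTuple):
    design: StudyDesign
    tables: dict[str, FeatureTable]  # domain -> counts (sequenced blocks only)
    taxonomies: dict[str, TaxonomyMap]
    incubations: list[IsotopeIncubation]
    amino_profiles: list[AminoSugarProfile]
    measurements: MeasurementTable
    truth: GroundTruth


def sample_id_for(management: str, warming: str, block: int, year: int) -> str:
    return f"{management}-{warming}-b{block}-y{year}"


def generate_design(config: GeneratorConfig) -> StudyDesign:
    samples = [
        SampleMetadata(
            sample_id=sample_id_for(m, w, b, y),
            plot_id=plot_id_for(m, w, b),
            block=b,
            management=m,
            warming=w,
            year=y,
        )
        for m in MANAGEMENTS
        for w in WARMING_LEVELS
        for b in range(1, config.n_blocks + 1)
        for y in config.years
    ]
    return StudyDesign(samples=samples)


# ---------------------------------------------------------------------------
# communities


def generate_taxonomy(config: GeneratorConfig, domain: str) -> TaxonomyMap:
    dom_label = "Bacteria" if domain == "bacteria" else "Fungi"
    prefix = domain[0]
    lineages = {}
    for i in range(config.n_taxa):
        lineages[f"{prefix}otu{i:05d}"] = Lineage(
            domain=dom_label, phylum=f"Phylum{i % config.n_phyla + 1}"
        )
    return TaxonomyMap(lineages)


def _taxon_ids(config: GeneratorConfig, domain: str) -> list[str]:
    return [f"{domain[0]}otu{i:05d}" for i in range(config.n_taxa)]


def _pool(config: GeneratorConfig, domain: str) -> np.ndarray:
    """Lognormal regional species-abundance pool; the tail 5% of taxa is the
    warm-specialist support and gets negligible pool mass."""
    dom_key = DOMAINS.index(domain)
    rng = _rng(config.seed, "pool", dom_key)
    probs = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_taxa)
    n_drift = max(1, config.n_taxa // 20)
    probs[-n_drift:] *= 1e-6
    return probs / probs.sum()


def _drift_profile(config: GeneratorConfig, domain: str) -> np.ndarray:
    n_drift = max(1, config.n_taxa // 20)
    u = np.zeros(config.n_taxa)
    u[-n_drift:] = 1.0 / n_drift
    return u


def _groups(
    config: GeneratorConfig, domain: str
) -> list[tuple[np.ndarray, float | None]]:
    """Taxon index groups with optional per-group rho overrides.

    Default: one group covering all taxa (treatment rho applies). When
    ``lineage_turnover`` is set, each named phylum evolves with its own rho
    and remaining taxa use the treatment rho.
    """
    if not config.lineage_turnover:
        return [(np.arange(config.n_taxa), None)]
    taxonomy = generate_taxonomy(config, domain)
    ids = _taxon_ids(config, domain)
    groups: list[tuple[np.ndarray, float | None]] = []
    assigned = np.zeros(config.n_taxa, dtype=bool)
    for phylum, rho in config.lineage_turnover.items():
        idx = np.array(
            [i for i, t in enumerate(ids) if taxonomy[t].phylum == phylum],
            dtype=int,
        )
        if len(idx):
            groups.append((idx, float(rho)))
            assigned[idx] = True
    rest = np.nonzero(~assigned)[0]
    if len(rest):
        groups.append((rest, None))
    return groups


def _evolve_step(
    p: np.ndarray,
    groups: Sequence[tuple[np.ndarray, float | None]],
    default_rho: float,
    pool: np.ndarray,
    rng: np.random.Generator,
    conc: float,
) -> np.ndarray:
    """One geometric-replacement step: within each group, a fraction rho of
    the group's mass is reassigned to taxa drawn from the regional pool
    (restricted to the group); group masses are conserved."""
    out = p.copy()
    for idx, rho_override in groups:
        rho = default_rho if rho_override is None else rho_override
        if rho == 0:
            continue
        mass = p[idx].sum()
        if mass == 0:
            continue
        alpha = np.maximum(pool[idx] * conc, 1e-9)
        q = rng.dirichlet(alpha)
        out[idx] = (1.0 - rho) * p[idx] + rho * mass * q
    return out


def latent_trajectories(
    config: GeneratorConfig,
    design: StudyDesign,
    domain: str,
    disjoint_replacement: bool = False,
) -> dict[str, np.ndarray]:
    """Latent relative-abundance vector per sequenced sample.

    Initial composition and replacement draws are keyed by (management,
    block, step) and shared between warming levels, so that with zero drift
    and equal turnover the warmed and ambient trajectories of a block are
    identical; the warmed plot then receives the configured linear-in-time
    directional drift toward the warm-specialist profile.

    ``disjoint_replacement`` switches to an analytically exact mode in which
    each step's replacement mass lands on a dedicated, previously untouched
    block of taxa, making expected shared mass after k steps exactly
    (1-rho)^k.
    """
    pool = _pool(config, domain)
    drift_u = _drift_profile(config, domain)
    groups = _groups(config, domain)
    dom_key = DOMAINS.index(domain)
    years = config.years
    y0 = years[0]
    n_steps = len(years) - 1
    seq_blocks = sorted(design.blocks)[: config.sequencing_blocks]

    if disjoint_replacement:
        slice_width = config.n_taxa // (n_steps + 1)
        if slice_width < 1:
            raise ConfigurationError(
                "disjoint_replacement needs n_taxa >= number of time points"
            )

    profiles: dict[str, np.ndarray] = {}
    for mi, m in enumerate(MANAGEMENTS):
        for b in seq_blocks:
            init_rng = _rng(config.seed, "initial", dom_key, mi, b)
            if disjoint_replacement:
                p_init = np.zeros(config.n_taxa)
                alpha = np.maximum(pool[:slice_width] * config.pool_concentration, 1e-9)
                p_init[:slice_width] = init_rng.dirichlet(alpha)
            else:
                p_init = init_rng.dirichlet(
                    np.maximum(pool * config.pool_concentration, 1e-9)
                )
            for w in WARMING_LEVELS:
                rho = config.rho_for(domain, m, w)
                drift = config.drift_for(domain, m) if w == "warmed" else 0.0
                p = p_init.copy()
                if not disjoint_replacement:
                    # burn-in so evenness (and hence the sampling-noise floor
                    # of dissimilarities) is stationary from the first year;
                    # draws shared between warming levels
                    for k in range(config.burn_in_steps):
                        burn_rng = _rng(
                            config.seed, "replacement", dom_key, mi, b, 1000 + k
                        )
                        p = _evolve_step(
                            p, groups, rho, pool, burn_rng,
                            config.pool_concentration,
                        )
                for step, year in enumerate(years):
                    if step > 0:
                        # keyed without warming level: warmed and ambient share
                        # replacement draws, so divergence reflects only the
                        # warming-specific turnover difference and drift
                        step_rng = _rng(
                            config.seed, "replacement", dom_key, mi, b, step
                        )
                        if disjoint_replacement:
                            lo = step * slice_width
                            hi = lo + slice_width
                            alpha = np.maximum(
                                pool[lo:hi] * config.pool_concentration, 1e-9
                            )
                            q = np.zeros(config.n_taxa)
                            q[lo:hi] = step_rng.dirichlet(alpha)
                            p = (1.0 - rho) * p + rho * q
                        else:
                            p = _evolve_step(
                                p, groups, rho, pool, step_rng,
                                config.pool_concentration,
                            )
                    delta = min(drift * (year - y0), 0.9)
                    observed = (1.0 - delta) * p + delta * drift_u
                    sid = sample_id_for(m, w, b, year)
                    profiles[sid] = observed
    return profiles


def generate_communities(
    config: GeneratorConfig,
    design: StudyDesign,
    domain: str,
    infinite_depth: bool = False,
    disjoint_replacement: bool = False,
) -> FeatureTable:
    """Taxon-count table for the sequenced blocks of one domain.

    ``infinite_depth=True`` skips multinomial sampling and returns the latent
    relative abundances (a relative FeatureTable) — the exact expectations.
    """
    if config.depth < 1:
        raise ConfigurationError("sequencing depth must be >= 1")
    profiles = latent_trajectories(
        config, design, domain, disjoint_replacement=disjoint_replacement
    )
    # preserve design order for the sequenced samples
    sample_ids = [s.sample_id for s in design.samples if s.sample_id in profiles]
    taxa = _taxon_ids(config, domain)
    dom_key = DOMAINS.index(domain)
    if infinite_depth:
        mat = np.column_stack([profiles[s] for s in sample_ids])
        return FeatureTable(taxa, sample_ids, mat, relative=True)
    cols = []
    for j, sid in enumerate(sample_ids):
        rng = _rng(config.seed, "counts", dom_key, j)
        cols.append(rng.multinomial(config.depth, profiles[sid]))
    return FeatureTable(taxa, sample_ids, np.column_stack(cols))


# ---------------------------------------------------------------------------
# latent physiology / measurements


def _block_effects(config: GeneratorConfig, which: int, sd: float) -> np.ndarray:
    rng = _rng(config.seed, "blocks", which)
    return rng.normal(0.0, sd, size=config.n_blocks)


def _soc_ramp(config: GeneratorConfig, year: int) -> float:
    """0 before the onset year, rising linearly to 1 in the final year."""
    years = config.years
    onset = config.soc_params.onset_year
    if year < onset:
        return 0.0
    before = [y for y in years if y < onset]
    anchor = max(before) if before else onset - (years[1] - years[0])
    top = years[-1]
    if top == anchor:
        return 1.0
    return (year - anchor) / (top - anchor)


def injected_cue_d(config: GeneratorConfig, management: str, year: int) -> float:
    cp = config.cue_params
    return cp.d_intercept[management] + cp.d_slope[management] * (
        year - config.years[0]
    )


def latent_physiology(
    config: GeneratorConfig, design: StudyDesign
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Latent CUE/growth/respiration per sample.

    CUE is built so the warmed-vs-ambient Cohen's d across blocks equals the
    injected trajectory exactly when noise is zero: block deviations are
    shared between warming levels and the warmed offset is d x sd(block
    deviations).
    """
    cp = config.cue_params
    devs = _block_effects(config, 0, cp.block_sd)
    s = float(np.std(devs, ddof=1)) if config.n_blocks > 1 else 0.0
    cue: dict[str, float] = {}
    growth: dict[str, float] = {}
    respiration: dict[str, float] = {}
    for smp in design.samples:
        d = injected_cue_d(config, smp.management, smp.year)
        value = cp.base + devs[smp.block - 1]
        if smp.warming == "warmed":
            value += d * s
        value = float(np.clip(value, 0.01, 0.99))
        cue[smp.sample_id] = value
        growth[smp.sample_id] = value * cp.uptake
        respiration[smp.sample_id] = (1.0 - value) * cp.uptake
    return cue, growth, respiration


def generate_incubation(
    config: GeneratorConfig,
    design: StudyDesign,
    truth: GroundTruth,
) -> list[IsotopeIncubation]:
    """Raw incubation records inverting the physiology forward computation.

    With noise_scale = 0, compute_growth/compute_respiration applied to the
    generated records return the latent values to machine precision.
    """
    ip = config.incubation_params
    scale = config.noise_scale
    out = []
    from warmsoil.physiology import CARBON_MOLAR_MASS_UG, R_GAS

    for i, smp in enumerate(design.samples):
        g = truth.growth[smp.sample_id]
        r = truth.respiration[smp.sample_id]
        rng = _rng(config.seed, "incubation_noise", i)
        new_dna_o = g * ip.soil_dry_mass / ip.f_co
        # keep the labeled fraction comfortably below 1
        dna_total_o = max(5.0, 2.0 * new_dna_o)
        frac = new_dna_o / dna_total_o if dna_total_o > 0 else 0.0
        atpct = ip.control_atpct + frac * (ip.water_label_atpct - ip.control_atpct)
        atpct += scale * config.noise.dna_atpct * rng.standard_normal()
        atpct = float(np.clip(atpct, ip.control_atpct, ip.water_label_atpct))
        moles = (r * ip.soil_dry_mass) / CARBON_MOLAR_MASS_UG
        volume_m3 = ip.headspace_volume * 1e-3
        ppm = moles * R_GAS * ip.headspace_temp / (ip.headspace_pressure * volume_m3)
        ppm = ppm / 1e-6
        ppm += scale * config.noise.co2_ppm * rng.standard_normal()
        out.append(
            IsotopeIncubation(
                sample_id=smp.sample_id,
                soil_dry_mass=ip.soil_dry_mass,
                dna_total_o=dna_total_o,
                dna_atpct_labeled=atpct,
                dna_atpct_control=ip.control_atpct,
                co2_delta_ppm=ppm,
                headspace_volume=ip.headspace_volume,
                headspace_temp=ip.headspace_temp,
                headspace_pressure=ip.headspace_pressure,
                water_label_atpct=ip.water_label_atpct,
                f_co=ip.f_co,
            )
        )
    return out


def latent_soc(config: GeneratorConfig, design: StudyDesign) -> dict[str, float]:
    sp = config.soc_params
    devs = _block_effects(config, 1, sp.block_sd)
    soc: dict[str, float] = {}
    for smp in design.samples:
        base = (
            sp.baseline[smp.management]
            + sp.annual_trend[smp.management] * (smp.year - config.years[0])
            + devs[smp.block - 1]
        )
        if smp.warming == "warmed":
            mult = sp.warming_multiplier[smp.management]
            base *= 1.0 + (mult - 1.0) * _soc_ramp(config, smp.year)
        soc[smp.sample_id] = base
    return soc


def latent_necromass(
    config: GeneratorConfig, design: StudyDesign
) -> tuple[dict[str, float], dict[str, float]]:
    npar = config.necromass_params
    devs = _block_effects(config, 2, npar.block_sd_frac)
    bact: dict[str, float] = {}
    fung: dict[str, float] = {}
    for smp in design.samples:
        dt = smp.year - config.years[0]
        blk = 1.0 + devs[smp.block - 1]
        b = npar.bacterial_base * (1.0 + npar.bacterial_annual_trend * dt) * blk
        f = npar.fungal_base * (1.0 + npar.fungal_annual_trend * dt) * blk
        if smp.warming == "warmed":
            f *= 1.0 + npar.fungal_warming_trend[smp.management] * dt
        bact[smp.sample_id] = b
        fung[smp.sample_id] = f
    return bact, fung


def generate_measurements(
    config: GeneratorConfig,
    design: StudyDesign,
    truth: GroundTruth | None = None,
) -> tuple[MeasurementTable, list[AminoSugarProfile]]:
    """Soil measurement table plus amino-sugar profiles.

    Amino sugars are constructed by inverting the necromass equations from
    (noisy) latent bacterial/fungal necromass C, so glucosamine >= 2 x
    muramic acid holds by construction and the noise-free forward computation
    recovers the latents exactly.
    """
    soc = latent_soc(config, design)
    bact, fung = latent_necromass(config, design)
    scale = config.noise_scale
    rows = {}
    profiles = []
    for i, smp in enumerate(design.samples):
        rng = _rng(config.seed, "measurement_noise", i)
        nrng = _rng(config.seed, "necromass_noise", i)
        soc_val = soc[smp.sample_id] + scale * config.noise.soc * rng.standard_normal()
        doc_val = (
            soc[smp.sample_id] * 10.0
            + scale * config.noise.doc * rng.standard_normal()
        )
        biomass = (
            600.0
            + (80.0 if smp.management == "conservation" else 0.0)
            + 10.0 * (smp.year - config.years[0])
            + scale * config.noise.biomass * rng.standard_normal()
        )
        rows[smp.sample_id] = {
            "soc": soc_val,
            "doc": doc_val,
            "aboveground_biomass": biomass,
        }
        b = bact[smp.sample_id] * (
            1.0 + scale * config.noise.necromass_frac * nrng.standard_normal()
        )
        f = fung[smp.sample_id] * (
            1.0 + scale * config.noise.necromass_frac * nrng.standard_normal()
        )
        b = max(b, 0.0)
        f = max(f, 0.0)
        mur_mass = b / BACTERIAL_CONVERSION  # µg g-1
        mur_mmol = muramic_mass_to_mmol(mur_mass)
        glc_fungal_mmol = f / 1000.0 / (GLUCOSAMINE_MOLAR_MASS * FUNGAL_CONVERSION)
        glc_mmol = glc_fungal_mmol + 2.0 * mur_mmol
        profiles.append(
            AminoSugarProfile(
                sample_id=smp.sample_id,
                glucosamine=glc_mmol,
                galactosamine=1.2 * glc_mmol,
                muramic_acid_mass=mur_mass,
                muramic_acid_mmol=mur_mmol,
            )
        )
    data = pd.DataFrame.from_dict(rows, orient="index")
    data = data.loc[[s.sample_id for s in design.samples]]
    table = MeasurementTable(
        data,
        units={
            "soc": "mg C g-1 soil",
            "doc": "mg C kg-1 soil",
            "aboveground_biomass": "g m-2",
        },
    )
    return table, profiles


def generate_experiment(config: GeneratorConfig) -> SyntheticExperiment:
    """Full deterministic synthetic experiment with recorded ground truth."""
    design = generate_design(config)
    cue, growth, respiration = latent_physiology(config, design)
    soc = latent_soc(config, design)
    bact, fung = latent_necromass(config, design)
    truth = GroundTruth(
        growth=growth,
        respiration=respiration,
        cue=cue,
        soc=soc,
        bacterial_necromass=bact,
        fungal_necromass=fung,
        turnover=dict(config.turnover),
        divergence_drift=dict(config.divergence_drift),
        soc_warming_multiplier=dict(config.soc_params.warming_multiplier),
        cue_d_trajectory={
            m: {y: injected_cue_d(config, m, y) for y in config.years}
            for m in MANAGEMENTS
        },
    )
    tables = {}
    taxonomies = {}
    for domain in DOMAINS:
        tables[domain] = generate_communities(config, design, domain)
        taxonomies[domain] = generate_taxonomy(config, domain)
    incubations = generate_incubation(config, design, truth)
    measurements, profiles = generate_measurements(config, design, truth)
    return SyntheticExperiment(
        design=design,
        tables=tables,
        taxonomies=taxonomies,
        incubations=incubations,
        amino_profiles=profiles,
        measurements=measurements,
        truth=truth,
    )
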