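"""Simulate observation-event tables with plantable correlation structure.

One selection event is generated per site per day. Within an event each
species enters each habitat independently with a configured inclusion
probability; its forage and roost head counts are gamma-Poisson (negative
binomial, shape ``dispersion``) around configured means, with a shared
per-(event, species, habitat) gamma multiplier so the two activity columns
of one species co-vary, as repeated counts of the same flock would.

Cross-column correlation is planted through event-level standard-normal
latent factors: a node label (species, behavior class) with loading ``a`` on
factor ``g`` has its expected count scaled by ``exp(a z_g - a^2/2)``, which
keeps the marginal mean fixed. Labels sharing a factor correlate positively;
labels on different factors are (asymptotically) uncorrelated, which is what
:func:`plant_block_correlation` exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as _date
from datetime import timedelta

import numpy as np
import yaml

from ._constants import ACTIVITIES, BEHAVIOR_CLASSES, HABITATS, SHORT_BEHAVIORS
from .event_store import ObservationEvent, SpeciesCatalog

DEFAULT_FACTOR = "shared"


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    n_days: int
    sites: list[tuple[str, str]]  # (site_id, regime)
    habitat_suitability: dict[tuple[str, str, str], float]  # (regime, habitat, species) -> p
    abundance_mean: dict[tuple[str, str, str], float]
    dispersion: float
    activity_split: float  # P(individual is foraging rather than roosting)
    behavior_rates: dict[str, float]
    latent_factor_loadings: dict[tuple[str, str], float]  # (species, behavior) -> loading
    latent_factor_groups: dict[tuple[str, str], str] = field(default_factory=dict)
    start_date: _date = _date(2016, 11, 1)
    seed: int = 0

    def validate(self) -> None:
        if self.n_days <= 0:
            raise ConfigError(f"n_days must be positive, got {self.n_days}")
        if not self.sites:
            raise ConfigError("sites must be non-empty")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        if not 0.0 <= self.activity_split <= 1.0:
            raise ConfigError(f"activity_split {self.activity_split} outside [0, 1]")
        for key, p in self.habitat_suitability.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"habitat_suitability[{key}] = {p} outside [0, 1]")
        for mkey, m in self.abundance_mean.items():
            if m < 0:
                raise ConfigError(f"abundance_mean[{mkey}] = {m} negative")
        for b, r in self.behavior_rates.items():
            if b not in SHORT_BEHAVIORS:
                raise ConfigError(f"behavior_rates has unknown behavior {b!r}")
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"behavior_rates[{b}] = {r} outside [0, 1]")

    def factor_of(self, label: tuple[str, str]) -> str:
        return self.latent_factor_groups.get(label, DEFAULT_FACTOR)


def make_default_config(
    catalog: SpeciesCatalog, n_days: int = 60, seed: int = 0
) -> SimConfig:
    """A documented baseline: richer, denser communities in managed (R1)
    sites than unmanaged (R2), with guild-mates sharing a latent factor."""
    base_incl = {"MF": 0.90, "SW": 0.80, "GL": 0.60, "DW": 0.45, "BG": 0.35}
    base_mean = {"MF": 60.0, "SW": 50.0, "GL": 35.0, "DW": 25.0, "BG": 15.0}
    suitability: dict[tuple[str, str, str], float] = {}
    mean: dict[tuple[str, str, str], float] = {}
    for habitat in HABITATS:
        for sp in catalog.species_ids:
            suitability[("R1", habitat, sp)] = base_incl[habitat]
            suitability[("R2", habitat, sp)] = round(base_incl[habitat] * 0.6, 6)
            mean[("R1", habitat, sp)] = base_mean[habitat]
            mean[("R2", habitat, sp)] = base_mean[habitat] * 0.5

    loadings: dict[tuple[str, str], float] = {}
    groups: dict[tuple[str, str], str] = {}
    guild_of = catalog.guild_of
    for sp in catalog.species_ids:
        for activity in ACTIVITIES:
            loadings[(sp, activity)] = 0.35
            groups[(sp, activity)] = f"guild-{guild_of[sp]}"

    return SimConfig(
        n_days=n_days,
        sites=[("L1", "R1"), ("L2", "R1"), ("L3", "R2"), ("L4", "R2")],
        habitat_suitability=suitability,
        abundance_mean=mean,
        dispersion=5.0,
        activity_split=0.6,
        behavior_rates={"competition": 0.08, "aggression": 0.04, "courtship": 0.02},
        latent_factor_loadings=loadings,
        latent_factor_groups=groups,
        seed=seed,
    )


def simulate_events(config: SimConfig) -> list[ObservationEvent]:
    """Draw one selection event per site per day; zero-count rows omitted."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    factors = sorted(
        {config.factor_of(lbl) for lbl in config.latent_factor_loadings}
        | {DEFAULT_FACTOR}
    )
    events: list[ObservationEvent] = []
    species_ids = sorted({sp for (_, _, sp) in config.abundance_mean})
    shape = config.dispersion

    for day in range(config.n_days):
        when = config.start_date + timedelta(days=day)
        for site_id, regime in config.sites:
            event_id = f"{site_id}-{when.isoformat()}"
            z = {f: rng.standard_normal() for f in factors}
            for habitat in HABITATS:
                for sp in species_ids:
                    p_incl = config.habitat_suitability.get((regime, habitat, sp), 0.0)
                    if p_incl <= 0.0 or rng.random() >= p_incl:
                        continue
                    mean = config.abundance_mean.get((regime, habitat, sp), 0.0)
                    if mean <= 0.0:
                        continue
                    gamma = rng.gamma(shape, 1.0 / shape)
                    counts: dict[str, int] = {}
                    for activity, frac in (
                        ("forage", config.activity_split),
                        ("roost", 1.0 - config.activity_split),
                    ):
                        mu = mean * frac * _latent_scale(config, (sp, activity), z)
                        counts[activity] = int(rng.poisson(gamma * mu)) if mu > 0 else 0
                    total = counts["forage"] + counts["roost"]
                    for behavior in SHORT_BEHAVIORS:
                        rate = config.behavior_rates.get(behavior, 0.0)
                        rate = min(1.0, rate * _latent_scale(config, (sp, behavior), z))
                        counts[behavior] = (
                            int(rng.binomial(total, rate)) if total and rate > 0 else 0
                        )
                    for behavior_class in BEHAVIOR_CLASSES:
                        c = counts[behavior_class]
                        if c > 0:
                            events.append(
                                ObservationEvent(
                                    event_id=event_id,
                                    date=when,
                                    site_id=site_id,
                                    regime=regime,
                                    habitat=habitat,
                                    species_id=sp,
                                    behavior_class=behavior_class,
                                    count=c,
                                )
                            )
    return events


def _latent_scale(
    config: SimConfig, label: tuple[str, str], z: dict[str, float]
) -> float:
    loading = config.latent_factor_loadings.get(label, 0.0)
    if loading == 0.0:
        return 1.0
    return math.exp(loading * z[config.factor_of(label)] - 0.5 * loading**2)


def loading_for_rho(rho: float, column_mean: float, dispersion: float) -> float:
    """Solve for the factor loading that yields ~rho between two same-factor
    gamma-Poisson columns with the given marginal mean.

    Derivation: with multiplier W = G exp(a z - a^2/2) (independent gamma G
    of shape k, shared normal z), Var(X) = mu + mu^2 ((1+1/k) e^{a^2} - 1)
    and Cov = mu^2 (e^{a^2} - 1), giving
    e^{a^2} = (mu (1-rho) + rho) / (mu (1 - rho (1+1/k))).
    Feasible only while rho < k/(k+1).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho {rho} outside [0, 1)")
    if rho == 0.0:
        return 0.0
    k = dispersion
    denom = column_mean * (1.0 - rho * (1.0 + 1.0 / k))
    if denom <= 0:
        raise ValueError(
            f"rho {rho} unattainable at dispersion {k} (needs rho < k/(k+1))"
        )
    e_a2 = (column_mean * (1.0 - rho) + rho) / denom
    if e_a2 < 1.0:
        return 0.0
    return math.sqrt(math.log(e_a2))


def plant_block_correlation(
    config: SimConfig,
    groups: list[list[tuple[str, str]]],
    rho: float,
) -> SimConfig:
    """Return a config whose loadings induce ~rho within each group of node
    labels and ~0 between groups, leaving marginal means unchanged.

    Each group gets its own latent factor; labels outside every group keep
    their existing loadings. Groups must be disjoint.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho {rho} outside [0, 1)")
    flat = [lbl for grp in groups for lbl in grp]
    if len(set(flat)) != len(flat):
        raise ValueError("groups must be disjoint")

    loadings = dict(config.latent_factor_loadings)
    factor_groups = dict(config.latent_factor_groups)
    for gi, group in enumerate(groups):
        for label in group:
            mu = _expected_column_mean(config, label)
            loadings[label] = loading_for_rho(rho, mu, config.dispersion)
            factor_groups[label] = f"block-{gi}"
    return replace(
        config,
        latent_factor_loadings=loadings,
        latent_factor_groups=factor_groups,
    )


def _expected_column_mean(config: SimConfig, label: tuple[str, str]) -> float:
    """Mean column value for a node label, averaged over configured strata
    where the species can appear (inclusion-weighted)."""
    sp, behavior_class = label
    keys = [k for k in config.abundance_mean if k[2] == sp]
    if not keys:
        raise ValueError(f"species {sp!r} has no configured abundance")
    if behavior_class == "forage":
        frac = config.activity_split
    elif behavior_class == "roost":
        frac = 1.0 - config.activity_split
    else:
        frac = config.behavior_rates.get(behavior_class, 0.0)
    means = [
        config.habitat_suitability.get(k, 0.0) * config.abundance_mean[k] * frac
        for k in keys
    ]
    mu = float(np.mean([m for m in means if m > 0] or [0.0]))
    if mu <= 0:
        raise ValueError(f"label {label} has zero expected abundance")
    return mu


def bridged_blocks_scenario(
    catalog: SpeciesCatalog,
    n_days: int = 1000,
    rho: float = 0.6,
    seed: int = 0,
) -> tuple[SimConfig, list[tuple[str, str]], list[tuple[str, str]], str]:
    """A parameter-recovery scenario: two planted correlation blocks joined
    by one bridge species with a node in each.

    Every species appears in a single (R1, MF) stratum with no background
    loadings; the first four species' forage nodes form one block, and the
    bridge species' roost node plus three others' roost nodes the second.
    The per-species gamma multiplier couples the bridge species' two nodes,
    so the recovered network should connect the blocks through it and rank
    it first. Returns (config, block1, block2, bridge_species_id).
    """
    ids = catalog.species_ids
    if len(ids) < 7:
        raise ValueError("scenario needs at least 7 species")
    bridge = ids[0]
    block1 = [(sp, "forage") for sp in ids[:4]]
    block2 = [(bridge, "roost")] + [(sp, "roost") for sp in ids[4:7]]
    config = SimConfig(
        n_days=n_days,
        sites=[("L1", "R1")],
        habitat_suitability={("R1", "MF", sp): 1.0 for sp in ids},
        abundance_mean={("R1", "MF", sp): 200.0 for sp in ids},
        dispersion=20.0,
        activity_split=0.5,
        behavior_rates={},
        latent_factor_loadings={},
        seed=seed,
    )
    return plant_block_correlation(config, [block1, block2], rho), block1, block2, bridge


# --- YAML round-trip -------------------------------------------------------

def config_to_yaml(config: SimConfig, path) -> None:
    doc = {
        "n_days": config.n_days,
        "sites": [list(s) for s in config.sites],
        "habitat_suitability": {
            "|".join(k): v for k, v in sorted(config.habitat_suitability.items())
        },
        "abundance_mean": {
            "|".join(k): v for k, v in sorted(config.abundance_mean.items())
        },
        "dispersion": config.dispersion,
        "activity_split": config.activity_split,
        "behavior_rates": dict(sorted(config.behavior_rates.items())),
        "latent_factor_loadings": {
            "|".join(k): v for k, v in sorted(config.latent_factor_loadings.items())
        },
        "latent_factor_groups": {
            "|".join(k): v for k, v in sorted(config.latent_factor_groups.items())
        },
        "start_date": config.start_date.isoformat(),
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        return SimConfig(
            n_days=int(doc["n_days"]),
            sites=[tuple(s) for s in doc["sites"]],
            habitat_suitability={
                tuple(k.split("|")): float(v)
                for k, v in doc["habitat_suitability"].items()
            },
            abundance_mean={
                tuple(k.split("|")): float(v)
                for k, v in doc["abundance_mean"].items()
            },
            dispersion=float(doc["dispersion"]),
            activity_split=float(doc["activity_split"]),
            behavior_rates={k: float(v) for k, v in doc["behavior_rates"].items()},
            latent_factor_loadings={
                tuple(k.split("|")): float(v)
                for k, v in doc.get("latent_factor_loadings", {}).items()
            },
            latent_factor_groups={
                tuple(k.split("|")): str(v)
                for k, v in doc.get("latent_factor_groups", {}).items()
            },
            start_date=_date.fromisoformat(doc.get("start_date", "2016-11-01")),
            seed=int(doc.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"config is missing field {exc.args[0]!r}") from None
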