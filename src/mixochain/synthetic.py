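"""Synthetic mixotrophic chain-elongation reactor with known ground truth.

The generator mimics the study design every analysis stage consumes: a
1-L semi-continuous reactor fed lactate/acetate medium at a fixed
hydraulic retention time, sparged from a recirculated H₂/CO/CO₂/N₂
reservoir that is periodically replenished, and inhabited by a small set
of metabolic guilds:

* a **homoacetogen** reducing H₂/CO/CO₂ to acetate (favoured by CO),
* a **mixotrophic elongator** converting lactate + acetate (plus some
  H₂/CO) to n-caproate and i-butyrate (requires CO),
* a **lactate heterotroph** fermenting lactate to n-butyrate, CO₂ and H₂
  (inhibited by CO), and
* a **propionate producer** running the acrylate route (CO-neutral).

Every guild stoichiometry is exactly electron- and carbon-balanced, so a
noiseless run closes the electron balance to machine precision and the
estimated interval rates reproduce the recorded ground truth.  Guild
kinetics are Monod in each consumed substrate, multiplied by a CO
response term (K/(K+p_CO) for CO-inhibited guilds, p_CO/(K+p_CO) for
CO-requiring ones), which drives the antagonistic dominance cycles of
the two gas-consuming guilds as the reservoir CO is drawn down and
restored.

Sequencing is emulated with a Dirichlet-multinomial layer: each guild is
split over several ASVs (as real populations are) and counts are drawn
at a fixed depth with tunable overdispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import AsvMatrix
from .reactor_rates import (
    BrothSample,
    FeedEvent,
    GasSample,
    R_GAS,
    RateRecord,
    ReactorConfig,
    gas_phase_moles,
)
from .stoichiometry import CompoundRegistry, default_registry

__all__ = [
    "GuildSpec",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "default_guilds",
    "antagonistic_pair_config",
    "default_config",
    "paperlike_config",
    "simulate",
    "sample_asv_counts",
    "guild_sequences",
]

GASES = ("H2", "CO", "CO2", "N2")

#: Nominal reservoir composition restored at each replenishment
#: (fractions of total pressure): H₂/CO/CO₂/N₂.
NOMINAL_GAS_FRACTIONS = {"H2": 0.32, "CO": 0.32, "CO2": 0.16, "N2": 0.20}

CO_RESPONSES = ("inhibited_by_CO", "requires_CO", "neutral")


@dataclass(frozen=True)
class GuildSpec:
    """One metabolic guild: stoichiometry, kinetics and CO response.

    ``stoichiometry`` maps compound → signed mmol per mmol of the
    ``reference`` substrate (consumption negative).  It must be electron-
    and carbon-balanced (Σ coeff·γ = Σ coeff·n_C = 0) — any biomass term
    included in the map participates in the check like any other
    compound.  ``max_uptake`` is the reference-substrate uptake capacity
    in mmol L⁻¹ d⁻¹ per unit of relative biomass; ``half_saturation``
    maps each consumed substrate to its Monod constant (mM for dissolved
    compounds, bar for gases).
    """

    name: str
    stoichiometry: Mapping[str, float]
    reference: str
    max_uptake: float
    half_saturation: Mapping[str, float]
    co_response: str = "neutral"
    k_co: float = 0.05              # bar
    growth_yield: float = 0.01      # relative biomass per mmol reference

    def __post_init__(self) -> None:
        if self.co_response not in CO_RESPONSES:
            raise ValueError(f"unknown co_response {self.co_response!r}")
        if self.reference not in self.stoichiometry:
            raise ValueError(f"{self.name}: reference substrate not in stoichiometry")
        if self.stoichiometry[self.reference] >= 0:
            raise ValueError(f"{self.name}: reference substrate must be consumed")
        if self.max_uptake <= 0 or self.k_co <= 0 or self.growth_yield < 0:
            raise ValueError(f"{self.name}: kinetic parameters must be positive")

    def validate_balance(self, registry: CompoundRegistry, tol: float = 1e-6) -> None:
        e = sum(c * registry[n].gamma for n, c in self.stoichiometry.items())
        cc = sum(c * registry[n].n_c for n, c in self.stoichiometry.items())
        if abs(e) > tol:
            raise ValueError(f"{self.name}: stoichiometry not electron-balanced ({e:g})")
        if abs(cc) > tol:
            raise ValueError(f"{self.name}: stoichiometry not carbon-balanced ({cc:g})")

    def substrates(self) -> list[str]:
        return [n for n, c in self.stoichiometry.items() if c < 0]

    def co_term(self, p_co: float) -> float:
        if self.co_response == "inhibited_by_CO":
            return self.k_co / (self.k_co + p_co)
        if self.co_response == "requires_CO":
            return p_co / (self.k_co + p_co)
        return 1.0


def default_guilds() -> list[GuildSpec]:
    """The four-guild community used by the default synthetic reactor.

    All stoichiometries are textbook acetogenesis / lactate chain
    elongation, written per mmol of reference substrate and exactly
    balanced in electrons and carbon:

    * homoacetogen:   3 H₂ + CO + CO₂ → acetate (+ H₂O)       (per CO)
    * elongator:      lactate + 0.1 acetate + H₂ + CO →
                      0.4 n-caproate + 0.2 i-butyrate + CO₂   (per lactate;
                      the C6 route 2 lactate + acetate → caproate + 2 CO₂
                      blended 80:20 with an i-butyrate route, plus
                      H₂/CO-driven acetogenesis)
    * heterotroph:    lactate → ½ n-butyrate + CO₂ + H₂       (per lactate)
    * propionate:     lactate → ⅔ propionate + ⅓ acetate + ⅓ CO₂
                      (acrylate pathway; per lactate)

    The two CO-requiring guilds draw the reservoir down after each
    replenishment; the CO-inhibited heterotroph takes over once CO runs
    low, producing the antagonistic dominance cycles seen in mixotrophic
    reactors.
    """
    return [
        GuildSpec(
            name="homoacetogen",
            stoichiometry={"H2": -3.0, "CO": -1.0, "CO2": -1.0, "acetate": 1.0},
            reference="CO",
            max_uptake=40.0,
            half_saturation={"H2": 0.03, "CO": 0.02, "CO2": 0.02},
            co_response="requires_CO",
            k_co=0.03,
            growth_yield=0.012,
        ),
        GuildSpec(
            name="elongator",
            stoichiometry={
                "lactate": -1.0,
                "acetate": -0.1,
                "H2": -1.0,
                "CO": -1.0,
                "n-caproate": 0.4,
                "i-butyrate": 0.2,
                "CO2": 1.0,
            },
            reference="lactate",
            max_uptake=30.0,
            half_saturation={"lactate": 4.0, "acetate": 10.0, "H2": 0.02, "CO": 0.01},
            co_response="requires_CO",
            k_co=0.02,
            growth_yield=0.016,
        ),
        GuildSpec(
            name="heterotroph",
            stoichiometry={"lactate": -1.0, "n-butyrate": 0.5, "CO2": 1.0, "H2": 1.0},
            reference="lactate",
            max_uptake=30.0,
            half_saturation={"lactate": 5.0},
            co_response="inhibited_by_CO",
            k_co=0.05,
            growth_yield=0.012,
        ),
        GuildSpec(
            name="propionate_producer",
            stoichiometry={
                "lactate": -1.0,
                "propionate": 2.0 / 3.0,
                "acetate": 1.0 / 3.0,
                "CO2": 1.0 / 3.0,
            },
            reference="lactate",
            max_uptake=20.0,
            half_saturation={"lactate": 8.0},
            co_response="neutral",
            growth_yield=0.010,
        ),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Simulation schedule, kinetics, noise and sequencing settings."""

    duration: float = 140.0                # days
    dt: float = 0.05                       # days; ≤ feed_interval/10
    reactor: ReactorConfig = field(
        default_factory=lambda: ReactorConfig(
            gas_system_volume=10.0, feed_interval=2.0
        )
    )
    feed_composition: Mapping[str, float] = field(
        default_factory=lambda: {"lactate": 133.0, "acetate": 200.0}
    )
    replenish_interval: float | None = 8.0    # days; multiple of feed interval
    gas_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(NOMINAL_GAS_FRACTIONS)
    )
    initial_broth: Mapping[str, float] = field(
        default_factory=lambda: {"lactate": 133.0, "acetate": 200.0}
    )
    initial_biomass: Mapping[str, float] | None = None  # guild → relative units
    guilds: Sequence[GuildSpec] = field(default_factory=default_guilds)
    noise_sd: float = 0.0                  # lognormal sd on observations
    sequencing_depth: int = 31892
    sequencing_dispersion: float = 300.0
    asvs_per_guild: int = 3
    sink_fraction: float = 0.0             # electron fraction diverted to biomass sink
    seed: int = 0
    reactor_id: str = "R1"

    def __post_init__(self) -> None:
        if self.dt > self.reactor.feed_interval / 10 + 1e-12:
            raise ValueError("dt must be at most feed_interval / 10")
        if not 0.0 <= self.sink_fraction < 1.0:
            raise ValueError("sink_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Exact quantities underlying one simulated dataset."""

    rates: list[RateRecord]                  # dilution-corrected, per interval
    guild_abundance: pd.DataFrame            # sample time × guild proportions
    sink_e_rates: dict[tuple[float, float], float]  # interval → e⁻-mmol L⁻¹ d⁻¹


@dataclass(frozen=True)
class SimResult:
    broth_samples: list[BrothSample]
    gas_samples: list[GasSample]
    feed_events: list[FeedEvent]
    truth: GroundTruth
    config: SimConfig


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """140-day reactor at HRT 14 d, fed every 2 days — the standard test bed.

    The gas reservoir (10 L at 32/32/16/20 H₂/CO/CO₂/N₂) is replenished
    every 8 days, giving 70 two-day sampling intervals and CO draw-down
    cycles slow enough for guild abundances to track them.
    """
    return SimConfig(seed=seed, **overrides)


def paperlike_config(seed: int = 0, duration: float = 292.0) -> SimConfig:
    """Preset approximating the full study design.

    292 days, HRT 14 d, daily feeding of 133 mM lactate + 200 mM acetate,
    32/32/16/20 H₂/CO/CO₂/N₂ reservoir, mild observation noise and
    sequencing at the study's rarefaction depth.
    """
    return SimConfig(
        duration=duration,
        seed=seed,
        noise_sd=0.02,
        sink_fraction=0.05,
    )


def antagonistic_pair_config(seed: int = 0, **overrides) -> SimConfig:
    """Two gas-consuming guilds with opposite CO responses, nothing else.

    The CO-requiring homoacetogen draws the reservoir CO down, handing
    the advantage to the CO-inhibited heterotroph until the next
    replenishment — the canonical cyclic-dominance configuration.
    """
    guilds = [g for g in default_guilds() if g.name in ("homoacetogen", "heterotroph")]
    return SimConfig(guilds=guilds, seed=seed, **overrides)


def _nominal_gas_moles(config: SimConfig) -> dict[str, float]:
    r = config.reactor
    return {
        g: gas_phase_moles(
            frac * r.total_pressure, r.gas_system_volume, r.temperature
        )
        for g, frac in config.gas_fractions.items()
    }


def simulate(
    config: SimConfig, registry: CompoundRegistry | None = None
) -> SimResult:
    """Integrate the guild model and emit observations plus ground truth.

    Explicit Euler in time; per step each guild's reference-substrate
    uptake is Monod-limited in every consumed substrate, scaled by its CO
    response, and capped so no pool goes negative.  Broth is sampled
    pre-feed at every feed time; gas is sampled with each broth sample
    and again right after each reservoir replenishment.  Observation
    noise is multiplicative lognormal; a noiseless run reproduces the
    recorded ground truth exactly.
    """
    registry = registry or default_registry()
    for guild in config.guilds:
        guild.validate_balance(registry)

    r = config.reactor
    rng = np.random.default_rng([config.seed, 0x5EED])
    replenish_every = config.replenish_interval or r.feed_interval

    conc: dict[str, float] = dict(config.initial_broth)
    gas_n: dict[str, float] = _nominal_gas_moles(config)
    biomass: dict[str, float] = dict(
        config.initial_biomass
        or {g.name: 1.0 / len(config.guilds) for g in config.guilds}
    )

    n_feeds = int(round(config.duration / r.feed_interval))
    feed_times = [k * r.feed_interval for k in range(1, n_feeds + 1)]
    sample_times = [0.0] + feed_times
    f = r.exchange_fraction

    broth_samples: list[BrothSample] = []
    gas_samples: list[GasSample] = []
    feed_events: list[FeedEvent] = []
    truth_rates: list[RateRecord] = []
    abundance_rows: list[dict[str, float]] = []
    sink_rates: dict[tuple[float, float], float] = {}

    acc_broth: dict[str, float] = {}
    acc_gas: dict[str, float] = {}
    acc_sink_e = 0.0
    interval_start = 0.0

    def noisy(value: float) -> float:
        if config.noise_sd == 0.0:
            return value
        return value * math.exp(rng.normal(0.0, config.noise_sd))

    def record_sample(t: float) -> None:
        nonlocal acc_broth, acc_gas, acc_sink_e, interval_start
        broth_samples.append(
            BrothSample(
                t,
                {c: max(noisy(v), 0.0) for c, v in conc.items()},
                od600=sum(biomass.values()),
            )
        )
        p_now = {
            g: n * R_GAS * r.temperature / r.gas_system_volume * 1e-3
            for g, n in gas_n.items()
        }
        gas_samples.append(GasSample(t, {g: max(noisy(p), 0.0) for g, p in p_now.items()}))
        total_b = sum(biomass.values())
        abundance_rows.append(
            {
                "time_d": t,
                **{
                    g: (b / total_b if total_b > 0 else 0.0)
                    for g, b in biomass.items()
                },
            }
        )
        if t > interval_start:
            dt_int = t - interval_start
            for c, dv in acc_broth.items():
                truth_rates.append(
                    RateRecord(interval_start, t, c, dv / dt_int, config.reactor_id)
                )
            for g, dn in acc_gas.items():
                truth_rates.append(
                    RateRecord(
                        interval_start, t, g,
                        dn / (dt_int * r.liquid_volume),
                        config.reactor_id,
                    )
                )
            sink_rates[(interval_start, t)] = acc_sink_e / dt_int
        acc_broth, acc_gas, acc_sink_e = {}, {}, 0.0
        interval_start = t

    record_sample(0.0)

    n_steps = int(round(config.duration / config.dt))
    next_feed = 0
    next_replenish = replenish_every

    for step in range(1, n_steps + 1):
        t = step * config.dt
        # --- reaction step over (t - dt, t) -------------------------------
        p_gas = {
            g: n * R_GAS * r.temperature / r.gas_system_volume * 1e-3
            for g, n in gas_n.items()
        }
        delta_conc: dict[str, float] = {}
        delta_gas: dict[str, float] = {}
        step_sink_e = 0.0
        desired: dict[str, float] = {}
        for guild in config.guilds:
            b = biomass[guild.name]
            if b <= 0:
                continue
            limit = guild.co_term(p_gas.get("CO", 0.0))
            for s in guild.substrates():
                ks = guild.half_saturation.get(s)
                if ks is None:
                    continue
                level = p_gas[s] if registry[s].phase == "gas" else conc.get(s, 0.0)
                limit *= level / (ks + level)
            uptake = guild.max_uptake * b * limit * config.dt  # mmol ref / L
            if uptake > 0:
                desired[guild.name] = uptake
        # joint cap: scale uptakes so no shared pool is overdrawn this step
        demand: dict[str, float] = {}
        for guild in config.guilds:
            u = desired.get(guild.name, 0.0)
            for s in guild.substrates():
                demand[s] = demand.get(s, 0.0) - guild.stoichiometry[s] * u
        scale: dict[str, float] = {}
        for s, need in demand.items():
            if need <= 0:
                continue
            if registry[s].phase == "gas":
                avail = gas_n.get(s, 0.0) / r.liquid_volume
            else:
                avail = conc.get(s, 0.0)
            scale[s] = min(1.0, avail / need)
        for guild in config.guilds:
            uptake = desired.get(guild.name, 0.0)
            if uptake <= 0:
                continue
            uptake *= min((scale.get(s, 1.0) for s in guild.substrates()), default=1.0)
            if uptake <= 0:
                continue
            for compound, coeff in guild.stoichiometry.items():
                amount = coeff * uptake  # mmol per L liquid
                if coeff > 0 and config.sink_fraction > 0:
                    sunk = amount * config.sink_fraction
                    amount -= sunk
                    step_sink_e += sunk * registry[compound].gamma
                if registry[compound].phase == "gas":
                    delta_gas[compound] = delta_gas.get(compound, 0.0) + amount
                else:
                    delta_conc[compound] = delta_conc.get(compound, 0.0) + amount
            biomass[guild.name] += guild.growth_yield * uptake

        for c, dv in delta_conc.items():
            conc[c] = max(conc.get(c, 0.0) + dv, 0.0)
            acc_broth[c] = acc_broth.get(c, 0.0) + dv
        for g, dn in delta_gas.items():
            gas_n[g] = max(gas_n.get(g, 0.0) + dn * r.liquid_volume, 0.0)
            acc_gas[g] = acc_gas.get(g, 0.0) + dn * r.liquid_volume
        acc_sink_e += step_sink_e

        # --- scheduled events at time t -----------------------------------
        if next_feed < len(feed_times) and math.isclose(
            t, feed_times[next_feed], abs_tol=config.dt / 4
        ):
            record_sample(feed_times[next_feed])
            event = FeedEvent(
                feed_times[next_feed], f, dict(config.feed_composition)
            )
            feed_events.append(event)
            names = set(conc) | set(config.feed_composition)
            for c in names:
                conc[c] = conc.get(c, 0.0) * (1 - f) + config.feed_composition.get(c, 0.0) * f
            for g in biomass:
                biomass[g] *= 1 - f
            next_feed += 1

            if math.isclose(t, next_replenish, abs_tol=config.dt / 4):
                # pre-replenishment state was just sampled; restore nominal mix
                gas_n = _nominal_gas_moles(config)
                p_post = {
                    g: n * R_GAS * r.temperature / r.gas_system_volume * 1e-3
                    for g, n in gas_n.items()
                }
                gas_samples.append(
                    GasSample(
                        t,
                        {g: max(noisy(p), 0.0) for g, p in p_post.items()},
                        is_post_replenishment=True,
                    )
                )
                next_replenish += replenish_every

    if not math.isclose(sample_times[-1], config.duration, abs_tol=1e-9):
        record_sample(config.duration)

    abundance = pd.DataFrame(abundance_rows).set_index("time_d")
    truth = GroundTruth(truth_rates, abundance, sink_rates)
    return SimResult(broth_samples, gas_samples, feed_events, truth, config)


# --------------------------------------------------------------------------
# Sequencing layer


def guild_sequences(
    guilds: Sequence[str],
    asvs_per_guild: int,
    seed: int,
    *,
    length: int = 250,
    within_guild_mutations: int = 2,
) -> tuple[dict[str, str], dict[str, str]]:
    """Synthetic 16S-like ASV sequences, several per guild.

    Each guild gets a random base sequence; its ASVs differ from it by a
    couple of point mutations (so within-guild identity is ~99%), while
    guilds are mutually unrelated random sequences.  Returns
    (asv → sequence, asv → guild).
    """
    rng = np.random.default_rng([seed, 0xA5])
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    asv_guild: dict[str, str] = {}
    counter = 1
    for guild in guilds:
        backbone = rng.choice(bases, size=length)
        for _ in range(asvs_per_guild):
            seq = backbone.copy()
            sites = rng.choice(length, size=within_guild_mutations, replace=False)
            for pos in sites:
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            asv_id = f"ASV{counter:03d}"
            sequences[asv_id] = "".join(seq)
            asv_guild[asv_id] = guild
            counter += 1
    return sequences, asv_guild


def sample_asv_counts(
    abundances: pd.DataFrame,
    depth: int,
    dispersion: float,
    seed: int,
    *,
    asvs_per_guild: int = 3,
    sample_meta: pd.DataFrame | None = None,
) -> AsvMatrix:
    """Dirichlet-multinomial sequencing counts from guild proportions.

    ``abundances`` is samples × guilds with rows summing to 1.  Each
    guild is spread over ``asvs_per_guild`` ASVs with fixed (seeded)
    within-guild weights, mirroring how one population shows up as
    several sequence variants.  Per sample, proportions are jittered with
    a Dirichlet draw of concentration ``dispersion`` × proportions and
    counted with a multinomial of size ``depth``; larger dispersion
    approaches a plain multinomial.  Taxa with zero proportion never
    receive counts.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rowsum = abundances.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-6):
        raise ValueError("guild proportions must sum to 1 per sample")

    guilds = list(abundances.columns)
    sequences, asv_guild = guild_sequences(guilds, asvs_per_guild, seed)
    asv_ids = sorted(asv_guild)
    rng = np.random.default_rng([seed, 0xD1])
    split = {
        g: rng.dirichlet(np.full(asvs_per_guild, 5.0)) for g in guilds
    }  # fixed within-guild ASV weights

    rows = []
    for _, guild_props in abundances.iterrows():
        p = np.array(
            [
                guild_props[asv_guild[a]]
                * split[asv_guild[a]][
                    [x for x in asv_ids if asv_guild[x] == asv_guild[a]].index(a)
                ]
                for a in asv_ids
            ]
        )
        counts = np.zeros(len(asv_ids), dtype=np.int64)
        nz = p > 0
        if nz.any():
            theta = rng.dirichlet(dispersion * p[nz])
            counts[nz] = rng.multinomial(depth, theta)
        rows.append(counts)

    if sample_meta is not None:
        index = sample_meta.index
    else:
        index = pd.Index(
            [f"S{i:03d}" for i in range(len(abundances))], name="sample_id"
        )
    counts_df = pd.DataFrame(rows, index=index, columns=asv_ids)
    taxonomy = {
        a: ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales",
            "synthetic", asv_guild[a], f"{asv_guild[a]} sp.")
        for a in asv_ids
    }
    return AsvMatrix(
        counts=counts_df,
        sample_meta=sample_meta,
        taxonomy=taxonomy,
        sequences=sequences,
    )
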