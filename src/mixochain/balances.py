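"""Electron and carbon balances aggregated over operating periods.

Rates are pooled into the groups used throughout chain-elongation
bookkeeping: the organic donor (lactate) and acceptor (acetate) fed with
the medium, the gases H₂/CO/CO₂, the product chain-length classes
C2 … C≥7 (each class groups the carboxylate and its alcohol of equal
chain length), an *others* pool (biomass, formate, CH₄), and an *unknown*
residual defined as consumed-minus-produced-minus-others.  Pools are kept
signed (production +, consumption −) in both electron equivalents
(e⁻-mmol L⁻¹ d⁻¹) and carbon equivalents (C-mmol L⁻¹ d⁻¹).

The carbon-fixation rate is defined as the net gaseous-carbon uptake,
−(r_CO + r_CO₂): carbon monoxide and dioxide taken out of the gas loop
minus any CO₂ returned to it.  CO₂ emissions are attributed to lactate
decarboxylation (one CO₂ per lactate routed to acetyl-CoA; lactate routed
to propionate or to the C3 primer of n-valerate via the acrylate pathway
releases none) with the shortfall booked as abatement by CO₂ consumers
and any excess as CO oxidation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .reactor_rates import RateRecord
from .stoichiometry import CompoundRegistry, CompoundSpec, c_rate_to_gCO2

__all__ = [
    "PeriodBalance",
    "CO2Attribution",
    "CarbonFixation",
    "BalanceError",
    "POOL_ORDER",
    "pool_of",
    "period_balance",
    "carbon_fixation_rate",
    "co2_attribution",
    "yield_elongated",
    "compare_communities",
]

POOL_ORDER = (
    "lactate_in",
    "acetate_in",
    "H2",
    "CO",
    "CO2",
    "C2",
    "C3",
    "C4",
    "C5",
    "C6",
    "C>=7",
    "others",
    "unknown",
)

#: Pools whose consumption counts as electron-donor supply.  CO₂ carries
#: no electrons (γ = 0) so it contributes carbon only.
DONOR_POOLS = ("lactate_in", "H2", "CO", "CO2")

ELONGATED_POOLS = ("C4", "C5", "C6", "C>=7")


class BalanceError(ValueError):
    """Raised for inconsistent balance inputs."""


def pool_of(spec: CompoundSpec, net_rate: float) -> str:
    """Pool assignment for one compound given its net (signed) rate.

    Lactate is always the organic-donor pool.  Acetate is part of the feed,
    so net consumption books it as ``acetate_in`` while net production
    books it with the C2 products.  Gases keep their own pools; biomass,
    formate and CH₄ form ``others``; everything else pools by chain
    length.
    """
    if spec.name == "lactate":
        return "lactate_in"
    if spec.name == "acetate":
        return "acetate_in" if net_rate < 0 else "C2"
    if spec.name in ("H2", "CO", "CO2"):
        return spec.name
    if spec.name in ("biomass", "formate", "CH4"):
        return "others"
    n = spec.chain_length
    if n >= 7:
        return "C>=7"
    if n >= 2:
        return f"C{n}"
    return "others"


@dataclass(frozen=True)
class PeriodBalance:
    """Signed pool rates for one reactor over one time window."""

    reactor_id: str | None
    window: tuple[float, float]
    pools_e: Mapping[str, float]  # e⁻-mmol L⁻¹ d⁻¹
    pools_c: Mapping[str, float]  # C-mmol L⁻¹ d⁻¹

    def consumed_e(self) -> float:
        """Total electron consumption (positive number)."""
        return -sum(v for k, v in self.pools_e.items() if v < 0 and k != "unknown")

    def produced_e(self) -> float:
        """Total electron production excluding others/unknown."""
        return sum(
            v
            for k, v in self.pools_e.items()
            if v > 0 and k not in ("others", "unknown")
        )

    def donors_e(self) -> float:
        """Electron-donor consumption (lactate + H₂ + CO; positive)."""
        return -sum(min(self.pools_e.get(p, 0.0), 0.0) for p in DONOR_POOLS)


@dataclass(frozen=True)
class CO2Attribution:
    """Source attribution of CO₂ emissions, mmol CO₂ L⁻¹ d⁻¹.

    Satisfies emitted = expected_decarboxylation − abated + co_oxidation.
    """

    expected_decarboxylation: float
    abated: float
    emitted: float
    co_oxidation: float

    def __post_init__(self) -> None:
        for name in ("expected_decarboxylation", "abated", "emitted", "co_oxidation"):
            if getattr(self, name) < -1e-9:
                raise BalanceError(f"{name} must be non-negative")
        identity = self.expected_decarboxylation - self.abated + self.co_oxidation
        if not math.isclose(identity, self.emitted, rel_tol=1e-9, abs_tol=1e-9):
            raise BalanceError("CO2 attribution identity violated")


@dataclass(frozen=True)
class CarbonFixation:
    """Net gaseous-carbon uptake in both reporting units."""

    c_mmol_per_L_d: float
    g_co2_eq_per_L_d: float


def _time_weighted_means(
    rates: Iterable[RateRecord], window: tuple[float, float]
) -> dict[str, float]:
    t0, t1 = window
    if t1 <= t0:
        raise BalanceError(f"empty or inverted window {window}")
    weight: dict[str, float] = {}
    total: dict[str, float] = {}
    for r in rates:
        lo, hi = max(r.t_start, t0), min(r.t_end, t1)
        if hi <= lo:
            continue
        total[r.compound] = total.get(r.compound, 0.0) + r.rate * (hi - lo)
        weight[r.compound] = weight.get(r.compound, 0.0) + (hi - lo)
    if not total:
        raise BalanceError(f"no rate records overlap window {window}")
    return {c: total[c] / weight[c] for c in total}


def period_balance(
    rates: Iterable[RateRecord],
    registry: CompoundRegistry,
    window: tuple[float, float],
    *,
    reactor_id: str | None = None,
) -> PeriodBalance:
    """Aggregate per-interval rates into signed pool rates over a window.

    Per compound the time-weighted mean rate over the window is computed
    first (so 1-day and 3.5-day sampling intervals weigh in proportion to
    their duration), then multiplied by γ and n_C and summed into pools.
    ``unknown`` closes the electron and carbon balances exactly.
    """
    means = _time_weighted_means(rates, window)
    pools_e = {p: 0.0 for p in POOL_ORDER}
    pools_c = {p: 0.0 for p in POOL_ORDER}
    for compound, mean_rate in means.items():
        spec = registry[compound]
        pool = pool_of(spec, mean_rate)
        pools_e[pool] += mean_rate * spec.gamma
        pools_c[pool] += mean_rate * spec.n_c
    pools_e["unknown"] = -sum(v for k, v in pools_e.items() if k != "unknown")
    pools_c["unknown"] = -sum(v for k, v in pools_c.items() if k != "unknown")
    return PeriodBalance(reactor_id, window, pools_e, pools_c)


def carbon_fixation_rate(
    gas_rates: Iterable[RateRecord],
    window: tuple[float, float],
) -> CarbonFixation:
    """Net gaseous-carbon uptake −(r_CO + r_CO₂) over a window.

    Consumption rates are negative, so fixation is positive when more
    CO + CO₂ carbon leaves the gas loop than returns; a negative value
    means net gaseous-carbon emission.  CO and CO₂ each carry one carbon,
    so molar rates are carbon rates.
    """
    relevant = [r for r in gas_rates if r.compound in ("CO", "CO2")]
    if not relevant:
        return CarbonFixation(0.0, 0.0)
    means = _time_weighted_means(relevant, window)
    fixation = -(means.get("CO", 0.0) + means.get("CO2", 0.0))
    return CarbonFixation(fixation, c_rate_to_gCO2(fixation))


def co2_attribution(
    lactate_rate: float,
    odd_chain_product_rates: Mapping[str, float],
    co2_emission_rate: float,
    *,
    tol: float = 1e-9,
) -> CO2Attribution:
    """Attribute observed CO₂ emission to decarboxylation vs CO oxidation.

    Parameters
    ----------
    lactate_rate:
        Net lactate rate in mmol L⁻¹ d⁻¹ (consumption negative).
    odd_chain_product_rates:
        Production rates (positive) of odd-chain products that consume
        lactate without decarboxylation: one lactate per propionate and
        one per n-valerate (its C3 primer).
    co2_emission_rate:
        Observed net CO₂ emission (mmol L⁻¹ d⁻¹, ≥ 0).

    Every other lactate is decarboxylated once on the way to acetyl-CoA.
    Emission below the expected decarboxylation is booked as abatement by
    CO₂-consuming organisms; emission above it as CO oxidation.
    """
    if lactate_rate > tol:
        raise BalanceError("lactate must be net consumed (negative rate)")
    if co2_emission_rate < -tol:
        raise BalanceError("co2_emission_rate must be non-negative")
    consumed = -min(lactate_rate, 0.0)
    routed_odd = sum(max(v, 0.0) for v in odd_chain_product_rates.values())
    expected = consumed - routed_odd
    if expected < -tol:
        raise BalanceError(
            f"odd-chain products ({routed_odd:.4g} mmol/L/d) exceed lactate "
            f"consumption ({consumed:.4g} mmol/L/d): inconsistent rates"
        )
    expected = max(expected, 0.0)
    emitted = max(co2_emission_rate, 0.0)
    if emitted <= expected:
        abated, co_ox = expected - emitted, 0.0
    else:
        abated, co_ox = 0.0, emitted - expected
    return CO2Attribution(expected, abated, emitted, co_ox)


def yield_elongated(balance: PeriodBalance) -> float:
    """Elongation yield: e⁻-mmol of C≥4 products per e⁻-mmol lactate consumed."""
    lactate = -balance.pools_e.get("lactate_in", 0.0)
    if lactate <= 0:
        raise BalanceError("no lactate consumption in balance; yield undefined")
    produced = sum(
        max(balance.pools_e.get(p, 0.0), 0.0) for p in ELONGATED_POOLS
    )
    return produced / lactate


@dataclass(frozen=True)
class PoolComparison:
    """Fold-difference of one quantity between two balances (on magnitudes)."""

    quantity: str
    value_a: float
    value_b: float
    ratio: float           # |a| / |b|; inf when b == 0 and a != 0
    percent_difference: float  # 100·(|a| − |b|)/|b|
    undefined: bool = False


def _fold(quantity: str, a: float, b: float) -> PoolComparison:
    mag_a, mag_b = abs(a), abs(b)
    if mag_b == 0.0:
        if mag_a == 0.0:
            return PoolComparison(quantity, a, b, 1.0, 0.0, undefined=True)
        return PoolComparison(quantity, a, b, math.inf, math.inf, undefined=True)
    return PoolComparison(
        quantity, a, b, mag_a / mag_b, 100.0 * (mag_a - mag_b) / mag_b
    )


def compare_communities(
    a: PeriodBalance, b: PeriodBalance
) -> dict[str, PoolComparison]:
    """Fold-differences between two period balances (electron basis).

    Returns per-pool comparisons plus the derived quantities
    ``total_donors`` (lactate + H₂ + CO consumed), ``C2_C8`` (all
    produced chain pools), ``C3_C8`` (products longer than acetate) and
    ``C6_C8`` (medium-chain products), and the elongation ``yield``
    ratio.
    """
    if set(a.pools_e) != set(b.pools_e):
        raise BalanceError("balances use different pool groupings")
    out: dict[str, PoolComparison] = {}
    for pool in a.pools_e:
        out[pool] = _fold(pool, a.pools_e[pool], b.pools_e[pool])

    def produced(balance: PeriodBalance, pools: Sequence[str]) -> float:
        return sum(max(balance.pools_e.get(p, 0.0), 0.0) for p in pools)

    chain = ("C2", "C3", "C4", "C5", "C6", "C>=7")
    out["total_donors"] = _fold("total_donors", a.donors_e(), b.donors_e())
    out["C2_C8"] = _fold("C2_C8", produced(a, chain), produced(b, chain))
    out["C3_C8"] = _fold("C3_C8", produced(a, chain[1:]), produced(b, chain[1:]))
    out["C6_C8"] = _fold("C6_C8", produced(a, ("C6", "C>=7")), produced(b, ("C6", "C>=7")))
    try:
        out["yield"] = _fold("yield", yield_elongated(a), yield_elongated(b))
    except BalanceError:
        pass
    return out
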