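"""Spearman screen linking ASV abundances to chemical conversion rates.

Each observation pairs the relative ASV abundances of one community
sample with the per-interval production/consumption rates of the interval
that the sample closes (broth for sequencing is drawn right before
feeding, i.e. at interval end).  Short intervals produce noisy rate
estimates, so intervals below a minimum length (default 1 day) are
excluded before correlating.

The correlation is the tie-corrected Spearman rank correlation.  Its
two-sided p-value comes from the usual t approximation for n ≥ 8 and from
exhaustive enumeration of all n! rank permutations for smaller n, where
the approximation is poor.  Rate signs are kept as-is (consumption
negative), so a guild that consumes a gas correlates *negatively* with
that gas's signed rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import AsvMatrix, relative_abundance
from .reactor_rates import RateRecord

__all__ = [
    "PairedObservation",
    "ConstantInputError",
    "build_pairs",
    "spearman",
    "correlation_screen",
]


class ConstantInputError(ValueError):
    """Raised when a correlation input has no variation (rho undefined)."""


@dataclass(frozen=True)
class PairedObservation:
    """Abundances at interval end paired with that interval's rates."""

    sample_id: str
    reactor_id: str
    interval: tuple[float, float]
    abundance: Mapping[str, float]
    rates: Mapping[str, float]

    @property
    def interval_length(self) -> float:
        return self.interval[1] - self.interval[0]


def build_pairs(
    rates: Sequence[RateRecord],
    m: AsvMatrix,
    *,
    min_interval: float = 1.0,
    time_tolerance: float = 1e-6,
    match_on: str = "end",
) -> list[PairedObservation]:
    """Pair community samples with the rate interval they close.

    ``match_on="end"`` (default) pairs a sample at time t with the
    interval whose end is t — the pre-feed convention; ``"start"``
    switches to interval starts.  Intervals shorter than ``min_interval``
    are dropped.  Returns an empty list (with a warning) when nothing
    overlaps.
    """
    if match_on not in ("end", "start"):
        raise ValueError("match_on must be 'end' or 'start'")
    by_key: dict[tuple[str | None, float], dict[str, float]] = {}
    intervals: dict[tuple[str | None, float], tuple[float, float]] = {}
    for r in rates:
        if r.duration < min_interval - time_tolerance:
            continue
        anchor = r.t_end if match_on == "end" else r.t_start
        key = (r.reactor_id, round(anchor / time_tolerance) * time_tolerance)
        by_key.setdefault(key, {})[r.compound] = r.rate
        intervals[key] = (r.t_start, r.t_end)

    abundances = relative_abundance(m)
    observations: list[PairedObservation] = []
    for sample_id in m.sample_ids:
        reactor_id, t = m.meta_for(sample_id)
        key = (reactor_id, round(t / time_tolerance) * time_tolerance)
        if key not in by_key:
            key = (None, key[1])  # rates without reactor labels
            if key not in by_key:
                continue
        observations.append(
            PairedObservation(
                sample_id=sample_id,
                reactor_id=reactor_id,
                interval=intervals[key],
                abundance=abundances.loc[sample_id].to_dict(),
                rates=dict(by_key[key]),
            )
        )
    if not observations:
        warnings.warn(
            "no community sample matched a qualifying rate interval",
            stacklevel=2,
        )
    return observations


def _tie_corrected_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ConstantInputError("constant input; Spearman rho undefined")
    return float(rx @ ry) / denom


def _exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by enumerating all n! permutations of y."""
    n = len(y)
    hits = 0
    total = 0
    threshold = abs(rho_obs) - 1e-12
    for perm in permutations(range(n)):
        rho = _tie_corrected_rho(x, y[list(perm)])
        total += 1
        if abs(rho) >= threshold:
            hits += 1
    return hits / total


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman correlation with a two-sided p-value.

    For n < 8 the p-value is the exact permutation tail probability
    (all n! relabelings enumerated); for n ≥ 8 the t approximation
    t = ρ·√((n−2)/(1−ρ²)) with n−2 degrees of freedom is used.

    Raises :class:`ConstantInputError` when either vector is constant
    rather than silently reporting ρ = 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(xa)
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("inputs must be finite")
    rho = _tie_corrected_rho(xa, ya)
    if n < 8:
        return rho, _exact_p(xa, ya, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def correlation_screen(
    pairs: Sequence[PairedObservation],
    asv_ids: Iterable[str] | None = None,
    variables: Iterable[str] | None = None,
    *,
    alpha: float = 0.01,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Spearman matrix between ASV abundances and rate variables.

    Returns a long-format frame with columns ``asv_id, variable, rho, p,
    n, significant``.  Pairs missing a variable are skipped for that
    variable.  Constant inputs yield ``rho = NaN`` with a note rather
    than a silent zero.  ``bh_correct=True`` applies Benjamini–Hochberg
    adjustment to the p-values before flagging significance (raw p-values
    with a fixed alpha are the default).
    """
    if not pairs:
        raise ValueError("no paired observations to screen")
    if asv_ids is None:
        asv_ids = sorted({a for p in pairs for a in p.abundance})
    if variables is None:
        variables = sorted({v for p in pairs for v in p.rates})

    rows = []
    for asv in asv_ids:
        for var in variables:
            xs, ys = [], []
            for obs in pairs:
                if var not in obs.rates or asv not in obs.abundance:
                    continue
                xs.append(obs.abundance[asv])
                ys.append(obs.rates[var])
            note = ""
            rho = p = math.nan
            if len(xs) >= 4:
                try:
                    rho, p = spearman(xs, ys)
                except ConstantInputError:
                    note = "constant input"
            else:
                note = "too few observations"
            rows.append(
                {
                    "asv_id": asv,
                    "variable": var,
                    "rho": rho,
                    "p": p,
                    "n": len(xs),
                    "note": note,
                }
            )
    result = pd.DataFrame(rows)
    pvals = result["p"].to_numpy()
    effective = pvals.copy()
    valid = np.isfinite(pvals)
    if bh_correct and valid.any():
        effective[valid] = stats.false_discovery_control(pvals[valid], method="bh")
        result["p_adjusted"] = effective
    result["significant"] = np.where(valid, effective < alpha, False)
    return result
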