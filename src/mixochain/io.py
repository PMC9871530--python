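"""Readers, writers, pipeline configuration and the full analysis run.

File dialects
-------------
* broth CSV: ``time_d`` column, one column per compound (mM), optional
  ``od600``;
* feed-event CSV: ``time_d``, ``f`` and ``feed_<compound>`` columns (mM);
* gas CSV: ``time_d``, one column per gas (bar) and a 0/1
  ``post_replenishment`` flag;
* ASV counts TSV: samples × ASVs with a ``#sample_id`` header sentinel
  (the transposed orientation is auto-detected when the sentinel reads
  ``#asv_id``); sample metadata TSV with ``sample_id, reactor_id,
  time_d``; taxonomy TSV with ``asv_id`` and a semicolon-ranked
  ``lineage``; sequences as plain FASTA.

All times are days, all concentrations mM internally; unit conversion
happens only at reporting boundaries.  Every pipeline run writes a
manifest (config, seed, package version) next to its reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .balances import (
    POOL_ORDER,
    PeriodBalance,
    carbon_fixation_rate,
    period_balance,
    yield_elongated,
)
from .community import AsvMatrix, rarefy
from .correlation import build_pairs, correlation_screen
from .reactor_rates import (
    BrothSample,
    FeedEvent,
    GasSample,
    RateRecord,
    ReactorConfig,
    gas_consumption_rates,
    interval_rates,
)
from .stoichiometry import CompoundRegistry, default_registry

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_broth_csv",
    "write_broth_csv",
    "read_events_csv",
    "write_events_csv",
    "read_gas_csv",
    "write_gas_csv",
    "read_asv_matrix",
    "write_asv_matrix",
    "read_fasta",
    "write_fasta",
    "write_rates_tsv",
    "read_rates_tsv",
    "write_balance_report",
    "run_pipeline",
]


class FileFormatError(ValueError):
    """Malformed input file; message carries file and line context."""


# --------------------------------------------------------------------------
# reactor series


def read_broth_csv(path: str | Path) -> list[BrothSample]:
    path = Path(path)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "time_d" not in frame.columns:
        raise FileFormatError(f"{path}: missing required column 'time_d'")
    compounds = [c for c in frame.columns if c not in ("time_d", "od600")]
    samples = []
    for i, row in frame.iterrows():
        conc = {}
        for c in compounds:
            value = float(row[c])
            if value < 0:
                raise FileFormatError(
                    f"{path}, line {i + 2}: negative concentration for {c}"
                )
            conc[c] = value
        od = float(row["od600"]) if "od600" in frame.columns and pd.notna(row.get("od600")) else None
        samples.append(BrothSample(float(row["time_d"]), conc, od600=od))
    return samples


def write_broth_csv(samples: Sequence[BrothSample], path: str | Path) -> None:
    compounds = sorted({c for s in samples for c in s.concentrations})
    rows = []
    for s in samples:
        row = {"time_d": s.time}
        row.update({c: s.concentrations.get(c, 0.0) for c in compounds})
        if s.od600 is not None:
            row["od600"] = s.od600
        rows.append(row)
    with open(path, "w") as fh:
        fh.write("# broth concentrations in mM; time in days\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_events_csv(path: str | Path) -> list[FeedEvent]:
    path = Path(path)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("time_d", "f"):
        if col not in frame.columns:
            raise FileFormatError(f"{path}: missing required column {col!r}")
    feed_cols = [c for c in frame.columns if c.startswith("feed_")]
    events = []
    for i, row in frame.iterrows():
        f = float(row["f"])
        if not 0.0 <= f <= 1.0:
            raise FileFormatError(f"{path}, line {i + 2}: f={f} outside [0, 1]")
        comp = {c[len("feed_"):]: float(row[c]) for c in feed_cols}
        events.append(FeedEvent(float(row["time_d"]), f, comp))
    times = [e.time for e in events]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise FileFormatError(f"{path}: event times not strictly increasing")
    return events


def write_events_csv(events: Sequence[FeedEvent], path: str | Path) -> None:
    compounds = sorted({c for e in events for c in e.feed_composition})
    rows = [
        {
            "time_d": e.time,
            "f": e.f,
            **{f"feed_{c}": e.feed_composition.get(c, 0.0) for c in compounds},
        }
        for e in events
    ]
    with open(path, "w") as fh:
        fh.write("# feed events: exchange fraction f, feed composition in mM\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_gas_csv(path: str | Path) -> list[GasSample]:
    path = Path(path)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "time_d" not in frame.columns:
        raise FileFormatError(f"{path}: missing required column 'time_d'")
    gases = [c for c in frame.columns if c not in ("time_d", "post_replenishment")]
    samples = []
    for i, row in frame.iterrows():
        pressures = {}
        for g in gases:
            p = float(row[g])
            if p < 0:
                raise FileFormatError(
                    f"{path}, line {i + 2}: negative partial pressure for {g}"
                )
            pressures[g] = p
        flag = bool(int(row["post_replenishment"])) if "post_replenishment" in frame.columns else False
        samples.append(GasSample(float(row["time_d"]), pressures, flag))
    return samples


def write_gas_csv(samples: Sequence[GasSample], path: str | Path) -> None:
    gases = sorted({g for s in samples for g in s.partial_pressures})
    rows = [
        {
            "time_d": s.time,
            **{g: s.partial_pressures.get(g, 0.0) for g in gases},
            "post_replenishment": int(s.is_post_replenishment),
        }
        for s in samples
    ]
    with open(path, "w") as fh:
        fh.write("# gas partial pressures in bar (dry basis); time in days\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


# --------------------------------------------------------------------------
# community tables


def read_asv_matrix(
    counts_path: str | Path,
    meta_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
) -> AsvMatrix:
    counts_path = Path(counts_path)
    frame = pd.read_csv(counts_path, sep="\t", index_col=0)
    sentinel = frame.index.name or ""
    if sentinel.lstrip("#") == "asv_id":
        frame = frame.T  # stored transposed (ASVs × samples)
    elif sentinel.lstrip("#") != "sample_id":
        raise FileFormatError(
            f"{counts_path}: first header cell must be '#sample_id' or '#asv_id', "
            f"got {sentinel!r}"
        )
    frame.index.name = "sample_id"
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    taxonomy = {}
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t")
        for row in tax.itertuples(index=False):
            taxonomy[str(row.asv_id)] = tuple(str(row.lineage).split(";"))
    sequences = dict(read_fasta(fasta_path)) if fasta_path is not None else {}
    return AsvMatrix(
        counts=frame.astype(int),
        sample_meta=meta,
        taxonomy=taxonomy,
        sequences=sequences,
    )


def write_asv_matrix(
    m: AsvMatrix,
    counts_path: str | Path,
    meta_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
) -> None:
    counts = m.counts.copy()
    counts.index.name = "#sample_id"
    counts.to_csv(counts_path, sep="\t")
    if meta_path is not None and m.sample_meta is not None:
        m.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    if taxonomy_path is not None and m.taxonomy:
        pd.DataFrame(
            {"asv_id": list(m.taxonomy), "lineage": [";".join(v) for v in m.taxonomy.values()]}
        ).to_csv(taxonomy_path, sep="\t", index=False)
    if fasta_path is not None and m.sequences:
        write_fasta(m.sequences, fasta_path)


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FileFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# rates / balance reports


def write_rates_tsv(rates: Sequence[RateRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "t_start": r.t_start,
                "t_end": r.t_end,
                "compound": r.compound,
                "rate_mmol_per_L_d": r.rate,
                "reactor_id": r.reactor_id or "",
            }
            for r in rates
        ]
    ).to_csv(path, sep="\t", index=False)


def read_rates_tsv(path: str | Path) -> list[RateRecord]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        RateRecord(
            float(row.t_start),
            float(row.t_end),
            str(row.compound),
            float(row.rate_mmol_per_L_d),
            reactor_id=(str(row.reactor_id) if str(row.reactor_id) not in ("", "nan") else None),
        )
        for row in frame.itertuples(index=False)
    ]


def write_balance_report(balance: PeriodBalance, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "group": list(POOL_ORDER),
            "e_mmol_per_L_d": [balance.pools_e.get(p, 0.0) for p in POOL_ORDER],
            "C_mmol_per_L_d": [balance.pools_c.get(p, 0.0) for p in POOL_ORDER],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration (loadable from YAML)."""

    outdir: str
    broth_csv: str | None = None
    events_csv: str | None = None
    gas_csv: str | None = None
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    taxonomy_tsv: str | None = None
    fasta: str | None = None
    reactor: Mapping[str, float] = field(default_factory=dict)
    windows: Sequence[Sequence[float]] = field(default_factory=list)
    alpha: float = 0.01
    min_interval: float = 1.0
    rarefaction_depth: int | None = None
    seed: int = 0
    simulate_first: bool = False
    simulate_noise_sd: float = 0.02
    simulate_duration: float = 80.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            k: (list(map(list, v)) if k == "windows" else v)
            for k, v in self.__dict__.items()
        }


@dataclass
class PipelineResult:
    rates: list[RateRecord]
    balances: list[PeriodBalance]
    screen: pd.DataFrame | None
    manifest: dict


def _reactor_config(config: PipelineConfig) -> ReactorConfig:
    return ReactorConfig(**dict(config.reactor))


def run_pipeline(
    config: PipelineConfig, registry: CompoundRegistry | None = None
) -> PipelineResult:
    """Execute simulate (optional) → rates → balances → correlation.

    Writes per-stage TSV reports, a plain-text summary and a JSON
    manifest into ``config.outdir`` and returns the in-memory results.
    Reruns with identical config and seed produce identical outputs.
    """
    registry = registry or default_registry()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate_first:
        from .synthetic import default_config, sample_asv_counts, simulate

        sim_cfg = default_config(
            seed=config.seed,
            noise_sd=config.simulate_noise_sd,
            duration=config.simulate_duration,
        )
        sim = simulate(sim_cfg, registry)
        write_broth_csv(sim.broth_samples, outdir / "broth.csv")
        write_events_csv(sim.feed_events, outdir / "events.csv")
        write_gas_csv(sim.gas_samples, outdir / "gas.csv")
        meta = pd.DataFrame(
            {
                "reactor_id": sim_cfg.reactor_id,
                "time_d": sim.truth.guild_abundance.index,
            },
            index=pd.Index(
                [f"S{i:03d}" for i in range(len(sim.truth.guild_abundance))],
                name="sample_id",
            ),
        )
        matrix = sample_asv_counts(
            sim.truth.guild_abundance,
            depth=sim_cfg.sequencing_depth,
            dispersion=sim_cfg.sequencing_dispersion,
            seed=config.seed,
            asvs_per_guild=sim_cfg.asvs_per_guild,
            sample_meta=meta,
        )
        write_asv_matrix(
            matrix,
            outdir / "counts.tsv",
            outdir / "samples.tsv",
            outdir / "taxonomy.tsv",
            outdir / "asvs.fasta",
        )
        write_rates_tsv(sim.truth.rates, outdir / "true_rates.tsv")
        broth, events, gas = sim.broth_samples, sim.feed_events, sim.gas_samples
        reactor = sim_cfg.reactor
        reactor_id = sim_cfg.reactor_id
    else:
        if config.broth_csv is None:
            raise FileFormatError("no broth_csv configured and simulate_first is off")
        broth = read_broth_csv(config.broth_csv)
        events = read_events_csv(config.events_csv) if config.events_csv else []
        gas = read_gas_csv(config.gas_csv) if config.gas_csv else []
        reactor = _reactor_config(config)
        reactor_id = None
        matrix = None
        if config.counts_tsv:
            matrix = read_asv_matrix(
                config.counts_tsv,
                config.samples_tsv,
                config.taxonomy_tsv,
                config.fasta,
            )

    # rates stage
    span = (broth[0].time, broth[-1].time)
    usable_events = [e for e in sorted(events, key=lambda e: e.time) if e.time < span[1]]
    rates = interval_rates(broth, usable_events, reactor_id=reactor_id)
    if gas:
        rates += gas_consumption_rates(gas, reactor, reactor_id=reactor_id)
    write_rates_tsv(rates, outdir / "rates.tsv")

    # balance stage
    windows = [tuple(w) for w in config.windows] or [span]
    balances = []
    for i, window in enumerate(windows):
        bal = period_balance(rates, registry, window, reactor_id=reactor_id)
        balances.append(bal)
        write_balance_report(bal, outdir / f"balance_window{i}.tsv")

    # correlation stage
    screen = None
    if matrix is not None:
        depth = config.rarefaction_depth
        rarefied = rarefy(matrix, depth=depth, seed=config.seed)
        pairs = build_pairs(rates, rarefied, min_interval=config.min_interval)
        if pairs:
            screen = correlation_screen(pairs, alpha=config.alpha)
            screen.to_csv(outdir / "correlations.tsv", sep="\t", index=False)

    manifest = {
        "package": "mixochain",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_rate_records": len(rates),
        "n_windows": len(windows),
        "n_correlation_pairs": 0 if screen is None else int(screen["n"].max()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    _write_summary(outdir, rates, balances, screen, config)
    return PipelineResult(rates, balances, screen, manifest)


def _write_summary(outdir: Path, rates, balances, screen, config) -> None:
    lines = ["mixochain pipeline summary", "=" * 26, ""]
    lines.append(f"rate records: {len(rates)}")
    for bal in balances:
        lines.append(
            f"window {bal.window}: donors {bal.donors_e():.2f} e-mmol/L/d, "
            f"unknown {bal.pools_e['unknown']:+.2f} e-mmol/L/d"
        )
        try:
            lines.append(f"  elongation yield: {yield_elongated(bal):.3f} e-mmol/e-mmol lactate")
        except Exception:
            lines.append("  elongation yield: undefined (no lactate consumption)")
        gas_rates = [r for r in rates if r.compound in ("CO", "CO2")]
        if gas_rates:
            fix = carbon_fixation_rate(gas_rates, bal.window)
            lines.append(
                f"  carbon fixation: {fix.c_mmol_per_L_d:.2f} C-mmol/L/d "
                f"({fix.g_co2_eq_per_L_d:.3f} g CO2-eq/L/d)"
            )
    if screen is None:
        lines.append("")
        lines.append("correlation screen: no qualifying intervals")
    else:
        n_sig = int(screen["significant"].sum())
        lines.append("")
        lines.append(
            f"correlation screen: {len(screen)} tests, {n_sig} significant "
            f"at alpha={config.alpha}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
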