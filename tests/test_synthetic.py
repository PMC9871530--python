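"""Guild simulator: conservation, ground-truth consistency, sequencing layer."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mixochain.reactor_rates import (
    ReactorConfig,
    gas_consumption_rates,
    interval_rates,
)
from mixochain.stoichiometry import default_registry
from mixochain.synthetic import (
    GuildSpec,
    SimConfig,
    antagonistic_pair_config,
    default_config,
    default_guilds,
    guild_sequences,
    sample_asv_counts,
    simulate,
)

REG = default_registry()


class TestGuildSpecs:
    def test_default_guild_stoichiometries_are_balanced(self):
        for guild in default_guilds():
            guild.validate_balance(REG)  # raises on imbalance

    def test_unbalanced_stoichiometry_rejected(self):
        bad = GuildSpec(
            "broken",
            {"lactate": -1.0, "acetate": 1.0},  # 12 e⁻ in, 8 e⁻ out
            "lactate",
            10.0,
            {"lactate": 5.0},
        )
        with pytest.raises(ValueError, match="balanced"):
            bad.validate_balance(REG)

    def test_co_response_terms(self):
        g = default_guilds()[0]  # requires CO
        assert g.co_term(0.0) == 0.0
        assert g.co_term(10.0) > 0.99
        h = [x for x in default_guilds() if x.co_response == "inhibited_by_CO"][0]
        assert h.co_term(0.0) == 1.0
        assert h.co_term(10.0) < 0.01


class TestSimulation:
    def test_sterile_reactor_relaxes_by_repeated_dilution(self):
        # zero biomass: concentrations follow C_k = F + (C0 − F)(1 − f)^k
        cfg = SimConfig(
            duration=20.0,
            initial_biomass={g.name: 0.0 for g in default_guilds()},
            initial_broth={"lactate": 0.0, "acetate": 0.0},
            seed=0,
        )
        res = simulate(cfg)
        f = cfg.reactor.exchange_fraction
        feed = cfg.feed_composition["lactate"]
        # samples are taken pre-feed: sample k has seen k−1 exchanges
        for k, sample in enumerate(res.broth_samples):
            expected = feed * (1 - (1 - f) ** max(k - 1, 0))
            assert sample.concentrations["lactate"] == pytest.approx(
                expected, rel=1e-9, abs=1e-12
            )

    def test_noiseless_run_reproduces_ground_truth_rates(self, noiseless_sim):
        res = noiseless_sim
        truth = {(r.t_start, r.t_end, r.compound): r.rate for r in res.truth.rates}
        est = interval_rates(res.broth_samples, res.feed_events)
        checked = 0
        for rec in est:
            true = truth.get((rec.t_start, rec.t_end, rec.compound))
            if true is None or abs(true) < 1e-9:
                continue
            assert rec.rate == pytest.approx(true, rel=1e-6)
            checked += 1
        assert checked > 100

    def test_noiseless_gas_rates_reproduce_ground_truth(self, noiseless_sim):
        res = noiseless_sim
        truth = {(r.t_start, r.t_end, r.compound): r.rate for r in res.truth.rates}
        for rec in gas_consumption_rates(res.gas_samples, res.config.reactor):
            true = truth.get((rec.t_start, rec.t_end, rec.compound), 0.0)
            assert rec.rate == pytest.approx(true, rel=1e-6, abs=1e-9)

    def test_inert_nitrogen_is_never_consumed(self, noiseless_sim):
        rates = gas_consumption_rates(noiseless_sim.gas_samples, noiseless_sim.config.reactor)
        for rec in rates:
            if rec.compound == "N2":
                assert abs(rec.rate) <= 1e-9

    def test_electron_and_carbon_conservation_per_interval(self, noiseless_sim):
        # every interval: Σ rate·γ = 0 and Σ rate·n_C = 0 (balanced guilds,
        # no biomass sink in the default config)
        res = noiseless_sim
        frames = {}
        for r in res.truth.rates:
            frames.setdefault((r.t_start, r.t_end), {})[r.compound] = r.rate
        for window, rates in frames.items():
            e = sum(rate * REG[c].gamma for c, rate in rates.items())
            cc = sum(rate * REG[c].n_c for c, rate in rates.items())
            assert abs(e) < 1e-6, window
            assert abs(cc) < 1e-6, window

    def test_biomass_sink_appears_in_unknown_pool(self):
        from mixochain.balances import period_balance

        cfg = default_config(seed=2, sink_fraction=0.05, duration=60.0)
        res = simulate(cfg)
        window = (10.0, 60.0)
        bal = period_balance(res.truth.rates, REG, window)
        sink = [
            rate
            for (t0, t1), rate in res.truth.sink_e_rates.items()
            if t0 >= window[0] and t1 <= window[1]
        ]
        assert bal.pools_e["unknown"] == pytest.approx(np.mean(sink), rel=1e-6)

    def test_antagonistic_guilds_anticorrelate(self):
        res = simulate(antagonistic_pair_config(seed=0, duration=80.0))
        ab = res.truth.guild_abundance
        rho, _ = stats.spearmanr(ab["homoacetogen"], ab["heterotroph"])
        assert rho < -0.5

    def test_same_seed_is_deterministic(self):
        a = simulate(default_config(seed=9, noise_sd=0.02, duration=30.0))
        b = simulate(default_config(seed=9, noise_sd=0.02, duration=30.0))
        for sa, sb in zip(a.broth_samples, b.broth_samples):
            assert sa.concentrations == sb.concentrations

    def test_step_size_guard(self):
        with pytest.raises(ValueError, match="dt"):
            SimConfig(dt=1.0, reactor=ReactorConfig(feed_interval=2.0))

    def test_paperlike_preset_matches_study_design(self):
        from mixochain.synthetic import paperlike_config

        cfg = paperlike_config(seed=0)
        assert cfg.duration == 292.0
        assert cfg.reactor.hrt == 14.0
        assert cfg.feed_composition == {"lactate": 133.0, "acetate": 200.0}
        assert cfg.gas_fractions == {"H2": 0.32, "CO": 0.32, "CO2": 0.16, "N2": 0.20}
        res = simulate(cfg)
        assert len(res.broth_samples) == 292 // 2 + 1
        # sink fraction routes electrons out of the product pools
        assert any(r > 0 for r in res.truth.sink_e_rates.values())


class TestSequencingLayer:
    def _abundances(self, n=5):
        rows = np.random.default_rng(0).dirichlet([5, 5, 5, 5], size=n)
        return pd.DataFrame(
            rows,
            index=pd.Index([f"t{i}" for i in range(n)], name="sample_id"),
            columns=["g1", "g2", "g3", "g4"],
        )

    def test_counts_sum_to_depth(self):
        m = sample_asv_counts(self._abundances(), depth=1000, dispersion=100.0, seed=0)
        assert (m.counts.sum(axis=1) == 1000).all()

    def test_single_guild_gets_all_reads(self):
        ab = pd.DataFrame(
            [[1.0, 0.0]],
            index=pd.Index(["s"], name="sample_id"),
            columns=["g1", "g2"],
        )
        m = sample_asv_counts(ab, depth=500, dispersion=100.0, seed=0, asvs_per_guild=2)
        g1_asvs = [a for a, tax in m.taxonomy.items() if tax[5] == "g1"]
        assert m.counts[g1_asvs].sum(axis=1).iloc[0] == 500

    def test_fixed_seed_is_bit_identical(self):
        a = sample_asv_counts(self._abundances(), depth=200, dispersion=50.0, seed=3)
        b = sample_asv_counts(self._abundances(), depth=200, dispersion=50.0, seed=3)
        assert a.counts.equals(b.counts)

    def test_large_dispersion_approaches_multinomial(self):
        # 200 samples with identical guild proportions: at huge dispersion the
        # per-guild count totals must match the multinomial mean depth·p
        # within 3 standard errors of the binomial sampling distribution
        props = {"g1": 0.4, "g2": 0.3, "g3": 0.2, "g4": 0.1}
        n, depth = 200, 2000
        ab = pd.DataFrame(
            [list(props.values())] * n,
            index=pd.Index([f"t{i}" for i in range(n)], name="sample_id"),
            columns=list(props),
        )
        m = sample_asv_counts(ab, depth, dispersion=1e7, seed=0)
        guild_of = {a: tax[5] for a, tax in m.taxonomy.items()}
        totals = m.counts.T.groupby(pd.Series(guild_of)).sum().T
        for guild, p in props.items():
            se = math.sqrt(depth * p * (1 - p)) / math.sqrt(n)
            assert abs(totals[guild].mean() - depth * p) <= 3 * se

    def test_invalid_depth_and_dispersion_rejected(self):
        with pytest.raises(ValueError):
            sample_asv_counts(self._abundances(), depth=0, dispersion=10.0, seed=0)
        with pytest.raises(ValueError):
            sample_asv_counts(self._abundances(), depth=10, dispersion=0.0, seed=0)

    def test_guild_sequences_are_similar_within_and_distinct_between(self):
        from mixochain.community import pairwise_identity

        seqs, asv_guild = guild_sequences(["gA", "gB"], 2, seed=1)
        by_guild = {}
        for asv, g in asv_guild.items():
            by_guild.setdefault(g, []).append(asv)
        a1, a2 = by_guild["gA"]
        b1, _ = by_guild["gB"]
        assert pairwise_identity(seqs[a1], seqs[a2]) > 98.0
        assert pairwise_identity(seqs[a1], seqs[b1]) < 90.0
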