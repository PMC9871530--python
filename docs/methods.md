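# Methods

## Compound bookkeeping

All balances run on two linear maps per compound: carbon equivalents
(n_C per molecule) and electron equivalents, the degree of reduction
γ = 4·n_C + n_H − 2·n_O for CHO compounds — the electrons transferred to
an acceptor on complete oxidation to CO₂ and H₂O. Carboxylates are
represented as undissociated acids (CnH2nO2): reported g/L
concentrations in low-pH fermentations match the acid molar masses
(133 mM lactic acid = 11.98 g/L ≈ the "12 g/L" a practitioner quotes),
and the equivalents are independent of speciation anyway. Atomic masses
are C 12.011, H 1.008, O 15.999, N 14.007; CO₂ is fixed at 44.01 g/mol
so that g-CO₂-equivalent reporting matches the 2-significant-figure
convention (2.0 C-mmol L⁻¹ d⁻¹ → 0.088 g L⁻¹ d⁻¹).

Two compounds fall outside the CHO formula and carry explicit overrides:
N₂ (γ = 0 — it is its own redox reference here, and its mass comes from
nitrogen) and the biomass pseudo-compound CH₁.₈O₀.₅N₀.₂ per C-mol with
γ = 4.2, which includes the −3 electrons per NH₃-referenced nitrogen.
Biomass concentration is derived from OD600 at 0.455 g dry mass per OD
unit. A user-supplied registry table can replace or extend the
defaults; a table that disagrees with the formula-derived factors is
rejected at load (mass within 0.1 g/mol, γ non-negative).

## Rate estimation in a semi-continuous reactor

Feeding is modelled as discrete exchange events: a fraction
f = feed_interval/HRT of broth replaced by fresh medium. Broth is
sampled before feeding, so an event at a sample time opens the next
interval. The estimator removes dilution by pushing the interval's
start concentration through every intervening event before
differencing; with events only at interval boundaries (the usual
sampling scheme) this is exact, which is what the ground-truth recovery
tests verify to 1e−6 relative. A config flag switches to post-feed
sampling conventions.

The gas loop (headspace + reservoir + recirculation lines) is treated
as one well-mixed volume at constant temperature; moles follow the
ideal gas law with R = 0.08314 L·bar·mol⁻¹·K⁻¹ and measurements are
assumed dry-basis. Reservoir replenishments are step discontinuities:
samples flagged post-replenishment reset the baseline and the
pre/post pair contributes no rate. N₂ is inert, so any apparent N₂
consumption on a noiseless series would expose an accounting leak; the
suite checks it is zero to 1e−9.

Window aggregation uses time-weighted means so that mixed 1-day and
3.5-day sampling intervals do not bias pools. Pools follow the field's
reporting: lactate_in; acetate_in (acetate is pooled with C2 products
when net produced, with the feed acceptors when net consumed); H₂, CO,
CO₂; chain classes C2…C≥7 (carboxylate + alcohol of equal chain
length); "others" (biomass, formate, CH₄); and "unknown", defined so all
signed pools sum to zero — consumed minus produced minus others.

## Carbon fixation and CO₂ attribution

The carbon-fixation rate is defined as net gaseous-carbon uptake,
−(r_CO + r_CO₂) in C-mmol L⁻¹ d⁻¹ (negative = net emission). This
matches the observation that fixation in these systems is driven by CO
consumption and that CO oxidation shows up as extra CO₂ emission. It
deliberately ignores dissolved CO₂/bicarbonate pools; users with
liquid-phase inorganic carbon data can account for them upstream.

CO₂ emissions are attributed with a single stoichiometric rule: one
CO₂ per lactate converted to acetyl-CoA (all even-chain and iso
products), zero for lactate routed to propionate or the C3 primer of
n-valerate (acrylate pathway releases no CO₂). Expected
decarboxylation = lactate consumed − odd-chain-routed lactate; observed
emission below that is booked as abatement by CO₂ consumers, above it
as CO oxidation. The identity emitted = expected − abated + co_oxidation
is enforced at construction. Negative expected decarboxylation
(odd-chain products exceeding lactate) raises an error rather than
clamping silently.

## Community operations

Rarefaction draws a multivariate hypergeometric sample per community
sample (subsampling without replacement), with the depth defaulting to
the smallest sample sum. Each sample has its own RNG substream keyed by
(seed, CRC32 of sample id), so adding or dropping samples never
reshuffles the others and results are bit-reproducible. Pairwise
sequence identity uses global alignment (match +1, mismatch 0, gap −1)
with identity = matched columns / alignment length; ASV clustering runs
average linkage on 100 − identity with flat groups cut at a
configurable identity (default 99%, the usual species-level ASV
grouping). This is a deliberately lightweight surrogate for
reference-database searches, suitable for grouping near-identical
variants, not for taxonomy assignment.

## The association screen

Each community sample is paired with the rate interval it closes
(pre-feed sampling puts the sample at interval end; a switch allows
start-matching). Intervals shorter than 1 day are dropped — short
intervals make the difference quotient noise-dominated. The statistic
is the tie-corrected Spearman ρ (Pearson correlation of mid-ranks).
Two-sided p-values: exact enumeration of all n! permutations for n < 8,
where the t approximation is unreliable; t = ρ·√((n−2)/(1−ρ²)) with
n − 2 df otherwise. Constant inputs raise an error instead of returning
ρ = 0. Rates keep their signs, so "associated with H₂ consumption"
appears as negative ρ against the signed H₂ rate. Raw p-values with a
fixed α = 0.01 are the default, mirroring common practice in this
literature; a Benjamini–Hochberg option (`bh_correct=True`) is provided
for users who prefer FDR control.

## The synthetic reactor

The generator exists so that every stage — rate estimation, balance
closure, rarefaction, the screen — can be validated against known
truth. It emulates a 1-L reactor at HRT 14 d fed 133 mM lactate +
200 mM acetate every 2 days (within the 1–4 day range such reactors
use), sparged from a 10-L recirculated reservoir at 32/32/16/20
H₂/CO/CO₂/N₂ that is restored to nominal composition every 8 days, for
140 days (70 sampling intervals) at 32 °C.

Four guilds carry exactly electron- and carbon-balanced net
stoichiometries:

| guild | reaction (per reference mmol) | CO response |
|---|---|---|
| homoacetogen | 3 H₂ + CO + CO₂ → acetate (+H₂O) | requires CO (K 0.03 bar) |
| mixotrophic elongator | lactate + 0.1 acetate + H₂ + CO → 0.4 n-caproate + 0.2 i-butyrate + CO₂ | requires CO (K 0.02 bar) |
| lactate heterotroph | lactate → ½ n-butyrate + CO₂ + H₂ | inhibited by CO (K 0.05 bar) |
| propionate producer | lactate → ⅔ propionate + ⅓ acetate + ⅓ CO₂ (acrylate route) | neutral |

The elongator's reaction blends the classic lactate elongation
(2 lactate + acetate → caproate + 2 CO₂) 80:20 with an i-butyrate
route and adds H₂/CO co-utilisation; i-butyrate as a fixed side
fraction of C4 output reflects how branched products co-occur with C1
co-feeding. Uptake is Monod in every consumed substrate (constants of a
few mM for dissolved substrates, a few hundredths of a bar for gases)
multiplied by a CO response term K/(K+p_CO) or p_CO/(K+p_CO), with a
joint cap that rescales competing uptakes so no pool is overdrawn
within a step — preserving stoichiometric balance exactly. Integration
is explicit Euler at dt = 0.05 d (≤ feed_interval/10).

These choices produce the qualitative dynamics such reactors show: the
CO-requiring guilds draw the reservoir down after each replenishment
and the CO-inhibited heterotroph takes over as CO runs low, giving
antagonistic dominance cycles; growth yields (~0.01 relative biomass
per mmol) put net growth near the washout rate so the composition keeps
moving instead of freezing at an equilibrium — a frozen composition
carries no abundance–activity signal for the screen, and real reactors
rarely freeze either. An optional sink fraction diverts a share of
product electrons to biomass, which the balance then reports in
"unknown"; the recorded ground truth includes the sink rate so closure
can be asserted exactly.

Sequencing is a Dirichlet-multinomial layer: each guild is split over 3
ASVs with fixed seeded weights (populations appear as several sequence
variants), per-sample proportions are jittered with concentration
`dispersion × p` (default 300, in the range Dirichlet-multinomial fits
to real amplicon data occupy) and counted at depth 31,892 — the
rarefaction depth used in the motivating study design. ASV sequences
are random 250-mers with ~99% within-guild identity, supporting the
clustering surrogate.

What the generator does **not** emulate: pH/DO dynamics, gas–liquid
mass-transfer limitation (uptake acts directly on the gas pool),
oxygen-contamination shocks, methanogen suppression chemistry, lag
phases and dormancy, and taxonomic richness beyond the four guilds.
Passing the synthetic suite therefore demonstrates correctness of the
estimators and the screen under the stated noise model, not that the
model captures every failure mode of real reactor data.

## Numerical and design notes

- Times are real-valued days throughout; concentrations are mM
  internally, converted only at I/O boundaries.
- Observation noise is multiplicative lognormal (sd 0.02 by default for
  noisy presets), applied independently to every broth concentration and
  partial pressure; a zero-noise run reproduces ground truth to machine
  precision.
- One seed governs process observation noise, sequencing and
  rarefaction, via labelled substreams; all outputs are bit-reproducible
  for a given config + seed.
- The end-to-end check screens at the guild (genus) level after taxon
  aggregation: guilds are the unit with a defined product signature, and
  pooling a guild's ASVs removes Dirichlet-multinomial noise that the
  per-ASV view adds.
- Degenerate inputs fail loudly: empty windows, constant correlation
  vectors, all-zero samples, negative concentrations with file/line
  context, inconsistent CO₂ attribution.
- `compare_communities` reports ratios on magnitudes with zero
  denominators flagged as infinite rather than raising, since sparse
  pools are routine.

## Known limitations

- The carbon-fixation definition is a net gas-phase balance; systems
  with large dissolved inorganic carbon swings need an extended
  definition.
- The rate estimator assumes feed events coincide with (or are known
  between) sampling times; conversion occurring before an unobserved
  intra-interval exchange is attributed with a small dilution bias.
- The identity clustering is not a taxonomy tool.
- Spearman screening finds monotone association, not causation;
  co-occurring guilds inherit each other's correlations exactly as in
  real reactor studies.
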