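# Methods

This note documents the model as implemented: its assumptions, the
provenance and meaning of the packaged parameters, the numerical choices
made where the design was genuinely open, and what the synthetic inputs do
and do not represent.

## Growing cycles and calendar

A growing cycle lasts about 18 months and overlaps the next: vegetative
growth August–May, flowering July–September, harvest December–February
(the Reunion Island cropping calendar for cv. Cogshall; `SimulationConfig`
anchors cycle 1's vegetative season at `start_year`, default 2003).
Calendar dates are the single temporal source of truth — months and weeks
are always derived from dates, never stored separately.  Within-cycle
daughter GUs can only burst in window months strictly later than their
mother's burst month; a mother bursting in the last window month therefore
cannot produce within-cycle daughters, and late (post-December) mothers
mostly defer production to the next cycle through the low late-season burst
probability (0.02) and the between-cycle tables (no explicit deferral queue
is kept; the two-automaton structure carries the deferral).

## Stochastic processes and their parameters

Each elementary process is a parametric distribution keyed by factor-level
combinations in a `ProbabilityTable`.  Printed values of the source
parameterization are transcribed verbatim:

- within-cycle burst: P = 0.80 (August–December mothers), 0.02 (later);
- apical daughter given burst: P = 0.98; lateral daughters: P = 0.66
  (apical mothers) / 0.28 (lateral); conditional mean lateral counts
  2.1 / 1.3 (cycle 1) and 2.3 / 1.9 (cycle 2);
- between cycles: apical daughter P = 0.82 for quiescent ancestors and 0
  otherwise (the apical bud of flowering/fruiting ancestors became an
  inflorescence); lateral P = 0.46 for quiescent ancestors; mean lateral
  counts 2.4 / 3.4 / 4.2 for quiescent / flowering / fruiting ancestors;
- mixed inflorescences: P = 0.06, always single and apical; their
  daughter production P = 0.53, mean 2.3 daughters, apical P = 0.47,
  appearing December–February;
- fruit set: P = 0.40 (bloom ≤ 15 September), 0.20 (15 September–15
  October), 0 (later).  The source text gives overlapping windows for the
  last two classes; the non-overlapping reading above is used;
- geometry: axis length N(18.1, 4.1²) / N(13.8, 4.0²) / N(12.6, 3.4²) cm by
  position; leaf length N(17.1, 2.7²) / N(14.9, 2.7²) cm; first internode
  Γ(2.0, 0.76) (apical) or 0.88 L + 0.38 (lateral); basal diameter
  N(0.025 L + 0.25, 0.11²) cm; inflorescence axis N(23.1, 6.7²) cm with
  round(1.19 L) second-order axes; fruit dry mass
  0.97 N(13.9, 4.1²) + 0.03 N(29.2, 0.66²) g.

**Lateral-count family.**  Counts are zero-truncated Poisson: the automaton
reaches the count only after a positive occurrence test, so zero is
impossible by construction.  Tables store the underlying Poisson rate
chosen so that the *conditional* mean E[X | X ≥ 1] = λ/(1 − e^{−λ}) matches
the printed mean; a conditional mean of exactly 1 is the degenerate λ → 0
limit and is encoded as rate 0 (the count is then always 1).

**Unprinted tables.**  The burst-month and bloom-week ordinal multinomials,
the flowering probabilities and the fruit-count means were published only
as qualitative patterns.  The defaults encode those patterns — a 1–4-month
daughter lag peaking at 2 months within cycle 1; early-season flushes for
quiescent ancestors versus post-harvest (February–March) flushes for
fruiting ancestors; a September-dominated bloom-week distribution with two
peaks; flowering higher for apical terminals and non-fruiting ancestries
(0.55/0.35 apical, 0.30/0.18 lateral); 1.6 mean inflorescences for
December–January GUs versus 1.0 otherwise; fruit-count means 1.3 / 1.8 by
inflorescence number.  They are deliberately plain rows in the CSV dialect
so users can substitute locally fitted tables (the calibration module
produces them in exactly this format).  The between-cycle burst-occurrence
probability is likewise unprinted; the only printed between-cycle
occurrence value, the deferral probability 0.73, is used for all fates.

**Sampling.**  Days within a selected month or week are uniform (the
source states only "randomly chosen").  Ordinal multinomials are sampled
by inverse CDF on the category probabilities.  Mixture draws ≤ 0 are
resampled (mass positivity against the Gaussian tails).  One RNG stream
per tree, seeded `seed + tree_index`, so adding trees never perturbs
earlier trees and a fixed seed reproduces event logs byte for byte.

## Thermal time, phenology and growth

Daily development increments are max(0, T_mean − T_base).  Stage schedules
(bases and thresholds per stage) and growth-model constants (base, growth
duration, inflexion t_ip, slope B) are the published Tables for GU stages
D–G, inflorescence stages D–F, and the GU-axis / leaf / inflorescence-axis
growth models.  Thermal time is counted from bud burst (stage C); the
stage-duration table starts at D, so stage C is implemented with zero
duration — D begins at burst.  Stages run strictly sequentially, each
accumulating against its own base temperature from its onset; a stage
completes on the first day its sum crosses the threshold, and the excess
of the crossing day is discarded (increments under different bases are not
commensurate, so carrying a remainder across stages would be ill-defined).

Organ elongation is logistic in thermal time with t_ip = TTS_S/2 for GU
axes and leaves and the fitted constant 136.6 °Cd for inflorescence axes;
the leaf slope rule B = L/(0.06 L − 0.08) depends on final leaf length.
Internode lengths, diameter and leaf width during growth scale with the
current/final axis-length ratio.  Secondary growth follows the pipe model
d = 0.88 nbd^0.41, applied on each new descendant and never shrinking an
existing diameter.

**Internode profile.**  The printed normalization constant of the
internode-decay equation is typographically ambiguous in the source, and
the footnote gives two conflicting definitions of the normalized position
u.  Implemented: u = (i−2)/(n−2) (0 at the second internode, 1 at the nth,
matching the prose endpoints), with relative weights e^{−2.64 u}
renormalized so that the internodes 2..n sum exactly to L minus the first
internode.  This preserves the printed decay rate 2.64 and guarantees the
testable conservation property Σ internodes = L ± 1e−6.  The first
internode is clamped to L when its own model exceeds the axis length
(possible for very short lateral GUs).  Leaf and second-order-axis counts
are rounded half-up with a floor of 1; the distal and penultimate leaf
multipliers are stored exactly as 1 − 0.52 and 1 − 0.38.

## Fruit growth

Phase 1 (cell division) ends when 352.7 °Cd above 16 °C accumulate after
full bloom (starting the day after bloom); the fruit then receives its
mixture-drawn dry mass and the allometric fresh mass 23.647 M_d^0.6182.

Phase 2 (cell expansion) is a pluggable interface.  The full ecophysiological
carbon/water model operating at the fruiting-branch scale is not part of
this package; the default `SourceSinkExpansionModel` is an explicitly
reduced stand-in with the same interface and qualitative behaviour: daily
demand follows a logistic in thermal time (base 16 °C, 900 °Cd span, slope
120 °Cd) toward a potential dry mass (113 g, putting the fresh-mass ceiling
near 440 g); supply is n_leaves × 0.05 g × gap-fraction per day plus a
finite initial reserve (default 15 g — the published value is cited from an
external source and not printed, so this is a required configurable
constant); realized growth is min(demand, supply) shared across the
branch's fruits in proportion to demand.  Consequently final mass is
nondecreasing and saturating in the branch leaf:fruit ratio, approaching
the ceiling around ratios of 60+; the reserve can only be drawn down, never
negative (asserted daily).  Gap fractions are drawn uniformly per branch
from a configurable list (default 0.4/0.6/0.8 — arbitrary contrasted light
environments).  Harvest is recorded after a configurable 90-day expansion
window (mango fruits ripen roughly four months after bloom), truncated at
the end of the weather series.  No claim of quantitative agreement with
the full branch-scale carbon/water model is made; that model can be
registered behind the same interface and selected by config key.

## Architecture queries and applications

Terminality is defined on the GU graph only: a GU with no daughter GU is
terminal even if it bears an apical inflorescence — the next cycle's
fate-keyed automaton (which forbids apical daughters after flowering)
decides what its bud can still do.  A GU whose apical bud was consumed by
an earlier inflorescence places later pure inflorescences laterally and
cannot receive a mixed (always apical) one.

Axes start at a lateral (or founding) GU and continue through successive
apical daughters; axis length is counted in GUs appearing within the
queried cycles, making Σ axis lengths equal the in-range GU count.

Graph distance is the number of edges on the unique GU–GU path (self = 0).
A fruiting branch of size N is the union of all GUs within N−1 edges of a
fruiting GU, with overlapping sets merged transitively; N = 1 therefore
yields exactly the fruiting GUs.  The branch leaf:fruit ratio sums member
leaves over the fruits of the branch's fruiting GUs.  The census counts
per-day stage occupancy reconstructed from burst dates and the weather
series, keeps zero days, and divides by the number of trees.

## Evaluation

The four global criteria are monthly GU-burst counts, weekly full-bloom
counts, fruits per cycle, and the axis-length histogram.  NRMSE divides
the RMSE of the model mean series (default 1000 simulations, configurable)
by the reference range.  The χ² comparison is made on counts, with the
expected series rescaled to the observed total and bins empty in both
series dropped.

The influence index ablates a factor by *marginalizing* it out of every
probability table: rows sharing the remaining levels are averaged,
weighted by the factor-level frequencies observed in the complete model's
own simulations (Bernoulli p's average; truncated-Poisson rates are
re-solved from averaged conditional means; multinomials average per
category; Gaussians/Gammas are moment-matched).  The source procedure
refits reduced GLMs to the raw data; without those data,
frequency-weighted marginalization is the faithful surrogate.  The
complete model's mean series is the reference; the ablated and null models
run on a common independent seed stream, so an ablated model identical to
the null model scores exactly 1 and one identical to the complete model
tends to 0 as simulations accumulate.

## Calibration

Event tables are replayed from the simulator's decision logs (one row per
stochastic decision, carrying the four factor levels), so eligibility
rules are inherited exactly — e.g. lateral-count rows exist only where the
lateral test was positive, keeping the zero-truncated convention.
Binomial and Poisson responses use statsmodels GLMs (zero-truncated
Poisson via the truncated-count likelihood); ordinal responses use the
cumulative-logit proportional-odds model — the standard ordinal GLM,
standing in for the vector-GLM machinery of the original workflow.
Backward stepwise selection minimizes AIC from the full four-factor
main-effects model, breaking ties toward fewer parameters; first-order
interactions between the selected factors are then added pairwise when
they strictly lower the AIC (the original's custom ordinal stepwise is
unspecified; the same standard stepwise is applied to all families).
Under a factor-free truth, AIC retains a spurious factor with probability
≈ P(χ²_df > 2 df) — about 16 % for a binary factor — so intercept-only is
the modal, not the certain, outcome of null fits.

## Synthetic inputs

The weather generator produces a sinusoidal southern-hemisphere climate
(annual mean 24 °C, half-range 4 °C, coolest mid-July, Gaussian daily
noise σ = 1 °C) — a plausible lowland Reunion-like regime, not a
reproduction of any measured record.  The ancestor generator samples
position / fate / burst-month mixes (defaults: 60 % apical; 60 % quiescent,
25 % flowering, 15 % fruiting; burst dates spread over the previous
season, peaking early) representing a typical end-of-cycle canopy of a
young tree with ~10–20 terminals per simulated tree.  Tests passing on
these fixtures demonstrate internal consistency — frequency recovery,
conservation laws, closed-loop parameter recovery — not agreement with
measured trees: real canopies have correlated ancestor attributes,
weather-modulated burst probabilities and mortality, none of which the
fixtures or the model represent.

## Problem sizes and determinism

Statistical tests use 10⁴ draws for frequencies and moments (3σ bands) and
10⁵ for the mixture composition; influence-index properties use 200
simulations of two 5-ancestor trees, and closed-loop GLM recovery uses
three 10-ancestor trees over two cycles (~10³ GUs) — sizes at which every
check runs in seconds to a couple of minutes on one core while leaving the
Monte-Carlo bands far narrower than the effects tested.  All randomness
flows from explicit seeds; simulations are bit-reproducible per tree.

## Known limitations

- No GU or leaf mortality, no pruning, no environmental modulation of the
  probability tables (temperature enters only through thermal time).
- The reduced expansion model ignores water relations, organic-acid and
  mineral accumulation, and between-branch carbohydrate exchange.
- 3-D geometry is limited to lengths, diameters and angles as attributes;
  no spatial embedding, light interception or rendering.
- Published influence-index values and validation NRMSE/χ² figures were
  computed against three exhaustively measured trees that are not publicly
  available; this package reproduces the machinery and its degenerate
  anchors, not those numbers.
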