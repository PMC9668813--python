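# Methods

`podnet` implements an analysis pipeline for dyadic affiliative/aggressive
interaction streams in small, fully observable animal groups (the motivating
system is captive bottlenose dolphin groups of four and five animals), plus
two generative models of such streams. This note records the models, the
conventions and numerical choices behind each stage, and what the synthetic
data do and do not establish.

## Data model

An observation session is divided into fixed periods (default 3 minutes).
Three record types carry all inputs:

- **InteractionEvent** — one observed dyadic contact: day, period, actor,
  receiver, valence (+1 affiliative, −1 aggressive), and observation order
  within the period. Networks are undirected; actor/receiver are provenance.
- **SamplingRecord** — 0–1 group sampling of synchronous swimming per dyad
  per period (`observed`, `synchronous`), used only for the affiliation
  index.
- **GroupRoster** — the group's members with sex and a 1-based node index.

Day labels are opaque (integers sort numerically, strings lexicographically);
no calendar arithmetic is done. Sessions may have unequal period counts, so
day length is always carried explicitly rather than assumed.

## Signed temporal networks

Each period maps to a symmetric N×N matrix with entries in {−1, 0, +1}. If a
dyad shows both valences within one period, the **last observed interaction**
(by observation order) wins. A *contact* is one non-zero dyad-period after
this collapsing; contact counts are reported by dyad sex class (F–F, F–M,
M–M).

## Qualitative-change aggregation

A link's *state* during a day is the valence of its last non-zero entry so
far; returning to neutral does not change the state, and an interaction
finishes only when the link's valence flips. A day's periods are partitioned
into windows: the current window closes just before the first period in
which any link changes **qualitatively**, meaning a non-zero entry that
either reverses the link's state or activates a link for the first time that
day. The triggering period starts the next window. Within a window each
link's weight is the signed sum of its entries — sign encodes valence,
magnitude encodes duration. A link running (+1, +1, 0, −1) gives snapshots
of weight +2 (periods 1–3) and −1 (period 4).

Two deliberate choices:

- **Day-scoped state, not window-scoped.** If the trigger were evaluated
  against the link's history *within the current window only*, every window
  break would "forget" all active links, and a process that touches one dyad
  per period could never produce a multi-link aggregated snapshot (its motif
  census collapses to three classes). Day-scoped state lets an established
  link resume its sign across window breaks as a continuation, which is what
  the underlying episode semantics ("finished when the valence changes")
  imply and what the observed aggregated-motif richness requires. The sign
  reversal of any link still closes the window before the opposite entry can
  enter it, so within every emitted window each link is single-signed (this
  is asserted property-style in the tests, together with conservation of the
  signed sums under the partition).
- **Global windows.** A change on any single link closes the snapshot for
  the whole network. A per-link windowing mode (`mode="per-link"`), in which
  each dyad is windowed independently at its own activations and reversals,
  is provided for sensitivity analysis; its windows overlap in time across
  links and each snapshot carries a single link.

Link-weight summaries (`mean_link_weight`) report the mean and **population
standard deviation** (divide by n) of |weight| over (snapshot, link) pairs of
one sign, and refuse to answer (rather than return 0) when no such link
exists.

## Motif census

A motif is the whole group's signed configuration in one period or one
snapshot (reduced to its sign pattern; weights are dropped because the
models have no calibrated weights to compare). With group sizes of 4–5 the
full-group configuration *is* the local structure of interest; a
subgraph-occurrence census is out of scope. Configurations are encoded as a
digit string over {0, 1, 2} (0 none, 1 affiliative, 2 aggressive), one digit
per dyad in the fixed order (1,2), (1,3), …, (N−1,N). Node identity is
immaterial, so codes are reduced to the lexicographic minimum over all N!
relabelings (cached; idempotent and permutation-invariant by property test).
The class count is computed by Burnside's lemma over the induced action on
dyads and, for N ≤ 4, cross-checked against exhaustive canonicalization of
all 3^6 = 729 configurations; both give 66 classes for four nodes. Rankings
order classes by descending count with ties broken by ascending code so
ranks are reproducible; tie structure is preserved for the comparison stage,
which uses average ranks. The all-neutral configuration is a legitimate
class and is counted; reporting can filter it.

## Affiliation index

For dyad (A, B), IA = X_AB / Y_AB: sampling periods with synchronous
swimming over sampling periods with both animals observed. IA is undefined
(NaN), not zero, when Y = 0. Sex-class summaries report the mean and
population SD per group and pooled across groups, with single-dyad classes
reporting a mean only. The population-SD convention was fixed by verifying
that it reproduces the published class summaries of the two study groups
from their printed per-dyad indices to 0.001 (the sample-SD convention does
not); the pooled rows simply pool all dyads of a class across groups.

## Post-conflict classification

Interactions are analyzed as **episodes**: a maximal same-sign run of one
dyad's link, spanning neutral gaps, finished by a valence flip or the end of
the day. Each conflict (negative episode) opens a memory on its opponent
pair; the memory window opens the period after the conflict *starts* (a long
conflict can already provoke bystander contacts while it runs) and lasts
until the end of the day (`memory_horizon=None`, the observational
convention) or for `h` periods past the conflict's last period
(`memory_horizon=h`; `h=1` matches the memory-based simulator). While a
memory is open:

- a positive episode between the two opponents → **reconciliation** (closes
  the memory);
- a positive episode between one opponent and a bystander → **new
  (third-party) affiliation** (closes the memory);
- a negative episode involving at least one opponent → **new (redirected)
  aggression** (does not close the memory; every conflict also opens its own
  memory).

Everything else is spontaneous. When several open memories are compatible
with an event, the **most recently opened** wins; this is the
least-assumption rule for overlapping conflicts. Whether a renewed
aggression between the same two opponents counts as redirected is
behaviorally arguable, so it is a flag (`include_renewed`, default True,
matching the subtraction bookkeeping in which all post-conflict aggressions
are "new"). Note that under episode semantics a pattern like (−1, 0, −1) on
one dyad is a single continuing conflict, not a renewal.

Count bookkeeping: spontaneous affiliations = total affiliations −
reconciliations − new affiliations; spontaneous aggressions = total
aggressions − new aggressions; negative results raise. Daily probabilities
divide a day's category periods by that day's period count and average over
days (days weigh equally regardless of length). Probabilities convert to
per-minute rates through p = 1 − e^(−rΔt) (Δt in minutes); p = 1 is
rejected as an infinite rate, and the conversion round-trips exactly.

## Generative models

Both models produce one signed temporal network per period, with the study
shape as default: 4 nodes, 20 periods/day, 80 days (1600 periods) per
realization, 100 realizations, all driven by one seeded NumPy generator so
identical seeds give bit-identical streams.

- **Memoryless ("simple") model.** Each period, one dyad is drawn uniformly
  and set +1 with the general-affiliation probability (fitted value 0.17)
  or −1 with the general-aggression probability (0.07). One draw per period
  — not independent per-dyad draws — keeps the model commensurate with the
  period-counting estimator that produced those probabilities.
- **Memory-based ("complex") model.** Per period, in order: (1) each dyad
  that held a conflict in the previous period reconciles (+1) with
  probability 0.04; (2) for each such conflict, one dyad containing exactly
  one former opponent (2(N−2) candidates; the conflict pair itself is
  excluded so renewal is not conflated with redirection) is drawn and set
  +1 with 0.01 (third-party affiliation) or −1 with 0.01 (redirected
  aggression); (3) a spontaneous draw as in the memoryless model with
  probabilities 0.05/0.02. First write wins within a period; multiple
  previous-period conflicts are processed in random order. The memory
  horizon is exactly one period and never crosses a day boundary. Whether
  step (2) runs once per conflict (default) or once per period is a flag
  (`post_conflict_draw`).

`run_experiment` aggregates every simulated day and censuses the snapshot
sign patterns, returning pooled and per-realization histograms. Snapshots
are not retained by default to bound memory.

## Probability estimation from simulated or observed streams

Two estimators are provided because they answer different questions.

`empirical_probabilities` is the descriptive, observational route: episode
counts per day over the day's periods, averaged across days.

`estimate_probabilities` is a **method-of-moments estimator** under the
one-period-memory process, used for parameter recovery. The latent category
of a single contact is not identifiable from the networks — a spontaneous
affiliation that happens to land on the conflict dyad is indistinguishable
from a reconciliation, and one landing on a one-opponent dyad mimics a
third-party affiliation — so naive category counting overestimates the
memory probabilities by ≈ p_spont/D terms comparable to the Monte-Carlo
error at the study scale. The moment estimator removes this bias exactly in
expectation: spontaneous rates come from periods with no previous-period
conflict (where the spontaneous draw is the only event source);
reconciliation successes are counted per conflict-dyad opportunity and
corrected by the spontaneous hit rate p̂_sa/D on the conflict dyad; new
contacts are counted over one-opponent dyads per opportunity and corrected
by the expected spontaneous contribution p̂_sa·u/D (u = eligible dyads that
period). Estimates are clipped to [0, 1]; with no opportunities the memory
probabilities are reported as NaN with a warning. Residual biases
(first-write-wins collisions, overlapping simultaneous conflicts, episode
merging) are an order of magnitude below the Monte-Carlo standard errors at
the default scale.

## Synthetic data

The generator reuses the memory-based per-period process but emits
observation-format event logs (with within-period observation order), so the
full I/O path is exercised, and writes a **ledger** tagging every event with
the latent category that generated it. IA sampling is generated
independently (synchronous swimming is a different behavior from the contact
ethogram), per dyad-period Bernoulli with configurable rates. `fixture_g1()`
is a deterministic synthetic stand-in shaped like the four-animal group (80
days × 20 periods at the fitted memory-model probabilities, fixed seed).

What the synthetic data emulate: per-period dyadic event streams with
post-conflict memory, variable day lengths, dyad-specific association rates.
What they do not: sex- or identity-dependent behavior, bond strength,
reproductive state, observation error, or partial visibility — so passing
recovery tests demonstrates estimator correctness under the stated process,
not robustness to those real-data features. Because the latent category of
an individual contact is unidentifiable in principle, ledger-vs-classifier
agreement is exact only in configurations without ambiguity (e.g. no
conflicts); at the study probabilities the tests assert close agreement and
rely on the moment estimator for quantitative recovery.

## Comparison statistics

Spearman's r_s is computed from average ranks (standard tie handling; the
covariance-over-σσ formula is verified against rank-transform-then-Pearson
to 1e−12) with the large-sample t approximation for the p-value. The motif
universe for ranking is the union of classes in either histogram, absent
classes entering with count 0 and a tied last rank; a reference-only mode is
provided since the published analysis does not state its universe. Top-k
overlap is the fraction of the reference's k most common classes present
with positive count in the model. The rank-scatter fit is ordinary least
squares of model rank on reference rank, reporting R² = squared Pearson
correlation; zero-variance inputs raise instead of returning a conventional
value.

## Problem sizes and determinism

Default simulation scale (100 × 1600 periods) runs in seconds, so tests and
the acceptance script use the full study shape; statistical tests fix seeds
and use 3-standard-error bands (binomial or Monte-Carlo as appropriate).
Property tests run hypothesis in derandomized mode. The published headline
correlations between empirical and model motif rankings (and the raw
contact totals) depend on the undeposited raw observation logs and are
therefore context, not reproduction targets; the published arithmetic
(count bookkeeping, IA summaries) and the model calibrations are.

## Known limitations

- Undirected networks only; initiator information is retained but unused.
- The census counts whole-group configurations, not subgraph occurrences,
  and performs no null-model significance testing of motifs.
- The equal-weight-per-day convention for daily probabilities is one of two
  defensible weightings (the alternative pools periods); it is the default
  because the descriptive analysis averages per-day means.
- Canonicalization enumerates all N! permutations; fine for N ≤ 7, not
  meant for large groups.
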