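# Methods

## Model

A SELEX round is modeled as N reads drawn over Ω = {A, C, G, T}, with an
i.i.d. background whose base probabilities p_j are *estimated from the
round itself* (p̂_j = n_j / Σ L_i, multiplicity-weighted). This matters
because the selection process skews composition round over round; scoring
against a uniform background would mistake compositional drift for
enrichment.

For a candidate string s, the containment probability P_{s,L} (an i.i.d.
L-mer contains s at least once) is computed by the renewal recurrence with
border corrections described in the README. The derivation is the
classical first-occurrence decomposition: the increment P_{s,L} − P_{s,L−1}
is the probability that the *first* occurrence of s ends exactly at L,
i.e. s occupies the final window and no earlier first-occurrence event
happened — either strictly before the window (the Q·P_{s,L−|s|} term) or
overlapping it, which is only possible at border offsets (the q_t⁻¹
terms, which divide out the double-counted shared region). The recurrence
is therefore exact, and the test suite confirms agreement with exhaustive
enumeration (all L ≤ 11) and with a KMP-failure-automaton dynamic program
(L ≤ 200) at the 1e-10 level; observed deviations are at machine epsilon.

Reads vary in length, so P_s averages P_{s,L} over the empirical length
distribution with read multiplicity. F_s counts reads *containing* s
(a read with several occurrences counts once), again with multiplicity.
Z_s is the normal approximation to the binomial excess of F_s/N over P_s.

**N and F_s are multiplicity-weighted** (reads, not unique sequences).
Whether the original formulation counted unique sequences is not
determinable from its description; multiplicity weighting is the choice
consistent with "number of observed sequences" including duplicates, and
with the binomial variance over N reads.

## Search

Seeds: all 4^{l_min} strings, keep Z ≥ 0. Extension: each survivor of
length l proposes x·s and s·x for the four bases (deduplicated across
parents); a child is kept iff Z_child ≥ Z_parent for at least one
proposing parent (ties retained — the exclusion rule is strict "less
than"). Extension is two-sided by default (`--extend both`) because a
short enriched core should be allowed to grow asymmetric flanks in either
direction; one-sided modes are available. Strings with degenerate
P ∈ {0, 1} (e.g. containing a base of estimated probability zero) are
excluded from scoring rather than assigned ±∞. Candidates absent from
every read are pruned without a probability table: F = 0 with P > 0
forces Z < 0.

F-counting is batched per length class: one scan over unique sequences
collects containment counts for every distinct substring of that length
(dict of l-mer → summed counts), so a level costs O(total bases) plus one
O(L_max · (1 + #borders)) probability table per candidate. The maximum
string length is enforced strictly at l_max.

## Ranking and clustering

Z grows mechanically with string length (rarer strings have smaller P), so
survivors are standardized within each length class: Z* = (Z − μ̂)/σ̂ with
the sample mean and (n−1) standard deviation of that class's selected
strings only. A class with fewer than two members, or zero spread, gets
Z* = 0, placing it at its class mean. The ranking key is
(Z* desc, Z desc, length desc, lexicographic asc) — fully deterministic.

Greedy clustering walks the ranking: each string claims all remaining
unique sequences containing it; empty claims do not consume a cluster
rank; clustering stops when the pool is exhausted; sequences matching no
selected string are reported with cluster NA. The implementation uses a
precomputed string → containing-sequences index rather than re-scanning
the shrinking pool; the observable result is identical. Multiplicity is
carried as metadata (cluster sizes are reported both unique and with
multiplicity).

## Evaluation

Labeled sequences are scored by −cluster_rank, with NA strictly below
every real cluster; sequences sharing a cluster are tied. AUC is the
tie-aware Mann–Whitney U over n₊·n₋, cross-checked against
scikit-learn's `roc_auc_score` in the tests, and is invariant to monotone
transforms of the rank.

## Synthetic pools

The generator emulates the features the statistics depend on: ~10²–10⁷
reads around a nominal random-region length (default 30 nt), a minority
of off-length reads (default 22%, jitter ±1–3 nt uniform — in real pools
roughly a fifth of reads deviate from the expected random-region length),
optionally skewed composition, and planted motif strings overwriting a
uniform window of a Bernoulli-chosen fraction of reads (mutually
exclusive across motifs). Ground truth records carrier read, motif and
position. It does **not** model PCR amplification dynamics (counts default
to 1 per read), sequencing error, primers, secondary structure, or
multi-round trajectories — so passing the synthetic studies shows the
statistics and search behave as designed, not that any laboratory pool
will be as clean.

A note on labels: a background read can contain a planted motif by pure
chance (about 0.09 reads per 10⁴-read replicate under the default skewed
composition). Such a read carries the binding region in every observable
sense, so evaluation labels in the studies define "carrier" by motif
containment; the planted set is always a subset of it.

## Study problem sizes

The packaged studies use 20 replicates of 10⁴ reads (one planted 10-mer,
prevalence 0.2, skewed composition 0.3/0.2/0.3/0.2), searched at
l_min = 5, l_max = 10 with no frequency filter (nearly every random
30-mer is unique at this depth, so a count cutoff would empty the pool;
on deep real rounds the default `--min-count 10` is the intended setting).
The anti-missing check exhaustively Z-scores every substring of lengths
5–8 present in the reads and asserts the top string per length survived
the pruned search. Enumeration-oracle checks stop at L = 11 (4¹¹ ≈ 4·10⁶
outcomes); the automaton oracle extends to L = 200.

## Numerical choices

Plain double precision throughout. Each recurrence value is asserted to
lie in [−1e−9, 1 + 1e−9] and clipped to [0, 1] with a logged warning only
inside that margin; anything larger raises. Q = 0 short-circuits to an
all-zero table. The Z of a string is computed once per level against the
full filtered pool; no subsampling anywhere. All randomness flows through
a single seed per generated pool; identical seed and parameters give
byte-identical FASTA output.

## Known limitations

Containment (not occurrence-count) statistics; no indels, no IUPAC
degenerate codes, no Markovian background, no secondary-structure
alphabet. The i.i.d. background is itself estimated from a selected pool,
so globally enriched composition is absorbed into p̂ rather than flagged.
Cluster membership is by exact substring match only; within-cluster
ordering beyond read count, and cluster merging, are out of scope.
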