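# Methods

This note records the models, conventions and numerical choices behind
irefkit, and what the synthetic test data does and does not establish.

## Data model

irefkit operates on consolidated protein–protein interaction tables in the
iRefIndex MITAB 2.6 dialect. Each line is either a binary interaction
(edgetype `X`), one member of an n-ary record in its bipartite representation
(edgetype `C`, with a `complex:<RIGID>` pseudo-node in the A slot), or a
polymer record (edgetype `Y`, one interactor type).

Redundancy is resolved at two levels. The **ROGID** is a digest over a
protein's primary amino-acid sequence plus NCBI taxon, so the same molecule
curated under different accession systems maps to one key; the **cROGID**
additionally collapses related records (splice isoforms of a gene) to the
ROGID of a chosen group representative. **RIGID**/**cRIGID** apply the same
idea to whole interactions: the digest of the ascii-sorted participant
(c)ROGIDs. Counting entities canonically therefore never yields more
proteins or interactions than counting sequence-specifically; equality holds
exactly when the isoform map is the identity.

Key computation (`compute_rogid`/`compute_rigid`) is provided for
verification and fixture construction only; keys present in an input file
are never overwritten. We use SHA-1 over the upper-cased sequence
concatenated with the decimal taxid, standard base64 with padding retained.
Published files may use a different padding convention; because irefkit
treats file keys as opaque strings this only matters when comparing computed
keys against a release, which should be spot-checked before relying on it.

## n-ary expansion

An n-ary record states that *m* proteins were observed together, not which
pairs touch. Every conversion to an edge list therefore carries an explicit
policy:

| policy    | edges per complex | semantics |
|-----------|-------------------|-----------|
| bipartite | m                 | member ↔ pseudo-node list view (not binary claims) |
| spoke     | m − 1             | hub → members; hub = the unique bait when exactly one member carries the bait role, else the lexicographically smallest member id (deterministic fallback, logged) |
| matrix    | m(m−1)/2          | all member pairs |
| exclude   | 0                 | n-ary data left out |

Edge weights count distinct supporting source records by default (a complex
counts once however many member rows it occupies); weighting by distinct
publications is available as a flag. Undirected edges are stored with
`node_a <= node_b`; self-loops (polymers, or isoform pairs collapsing at the
canonical level) are excluded unless requested. Directed edge lists orient
bait → prey; binary records without role information are embedded as
reciprocal arc pairs, or dropped on request. Matrix expansion has no
direction semantics and combining it with `directed` is an error.

## Regenerated complexes

Some databases curate co-purification experiments as binary records
radiating from the bait (a spoke-represented complex). The detector keeps
binary records carrying an n-ary-producing method (default list: affinity
chromatography MI:0004, co-immunoprecipitation variants MI:0006/0007/0019,
cosedimentation MI:0027, pull down MI:0096, TAP MI:0676) and exactly one
supporting publication, groups them by (source database, publication,
method), and forms one complex per shared hub protein. With bait roles
present the hub is the bait (one complex per bait in the group); without
them a greedy search repeatedly takes the protein covering the most
remaining records (ties broken lexicographically) and consumes its records,
so complexes from one group do not overlap — an overlap-permitting mode
exists for method comparison. Complexes below 3 members are discarded.
Records citing several publications are excluded outright: a per-paper view
would count them twice.

A conservative preset restricts to BioGrid + MI:0004. Each regenerated
complex carries a throughput class from the recomputed lpr of its
supporting records (all ≤ 21 → low, all > 21 → high, else unknown).
Small regenerated complexes can be false positives — independent binary
observations sharing a protein and method; confirming a regenerated record
requires reading the original paper and is out of scope.

## Bibliometric scores

For a distinct interaction with supporting publication set P and
reuse(p) = number of distinct interactions publication p supports:
np = |P|, lpr = min reuse, hpr = max reuse. lpr ≤ 21 is the conventional
low-throughput cut (a parameter everywhere it appears). Scores are
recomputed from the table at hand by default; a flag trusts file-supplied
values instead. The two views legitimately differ on subsets: file scores
reflect the whole release the file was cut from. These are descriptive
bibliometric quantities, not confidence scores.

Degree summaries report n, mean degree (2|E|/n for simple undirected
graphs; total degree for directed), population variance (ddof = 0 — a
documented choice, trivially switchable) and maximum degree, plus
interaction counts from the source table when given.

## Discrete power-law fitting

Degrees are integers, so the model is P(X = x) = x^(−α)/ζ(α, xmin) with the
Hurwitz zeta normaliser. For every candidate xmin among the observed values
whose tail holds ≥ `min_tail` points (default 10) and ≥ 2 distinct values,
α is the maximum-likelihood estimate found by golden-section search on the
(concave) log-likelihood over (1.01, 25.0) with tolerance 1e-5, and the
candidate minimising the KS distance between empirical and model tail CDFs
is selected, ties going to the smaller xmin (larger tail). The upper α
bound matters: light (e.g. geometric) tails have local exponents well above
6, and a clamped α distorts the xmin selection. On power-law samples the
fit agrees with igraph's bundled plfit to ~3 decimals in α and exactly in
xmin; the cross-check is kept as a test.

Goodness of fit is a semiparametric bootstrap: each of B synthetic samples
draws from the fitted tail model with probability ntail/n and uniformly
from the observed sub-xmin values otherwise, is refitted from scratch, and
p is the fraction of synthetic KS distances ≥ the observed one. p < 0.1
rejects the power law; p ≥ 0.1 means "plausible", which never excludes a
better-fitting alternative (likelihood-ratio comparisons against other
distributions are deliberately out of scope). Sampling uses exact
inverse-CDF lookup against a table leaving ~1/(10n) overflow mass, with
integer bisection beyond it; everything is deterministic given a seed.

**Power caveat.** Because xmin is re-estimated per sample, the effective
test size is the selected ntail, not n. Against geometric alternatives at
n = 10000 the bootstrap rejects in only about half of seeds: the
KS-minimising xmin crops the sample to an extreme tail (ntail ≈ 60–800)
where an exponential decay is locally power-law-like. This is a property of
the method, reproduced by igraph's independent plfit on the same samples,
and is reported as measured by the acceptance script rather than hidden.
Acceptance of the power-law hypothesis on real degree data should be read
with the same caution.

## Synthetic data generator

`generate_mitab` produces a MITAB table plus an exact manifest from one
seed (per-component sub-streams keep record classes independent). The
default configuration is a small mixed interactome extract: 60 proteins
(15% foreign-taxon, three isoform groups of sizes 3/2/2), 80 independent
binary records each supported by a fresh publication (15% re-curated by a
second database), two high-throughput yeast-two-hybrid screens of 25
bait–prey records sharing one publication each, five reported complexes of
3–9 members in bipartite representation (60% with a recorded bait), four
planted spoke-represented complexes of 3–8 members (BioGrid/MINT,
MI:0004/MI:0096, one publication per group), and three homodimer polymer
records. Sequence lengths are 50–400 residues; the primary taxon is
budding yeast (4932) with human and mouse as foreign taxa.

Two deliberate modelling choices: HT screens use two-hybrid (MI:0018),
which is not an n-ary-producing method — matching real curation practice
(AP-MS produces n-ary evidence, Y2H binary evidence) and ensuring the only
(db, publication, n-ary method) groups in a default fixture are the planted
spoke complexes; and independent binaries each cite a fresh publication, so
they form singleton groups that cannot regenerate. Degree samples for
distribution tests come from exact discrete power-law, geometric
(default p = 0.05, mean 20 — in the range of dense interactome average
degrees) and zero-truncated Poisson generators.

What the fixtures do **not** emulate: real accession noise (obsolete or
ambiguous identifiers), heterogeneous column dialects across releases,
multi-species complexes, correlated publication structure beyond the
screen/unique-pmid dichotomy, and realistic interactome-scale marginals.
Passing tests therefore establish algorithmic correctness on
structurally faithful data, not robustness to the full messiness of a
production release file.

## Problem sizes

The test suite and the acceptance script run the regeneration oracle on 100
fixtures of ≤ 50 binary records, the score oracle on 50 fixtures, round
trips on 5 reference fixtures, and the power-law study on 20 seeds per
condition (n = 5000 power-law draws, n = 10000 geometric draws) with
B = 100 bootstrap resamples; B = 1000 is the default for reported p-values
in interactive use. These sizes were chosen so the full suite completes in
a few minutes while keeping every estimate's Monte-Carlo error far below
the asserted tolerances.
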