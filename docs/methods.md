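# Methods

## The reconciliation model

The package treats name reconciliation as string comparison under a single
metric, applied in two settings: within one database (clustering duplicate
spellings) and across two databases (matching names to taxa).

**Fingerprinting.** All comparison happens on a normal form: full Unicode
casefold, canonical (NFKD) decomposition with combining marks removed, a
small substitution table for letters that do not decompose (ø→o, ß→ss,
æ→ae, œ→oe, đ/ð→d, þ→th, ł→l, ı→i), removal of every character in a
Unicode punctuation category, and collapse of whitespace runs to one ASCII
space. The pipeline is idempotent (property-tested over random Unicode
strings) and locale-independent; the space survives as an ordinary
character in the LCS. Punctuation-only differences ("Kaup 1829" vs
"Kaup, 1829") therefore vanish before any score is computed.

**Similarity.** For fingerprints *a* and *b* with longest common
subsequence length ℓ,

    sim(a, b) = min(ℓ/|a|, ℓ/|b|),

a value in [0, 1]. Thresholding this scalar at *t* is equivalent to
requiring the LCS to be long relative to **each** input, which is the
two-sided rule the clustering uses; keeping one scalar also lets the same
quantity serve as a bipartite edge weight, so there is exactly one metric
in the package. Identical non-empty fingerprints score exactly 1.0; the
similarity of two empty strings is defined as 0, not 1, so that two
authorless records can never merge *through the metric* — they are handled
by the explicit authorless rule below. The subsequence (not substring)
choice makes single insertions/deletions degrade the score smoothly.

The LCS is the textbook dynamic programme with two rolling rows, checked
in tests against an exhaustive memoized recursion for all short strings.

## Name parsing

No grammar for zoological name strings exists, so the canonical/authorship
split is an explicit heuristic with a reject path, documented here as the
package's own convention:

- the canonical part is a leading capitalized Latin word (genus), an
  optional single parenthesized capitalized word (subgenus), then up to
  two all-lowercase epithets;
- authorship starts at the first token breaking that pattern — a
  capitalized surname, "(", a year, or a lowercase surname particle
  (de/van/von/der/den/du/la/le/di) followed by a capitalized word, so
  "Rana van Hasselt" splits before "van";
- the year is the first 4-digit token in [1750, 2100] of the authorship;
  parenthesized authorship is kept verbatim and flagged (the parentheses
  are punctuation and vanish from the fingerprint);
- strings with no leading capitalized word, hybrid signs, or botanical
  rank markers ("var.", "subsp.") raise a parse error and are routed to
  reject lists, never dropped silently.

## Clustering

Records are blocked by exact canonical name. Within a block, authored
records are nodes of an undirected graph; an edge joins two records iff
the similarity of their authorship fingerprints is ≥ the threshold
(default **0.8**, the package's standard operating point; identical
strings score 1.0). Connected components are the name clusters —
equivalent to transitive closure over the pairwise score matrix, which is
how the test oracle computes them.

The year token participates in the authorship fingerprint, so
"Gloger 1827" and "Gloger 1829" differ by evidence, not by a special
veto.

**Authorless records.** A record with no authorship carries no signal, so
it is merged by rule: with one authored cluster the merge is forced
(`attachment="merged"`); with several, the record attaches to the largest
cluster, ties broken by the lexicographically smallest representative
authorship, and the cluster is flagged `attachment="ambiguous"` — the
flag records that the assignment is a convention, not an inference. With
no authored cluster at all, the authorless records form one cluster.
Attaching to a single cluster (rather than all) keeps the output a
partition, which every downstream consumer assumes.

Cluster ids are content-derived (SHA-1 of canonical + sorted member ids,
truncated), so identical input yields identical ids across runs and
machines. The representative is the member with the longest authorship
(ties: lexicographically smallest authorship, then smallest record id).

## Mapping names to taxa

Records from two sources are blocked by canonical name; within a block
every left/right pair is weighted by the similarity of the **full name
strings** (the strings a database actually shows), and edges below
**min_weight = 0.5** are not admitted. The floor exists because a bare
genus name is a subsequence of every authored variant of that genus: with
no floor it would attach to whichever authored taxon happened to be left
over. 0.5 suppresses those spurious matches while keeping every
same-author pair in the shipped examples (lowest such weight: 0.762).

The map is the maximum weighted bipartite matching, solved per block with
`scipy.optimize.linear_sum_assignment` on a dense matrix (zeros for
missing edges; zero-weight assignments discarded afterwards). Among
equal-weight optima the returned matching is made deterministic by a
refinement pass: candidate pairs are visited in sorted (left_id, right_id)
order and kept iff forcing them preserves the optimal total weight — so
output is bit-reproducible. Tests verify optimality against brute-force
enumeration of all matchings (≤ 6×6) and against networkx's independent
general-graph matcher, and verify the greedy lower bound and left/right
symmetry.

## Citation parsing

The parser is an ordered bank of regular expressions — first match wins —
targeting the conventional shape

    Title. Journal, Volume(Issue) Year: Start–End. CitedPage (Note)

with three patterns: full journal title (no internal periods/commas),
abbreviated journal (capitalized dotted tokens), and title-less strings.
Hyphen, en-dash and em-dash are all accepted as page separators. A match
must also validate (year in [1750, 2100], start ≤ end when both numeric)
or the next pattern is tried; a string nothing matches returns a
structured failure carrying the raw text, never an exception. Because the
bank is ordered data, appending patterns cannot change results for
strings matched earlier (tested). The "cited page" — the bare page number
after the pagination on which the name itself appears — is an optional
trailing group. OpenURL export emits one key per populated bibliographic
field (rft.atitle, rft.jtitle, rft.volume, rft.issue, rft.date,
rft.spage, rft.epage); cited page and note, which have no standard
OpenURL key, travel as extension keys so the rendering stays lossless.

## Journal normalization

Resolution against a registry (CSV: canonical_title, issn, oclc,
pipe-separated variants) tries, in order: exact fingerprint match on the
canonical title; exact fingerprint match on any listed variant (both
score 1.0); then abbreviation matching — every query token, its trailing
periods already removed by fingerprinting, must be a prefix of the
positionally corresponding canonical-title token, skipping the connective
stopwords of/the/and/de/der/und; the score is the fraction of canonical
content tokens covered. Prefix matching rather than LCS because that is
how journal abbreviations are formed; LCS over whole titles rewards
unrelated journals sharing common words. Candidates are examined in
canonical-title order, so the result is independent of registry row
order. ISSNs are validated by the public mod-11 check digit (weights
8..2, X = 10), tested against a brute-force check-digit table.

## Synthetic corpora

The generator emulates nomenclator variation: for each generated genus
name, one true name cluster (or two, for homonyms, with probability 0.2),
each emitted as several variants of "Canonical Surname Year". Per-variant
perturbations, each applied independently with its own probability:

| parameter         | default | emulates                                 |
|-------------------|---------|------------------------------------------|
| n_canonicals      | 50      | corpus breadth                            |
| variants_per_name | 4       | duplication depth per true name           |
| p_accent          | 0.2     | accent loss ("Böhlke" → "Bohlke")         |
| p_punct           | 0.3     | comma before the year                     |
| p_drop_year       | 0.3     | year omitted                              |
| p_typo            | 0.05    | single-char surname deletion/substitution |
| p_authorless      | 0.1     | bare canonical, no authorship             |

Surnames come from a fixed in-repo list that deliberately includes
accented forms; years are drawn from 1758–2013. One `random.Random(seed)`
stream drives everything, so a fixed seed reproduces the corpus byte for
byte. Every record carries exactly one truth label — authorless variants
keep the label of the cluster they were generated from, which is exactly
the case the attachment rule can get wrong under homonymy.

Recovery is scored with the adjusted Rand index, implemented in-repo in
its pair-counting form, tested against a hand-computed two-partition
example and cross-checked against scikit-learn. With all perturbation
probabilities at zero, recovery is exact (ARI 1.0) by construction. At
the registered evaluation settings (surname typo rate 0.1, 50 canonicals
× 4 variants, fixed seed) the pipeline's measured ARI is frozen in the
test suite as a regression floor. Note what noisy recovery does *not*
show: real nomenclator dumps contain multi-author strings, initials,
"in"-attributions and transliteration drift that the generator does not
emulate, so synthetic ARI is a consistency check on the pipeline, not an
estimate of accuracy on real data. A known systematic effect: dropping
the year lowers similarity below 0.8 ("gloger" vs "gloger 1827" scores
0.55), so year-free variants tend to split from their year-bearing
cluster — a property of the min-ratio metric at the default threshold,
visible in the shipped examples too ("Nystactes Bohlke" vs
"Nystactes Bohlke, 1957" scores 0.762).

## Numerical and degenerate-input choices

- Similarity of anything empty-fingerprinted is 0; empty-vs-empty is 0.
- Thresholds are compared with ≥; matching-optimality comparisons use an
  absolute 1e-9 slack on sums of floats.
- Problem sizes in tests (oracle strings ≤ 8 chars, bipartite instances
  ≤ 6×6, clustering groups ≤ 12, corpora of ~200 records) are the sizes
  at which the exhaustive oracles stay instant; the algorithms themselves
  have no such limits.
- All I/O is UTF-8 with an explicit Latin-1 fallback for legacy dumps;
  JSON output has sorted keys so re-runs are byte-identical.

## Known limitations

- The canonical/authorship heuristic handles the dominant zoological
  forms; multi-word authorship teams, "in"-attributions and non-Latin
  scripts beyond decomposable accents are untested territory.
- The citation bank covers the conventional article shape only; books,
  "in" chapters and multi-volume pagination fail soft to `unparsed`.
- Journal abbreviation matching is positional; reordered or fused
  abbreviations ("Zool. Bull.") will not resolve.
- Authorless attachment under homonymy is a convention (largest cluster)
  and is flagged as such in the output rather than hidden.
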