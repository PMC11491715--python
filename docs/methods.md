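# Methods

## Motif model and matching semantics

The PPRE is modeled as a fixed-length IUPAC consensus (default
`AGGTCANAGGTCA`, 13 bp: two `AGGTCA` half-sites with a 1-bp spacer — a
DR1 element).  There is no position-weight-matrix scoring and no
mismatch tolerance: a position either satisfies its IUPAC class or the
candidate is rejected, which matches the "exact match" search the
pipeline reproduces.

Each IUPAC letter denotes a set of concrete bases.  Two matching rules
are implemented:

* **strict** (default): genome base set ⊆ pattern position set.  An
  assembly-gap `N` in the genome therefore matches only a pattern `N`
  position — a gap can never manufacture an exact consensus hit.  A
  genomic `R` matches pattern `R`, `D`, `V`, `N`, etc.
* **intersection** (`--ambiguous-genome-matches`): non-empty set
  overlap, the permissive convention some genome browsers use.

Matching is case-insensitive by default because repeat-masked (lowercase)
sequence is not excluded from the analysis; `--respect-softmask`
excludes lowercase bases.  Minus-strand occurrences are found by
matching the reverse-complement consensus against the forward text, so
every site is reported in forward-strand coordinates with the strand
flag carrying the orientation.  Overlapping occurrences are all
reported (regex scanning uses a zero-width lookahead); a greedy
non-overlapping mode exists for comparison.  The scan streams one
chromosome at a time, so memory is bounded by the largest chromosome
plus the site list.  Site tables carry both 0-based half-open (BED) and
1-based inclusive coordinates because downstream genome browsers
display the latter.

The default reproduction manifest for a whole-genome run is chr1–chr22,
chrX, chrY (mitochondrion and unplaced scaffolds excluded); whether the
original count included overlapping occurrences or gap-spanning windows
is not documented anywhere we could find, so these defaults are stated
choices, and the scan flags above span the plausible alternatives.

## Gene association

A site's window is `[start − 10000, end + 20000)` for a plus-strand
site and the mirror image for a minus-strand site (default
**site-strand** orientation: a response element's own orientation
defines its upstream and downstream).  A **forward-fixed** mode applies
upstream to smaller coordinates regardless of strand, reproducing a
strand-agnostic table-browser query.  A gene is associated when its
body overlaps the window under half-open interval intersection — any
overlap, not containment (a containment flag exists).  Signed distances
are 0 for genes overlapping the site itself, otherwise the 1-based
offset of the nearest gene base from the site edge, positive downstream
in site orientation.  Lookup uses an interval tree per chromosome; a
quadratic all-pairs mode is retained purely as a testing oracle.
Summaries group unique gene symbols by the *site's* strand (grouping by
gene strand is also emitted).  The published associated-gene totals
(660 genes; 311/349 by strand) depend on an unstated annotation track
and are deliberately not asserted anywhere; the association stage is
instead validated by boundary-exact, translation-invariance, and
oracle-equivalence properties.

Gene-set filtering is a case-insensitive intersection that returns the
reference set's casing, since curated lists (e.g. the UniProt human
kinome) are the naming authority.

## Network analysis

Edges carry a confidence in [0, 1]; the high-confidence graph keeps
score ≥ 0.7 (inclusive, as published).  The graph is undirected;
duplicate edges collapse keeping the maximum confidence; self-loops are
dropped.  Interactome coverage divides the query set's distinct
non-query interactors by the node count of the *unthresholded* network
(19485 in the published analysis, which matches the full protein count
rather than the post-threshold node set; a flag switches the
denominator).  The count including query nodes is also reported because
the published "interacts with 1084 nodes" is ambiguous on this point.

Centralities are computed on the unweighted neighborhood subgraph:

* **degree** — incident edge count;
* **closeness** — harmonic form, Σ<sub>u≠v</sub> 1/d(v,u), finite under
  disconnection (the convention of cytoHubba-style hub calling; classic
  closeness would be undefined on the disconnected neighborhoods that
  zero-degree queries produce);
* **betweenness** — shortest-path betweenness with pair normalization
  disabled (raw pair counts).

Hubs are the top-k (default 10) nodes per measure, ordered by (score
descending, symbol ascending); ties at the k-th rank are cut
lexicographically rather than expanded, keeping rankings deterministic.
The union and intersection across the three measures are reported.
Candidates default to all nodes of the neighborhood subgraph; a
`query-only` restriction exists because in the published analysis all
13 hub genes are query kinases, suggesting the hub search was
restricted to them.

## Disease annotation

Records with score strictly > 0.3 survive (the published cutoff is
written as an inequality, so 0.30 itself is dropped; an inclusive mode
is a flag away), and whole disease types — by default `phenotype` — are
excluded case-insensitively.  The filtered table pivots to a gene ×
disease matrix (lexicographic ordering, duplicate cells keep the
maximum score, absent pairs are 0) written as wide TSV for heatmap
rendering.  No live database access is performed: version drift and
licensing make a snapshot TSV the only reproducible input.

## Synthetic data: what it emulates and what it does not

The generators stand in for the four external inputs (genome assembly,
annotation track, scored interactome, GDA snapshot).  All randomness
flows from one seed through named sub-streams, so outputs are
byte-identical across runs and stages can be regenerated independently.

* **Genome**: i.i.d. bases at GC fraction 0.41 (human-like); chance
  consensus occurrences on either strand are destroyed by single-base
  substitution at a maximally constrained pattern position
  ("scrubbing", with re-scan until clean), then sites are planted
  non-overlapping and ≥ one pattern length apart, `+` sites carrying
  the consensus with random bases at `N` positions and `−` sites its
  reverse complement.  Generation re-validates with a naive
  position-by-position oracle that the final sequence contains exactly
  the planted occurrences, so planted-recovery assertions are exact.
  The default fixture is one 100 kb chromosome with 12 `+` and 8 `−`
  sites — large enough for window structure, small enough that the
  whole suite runs in seconds.
* **Annotation**: per site, genes strictly inside the window, a
  boundary pair probing the half-open contract (last covered base =
  window end − 1 → in; first base = window end → out), and genes
  strictly outside; one inside gene per site is designated a kinase and
  flows into the fixture's reference gene set.  Because neighboring
  sites' windows may overlap, the truth's association list is computed
  with the all-pairs oracle over all sites and genes, which keeps it
  exact under any spacing.
* **Network**: query i receives exactly its configured number of
  partners at confidence ≥ 0.7 (the first pinned at exactly 0.70 to
  exercise the inclusive boundary) plus sub-threshold partners that the
  0.7 cutoff must remove; background edges connect only non-query
  nodes, so post-threshold per-query counts equal the planted degrees
  by construction (re-validated by an adjacency recount).  The
  highest-degree query is wired as a bridge to one partner of every
  other connected query, making it the provably top-ranked node under
  all three centralities — a known hub-calling answer.  The
  kinase-panel preset uses 29 queries named after the published kinase
  panel with planted degrees following the published per-kinase spread
  (167 … 0).
* **GDA**: scores drawn from a grid straddling the cutoff
  (0.29/0.30/0.31/…) with a disease/phenotype/group type mix; the truth
  lists the records surviving the default filter.

What the fixtures do **not** emulate: chromatin or repeat structure,
realistic gene length/density distributions, scale-free interactome
degree distributions, or correlated GDA scores.  Passing tests
therefore demonstrate the correctness of coordinate arithmetic, strand
handling, thresholding, counting, and ranking logic — not biological
discovery performance on real data, where motif density, annotation
quality and network topology differ.

## Numerical and degenerate-input choices

Coverage percentages are rounded half-even to two decimals at the
reporting boundary only.  Empty genomes, empty annotation files, and
queries absent from the network are legal inputs producing empty/zero
outputs (absent queries are listed in the report, mirroring a
zero-interactor kinase like SRRM5).  Confidence and GDA scores outside
[0, 1] are rejected with line context rather than clamped.  Duplicate
chromosome identifiers abort the scan.  Rankings, site tables and all
emitted files are deterministically ordered so reruns are
byte-identical; the run manifest differs only in timestamps.

## Problem sizes

The test suite runs entirely on generated fixtures: 100–200 kb genomes
with ≤ 29 planted sites, networks of ≤ ~1300 nodes, and centrality
oracles on graphs of ≤ 50 nodes — sizes at which exhaustive brute-force
oracles (position-by-position scan, all-pairs overlap, BFS shortest-path
enumeration) are feasible and exact.  The whole-genome and
full-interactome reproductions run the same code paths unchanged; they
are exercised by the two pinned-input tests described in the README.
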