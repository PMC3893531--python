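# Methods

This note records the models and conventions behind `stacklogo`, the
defaults and why they were chosen, and what the synthetic-data generator
does and does not emulate.

## Column model and information content

Each alignment column (or profile match state) is summarized by a letter
distribution **p** over the canonical alphabet (4 letters for DNA/RNA, 20
for protein). Conservation is measured as relative entropy against a
background **q**, `D(p‖q) = Σ pᵢ log₂(pᵢ/qᵢ)`, with the convention
`0·log(0/q) = 0`. Inputs are validated to sum to 1 within 1e-4 — wide
enough to absorb the rounding introduced by HMMER's 5-decimal negative-log
storage — and renormalized before the sum is taken, which keeps `D ≥ 0`
exactly. If `pᵢ > 0` where `qᵢ = 0` the divergence is undefined and an
error is raised rather than returning infinity.

Backgrounds default to uniform for DNA/RNA and to the Robinson–Robinson
amino acid frequencies (the background conventionally paired with the
BLOSUM62 matrix) for protein; both are user-overridable per call, via a
frequency file in the CLI, or by constructing an `Alphabet` with a custom
vector. Under the shipped amino background the theoretical stack-height
ceiling `max −log₂ qᵢ` is ≈ 6.23 bits, attained by tryptophan; other
BLOSUM62-derived tables put this anywhere between ≈ 6.2 and 6.5 bits, which
is why the package treats the ceiling as background-dependent rather than a
constant.

## Letter heights and stack order

* `info_all`: height `pᵢ·D` for every letter with `pᵢ > 0`.
* `info_above_bg`: total height is still `D`, split among letters with
  positive score `sᵢ = log₂(pᵢ/qᵢ)` in proportion to their `pᵢ`. When
  `p = q` (so `D = 0`) the stack is empty.
* `score`: height `sᵢ` for each positive-scoring letter. Stack totals in
  this mode are sums of log-odds and deliberately carry no conservation
  semantics; a diffusely enriched column can out-stack a strongly conserved
  one.

Stacks are stored bottom-to-top in ascending height. Equal heights are
broken alphabetically with the earlier letter nearer the top, so output is
deterministic. Letters with `pᵢ = 0` score `−∞`; that sentinel is kept as
`float('-inf')` in memory and serialized as JSON `null`.

## Alignment processing

Characters `-`, `.`, `_`, `~` are gaps. Case is preserved in storage and
ignored in counting (Stockholm files mark insert residues in lower case).
Ambiguity codes (`N`, `X`, IUPAC nucleotide codes, `B/Z/J/X/U/O` for
protein) count toward column occupancy but contribute no letter counts; a
column whose residues are all ambiguous falls back to the background
distribution. This all-or-nothing policy is simpler than fractional
redistribution of ambiguity codes over their compatible letters; for
typical inputs the difference is negligible, but heavily degenerate
alignments will look flatter than a fractional scheme would make them.

Three estimation regimes:

* **observed** — unit weights, `p = counts / Σcounts`.
* **weighted** — Henikoff–Henikoff position-based weights: in a column with
  `r` distinct letters, a sequence showing a letter occurring `s` times
  receives `1/(r·s)`. Each sequence's increments are averaged over the
  columns where that sequence bears a canonical residue (so heavily gapped
  sequences are not penalized for their gaps), then the vector is scaled to
  mean 1. Duplicating every sequence leaves the weighted estimates
  unchanged.
* **weighted_prior** — weighted counts combined with a Dirichlet prior.
  The default prior is a single component with `α = c·q`, concentration
  `c = 1`, chosen so that an empty column posterior equals the background
  exactly and a single observation is pulled visibly toward it. Mixture
  priors are supported (responsibilities via Dirichlet-multinomial marginal
  likelihoods computed with log-gamma; posterior means averaged by
  responsibility) and can be loaded from a plain-text file: one mixture
  coefficient followed by L alphas per line.

Occupancy of a column is the weighted fraction of sequences bearing any
residue there. A column is a consensus column when occupancy ≥ `symfrac`
(default 0.5, matching common profile-construction practice); `symfrac 0`
retains every non-empty column. Empty columns never become positions.

Entropy weighting (target-information rescaling of effective sequence
number) is deliberately not implemented; logos reflecting it can be
produced by building the profile externally and feeding the `.hmm` file.

## Profile HMMs

The HMMER3 plain-text format is parsed directly: stored values are
negative natural logs, `*` means probability zero, and node 0 is the begin
node whose m→m/m→i/m→d slots hold B→M1/B→I0/B→D1. The reader consumes
NAME, LENG, ALPH, MAP, COMPO and the state table, preserving other header
lines opaquely; the writer emits the HMMER3/f layout with 5-decimal
values, so read↔write round trips agree to better than 1e-4 per value.
Files written here are accepted by pyhmmer's parser (checked in tests).
Binary sidecar formats and DP scoring are out of scope.

Per-position gap parameters come from the transition table:

* occupancy by the visit-probability recursion
  `occ(1) = t₀(m→m) + t₀(m→i)`,
  `occ(k) = occ(k−1)·(t(m→m)+t(m→i)) + (1−occ(k−1))·t(d→m)` — exact
  because the insert state always returns to the next match state; the
  recursion is verified against exhaustive enumeration over all
  match/delete paths for models up to length 6, and against pyhmmer's
  occupancy vector for a real `hmmbuild` save file;
* insert probability as the single transition `t_k(m→i)` (the chance that
  the match at k is followed by one or more inserted letters, given the
  match state is used), not a path-marginalized quantity;
* expected insert length `1/(1−ε)` from the geometric length model with
  self-transition `ε`; `ε = 1` is rejected as divergent.

Alignment logos report occupancy only — insert rows are absent (`None`,
and omitted from the JSON document), never zero, because every non-empty
column already has its own position.

## Rendering

The JSON document (`version: stacklogo-1`) is the seam for interactive
viewers: deterministic key order, every float canonicalized through
`%.12g` so that serialize→parse→serialize is byte-identical and numeric
round trips are lossless to well below 1e-9.

SVG output draws glyphs as vector paths taken once from the DejaVu Sans
Bold outline bundled with matplotlib, normalized to a unit box and
stretched non-uniformly into each stack cell — no text metrics, so output
is deterministic. Stack spacing is uniform; gap parameters appear as a
value table under the stacks (occupancy row for alignment logos; plus
insert probability and expected length rows for profiles), each cell
shaded blue→white (occupancy 0→1) or white→red (insert probability 0→1,
insert length 1→cap, cap default 10). A non-white insert-probability cell
additionally draws a thin matching red bar immediately after its stack.
Numeric cells print two significant digits (percent for the probability
rows). The overview renderer replaces glyphs with colored bars (same
stacking order, no text elements), sized so hundreds of positions fit one
panel. PNG output paints the same primitive list through matplotlib's Agg
canvas at 1 px/unit, so pixel dimensions equal the SVG's declared size.
In score mode the y-axis is captioned "score (bits)" and scaled to the
tallest stack, since the theoretical info-mode ceiling does not apply.

## Synthetic data

The generator samples alignments column-by-column: each sequence
independently bears a gap with probability `1 − occupancy` or a letter
from the column's true distribution, and toy profile HMMs are assembled
from explicit per-node parameters. Everything is seeded; there are no
unseeded entry points. This emulates exactly what the estimators consume —
known per-column distributions and occupancies, known transition
parameters — and none of what real families add: phylogenetic correlation
between sequences, insert-length structure, composition drift along the
sequence. Passing tests therefore demonstrate correctness of the
estimators and renderers against their stated models, not robustness to
tree-structured redundancy (that is precisely what position-based
weighting is for, and it is exercised via constructed redundant fixtures
instead).

Problem sizes used in tests and in `scripts/acceptance.py` — models of
length ≤ 6 for the path-enumeration oracle, alignments of 10–5000
sequences for convergence checks, 200 random columns for height-mode
identities — were chosen as the smallest sizes at which the checked
effects are unambiguous.

## Known limitations

* No entropy weighting, and no attempt to reproduce any specific HMMER
  Dirichlet mixture; profiles built with those defaults will show lower
  per-position information than this package's `weighted_prior` regime.
* Ambiguity codes are never fractionally assigned.
* Stockholm parsing normalizes `.` to `-` (both are gaps here, so only the
  stored characters differ, not any statistic).
* The CLI reads whole files into memory; alignments with millions of rows
  are out of intended scope.
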