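# Methods

## The model

A *functional center* is a short stretch (typically 12–50 aa) of a
multi-domain protein in which only the residues that directly perform a
molecular function — catalysis, gas sensing, hormone binding — are
conserved across distant lineages. The working model is therefore a
PROSITE-style pattern: an ordered list of conserved anchors (fixed
residues or residue classes) separated by ranged wildcards `x(N,M)`
that absorb the non-conserved spacer residues. Matching such a pattern
against a proteome is the discovery step; everything upstream
(consensus construction) and downstream (physicochemical ranking,
candidate export) supports it.

The package ships five curated center motifs with their expected spans:
GC `[KS]x[CGS]x(10)[KR]` (14 aa), AC `[RKS]x[DE]x(10)[KR]` (14 aa),
PDE `[YFW]Hx[YFW]Rx(20,40)[HRK][DE]` (27–47 aa), H-NOX
`Hx(12)Px(14,16)YxSxR` (33–35 aa) and ABA
`[DE]x(7,8)Rx(3,4)[DE]x(5)Yx(6)H` (26–28 aa). The registry asserts at
construction time that each pattern's computed length range equals its
expected span.

## Pattern dialect and matching

The parser accepts a compact dialect (`[KS]x[CGS]x(10)[KR]`) and
hyphen-separated PROSITE (`H-x(12)-P`); both canonicalise to the
compact form with alphabetised classes and collapsed degenerate ranges
(`x(3,3)` → `x(3)`). Following standard PROSITE semantics, `{ABC}`
denotes an *excluded* class; ranged gaps are written only as `x(N,M)`
(some of the literature also writes gaps in curly braces — that prose
form is deliberately not parsed, to keep exclusion semantics
unambiguous). A pattern made only of wildcards parses fine but draws a
"matches almost everywhere" warning rather than an error, since such
degenerate patterns are legitimate inputs to length arithmetic.

Matching is a dynamic program over (element index, position): for each
sequence, `table[ei][pos]` holds the set of end offsets reachable when
elements `ei:` match starting at `pos`. The table is shared by all
start positions, so enumeration of *every* distinct `(start, end)` span
— overlaps included, multiple ends per start from ranged gaps included
— costs O(elements × length × gap-width) rather than exponential
backtracking. Its behavioural contract is defined solely by equality
with `brute_force_matches`, a deliberately naive recursive enumerator
kept free of shared code; the suite checks exact span-set equality on
500 randomized (pattern ≤ 6 elements, sequence ≤ 40 aa) instances.

Coordinates are 1-based with inclusive ends everywhere (the
ScanProsite convention), stated in every output header. All distinct
spans are reported by default; `shortest_per_start` gives compact
reports. Ambiguity codes in sequences (X, B, Z, J, U, O) match only
wildcards — the conservative reading that minimises false positives;
`*` truncates and `-` is dropped, each with a logged warning.

Relaxation follows the two documented moves: `expand_class` enlarges an
anchor's residue set (a fixed residue is promoted to a class) and
`widen_gap` loosens a wildcard's range; narrowing through `widen_gap`
is rejected so that the superset-of-matches property holds by
construction, and both moves are property-tested for never losing a
span.

## Consensus construction

A column of the input alignment becomes an anchor when its dominant
residue *or* dominant physicochemical group reaches the conservation
threshold among non-gap rows **and** its gap fraction is at most
`max_gap_fraction`. Defaults are 0.9 and 0.2: the threshold is an
implementation choice (the protocol literature says only "highly
conserved"), set high to reproduce the keep-only-key-residues
minimalism of the curated motifs; both are CLI flags. The default
groups are basic {K,R}, acidic {D,E}, aliphatic {I,L,V,M}, aromatic
{F,Y,W}, hydroxyl {S,T}, with every other residue a singleton. Ties at
the threshold are kept (inclusive ≥) for determinism.

An anchor element contains the residues actually observed in its
column; completing classes with unobserved group members (K observed →
`[KR]`) is opt-in (`complete_groups`), matching the recommendation
character of that practice rather than making it default. Note that
completion applies to every anchor, so a fixed aromatic anchor Y
widens to `[FWY]` when enabled. Each maximal run of non-anchor columns
becomes one wildcard whose bounds are the minimum and maximum count of
non-gap residues any row spans in the run — so a run that some row
crosses without residues renders as `x(0,M)`. Leading and trailing
non-anchor runs are trimmed. `force_positions` pins chosen columns as
anchors regardless of conservation; it exists because an anchor class
whose members straddle groups (e.g. `[KS]`) cannot reach a group
conservation threshold by definition.

Two properties are enforced by tests: every training row (gaps removed)
matches the built motif over its full length, for any threshold, and
raising the threshold never adds anchors.

## Scanning, the cation-binding flag, exports

Scanning streams one sequence at a time over all motifs; hits are
ordered by proteome position, start, end, motif and never deduplicated
across motifs (a 14-mer matching both GC and AC patterns is two hits —
the classes carry distinct biology). GC/AC hits get the
*downstream-acidic* annotation: the smallest offset in a window
(default 1–3) past the hit end at which D or E occurs. The window
default follows the "1, 2 or 3 residues downstream" reading; an
offset-0 variant (acidic final window position inside the center's
tail) is selectable as `0:3` because the source descriptions vary
between 0–3 and 1–3. The flag is carried as a boolean bonus column and
deliberately not folded into the numeric score — no weighting is
documented anywhere.

TSV exports carry a commented header (tool version, motif registry
hash, options, coordinate convention) and round-trip coordinates
exactly; GFF3 rows use type `protein_match`. Candidate export writes
the top-N ranked hits padded by 20 residues (clipped at sequence
bounds) as FASTA — the hand-off point to homology modelling and
docking, which are out of scope here.

## Physicochemical ranking

Each hit fragment is reduced to molecular weight, isoelectric point and
mean Kyte–Doolittle hydropathy (GRAVY); net charge at pH 7 is computed
as an auxiliary, unscored descriptor. MW uses average free-amino-acid
masses minus one water per peptide bond; pI is the Brent root of the
Henderson–Hasselbalch net-charge curve on (0, 14) using the EMBOSS pKa
set. All three tables ship as versioned TSV data files and are
cross-checked in tests against Biopython's ProtParam (MW to 0.01 Da,
GRAVY to 1e-6, pI loosely at ±1.2 pH since the pKa sets differ).

Reference statistics (mean, sd per descriptor) come from a user-supplied
pool of validated-center fragments; no pool is shipped as ground truth
because real validated centers live behind database accessions, so the
simulator doubles as a fixture-reference generator. Standard deviations
are floored at `1e-6·|mean| + 1e-9` so single-member pools remain
usable. The score is `max(0, 1 − |x − μ|/(c·σ))` with spread `c = 3`:
the published screen describes only a 0–1 score that is "1 closest to
the mean" plus green/red colour bands, so the linear decay was chosen
for monotonicity, boundedness and the exact anchor of 1 at the mean;
green ≥ 0.6 and red < 0.3 are likewise documented implementation
choices, all configurable and echoed in output headers. A hit is
*selected* iff the overall mean score is green, at least two
descriptors are green and none is red — the selection rule verbatim.
Ranking sorts by (selected, overall, green count, seq_id, start);
no numeric equivalence with any external prediction server is claimed
or attempted.

## Synthetic data

The simulator emulates the *null and the signal* of a proteome scan,
not real protein architecture: background sequences are i.i.d. draws
from a uniform residue law (the simplest analytic null — a
single-residue pattern then has Binomial(n, 1/20) hits, which the suite
checks to 3σ) or an empirical frequency preset; planted instances are
sampled uniformly from a motif's language, verified against the motif
at generation time, and placed without overlap by rejection sampling
(cap 1000 tries, then error). `with_downstream_de` writes D/E at a
random offset 1–3 past each instance and scrubs the rest of the window
so the planted offset is the annotated one. Toy center alignments place
anchor residues so every class member and both gap extremes are
observed, and fill gap runs with residues drawn from pairwise-distinct
physicochemical groups per column so random filler cannot masquerade as
a conserved anchor; consequently consensus building regenerates the
specified pattern exactly, which the suite asserts for all five curated
motifs. What passing these tests does *not* show: performance on real
proteomes with domain structure, composition bias or low-complexity
regions — the uniform null understates false-positive rates there, and
no low-complexity filter is applied.

Default problem sizes — 100 × 300-aa proteomes with 7 planted instances
per motif, 500 oracle instances, 100 builder alignments — were chosen
as the smallest sets at which every property is exercised across all
five motifs; the full suite runs in a few seconds.

## Numerical and degenerate-input choices

Features are deterministic to 1e-6 (values rounded at that precision);
pI bisection tolerance is 1e-9. Empty sequences yield empty match
lists, never errors; empty motif lists, empty FASTA files, duplicate
IDs and ragged alignments are errors. `top_n = 0` writes an empty
candidate FASTA with a comment line. Motif length bounds (12, 50) are
advisory: violations warn ("too short; false-positive risk" / "too
long") but never block.

## Known limitations

* No fuzzy/mismatch-tolerant matching and no PROSITE profile (weight
  matrix) support — patterns are exact within their class/gap algebra.
* The ranking descriptors are the three documented ones; the screen the
  package emulates hints at more ("such as"), so the feature set is
  kept small rather than guessed at.
* GO-term sorting, structural assessment (modelling, docking) and any
  network queries are out of scope; the candidate FASTA is the
  interface to those tools.
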