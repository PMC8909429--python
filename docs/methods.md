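# Methods

## The funnel

Input is one read pool per selection cycle (cycle 0 = naive library), or an
already-tabulated counts spreadsheet (TSV: `sequence`, `count_cycle0`, ...).
Counting is exact-match on DNA: identical reads are collapsed, nothing else.
Reads containing `N` are excluded (and tallied); an optional `min_count`
prune drops sequences never reaching that count in any cycle. Cycle totals
are recorded **before** both removals, so counts-per-million always reflect
true sequencing depth; on an unpruned table each CPM column sums to 10⁶
exactly.

Step order is fixed: delta filter → FR1/stop/FR4 cascade → synonymous
collapse → TUP scan → ranking. Reordering changes every intermediate count,
so it is deliberately not configurable.

**Positive-delta filter.** A sequence passes if cpm rises by more than a
threshold (default 1 cpm) between at least one *consecutive* cycle pair, or
between one specified pair. The stringent preset replaces the additive test
with a fold-change requirement of ≥ 100× between consecutive cycles —
matching the empirical enrichment of a good binder, which spans two or more
orders of magnitude per cycle — with a pseudo-cpm floor of 1 in the
denominator so sequences absent from the earlier cycle stay finite.
Non-consecutive pairs are not searched in `any_pair` mode.

**ORF cascade.** Translation uses the standard genetic code in a *fixed*
frame (default 0) given by the library design; scanning for a best ORF
would mask exactly the frameshifts the filter exists to catch. Codons
containing `N` render `X`; trailing partial codons are dropped. The three
filters run in order (FR1 prefix → stop-free → FR4 suffix) and a sequence
is binned by the first filter it fails, so bins are disjoint and partition
the input. Consensus motifs are exact-match (defaults `MAEVQ`/`MAQVQ`,
`TVS`) and configurable per library; mismatch tolerance would re-admit
error-bearing reads. Because restriction-excised VH fragments can carry
primer/adapter remnants, the FR4 suffix is accepted anywhere within the
final 10 residues of the translation (the VH is truncated at the suffix for
downstream use); `X` counts as a mismatch in both consensus tests.

**Synonymous collapse.** Valid sequences are grouped by exact amino-acid
identity; per-cycle counts and cpm are summed and the multiplicity (number
of distinct DNA members) recorded. Count mass is conserved exactly; output
is ordered lexicographically by amino-acid sequence, so the operation is
idempotent and independent of input order. The delta filter runs *before*
collapse (funnel order); re-testing the delta on group-level cpm is
available as a switch but off by default.

**Ranking.** Descending cpm at the ranking cycle; ties break by higher
multiplicity (more independent DNA clones supporting the same protein —
more weight to the binding potential), then lexicographically for
determinism. The ranking cycle defaults to the detected breakpoint and can
be overridden.

**Breakpoint detection.** Per cycle we report Shannon entropy (base 2 —
bits; the base is internal and only consistency matters) of the clone
frequency distribution and the read share of the top k clones (default
k = 100). The breakpoint is the earliest cycle c ≥ 1 whose top-k share gain
over the previous cycle falls below `saturation_epsilon` (default 0.1, i.e.
a cycle adding fewer than ten percentage points of top-k share is considered
uninformative) and whose preceding entropy drop was the largest seen so far;
if no cycle saturates, the cycle with the maximal entropy drop is returned.
Both components are reported per cycle so users can override the choice.
Ties break toward the earlier cycle.

**TUP database.** A flat TSV archive (schema-versioned header comment) of
top-ranked groups from completed screens, storing VH, HCDR3, target,
screen id, best rank, max cpm, and a status. `best_rank` is the group's
best cpm rank over the *selection* cycles (cycle 1 onward), not just the
final ranking cycle: sticky clones typically peak early and are later
out-competed by strong binders, yet were genuinely enriched — and it is
precisely those clones that resurface elsewhere. A sequence observed
enriched against ≥ 2 distinct targets (configurable) is flagged a
*predicted* TUP. Scanning discards a candidate group iff its VH
(`vh_exact`, default) or HCDR3 (`hcdr3_exact`) matches any entry recorded
against a **different** target; entries from the current screen are
circular evidence and raise an error. Matching is membership, not
similarity; an opt-in fuzzy mode (edit distance ≤ 1 on HCDR3, via edlib)
tolerates residual sequencing errors. Rank and cpm are recorded but not
used as evidence weight.

**HCDR3 boundaries.** The loop is taken strictly between the last cysteine
preceded by a tyrosine within the three previous residues (the Y-x-C end of
FR3) and the tryptophan of the first subsequent `WG.G` motif (FR4 start);
absent if either anchor is missing or the loop is outside 2–40 residues.
This anchor heuristic is deliberately isolated in one function and can be
overridden with explicit coordinates; it is not a Kabat/IMGT numbering.

## The biopanning simulator

Each clone carries an affinity *a* (binders), a stickiness *s* (TUPs — the
advantage is target-independent), a growth advantage *g* (broken inserts:
the helper phage supplies pIII, so insert-dead phage can amplify faster),
and an initial frequency. One selection cycle is a two-phase update,

    panning:        f' ∝ f · (a·λ + s + 1)
    amplification:  f'' ∝ f' · g

with selection strength λ. Keeping panning and amplification separate is
what lets the simulator realise both false-positive routes the funnel must
distinguish: stickiness acts in the panning phase (selection-related),
growth advantage in the amplification phase (selection-unrelated). Reads
are drawn multinomially at the configured depth per cycle; each read then
acquires substitution errors at a per-base rate ε (default 0.001, the
typical short-read platform error rate). Indel sequencing errors are off by
default so frameshift class labels stay unambiguous. All randomness flows
from one seeded generator; identical seed + config reproduce FASTQ, truth
and report files byte for byte.

**Scaffold.** Clones are built on a fixed VH scaffold — FR1 starting
`MAEVQ`, a constant FR2/FR3 core ending on the conserved `...YYC`, a
randomised HCDR3 (8–16 residues; the alphabet excludes C and W so the
anchor heuristic recovers the planted loop unambiguously), and FR4
`WGQGTTVTVS` — reverse-translated with uniformly random synonymous codons.
Stop-codon clones carry one in-frame internal stop placed after the FR1
prefix (so the cascade attributes them to the stop filter); frameshift
clones carry a 1–2-base indel upstream of FR4, resampled in the rare case
the scrambled tail still spells the FR4 suffix, so corrupt classes fail the
cascade by construction.

**Default study conditions** (chosen once; all configurable):

| parameter | default | rationale |
|---|---|---|
| library size | 10⁴ clones | desk-scale stand-in for 10¹¹–10¹³ real diversity; preserves head/tail structure |
| reads per cycle | 10⁵ | ~10× clone coverage, minutes of runtime |
| selection cycles | 3 | typical campaign; breakpoint usually cycle 2–3 |
| class mix | 10 binders, 5 TUPs, 10% stop, 10% frameshift, rest neutral | broken inserts are a large minority of real libraries |
| initial abundances | Zipf(1) over non-planted clones; binders/TUPs at 1/n | heavy-tailed naive libraries; planted clones start at typical abundance |
| binder affinity | a ~ U[0.5, 1.5], λ = 10⁴ | a strong-selection regime: per-cycle binder enrichment of 2–4 orders of magnitude, so the sub-library saturates by cycle 2 — the regime in which retrospective breakpoint detection is meaningful |
| TUP stickiness | s ~ U[100, 500] | enriches clearly above background but below strong binders |
| growth advantage | g ~ U[1.5, 4] for broken inserts | propagation advantage without overwhelming selection |
| sequencing error | ε = 0.001 substitutions/base | short-read platform typical |

**What the simulator does and does not emulate.** It reproduces the
*statistical* structure the funnel assumes — heavy-tailed abundances,
affinity-proportional enrichment, sticky clones shared across screens,
growth-advantaged broken inserts, substitution noise. It does not model
phage infection kinetics, elution chemistry, PCR amplification bias,
chimera formation, indel sequencing errors (by default) or read
truncation — every simulated read covers the full VH. Passing tests
therefore demonstrate the pipeline's correctness and its behaviour under
the assumed enrichment model, not performance on any particular wet-lab
campaign; on real data the consensus motifs, frame and thresholds must be
set to the library design.

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

All experiments are seeded and re-derive their inputs at run time.

* **Normalization identity** — CPM columns of random unpruned tables sum to
  10⁶ within 10⁻⁶ relative.
* **Cascade by construction** — on a 3 000-clone library of 60% neutral /
  20% stop / 20% frameshift (2 cycles, 50 000 reads), clone-level validity
  classification of every observed planted clone is perfect without
  sequencing error and ≥ 0.99 at ε = 0.001. (Classification applies to each
  planted clone's canonical sequence; errors affect which clones are
  observed, not how a sequence classifies.)
* **Oracle agreement** — the delta filter and the synonym collapse agree
  with independent brute-force reimplementations (exhaustive pair scan;
  dictionary tally) on 1 000 random tables of ≤ 10 sequences × 4 cycles.
* **Conservation** — collapse preserves per-cycle integer totals exactly;
  the report's terminal bins partition the input sequences.
* **Binder recovery** — default conditions (10⁴ clones, 10 planted binders,
  3 cycles, 10⁵ reads/cycle, ε = 0.001): ≥ 9/10 binders in the final
  top-20.
* **TUP removal** — two sibling screens (5 000 clones, 50 000 reads/cycle)
  against different targets share 3 sticky clones; after archiving screen 1,
  the scan on screen 2 flags 3/3 sticky clones and no planted binder.
* **Breakpoint recovery** — 20 replicates with the selection-strength
  schedule (λ, λ, 0, 0) over 4 cycles, error-free counts: the detector
  returns cycle 2 in ≥ 18/20. Run at ε = 0 because the diagnostics depend
  on the count distribution, not on read identities.
* **Determinism** — a small screen plus full funnel run twice with the same
  seed produces byte-identical FASTQ, truth and report files.
* **Consensus literals** — `MAEVQ`/`MAQVQ` prefixes and the `TVS` suffix
  pass exactly as written; every single-character perturbation fails
  (exhaustive).

## Numerical and degenerate-input choices

* Fold changes floor the denominator at 1 cpm (`PSEUDO_CPM`), keeping
  trajectories from zero finite.
* Empty cycles have entropy 0 and top-k share 0; zero-total cycles are an
  error at normalization (cpm undefined).
* Fewer than 2 cycles is an error everywhere (delta and breakpoint are
  undefined).
* Tabulation order is descending total count, then lexicographic —
  deterministic under any read or file permutation.
* Paired-end merging takes the longest suffix/prefix overlap with mismatch
  fraction ≤ 0.1 (length ≥ 10 by default); disagreements resolve to the
  higher-quality base, or to the forward read without qualities;
  unmergeable pairs are dropped and counted.
* The expected-frequency update renormalises to 1 at each phase (tolerance
  10⁻¹² asserted in tests).

## Known limitations

* Exact-match counting means heavy sequencing error inflates singleton
  sequences; the `min_count` prune and the synonymous collapse absorb most
  of it (synonymous error copies fold back into their parent group), but
  non-synonymous error copies of an abundant clone appear as spurious
  low-rank candidate groups sharing the parent's HCDR3.
* The breakpoint statistic formalises a qualitative criterion; in screens
  that saturate gradually the share-gain test and the entropy-drop test can
  disagree, in which case the fallback (max entropy drop) applies and both
  diagnostics should be inspected per cycle.
* TUP scanning is membership-based: a sticky clone is only removable after
  it has been archived from at least one other target's screen.
* Full-length scFv reads are accepted as VH-scoped input but no
  circular-consensus processing, demultiplexing, quality trimming or UMI
  handling is performed.
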