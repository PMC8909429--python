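# phagefunnel

**NGS-guided funnel analysis of phage-display scFv antibody screens.**

Phage display selects antigen binders from scFv libraries by iterative
biopanning, and deep sequencing of every selection cycle turns that
selection into per-clone enrichment trajectories. But raw enrichment is a
poor proxy for binding: two classes of false positives enrich without
binding the target at all —

* **non-valid inserts** — clones whose VH coding sequence carries a
  premature stop codon or a frameshift indel; the helper phage supplies
  intact pIII during amplification, so a broken insert can be a *growth*
  advantage (selection-unrelated false positives);
* **target-unrelated clones (TUPs)** — clones that bind panning components
  (plastic, blocking proteins, Fc tags, streptavidin) rather than the
  target; because that behaviour is target-independent, the same clones
  resurface in screens against unrelated antigens (selection-related false
  positives).

`phagefunnel` implements the six-step "funnel" that removes both classes
and ranks what remains:

1. **Normalize** raw counts within each cycle to counts per million
   (cpm<sub>s,c</sub> = n<sub>s,c</sub> / N<sub>c</sub> × 10⁶) and keep only
   clones with a **positive delta** (Δ⁺ = cpm<sub>c+1</sub> −
   cpm<sub>c</sub> > 1 between some pair of cycles; a stringent preset
   instead requires a ≥ 100-fold increase, the enrichment magnitude typical
   of a good binder).
2. **Translate** each sequence in the known vector frame and discard clones
   not starting with the framework-1 consensus (`MAEVQ`/`MAQVQ`),
3. … clones bearing stop codons,
4. … clones whose VH does not end on the framework-4 consensus (`TVS`).
5. **Collapse synonymous clones** (identical amino-acid sequence, different
   DNA) — counts are summed and the number of contributing DNA clones
   (multiplicity) is kept as independent corroborating evidence.
6. **Scan a cross-screen TUP database**: candidates whose VH (or HCDR3)
   matches a clone enriched against a *different* target are discarded; each
   completed screen is archived back into the database.

Ranking is read off at the **breakpoint cycle** — the earliest cycle at
which the sub-library saturates (per-cycle Shannon entropy stops dropping
and the top-k clone share stops growing), after which relative-enrichment
information is lost. The package also ships a seeded **biopanning
simulator** (affinity-driven selection + growth-advantage amplification,
multinomial sequencing with substitution errors, full ground truth) used to
validate every step end to end.

## Worked example

Simulate a screen (2 000 clones, two planted binders, 3 selection cycles at
20 000 reads each), tabulate it, and run the funnel:

```bash
phagefunnel simulate --n-clones 2000 --depth 20000 --seed 5 --screen-id demo -o sim
phagefunnel tabulate sim/cycle0.fastq sim/cycle1.fastq sim/cycle2.fastq sim/cycle3.fastq -o counts.tsv
phagefunnel funnel --counts counts.tsv --screen-id demo --target CD27 -o run1
```

which prints:

```
screen: demo
breakpoint cycle: 2 (ranking at cycle 2)

funnel steps:
  delta_filter       in=13417    out=6135     removed=7282
  fr1_filter         in=6135     out=5824     removed=311
  stop_filter        in=5824     out=5131     removed=693
  fr4_filter         in=5131     out=4971     removed=160
  synonym_collapse   in=4971     out=3212     removed=1759
  tup_scan           in=3212     out=3212     removed=0

top-100 composition:
  candidate          n=89     fraction=0.890
  non_valid          n=11     fraction=0.110
  target_unrelated   n=0      fraction=0.000

final candidates: 3212
  #1   cpm=548400.0     mult=368 hcdr3=SASLMPHYAHINKE
  #2   cpm=203850.0     mult=298 hcdr3=PVIHSAFFKESTIAQ
  #3   cpm=1000.0       mult=27  hcdr3=GAYFFNETS
```

Reading this: of 13 417 unique sequences, 6 135 enrich (positive delta);
the ORF cascade removes 1 164 broken inserts; collapsing synonymous DNA
leaves 3 212 amino-acid groups, ranked by cpm at the detected breakpoint
(cycle 2). The two planted binders are the top two candidates — their high
multiplicity (hundreds of synonymous DNA variants, here mostly
sequencing-error copies) corroborates the ranking. No TUP database was
given, so nothing is flagged target-unrelated. Archive this screen and the
next screen benefits:

```bash
phagefunnel tupdb add --db tup.tsv --run-dir run1 --screen-id prior1 --target OTHER --top-n 50
phagefunnel funnel --counts counts.tsv --screen-id demo2 --target CD27b --tup-db tup.tsv -o run2
phagefunnel report run1 run2          # side-by-side composition table
```

The same pipeline is available as a library (`phagefunnel.run_funnel`,
`phagefunnel.build_library`, `phagefunnel.run_selection`, ...); see
`docs/methods.md` for the model and parameter choices.

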