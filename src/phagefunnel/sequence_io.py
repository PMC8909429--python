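"""Reading, writing and tabulating per-cycle sequencing data.

Biopanning screens are sequenced once per selection cycle (cycle 0 being the
unselected, naive library).  This module turns those per-cycle FASTQ/FASTA
files into a single counts table — unique DNA sequence x cycle — which is the
object the rest of the funnel operates on.  It also reads and writes the
tab-separated "standardized spreadsheet" form of that table, so screens
tabulated elsewhere can enter the pipeline directly.

Counting is exact-match: identical DNA sequences are collapsed, nothing else.
Sequencing-error handling is delegated to the optional ``min_count`` prune.
Cycle totals are recorded *before* any pruning so that depth normalisation
downstream reflects true sequencing depth.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "ReadSet",
    "CountsTable",
    "read_cycle_files",
    "merge_paired_ends",
    "tabulate",
    "read_counts_spreadsheet",
    "write_counts_spreadsheet",
    "reverse_complement",
]


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadSet:
    """Reads from one sequenced selection cycle.

    cycle_index 0 denotes the naive library; 1..n the selection cycles.
    ``qualities`` holds Sanger Phred+33 strings when the source was FASTQ.
    """

    cycle_index: int
    reads: list[str]
    qualities: list[str] | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.cycle_index < 0:
            raise ValueError(f"cycle_index must be >= 0, got {self.cycle_index}")
        if self.qualities is not None and len(self.qualities) != len(self.reads):
            raise ValueError("qualities and reads differ in length")
        for i, read in enumerate(self.reads):
            if not read:
                raise ValueError(f"empty read at index {i} in {self.source_path or 'ReadSet'}")
            if not DNA_ALPHABET.issuperset(read):
                bad = set(read) - DNA_ALPHABET
                raise ValueError(
                    f"read {i} in {self.source_path or 'ReadSet'} contains "
                    f"non-ACGTN characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class CountsTable:
    """Unique-sequence x cycle integer counts with depth bookkeeping.

    ``cycle_totals`` are raw per-cycle read totals *before* N-exclusion and
    min_count pruning; ``n_excluded`` and ``pruned_mass`` record the reads
    removed by each, so that per cycle::

        column_sum + n_excluded + pruned_mass == cycle_total

    whenever the table was produced by :func:`tabulate`.
    """

    sequences: list[str]
    counts: np.ndarray  # (n_sequences, n_cycles) int64
    cycle_totals: np.ndarray  # (n_cycles,) int64
    n_excluded: np.ndarray = field(default=None)  # type: ignore[assignment]
    pruned_mass: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix [sequence x cycle]")
        self.cycle_totals = np.asarray(self.cycle_totals, dtype=np.int64)
        if self.n_excluded is None:
            self.n_excluded = np.zeros(self.n_cycles, dtype=np.int64)
        if self.pruned_mass is None:
            self.pruned_mass = np.zeros(self.n_cycles, dtype=np.int64)
        self.n_excluded = np.asarray(self.n_excluded, dtype=np.int64)
        self.pruned_mass = np.asarray(self.pruned_mass, dtype=np.int64)
        if len(self.sequences) != self.counts.shape[0]:
            raise ValueError("sequences and counts rows differ in length")
        if self.counts.shape[1] != len(self.cycle_totals):
            raise ValueError("counts columns and cycle_totals differ in length")
        if self.n_cycles < 2:
            raise ValueError("at least 2 cycles are required for delta analysis")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.sequences)) != len(self.sequences):
            dupes = [s for s, c in Counter(self.sequences).items() if c > 1]
            raise ValueError(f"duplicate sequences in table: {dupes[0][:30]}...")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_totals)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            columns=[f"count_cycle{c}" for c in range(self.n_cycles)],
        )
        df.insert(0, "sequence", self.sequences)
        return df


def read_cycle_files(paths: Sequence[str | Path], format: str = "fastq") -> list[ReadSet]:
    """Parse one FASTQ/FASTA file per selection cycle, in the given order."""
    if format not in ("fastq", "fasta"):
        raise ValueError(f"format must be 'fastq' or 'fasta', got {format!r}")
    readsets = []
    for cycle, path in enumerate(paths):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"cycle {cycle} file not found: {path}")
        reads: list[str] = []
        quals: list[str] | None = [] if format == "fastq" else None
        records = SeqIO.parse(str(path), format)
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"malformed {format} record {index} in {path}: {exc}"
                ) from exc
            reads.append(str(rec.seq).upper())
            if quals is not None:
                quals.append(
                    "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                )
            index += 1
        if not reads:
            logger.warning("cycle %d file %s contains no reads", cycle, path)
        readsets.append(
            ReadSet(cycle_index=cycle, reads=reads, qualities=quals, source_path=str(path))
        )
    return readsets


def _resolve_overlap(
    s1: str, q1: str | None, s2: str, q2: str | None
) -> tuple[str, str | None]:
    """Resolve disagreements toward the higher-quality base (or read 1)."""
    if s1 == s2:
        return s1, q1
    out = []
    qout = []
    for i in range(len(s1)):
        if s1[i] == s2[i]:
            out.append(s1[i])
            qout.append(q1[i] if q1 else "I")
        elif q1 is not None and q2 is not None and q2[i] > q1[i]:
            out.append(s2[i])
            qout.append(q2[i])
        else:
            out.append(s1[i])
            qout.append(q1[i] if q1 else "I")
    return "".join(out), ("".join(qout) if q1 is not None else None)


def merge_paired_ends(
    r1: ReadSet,
    r2: ReadSet,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> tuple[ReadSet, int]:
    """Merge 2x read pairs by suffix/prefix overlap; returns (merged, n_dropped).

    The mate (``r2``) is reverse-complemented, then the longest suffix of r1
    matching a prefix of the mate with at most ``max_mismatch_frac`` mismatches
    and length >= ``min_overlap`` defines the merge.  Overlap disagreements are
    resolved toward the base with the higher Phred quality (toward r1 when no
    qualities are available).  Pairs with no acceptable overlap are dropped.
    """
    if len(r1) != len(r2):
        raise ValueError(
            f"paired files differ in read count: {len(r1)} vs {len(r2)}"
        )
    if r1.cycle_index != r2.cycle_index:
        raise ValueError("paired ReadSets must share cycle_index")
    merged: list[str] = []
    merged_q: list[str] | None = (
        [] if (r1.qualities is not None and r2.qualities is not None) else None
    )
    n_dropped = 0
    for i in range(len(r1)):
        fwd = r1.reads[i]
        q_fwd = r1.qualities[i] if r1.qualities else None
        rev = reverse_complement(r2.reads[i])
        q_rev = r2.qualities[i][::-1] if r2.qualities else None
        best = None
        for o in range(min(len(fwd), len(rev)), min_overlap - 1, -1):
            tail, head = fwd[-o:], rev[:o]
            mismatches = sum(a != b for a, b in zip(tail, head))
            if mismatches <= max_mismatch_frac * o:
                over, over_q = _resolve_overlap(
                    tail,
                    q_fwd[-o:] if q_fwd else None,
                    head,
                    q_rev[:o] if q_rev else None,
                )
                best = (
                    fwd[:-o] + over + rev[o:],
                    ((q_fwd[:-o] if q_fwd else "") + (over_q or "") + (q_rev[o:] if q_rev else ""))
                    if merged_q is not None
                    else None,
                )
                break  # longest acceptable overlap wins
        if best is None:
            n_dropped += 1
            continue
        merged.append(best[0])
        if merged_q is not None:
            merged_q.append(best[1])  # type: ignore[arg-type]
    return (
        ReadSet(
            cycle_index=r1.cycle_index,
            reads=merged,
            qualities=merged_q,
            source_path=r1.source_path,
        ),
        n_dropped,
    )


def tabulate(readsets: Sequence[ReadSet], min_count: int = 1) -> CountsTable:
    """Exact-match tally of unique sequences per cycle.

    Reads containing N are excluded from counting (and tallied); sequences
    whose maximum count over all cycles is below ``min_count`` are dropped,
    with their mass recorded in ``pruned_mass``.  Cycle totals are the raw
    read totals before either removal.
    """
    if len(readsets) < 2:
        raise ValueError("need at least 2 cycles for delta analysis")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counters: list[Counter[str]] = []
    totals = []
    excluded = []
    for rs in readsets:
        counter: Counter[str] = Counter()
        n_excl = 0
        for read in rs.reads:
            if "N" in read:
                n_excl += 1
            else:
                counter[read] += 1
        counters.append(counter)
        totals.append(len(rs.reads))
        excluded.append(n_excl)
    return counts_from_counters(
        counters,
        cycle_totals=totals,
        n_excluded=excluded,
        min_count=min_count,
    )


def counts_from_counters(
    counters: Sequence[Counter[str] | dict[str, int]],
    cycle_totals: Sequence[int],
    n_excluded: Sequence[int] | None = None,
    min_count: int = 1,
) -> CountsTable:
    """Assemble a CountsTable from per-cycle {sequence: count} tallies."""
    all_seqs: dict[str, None] = {}
    for counter in counters:
        for seq in counter:
            all_seqs.setdefault(seq)
    if not all_seqs:
        raise ValueError("no countable reads in any cycle (all excluded or empty)")
    n_cycles = len(counters)
    counts = np.zeros((len(all_seqs), n_cycles), dtype=np.int64)
    seq_list = list(all_seqs)
    index = {s: i for i, s in enumerate(seq_list)}
    for c, counter in enumerate(counters):
        for seq, n in counter.items():
            counts[index[seq], c] = n
    # deterministic order: descending total count, then lexicographic
    order = sorted(
        range(len(seq_list)), key=lambda i: (-int(counts[i].sum()), seq_list[i])
    )
    counts = counts[order]
    seq_list = [seq_list[i] for i in order]
    keep = counts.max(axis=1) >= min_count
    pruned = counts[~keep].sum(axis=0)
    counts = counts[keep]
    seq_list = [s for s, k in zip(seq_list, keep) if k]
    if not seq_list:
        raise ValueError(f"no sequence reaches min_count={min_count} in any cycle")
    return CountsTable(
        sequences=seq_list,
        counts=counts,
        cycle_totals=np.asarray(cycle_totals, dtype=np.int64),
        n_excluded=np.asarray(
            n_excluded if n_excluded is not None else np.zeros(n_cycles), dtype=np.int64
        ),
        pruned_mass=pruned,
    )


_META_KEYS = ("cycle_totals", "n_excluded", "pruned_mass")


def write_counts_spreadsheet(table: CountsTable, path: str | Path) -> None:
    """Write the counts table as a UTF-8 TSV (``sequence<TAB>count_cycle0...``).

    Depth bookkeeping is carried in leading ``#`` comment lines so a
    write-read round trip reproduces the table exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in _META_KEYS:
            values = getattr(table, key)
            fh.write(f"# {key}: " + "\t".join(str(int(v)) for v in values) + "\n")
        table.to_frame().to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_counts_spreadsheet(path: str | Path) -> CountsTable:
    path = Path(path)
    meta: dict[str, np.ndarray] = {}
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, rest = body.partition(":")
                key = key.strip()
                if key in _META_KEYS:
                    meta[key] = np.array(
                        [int(x) for x in rest.split()], dtype=np.int64
                    )
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"sequence": str})
    if df.columns[0] != "sequence" or not all(
        c.startswith("count_cycle") for c in df.columns[1:]
    ):
        raise ValueError(
            f"{path}: expected header 'sequence<TAB>count_cycle0...', got {list(df.columns)[:4]}"
        )
    if len(df.columns) < 3:
        raise ValueError(f"{path}: at least 2 cycle columns required")
    dupes = df["sequence"][df["sequence"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"{path}: duplicate sequence row: {dupes.iloc[0][:40]}")
    counts = df.iloc[:, 1:].to_numpy()
    if (counts < 0).any():
        raise ValueError(f"{path}: negative counts")
    totals = meta.get("cycle_totals", counts.sum(axis=0))
    return CountsTable(
        sequences=df["sequence"].tolist(),
        counts=counts,
        cycle_totals=totals,
        n_excluded=meta.get("n_excluded"),
        pruned_mass=meta.get("pruned_mass"),
    )
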