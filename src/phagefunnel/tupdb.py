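"""Cross-screen database of target-unrelated clones (TUPs).

Some clones enrich in biopanning by sticking to panning components —
plastic, blocking protein, Fc tags, streptavidin — rather than to the
target.  Because that behaviour is target-independent, the same clone
resurfaces in screens against unrelated targets, and a growing archive of
past screens identifies them: a candidate whose VH (or HCDR3) matches a
clone enriched against a *different* target is discarded as target-unrelated.

The database is a flat, diffable TSV.  Each completed screen appends its
top-ranked groups (``add_screen``); a sequence observed enriched against
enough distinct targets is flagged a predicted TUP.  Scanning uses exact
membership by default; an opt-in fuzzy mode (edit distance <= 1 on the
HCDR3, via edlib) tolerates residual sequencing errors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .synonyms import SynonymGroup

__all__ = [
    "HCDR3",
    "TupEntry",
    "TupDatabase",
    "extract_hcdr3",
    "scan",
]

SCHEMA_VERSION = 1
_COLUMNS = [
    "aa_vh",
    "hcdr3",
    "target",
    "screen_id",
    "best_rank",
    "max_cpm",
    "status",
    "date_added",
]
_STATUSES = ("observed", "predicted", "validated")
_FR4_START = re.compile(r"WG.G")


@dataclass(frozen=True)
class HCDR3:
    """Heavy-chain CDR3 with half-open residue coordinates into the VH."""

    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("HCDR3 coordinates inconsistent with sequence length")


def extract_hcdr3(aa_vh: str) -> HCDR3 | None:
    """Locate the HCDR3 between the conserved FR3 end and FR4 start.

    Anchors: the last cysteine preceded by a tyrosine within the three
    previous residues (the Y-x-C end of FR3), and the tryptophan of the
    first subsequent ``WG.G`` motif (FR4 start).  The HCDR3 is everything
    strictly between them; absent (None) if either anchor is missing or the
    loop is shorter than 2 or longer than 40 residues.

    This anchor heuristic is a pragmatic boundary definition, not a full
    Kabat/IMGT numbering; override with explicit coordinates where the
    library design provides them.
    """
    aa = aa_vh.upper()
    cys = None
    for i in range(len(aa) - 1, -1, -1):
        if aa[i] == "C" and "Y" in aa[max(0, i - 3) : i]:
            cys = i
            break
    if cys is None:
        return None
    m = _FR4_START.search(aa, cys + 1)
    if m is None:
        return None
    seq = aa_vh[cys + 1 : m.start()]
    if not 2 <= len(seq) <= 40:
        return None
    return HCDR3(sequence=seq, start=cys + 1, end=m.start())


@dataclass
class TupEntry:
    """One archived clone from a past screen.

    status: "observed" (archived, single screen so far), "predicted"
    (enriched against >= 2 distinct targets), or "validated" (confirmed
    target-unrelated experimentally).
    """

    aa_vh: str
    hcdr3: str
    target: str
    screen_id: str
    best_rank: int
    max_cpm: float
    status: str = "observed"
    date_added: str = ""

    def __post_init__(self) -> None:
        if not self.aa_vh and not self.hcdr3:
            raise ValueError("TupEntry needs at least one of aa_vh, hcdr3")
        if self.best_rank < 1:
            raise ValueError("best_rank must be >= 1")
        if self.status not in _STATUSES:
            raise ValueError(f"status must be one of {_STATUSES}, got {self.status!r}")


class TupDatabase:
    """Append-only archive of enriched clones across screens, stored as TSV."""

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=_COLUMNS)
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"TUP database missing columns: {sorted(missing)}")
        self.df = df[_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def load(cls, path: str | Path) -> "TupDatabase":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        skip = 0
        if first.startswith("#"):
            skip = 1
            m = re.search(r"schema_version=(\d+)", first)
            if m and int(m.group(1)) > SCHEMA_VERSION:
                raise ValueError(
                    f"{path}: schema_version {m.group(1)} newer than supported {SCHEMA_VERSION}"
                )
        df = pd.read_csv(
            path,
            sep="\t",
            skiprows=skip,
            dtype={c: str for c in _COLUMNS if c not in ("best_rank", "max_cpm")},
            keep_default_na=False,
        )
        if len(df):
            df["best_rank"] = df["best_rank"].astype(int)
            df["max_cpm"] = df["max_cpm"].astype(float)
        return cls(df)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# phagefunnel-tupdb schema_version={SCHEMA_VERSION}\n")
            self.df.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    def add_screen(
        self,
        groups: Sequence[SynonymGroup],
        screen_id: str,
        target: str,
        top_n: int = 100,
        min_screens_for_tup: int = 2,
        date: str = "",
    ) -> "TupDatabase":
        """Archive the groups ranked ``top_n`` or better in any enriched
        sub-library of a completed screen.

        A clone's ``best_rank`` is its best CPM rank over the selection
        cycles (cycle 1 onward): clones that peak early and are later
        out-competed were still enriched, and it is precisely those that
        resurface in other screens.  ``max_cpm`` is likewise the maximum
        over cycles.  Returns a new database (the store is append-only).
        Re-inserting a screen_id already present is an error.  After
        appending, every sequence observed enriched against >=
        ``min_screens_for_tup`` distinct targets is flagged
        status="predicted" (unless already "validated").
        """
        if screen_id in set(self.df["screen_id"]):
            raise ValueError(f"screen {screen_id!r} already present in TUP database")
        from .synonyms import rank_groups

        best_rank: dict[int, int] = {}
        n_cycles = len(groups[0].cpm) if groups else 0
        index = {id(g): i for i, g in enumerate(groups)}
        for cycle in range(1, n_cycles):
            for rank, g in enumerate(rank_groups(groups, cycle), start=1):
                i = index[id(g)]
                if rank < best_rank.get(i, 10**9):
                    best_rank[i] = rank
        rows = []
        for i, group in enumerate(groups):
            rank = best_rank.get(i, 10**9)
            if rank > top_n:
                continue
            cdr = extract_hcdr3(group.aa)
            rows.append(
                {
                    "aa_vh": group.aa,
                    "hcdr3": cdr.sequence if cdr else "",
                    "target": target,
                    "screen_id": screen_id,
                    "best_rank": rank,
                    "max_cpm": group.max_cpm(),
                    "status": "observed",
                    "date_added": date,
                }
            )
        rows_df = pd.DataFrame(rows, columns=_COLUMNS)
        rows_df = rows_df.sort_values(["best_rank", "aa_vh"]).reset_index(drop=True)
        new = rows_df if self.df.empty else pd.concat([self.df, rows_df], ignore_index=True)
        # flag sequences enriched against enough distinct targets
        targets_per_seq = new.groupby("aa_vh")["target"].nunique()
        tup_seqs = set(targets_per_seq[targets_per_seq >= min_screens_for_tup].index)
        is_tup = new["aa_vh"].isin(tup_seqs) & (new["status"] != "validated")
        new.loc[is_tup, "status"] = "predicted"
        return TupDatabase(new)


def scan(
    groups: Sequence[SynonymGroup],
    db: TupDatabase,
    screen_id: str,
    target: str,
    mode: str = "vh_exact",
    fuzzy_hcdr3_max_dist: int = 0,
) -> tuple[list[SynonymGroup], list[SynonymGroup], pd.DataFrame]:
    """Partition groups into (candidate, target_unrelated) against the archive.

    A group is target-unrelated iff its VH (mode="vh_exact") or its HCDR3
    (mode="hcdr3_exact") matches a database entry recorded against a
    *different* target.  Entries from the current screen_id are circular
    evidence and raise an error.  ``fuzzy_hcdr3_max_dist`` > 0 additionally
    matches HCDR3s within that edit distance (requires edlib; opt-in).

    Returns (candidates, target_unrelated, provenance) where provenance has
    one row per flagged group with the matching entry's screen and status.
    """
    if mode not in ("vh_exact", "hcdr3_exact"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if screen_id in set(db.df["screen_id"]):
        raise ValueError(
            f"TUP database contains entries from the current screen {screen_id!r}; "
            "scanning against them would be circular evidence"
        )
    other = db.df[db.df["target"] != target]
    if mode == "vh_exact":
        lookup = {
            seq: (row.screen_id, row.target, row.status)
            for seq, row in zip(other["aa_vh"], other.itertuples())
            if seq
        }
        keys = [g.aa for g in groups]
    else:
        lookup = {
            seq: (row.screen_id, row.target, row.status)
            for seq, row in zip(other["hcdr3"], other.itertuples())
            if seq
        }
        keys = []
        for g in groups:
            cdr = extract_hcdr3(g.aa)
            keys.append(cdr.sequence if cdr else None)

    fuzzy_keys = None
    if fuzzy_hcdr3_max_dist > 0:
        import edlib  # optional dependency, opt-in flag only

        db_cdrs = [s for s in other["hcdr3"].unique() if s]
        cdr_info = {
            s: next(
                (row.screen_id, row.target, row.status)
                for row in other.itertuples()
                if row.hcdr3 == s
            )
            for s in db_cdrs
        }

        def fuzzy_match(cdr: str):
            for s in db_cdrs:
                if (
                    edlib.align(cdr, s, mode="NW", k=fuzzy_hcdr3_max_dist)["editDistance"]
                    != -1
                ):
                    return cdr_info[s]
            return None

        fuzzy_keys = fuzzy_match

    candidates: list[SynonymGroup] = []
    flagged: list[SynonymGroup] = []
    prov_rows = []
    for g, key in zip(groups, keys):
        hit = lookup.get(key) if key else None
        if hit is None and fuzzy_keys is not None:
            cdr = extract_hcdr3(g.aa)
            if cdr:
                hit = fuzzy_keys(cdr.sequence)
        if hit is None:
            candidates.append(g)
        else:
            flagged.append(g)
            prov_rows.append(
                {
                    "aa": g.aa,
                    "matched_screen": hit[0],
                    "matched_target": hit[1],
                    "matched_status": hit[2],
                }
            )
    provenance = pd.DataFrame(
        prov_rows, columns=["aa", "matched_screen", "matched_target", "matched_status"]
    )
    return candidates, flagged, provenance
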