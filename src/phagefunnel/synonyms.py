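"""Synonymous-clone aggregation and candidate ranking.

Distinct DNA sequences that encode the same amino-acid VH ("synonymous
phages") are independent lines of evidence for the same binder: their counts
are pooled and the number of contributing DNA clones (multiplicity) is kept
as corroboration.  Ranking is by pooled CPM at the chosen cycle, with
multiplicity breaking ties in favour of groups supported by more independent
clones, then lexicographic amino-acid order for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SynonymGroup", "collapse", "rank_groups"]


@dataclass
class SynonymGroup:
    aa: str
    member_dnas: tuple[str, ...]
    counts: np.ndarray  # per-cycle summed integer counts
    cpm: np.ndarray  # per-cycle summed cpm

    @property
    def multiplicity(self) -> int:
        return len(self.member_dnas)

    def max_cpm(self) -> float:
        return float(self.cpm.max())


def collapse(
    dnas: Sequence[str],
    aas: Sequence[str],
    counts: np.ndarray,
    cpm: np.ndarray,
) -> list[SynonymGroup]:
    """Group rows by exact amino-acid identity, summing counts and cpm.

    Inputs are parallel: ``aas[i]`` is the translation of ``dnas[i]`` and
    row i of ``counts``/``cpm`` its per-cycle abundance.  Count mass is
    conserved exactly; output order is deterministic (lexicographic by aa)
    and independent of input order.
    """
    if not (len(dnas) == len(aas) == counts.shape[0] == cpm.shape[0]):
        raise ValueError("dnas, aas and count/cpm rows must be parallel")
    members: dict[str, list[int]] = {}
    for i, aa in enumerate(aas):
        members.setdefault(aa, []).append(i)
    groups = []
    for aa in sorted(members):
        idx = members[aa]
        # member order deterministic regardless of input permutation
        dna_sorted = tuple(sorted(dnas[i] for i in idx))
        groups.append(
            SynonymGroup(
                aa=aa,
                member_dnas=dna_sorted,
                counts=counts[idx].sum(axis=0),
                cpm=cpm[idx].sum(axis=0),
            )
        )
    return groups


def rank_groups(
    groups: Sequence[SynonymGroup],
    cycle: int,
    key: str = "cpm_then_multiplicity",
) -> list[SynonymGroup]:
    """Order groups by descending CPM at ``cycle``.

    key="cpm_then_multiplicity" (default) breaks CPM ties by higher
    multiplicity — more independent DNA clones, more weight to the binding
    potential — then lexicographically by aa; key="cpm" skips the
    multiplicity tie-break.
    """
    if groups and not 0 <= cycle < len(groups[0].cpm):
        raise ValueError(f"cycle {cycle} out of range")
    if key not in ("cpm", "cpm_then_multiplicity"):
        raise ValueError(f"unknown ranking key {key!r}")
    if key == "cpm":
        return sorted(groups, key=lambda g: (-g.cpm[cycle], g.aa))
    return sorted(groups, key=lambda g: (-g.cpm[cycle], -g.multiplicity, g.aa))
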