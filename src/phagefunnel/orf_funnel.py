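"""Open-reading-frame validity cascade for VH inserts.

Phage clones with broken inserts — premature stop codons, or frameshift
indels that scramble the reading frame — are carried through biopanning by
propagation advantage (the helper phage supplies intact pIII), so they enrich
without binding anything.  They are recognised here by translating each
sequence in the known vector frame and applying three filters in order:

1. the translation must start with a framework-1 consensus prefix
   (``MAEVQ`` or ``MAQVQ`` by default),
2. it must be free of stop codons,
3. the VH must end on the framework-4 consensus suffix (``TVS`` by default).

Each sequence lands in exactly one bin, named after the first filter it
fails.  The consensus motifs are configurable for libraries built on other
scaffolds (nanobodies, different framework sets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Data import CodonTable

__all__ = [
    "ConsensusConfig",
    "TranslatedClone",
    "CascadeResult",
    "translate",
    "filter_fr1",
    "filter_stop",
    "filter_fr4",
    "classify",
    "run_cascade",
    "CASCADE_BINS",
]

CASCADE_BINS = ("valid", "no_fr1", "has_stop", "no_fr4")

# standard genetic code (NCBI table 1); codons with non-ACGT characters -> 'X'
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"


@dataclass(frozen=True)
class ConsensusConfig:
    """Framework consensus motifs and reading frame for one library design.

    ``fr4_search_window``: the FR4 suffix may sit up to this many residues
    before the end of the translation, to tolerate primer/adapter remnants
    past the VH.
    """

    fr1_prefixes: tuple[str, ...] = ("MAEVQ", "MAQVQ")
    fr4_suffix: str = "TVS"
    frame_offset: int = 0
    fr4_search_window: int = 10

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")
        if not self.fr1_prefixes or not self.fr4_suffix:
            raise ValueError("FR1 prefixes and FR4 suffix must be non-empty")
        for motif in (*self.fr1_prefixes, self.fr4_suffix):
            if not motif or motif != motif.upper() or "*" in motif:
                raise ValueError(f"consensus motif must be uppercase and stop-free: {motif!r}")


@dataclass
class TranslatedClone:
    dna: str
    frame_offset: int
    aa: str
    fr1_ok: bool
    stop_free: bool
    fr4_ok: bool

    @property
    def valid_insert(self) -> bool:
        return self.fr1_ok and self.stop_free and self.fr4_ok

    @property
    def bin(self) -> str:
        """First failing filter, in cascade order."""
        if not self.fr1_ok:
            return "no_fr1"
        if not self.stop_free:
            return "has_stop"
        if not self.fr4_ok:
            return "no_fr4"
        return "valid"


def translate(dna: str, frame_offset: int = 0) -> str:
    """Translate in a fixed frame; '*' for stops, 'X' for codons containing N.

    The trailing partial codon is dropped; sequences shorter than one codon
    translate to the empty string.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    dna = dna.upper()
    end = frame_offset + 3 * ((len(dna) - frame_offset) // 3)
    get = _CODON_TO_AA.get
    return "".join(get(dna[i : i + 3], "X") for i in range(frame_offset, end, 3))


def filter_fr1(aa: str, cfg: ConsensusConfig = ConsensusConfig()) -> bool:
    up = aa.upper()
    return any(up.startswith(p) for p in cfg.fr1_prefixes)


def filter_stop(aa: str) -> bool:
    return "*" not in aa


def filter_fr4(aa: str, cfg: ConsensusConfig = ConsensusConfig()) -> bool:
    """True iff the FR4 suffix ends within the final ``fr4_search_window`` residues."""
    idx = aa.upper().rfind(cfg.fr4_suffix)
    if idx < 0:
        return False
    return len(aa) - (idx + len(cfg.fr4_suffix)) <= cfg.fr4_search_window


def vh_region(aa: str, cfg: ConsensusConfig = ConsensusConfig()) -> str:
    """Translation truncated at the end of the FR4 suffix (if found near the
    terminus), i.e. the VH proper without trailing linker/adapter residues."""
    idx = aa.upper().rfind(cfg.fr4_suffix)
    if idx >= 0 and len(aa) - (idx + len(cfg.fr4_suffix)) <= cfg.fr4_search_window:
        return aa[: idx + len(cfg.fr4_suffix)]
    return aa


def classify(dna: str, cfg: ConsensusConfig = ConsensusConfig()) -> TranslatedClone:
    aa = translate(dna, cfg.frame_offset)
    return TranslatedClone(
        dna=dna,
        frame_offset=cfg.frame_offset,
        aa=aa,
        fr1_ok=filter_fr1(aa, cfg),
        stop_free=filter_stop(aa),
        fr4_ok=filter_fr4(aa, cfg),
    )


@dataclass
class CascadeResult:
    clones: list[TranslatedClone]

    @property
    def bins(self) -> dict[str, list[TranslatedClone]]:
        out: dict[str, list[TranslatedClone]] = {b: [] for b in CASCADE_BINS}
        for clone in self.clones:
            out[clone.bin].append(clone)
        return out

    @property
    def bin_counts(self) -> dict[str, int]:
        out = {b: 0 for b in CASCADE_BINS}
        for clone in self.clones:
            out[clone.bin] += 1
        return out

    @property
    def labels(self) -> list[str]:
        return [c.bin for c in self.clones]


def run_cascade(
    dnas: Iterable[str], cfg: ConsensusConfig = ConsensusConfig()
) -> CascadeResult:
    """Apply the FR1 / stop / FR4 filters in order; first failure names the bin.

    Sequences and counts are never modified — the cascade only labels.
    """
    return CascadeResult(clones=[classify(dna, cfg) for dna in dnas])
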