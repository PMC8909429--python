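"""Seeded generative simulator of multi-cycle biopanning.

Emulates the statistical structure the funnel assumes, with ground truth:

* **binders** enrich in proportion to affinity under selection pressure;
* **TUPs** (sticky clones) enrich by binding panning components, so their
  advantage persists regardless of the target;
* **stop-codon / frameshift clones** carry broken inserts yet can enrich
  through a propagation (growth) advantage during amplification;
* **neutral** clones make up the naive background, Zipf-distributed.

Each selection cycle applies a two-phase frequency update — panning, then
amplification — separating the selection-related and selection-unrelated
enrichment routes the funnel must distinguish::

    panning:        f' ∝ f · (a·λ + s + 1)
    amplification:  f'' ∝ f' · g

with affinity ``a``, stickiness ``s``, growth advantage ``g`` and selection
strength ``λ``.  Reads are drawn multinomially at the requested depth, with
optional per-base substitution errors (default 1e-3, i.e. ~0.1%).  All
randomness flows from one numpy Generator, so a seed fixes every output
byte-for-byte.

Defaults are desk-scale: 10^4 clones and 10^5 reads per cycle keep an
end-to-end run in seconds while preserving the head/tail abundance
structure of far larger real libraries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import orf_funnel
from .orf_funnel import ConsensusConfig, classify
from .sequence_io import CountsTable, ReadSet, counts_from_counters
from .tupdb import extract_hcdr3

__all__ = [
    "SimClone",
    "ScreenTruth",
    "SimulatedScreen",
    "build_library",
    "build_tup_clones",
    "run_selection",
    "score_recovery",
    "DEFAULT_CLASS_MIX",
    "FR1_AA",
    "CORE_AA",
    "FR4_AA",
]

# VH scaffold: FR1 (starts with the MAEVQ consensus), a fixed FR2/FR3 core
# ending on the conserved ...YYC, a randomised HCDR3, and FR4 ending in TVS.
FR1_AA = "MAEVQLVESGGGLVQPGGSLRLSCAAS"
CORE_AA = "GFTFSSYAMSWVRQAPGKGLEWVSAISGSGGSTYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC"
FR4_AA = "WGQGTTVTVS"

# HCDR3 alphabet excludes C and W so the anchor heuristic (last Y-x-C, first
# WG.G) recovers the planted loop boundaries unambiguously.
_HCDR3_ALPHABET = "ADEFGHIKLMNPQRSTVY"
_HCDR3_LEN_RANGE = (8, 17)  # sampled uniformly in [8, 16]

CLASSES = ("binder", "neutral", "tup", "stop_codon", "frameshift")

#: library composition: 10 binders and 5 sticky clones per 10^4 clones, 20%
#: broken inserts, the rest neutral background
DEFAULT_CLASS_MIX: dict[str, float] = {
    "binder": 0.001,
    "tup": 0.0005,
    "stop_codon": 0.10,
    "frameshift": 0.10,
    "neutral": 0.7985,
}

#: selection strength: a planted binder's panning weight is a·λ with
#: a ~ U[0.5, 1.5], i.e. 3-4 orders of magnitude over the neutral baseline —
#: the strong-selection regime in which sub-libraries saturate by the second
#: or third cycle
DEFAULT_LAMBDA = 10_000.0
DEFAULT_ERROR_RATE = 0.001
DEFAULT_DEPTH = 100_000

_BASES = "ACGT"
_STOP_CODONS = ("TAA", "TAG", "TGA")

# codon choices per amino acid, alphabetical, for reverse translation
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(orf_funnel._CODON_TO_AA.items()):
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class SimClone:
    dna: str
    aa: str
    hcdr3: str
    clazz: str
    affinity: float = 0.0
    stickiness: float = 0.0
    growth_advantage: float = 1.0
    initial_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.clazz not in CLASSES:
            raise ValueError(f"unknown clone class {self.clazz!r}")


@dataclass
class ScreenTruth:
    """Ground truth emitted alongside the reads: per-clone labels and
    parameters, expected per-cycle frequencies, and the origin clone of every
    observed sequence (error variants map back to the clone they came from)."""

    clones: pd.DataFrame
    expected_freqs: np.ndarray  # (n_clones, n_cycles+1)
    origin: dict[str, int]  # observed sequence -> clone index
    screen_id: str
    params: dict

    def write(self, path: str | Path) -> None:
        df = self.clones.copy()
        for c in range(self.expected_freqs.shape[1]):
            df[f"expected_freq_cycle{c}"] = self.expected_freqs[:, c]
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# screen_id: {self.screen_id}\n")
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


@dataclass
class SimulatedScreen:
    truth: ScreenTruth
    counters: list[Counter]  # per cycle: observed sequence -> read count
    clone_counts: np.ndarray  # (n_clones, n_cycles+1) reads drawn per clone
    depth: int

    @property
    def screen_id(self) -> str:
        return self.truth.screen_id

    @property
    def n_cycles(self) -> int:
        return len(self.counters) - 1

    def counts_table(self, min_count: int = 1) -> CountsTable:
        return counts_from_counters(
            self.counters,
            cycle_totals=[sum(c.values()) for c in self.counters],
            min_count=min_count,
        )

    def readsets(self) -> list[ReadSet]:
        out = []
        for cycle, counter in enumerate(self.counters):
            reads: list[str] = []
            for seq, n in counter.items():
                reads.extend([seq] * n)
            out.append(ReadSet(cycle_index=cycle, reads=reads))
        return out

    def write_fastq(self, outdir: str | Path, prefix: str = "cycle") -> list[Path]:
        """One FASTQ per cycle (constant quality 'I' = Q40); deterministic."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for cycle, counter in enumerate(self.counters):
            path = outdir / f"{prefix}{cycle}.fastq"
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                i = 0
                for seq, n in counter.items():
                    qual = "I" * len(seq)
                    for _ in range(n):
                        fh.write(f"@{self.screen_id}_c{cycle}_r{i}\n{seq}\n+\n{qual}\n")
                        i += 1
            paths.append(path)
        return paths


def _reverse_translate(aa: str, rng: np.random.Generator) -> str:
    parts = []
    for residue in aa:
        codons = _AA_TO_CODONS[residue]
        parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)


def _random_hcdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(*_HCDR3_LEN_RANGE))
    idx = rng.integers(len(_HCDR3_ALPHABET), size=length)
    return "".join(_HCDR3_ALPHABET[i] for i in idx)


def build_tup_clones(n: int, rng: np.random.Generator) -> list[SimClone]:
    """Sticky clones, reusable across sibling screens (shared provenance)."""
    out = []
    for _ in range(n):
        hcdr3 = _random_hcdr3(rng)
        aa = FR1_AA + CORE_AA + hcdr3 + FR4_AA
        out.append(
            SimClone(
                dna=_reverse_translate(aa, rng),
                aa=aa,
                hcdr3=hcdr3,
                clazz="tup",
                stickiness=float(rng.uniform(100.0, 500.0)),
            )
        )
    return out


def build_library(
    n_clones: int = 10_000,
    class_mix: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    zipf_exponent: float = 1.0,
    tup_clones: Sequence[SimClone] | None = None,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> list[SimClone]:
    """Build a naive library of simulated clones on the VH scaffold.

    Class counts follow ``class_mix`` (fractions summing to 1).  Planted
    binders and TUPs start at frequency 1/n_clones (typical library
    abundance); all other clones share the remaining mass under a Zipf
    distribution with the given exponent, rank-shuffled.  Stop-codon clones
    carry one in-frame internal stop; frameshift clones a 1- or 2-base indel
    upstream of FR4.  Corrupt clones are verified to fail the ORF cascade.
    Pass ``tup_clones`` to share sticky clones between sibling screens.
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    unknown = set(mix) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix fractions must sum to 1, got {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_per = {c: int(round(mix.get(c, 0.0) * n_clones)) for c in CLASSES}
    if tup_clones is not None:
        n_per["tup"] = len(tup_clones)
    n_per["neutral"] = n_clones - sum(n for c, n in n_per.items() if c != "neutral")
    if n_per["neutral"] < 0:
        raise ValueError("class_mix leaves no room for neutral clones")

    clones: list[SimClone] = []
    for _ in range(n_per["binder"]):
        hcdr3 = _random_hcdr3(rng)
        aa = FR1_AA + CORE_AA + hcdr3 + FR4_AA
        clones.append(
            SimClone(
                dna=_reverse_translate(aa, rng),
                aa=aa,
                hcdr3=hcdr3,
                clazz="binder",
                affinity=float(rng.uniform(0.5, 1.5)),
            )
        )
    if tup_clones is not None:
        clones.extend(tup_clones)
    else:
        clones.extend(build_tup_clones(n_per["tup"], rng))

    scaffold_len = len(FR1_AA + CORE_AA) + _HCDR3_LEN_RANGE[0] + len(FR4_AA)
    for clazz in ("stop_codon", "frameshift", "neutral"):
        for _ in range(n_per[clazz]):
            hcdr3 = _random_hcdr3(rng)
            aa = FR1_AA + CORE_AA + hcdr3 + FR4_AA
            base_dna = _reverse_translate(aa, rng)
            dna = base_dna
            if clazz == "stop_codon":
                # one in-frame stop at a random internal codon, past the FR1
                # prefix so the clone is binned by the stop filter
                pos = int(rng.integers(len(cfg.fr1_prefixes[0]) + 1, len(aa) - len(FR4_AA)))
                stop = _STOP_CODONS[rng.integers(3)]
                dna = base_dna[: 3 * pos] + stop + base_dna[3 * pos + 3 :]
                aa = aa[:pos] + "*" + aa[pos + 1 :]
            elif clazz == "frameshift":
                # 1- or 2-base indel upstream of FR4, past the FR1 prefix.
                # A frameshifted tail can, very rarely, still spell the FR4
                # suffix; resample the indel until the clone fails the
                # cascade, as its class promises.
                fr4_start = 3 * (len(aa) - len(FR4_AA))
                for _ in range(100):
                    pos = int(rng.integers(3 * len(cfg.fr1_prefixes[0]), fr4_start))
                    width = int(rng.integers(1, 3))
                    if rng.random() < 0.5:
                        ins = "".join(_BASES[i] for i in rng.integers(4, size=width))
                        dna = base_dna[:pos] + ins + base_dna[pos:]
                    else:
                        dna = base_dna[:pos] + base_dna[pos + width :]
                    if not classify(dna, cfg).valid_insert:
                        break
                aa = orf_funnel.translate(dna, cfg.frame_offset)
            if clazz != "neutral" and classify(dna, cfg).valid_insert:
                raise AssertionError("corrupt clone unexpectedly passes the cascade")
            growth = float(rng.uniform(1.5, 4.0)) if clazz != "neutral" else 1.0
            clones.append(
                SimClone(
                    dna=dna,
                    aa=aa,
                    hcdr3=hcdr3,
                    clazz=clazz,
                    growth_advantage=growth,
                )
            )

    # initial abundances: planted binders/TUPs at 1/n, Zipf for the rest
    planted = [c for c in clones if c.clazz in ("binder", "tup")]
    rest = [c for c in clones if c.clazz not in ("binder", "tup")]
    for c in planted:
        c.initial_freq = 1.0 / n_clones
    if rest:
        ranks = np.arange(1, len(rest) + 1, dtype=float)
        weights = ranks ** (-zipf_exponent)
        weights /= weights.sum()
        weights = weights[rng.permutation(len(rest))]
        remaining = 1.0 - len(planted) / n_clones
        for c, w in zip(rest, weights):
            c.initial_freq = remaining * float(w)
    return clones


def _selection_weights(clones: Sequence[SimClone], lam: float) -> np.ndarray:
    a = np.array([c.affinity for c in clones])
    s = np.array([c.stickiness for c in clones])
    return a * lam + s + 1.0


def _mutate_read(seq: str, n_errors: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=n_errors, replace=False)
    chars = list(seq)
    for p in positions:
        current = chars[p]
        alternatives = [b for b in _BASES if b != current]
        chars[p] = alternatives[rng.integers(3)]
    return "".join(chars)


def run_selection(
    library: Sequence[SimClone],
    n_cycles: int = 3,
    depth: int = DEFAULT_DEPTH,
    lam: float = DEFAULT_LAMBDA,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int | np.random.Generator = 0,
    lambda_schedule: Sequence[float] | None = None,
    screen_id: str = "sim",
) -> SimulatedScreen:
    """Simulate ``n_cycles`` rounds of panning + amplification and sequencing.

    Emits cycle 0 (the naive library) plus one read pool per selection cycle,
    each of ``depth`` reads drawn multinomially from the expected clone
    frequencies, with per-base substitution errors at ``error_rate``.
    ``lambda_schedule`` overrides the selection strength per cycle (e.g. to
    halt selection partway); its length must be ``n_cycles``.
    """
    if n_cycles < 2:
        raise ValueError("need at least 2 selection cycles")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if lambda_schedule is not None and len(lambda_schedule) != n_cycles:
        raise ValueError("lambda_schedule length must equal n_cycles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lams = list(lambda_schedule) if lambda_schedule is not None else [lam] * n_cycles

    f = np.array([c.initial_freq for c in library], dtype=float)
    if not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("library initial frequencies must sum to 1")
    growth = np.array([c.growth_advantage for c in library])

    freqs = np.empty((len(library), n_cycles + 1))
    freqs[:, 0] = f
    for c, lam_c in enumerate(lams, start=1):
        w = _selection_weights(library, lam_c)
        f = f * w
        f = f / f.sum()  # panning
        f = f * growth
        f = f / f.sum()  # amplification
        freqs[:, c] = f

    counters: list[Counter] = []
    clone_counts = np.empty((len(library), n_cycles + 1), dtype=np.int64)
    origin: dict[str, int] = {}
    for c in range(n_cycles + 1):
        drawn = rng.multinomial(depth, freqs[:, c])
        clone_counts[:, c] = drawn
        counter: Counter = Counter()
        for i in np.flatnonzero(drawn):
            seq = library[i].dna
            m = int(drawn[i])
            origin.setdefault(seq, i)
            if error_rate > 0:
                n_err = rng.binomial(len(seq), error_rate, size=m)
                clean = int((n_err == 0).sum())
                if clean:
                    counter[seq] += clean
                for k in n_err[n_err > 0]:
                    mutated = _mutate_read(seq, int(k), rng)
                    origin.setdefault(mutated, i)
                    counter[mutated] += 1
            else:
                counter[seq] += m
        counters.append(counter)

    clones_df = pd.DataFrame(
        {
            "clone_id": np.arange(len(library)),
            "dna": [c.dna for c in library],
            "aa": [c.aa for c in library],
            "hcdr3": [c.hcdr3 for c in library],
            "clazz": [c.clazz for c in library],
            "affinity": [c.affinity for c in library],
            "stickiness": [c.stickiness for c in library],
            "growth_advantage": [c.growth_advantage for c in library],
            "initial_freq": [c.initial_freq for c in library],
        }
    )
    truth = ScreenTruth(
        clones=clones_df,
        expected_freqs=freqs,
        origin=origin,
        screen_id=screen_id,
        params={
            "n_cycles": n_cycles,
            "depth": depth,
            "lambda_schedule": lams,
            "error_rate": error_rate,
        },
    )
    return SimulatedScreen(
        truth=truth, counters=counters, clone_counts=clone_counts, depth=depth
    )


def cascade_confusion(
    screen: SimulatedScreen, cfg: ConsensusConfig = ConsensusConfig()
) -> dict[str, float]:
    """Clone-level validity confusion of the ORF cascade on a simulated screen.

    For every planted clone observed in the reads (>= 1 read in any cycle),
    the canonical sequence is classified by the cascade and compared with the
    planted validity (binder/neutral/tup = valid insert; stop_codon /
    frameshift = non-valid).  Sequencing errors never alter the canonical
    sequence, so this measures the filters' construction, not read noise.
    """
    observed = np.flatnonzero(screen.clone_counts.sum(axis=1) > 0)
    truth_valid = screen.truth.clones["clazz"].isin(("binder", "neutral", "tup")).to_numpy()
    tp = fp = tn = fn = 0
    for i in observed:
        predicted_valid = classify(screen.truth.clones["dna"].iloc[i], cfg).valid_insert
        if truth_valid[i]:
            if predicted_valid:
                tn += 1  # valid kept
            else:
                fp += 1  # valid wrongly discarded
        else:
            if predicted_valid:
                fn += 1  # corrupt missed
            else:
                tp += 1  # corrupt caught
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return {
        "sensitivity": sens,
        "specificity": specificity,
        "n_corrupt_observed": tp + fn,
        "n_valid_observed": tn + fp,
    }


def score_recovery(report, screen: SimulatedScreen, top_k: int = 20) -> dict:
    """Score a funnel report against the simulator's ground truth.

    binder_recovery: fraction of planted binders whose amino-acid group
    appears among the top ``top_k`` final candidates.  Also reports how many
    planted TUPs were flagged target-unrelated, and the clone-level cascade
    confusion.  The report must come from the same screen (ids must match).
    """
    if report.screen_id != screen.screen_id:
        raise ValueError(
            f"report screen id {report.screen_id!r} does not match "
            f"simulation {screen.screen_id!r}"
        )
    clones = screen.truth.clones
    binder_aas = set(clones.loc[clones["clazz"] == "binder", "aa"])
    tup_aas = set(clones.loc[clones["clazz"] == "tup", "aa"])
    top = report.candidates.head(top_k)
    top_aas = set(top["aa"])
    flagged_aas = set(report.tup_flagged["aa"]) if len(report.tup_flagged) else set()
    ranks = {
        aa: int(rank)
        for aa, rank in zip(report.candidates["aa"], report.candidates["rank"])
        if aa in binder_aas
    }
    return {
        "n_binders_planted": len(binder_aas),
        "n_binders_in_top_k": len(binder_aas & top_aas),
        "binder_recovery": len(binder_aas & top_aas) / len(binder_aas) if binder_aas else float("nan"),
        "binder_ranks": ranks,
        "n_tups_planted": len(tup_aas),
        "n_tups_flagged": len(tup_aas & flagged_aas),
        "n_binders_flagged_tup": len(binder_aas & flagged_aas),
        "cascade": cascade_confusion(screen),
    }
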