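"""End-to-end funnel orchestration and reporting.

Runs the six steps in their fixed order — tabulate, CPM + positive-delta
filter, ORF cascade (FR1 / stop / FR4), synonymous collapse, TUP-database
scan, ranking at the breakpoint cycle — and assembles a report: per-step
retained/discarded accounting, per-cycle diversity diagnostics, the ranked
candidate list, and a composition summary of the top-k clones (potential
binders vs broken inserts vs target-unrelated) suitable for comparing
screens side by side.

The step order is not configurable: reordering changes every intermediate
count and would make reports incomparable between runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import (
    cycle_entropy,
    delta_filter,
    diagnostics_frame,
    find_breakpoint,
    normalize_cpm,
)
from .orf_funnel import CASCADE_BINS, ConsensusConfig, run_cascade
from .sequence_io import (
    CountsTable,
    read_counts_spreadsheet,
    read_cycle_files,
    tabulate,
    write_counts_spreadsheet,
)
from .synonyms import SynonymGroup, collapse, rank_groups
from .tupdb import TupDatabase, extract_hcdr3, scan

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "FunnelReport", "run_funnel", "composition_chart"]

COMPOSITION_CATEGORIES = ("candidate", "non_valid", "target_unrelated")


@dataclass
class RunConfig:
    """Everything a funnel run depends on; validated before any compute and
    serialized alongside the outputs for provenance."""

    input_paths: list[str] = field(default_factory=list)
    input_format: str = "fastq"
    counts_path: str | None = None
    screen_id: str = "screen"
    target: str = ""
    frame_offset: int = 0
    fr1_prefixes: list[str] = field(default_factory=lambda: ["MAEVQ", "MAQVQ"])
    fr4_suffix: str = "TVS"
    delta_mode: str = "any_pair"
    delta_pair: list[int] | None = None
    delta_threshold: float = 1.0
    stringent: bool = False
    min_count: int = 1
    top_k: int = 100
    ranking_cycle: int | None = None
    saturation_epsilon: float = 0.1
    tup_db_path: str | None = None
    tup_scan_mode: str = "vh_exact"
    seed: int | None = None  # used by the simulator only
    output_dir: str | None = None

    def validate(self) -> None:
        if not self.fr4_suffix or not self.fr1_prefixes:
            raise ValueError("config missing FR1 prefixes or FR4 suffix")
        # delegate motif/frame validation
        self.consensus()
        if self.delta_mode not in ("any_pair", "specified_pair"):
            raise ValueError(f"unknown delta_mode {self.delta_mode!r}")
        if self.delta_mode == "specified_pair" and (
            self.delta_pair is None or len(self.delta_pair) != 2
        ):
            raise ValueError("delta_mode=specified_pair requires delta_pair=[i, j]")
        if self.delta_threshold < 0:
            raise ValueError("delta_threshold must be >= 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.tup_scan_mode not in ("vh_exact", "hcdr3_exact"):
            raise ValueError(f"unknown tup_scan_mode {self.tup_scan_mode!r}")
        if not self.input_paths and self.counts_path is None:
            raise ValueError("config needs input_paths or counts_path")

    def consensus(self) -> ConsensusConfig:
        return ConsensusConfig(
            fr1_prefixes=tuple(self.fr1_prefixes),
            fr4_suffix=self.fr4_suffix,
            frame_offset=self.frame_offset,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class FunnelReport:
    """Complete output of one funnel run."""

    screen_id: str
    steps: pd.DataFrame  # step, n_in, n_out, n_removed
    diagnostics: pd.DataFrame
    breakpoint_cycle: int
    ranking_cycle: int
    candidates: pd.DataFrame  # ranked final candidate groups
    tup_flagged: pd.DataFrame
    composition: pd.DataFrame  # category, n, fraction over top-k
    sequence_bins: pd.DataFrame  # terminal bin of every input sequence
    groups: list[SynonymGroup] = field(default_factory=list, repr=False)
    config: RunConfig | None = None

    def summary(self) -> str:
        lines = [
            f"screen: {self.screen_id}",
            f"breakpoint cycle: {self.breakpoint_cycle} (ranking at cycle {self.ranking_cycle})",
            "",
            "funnel steps:",
        ]
        for row in self.steps.itertuples(index=False):
            lines.append(
                f"  {row.step:<18} in={row.n_in:<8} out={row.n_out:<8} removed={row.n_removed}"
            )
        lines.append("")
        lines.append(f"top-{int(self.composition['k'].iloc[0])} composition:")
        for row in self.composition.itertuples(index=False):
            lines.append(f"  {row.category:<18} n={row.n:<6} fraction={row.fraction:.3f}")
        lines.append("")
        lines.append(f"final candidates: {len(self.candidates)}")
        for row in self.candidates.head(10).itertuples(index=False):
            lines.append(
                f"  #{row.rank:<3} cpm={row.cpm_at_ranking_cycle:<12.1f} "
                f"mult={row.multiplicity:<3} hcdr3={row.hcdr3}"
            )
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kwargs = dict(sep="\t", index=False, lineterminator="\n")
        self.steps.to_csv(outdir / "funnel_steps.tsv", **kwargs)
        self.diagnostics.to_csv(outdir / "cycle_diagnostics.tsv", **kwargs)
        self.candidates.to_csv(outdir / "candidates.tsv", **kwargs)
        self.tup_flagged.to_csv(outdir / "target_unrelated.tsv", **kwargs)
        self.composition.to_csv(outdir / "composition.tsv", **kwargs)
        self.sequence_bins.to_csv(outdir / "sequence_bins.tsv", **kwargs)
        with open(outdir / "summary.txt", "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.summary() + "\n")
        if self.config is not None:
            self.config.to_yaml(outdir / "config.yaml")


def _groups_frame(
    groups: Sequence[SynonymGroup], ranking_cycle: int, n_cycles: int
) -> pd.DataFrame:
    rows = []
    for rank, g in enumerate(groups, start=1):
        cdr = extract_hcdr3(g.aa)
        row = {
            "rank": rank,
            "aa": g.aa,
            "hcdr3": cdr.sequence if cdr else "",
            "multiplicity": g.multiplicity,
            "cpm_at_ranking_cycle": g.cpm[ranking_cycle],
            "member_dnas": ";".join(g.member_dnas),
        }
        for c in range(n_cycles):
            row[f"count_cycle{c}"] = int(g.counts[c])
        for c in range(n_cycles):
            row[f"cpm_cycle{c}"] = g.cpm[c]
        rows.append(row)
    columns = (
        ["rank", "aa", "hcdr3", "multiplicity", "cpm_at_ranking_cycle", "member_dnas"]
        + [f"count_cycle{c}" for c in range(n_cycles)]
        + [f"cpm_cycle{c}" for c in range(n_cycles)]
    )
    return pd.DataFrame(rows, columns=columns)


def run_funnel(
    cfg: RunConfig,
    counts_table: CountsTable | None = None,
    tup_db: TupDatabase | None = None,
) -> FunnelReport:
    """Execute the funnel end-to-end.

    Inputs come from ``counts_table`` if given, else from ``cfg.counts_path``
    (standardized spreadsheet) or ``cfg.input_paths`` (per-cycle FASTQ/FASTA).
    A TUP database is taken from ``tup_db`` or loaded from
    ``cfg.tup_db_path``; with neither, the scan step is an identity.
    The report is fully determined by inputs + config.
    """
    if counts_table is None:
        cfg.validate()
    else:
        # table provided programmatically; config may omit input paths
        ccfg = dataclasses.replace(cfg, counts_path="<in-memory>")
        ccfg.validate()
    ccfg = cfg.consensus()

    if counts_table is None:
        if cfg.counts_path is not None:
            counts_table = read_counts_spreadsheet(cfg.counts_path)
        else:
            readsets = read_cycle_files(cfg.input_paths, cfg.input_format)
            counts_table = tabulate(readsets, min_count=cfg.min_count)
    if tup_db is None and cfg.tup_db_path is not None:
        tup_db = TupDatabase.load(cfg.tup_db_path)

    n_cycles = counts_table.n_cycles
    sequences = counts_table.sequences
    n_seqs = len(sequences)
    logger.info("tabulate: %d unique sequences across %d cycles", n_seqs, n_cycles)

    # breakpoint diagnostics on the full, unfiltered table
    cp = cycle_entropy(counts_table, k=cfg.top_k)
    breakpoint_cycle = find_breakpoint(cp, cfg.saturation_epsilon)
    diagnostics = diagnostics_frame(counts_table, cp)
    ranking_cycle = cfg.ranking_cycle if cfg.ranking_cycle is not None else breakpoint_cycle
    if not 0 <= ranking_cycle < n_cycles:
        raise ValueError(f"ranking cycle {ranking_cycle} out of range")

    # step 1: CPM normalization + positive-delta filter
    profile = normalize_cpm(counts_table)
    passed = delta_filter(
        profile,
        mode=cfg.delta_mode,
        pair=tuple(cfg.delta_pair) if cfg.delta_pair else None,
        threshold=cfg.delta_threshold,
        stringent=cfg.stringent,
    )
    idx_passed = np.flatnonzero(passed)
    logger.info("delta filter: %d/%d sequences retained", len(idx_passed), n_seqs)

    bins = {sequences[i]: "delta_fail" for i in np.flatnonzero(~passed)}

    # steps 2-4: translate + FR1/stop/FR4 cascade
    cascade = run_cascade((sequences[i] for i in idx_passed), ccfg)
    valid_idx = []
    for local, (i, clone) in enumerate(zip(idx_passed, cascade.clones)):
        if clone.valid_insert:
            valid_idx.append((int(i), clone))
        else:
            bins[sequences[i]] = clone.bin
    logger.info("ORF cascade: %s", cascade.bin_counts)

    # step 5: synonymous collapse
    vdnas = [sequences[i] for i, _ in valid_idx]
    vaas = [c.aa for _, c in valid_idx]
    vrows = np.array([i for i, _ in valid_idx], dtype=int)
    if len(vrows):
        groups = collapse(vdnas, vaas, counts_table.counts[vrows], profile.cpm[vrows])
    else:
        groups = []
    logger.info("collapse: %d valid sequences -> %d groups", len(vrows), len(groups))

    # step 6: TUP-database scan
    if tup_db is not None and len(tup_db):
        candidates_g, flagged_g, provenance = scan(
            groups, tup_db, cfg.screen_id, cfg.target, mode=cfg.tup_scan_mode
        )
    else:
        candidates_g, flagged_g = list(groups), []
        provenance = pd.DataFrame(
            columns=["aa", "matched_screen", "matched_target", "matched_status"]
        )
    flagged_aas = {g.aa for g in flagged_g}
    for g in flagged_g:
        for dna in g.member_dnas:
            bins[dna] = "target_unrelated"
    for g in candidates_g:
        for dna in g.member_dnas:
            bins[dna] = "candidate"
    logger.info("TUP scan: %d flagged, %d candidates", len(flagged_g), len(candidates_g))

    # rank at the (breakpoint or overridden) ranking cycle
    ranked = rank_groups(candidates_g, ranking_cycle)
    candidates_df = _groups_frame(ranked, ranking_cycle, n_cycles)
    flagged_df = _groups_frame(
        rank_groups(flagged_g, ranking_cycle), ranking_cycle, n_cycles
    )
    if len(flagged_df):
        flagged_df = flagged_df.merge(provenance, on="aa", how="left")

    # step accounting (n_removed for collapse = synonymous merges)
    n_pass_delta = len(idx_passed)
    bc = cascade.bin_counts
    steps = pd.DataFrame(
        [
            ("delta_filter", n_seqs, n_pass_delta, n_seqs - n_pass_delta),
            ("fr1_filter", n_pass_delta, n_pass_delta - bc["no_fr1"], bc["no_fr1"]),
            ("stop_filter", n_pass_delta - bc["no_fr1"], n_pass_delta - bc["no_fr1"] - bc["has_stop"], bc["has_stop"]),
            ("fr4_filter", n_pass_delta - bc["no_fr1"] - bc["has_stop"], bc["valid"], bc["no_fr4"]),
            ("synonym_collapse", bc["valid"], len(groups), bc["valid"] - len(groups)),
            ("tup_scan", len(groups), len(candidates_g), len(flagged_g)),
        ],
        columns=["step", "n_in", "n_out", "n_removed"],
    )

    # composition of the top-k clones at the ranking cycle (Fig-4 style)
    order = np.argsort(-profile.cpm[:, ranking_cycle], kind="stable")[: cfg.top_k]
    comp_counts = dict.fromkeys(COMPOSITION_CATEGORIES, 0)
    top_cascade = run_cascade((sequences[i] for i in order), ccfg)
    for i, clone in zip(order, top_cascade.clones):
        if not clone.valid_insert:
            comp_counts["non_valid"] += 1
        elif clone.aa in flagged_aas:
            comp_counts["target_unrelated"] += 1
        else:
            comp_counts["candidate"] += 1
    k_eff = len(order)
    composition = pd.DataFrame(
        {
            "category": list(COMPOSITION_CATEGORIES),
            "n": [comp_counts[c] for c in COMPOSITION_CATEGORIES],
            "fraction": [comp_counts[c] / k_eff for c in COMPOSITION_CATEGORIES],
            "k": k_eff,
        }
    )

    sequence_bins = pd.DataFrame(
        {"sequence": sequences, "bin": [bins[s] for s in sequences]}
    )

    report = FunnelReport(
        screen_id=cfg.screen_id,
        steps=steps,
        diagnostics=diagnostics,
        breakpoint_cycle=breakpoint_cycle,
        ranking_cycle=ranking_cycle,
        candidates=candidates_df,
        tup_flagged=flagged_df,
        composition=composition,
        sequence_bins=sequence_bins,
        groups=list(groups),
        config=cfg,
    )
    if cfg.output_dir:
        report.write(cfg.output_dir)
        write_counts_spreadsheet(counts_table, Path(cfg.output_dir) / "counts.tsv")
    return report


def composition_chart(
    reports: Sequence[FunnelReport] | FunnelReport,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Stacked-fraction composition table across screens, one row per screen.

    With ``plot_path`` set, also renders a stacked bar chart (requires
    matplotlib).
    """
    if isinstance(reports, FunnelReport):
        reports = [reports]
    rows = []
    for rep in reports:
        row = {"screen": rep.screen_id}
        for r in rep.composition.itertuples(index=False):
            row[r.category] = r.fraction
        rows.append(row)
    df = pd.DataFrame(rows, columns=["screen", *COMPOSITION_CATEGORIES])
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ax = df.set_index("screen")[list(COMPOSITION_CATEGORIES)].plot(
            kind="bar", stacked=True, figsize=(1.5 + len(df), 4)
        )
        ax.set_ylabel("fraction of top-ranking clones")
        ax.figure.tight_layout()
        ax.figure.savefig(plot_path)
        plt.close(ax.figure)
    return df
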