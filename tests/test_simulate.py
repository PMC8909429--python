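import numpy as np
import pytest
from scipy import stats

from phagefunnel import (
    RunConfig,
    build_library,
    run_funnel,
    run_selection,
    score_recovery,
)
from phagefunnel.enrichment import cycle_entropy, delta_filter, normalize_cpm
from phagefunnel.orf_funnel import classify
from phagefunnel.simulate import DEFAULT_CLASS_MIX, build_tup_clones


class TestBuildLibrary:
    def test_all_neutral_mix_passes_cascade(self):
        mix = {"binder": 0.0, "neutral": 1.0, "tup": 0.0, "stop_codon": 0.0, "frameshift": 0.0}
        library = build_library(n_clones=100, class_mix=mix, seed=0)
        assert all(classify(c.dna).valid_insert for c in library)

    def test_stop_clones_translate_with_stop(self):
        library = build_library(n_clones=400, seed=1)
        stops = [c for c in library if c.clazz == "stop_codon"]
        assert stops
        for c in stops:
            assert "*" in classify(c.dna).aa

    def test_corrupt_clones_fail_cascade_by_construction(self):
        library = build_library(n_clones=400, seed=2)
        for c in library:
            valid = classify(c.dna).valid_insert
            assert valid == (c.clazz in ("binder", "neutral", "tup"))

    def test_same_seed_identical_library(self):
        lib1 = build_library(n_clones=200, seed=7)
        lib2 = build_library(n_clones=200, seed=7)
        assert [(c.dna, c.clazz, c.initial_freq) for c in lib1] == [
            (c.dna, c.clazz, c.initial_freq) for c in lib2
        ]

    def test_initial_freqs_sum_to_one(self):
        library = build_library(n_clones=500, seed=3)
        assert sum(c.initial_freq for c in library) == pytest.approx(1.0, abs=1e-9)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            build_library(n_clones=10, class_mix={"neutral": 0.5}, seed=0)

    def test_planted_binder_and_tup_parameters(self):
        library = build_library(n_clones=500, seed=4)
        for c in library:
            if c.clazz == "binder":
                assert c.affinity > 0 and c.stickiness == 0
            elif c.clazz == "tup":
                assert c.stickiness > 0 and c.affinity == 0


class TestRunSelection:
    def test_expected_freqs_conserve_mass(self, small_screen):
        sums = small_screen.truth.expected_freqs.sum(axis=0)
        assert sums == pytest.approx(np.ones(len(sums)), abs=1e-12)

    def test_single_binder_expected_freq_nondecreasing_under_selection(self):
        """A lone binder among neutrals (equal growth) always out-weighs the
        population mean, so its expected frequency never decreases."""
        mix = {"binder": 0.005, "neutral": 0.995, "tup": 0.0, "stop_codon": 0.0, "frameshift": 0.0}
        library = build_library(n_clones=200, class_mix=mix, seed=5)
        screen = run_selection(library, n_cycles=3, depth=1000, seed=6)
        (binder_row,) = [i for i, c in enumerate(library) if c.clazz == "binder"]
        freqs = screen.truth.expected_freqs[binder_row]
        assert (np.diff(freqs) >= -1e-15).all()

    def test_total_binder_mass_nondecreasing_under_selection(self):
        mix = {"binder": 0.01, "neutral": 0.99, "tup": 0.0, "stop_codon": 0.0, "frameshift": 0.0}
        library = build_library(n_clones=200, class_mix=mix, seed=5)
        screen = run_selection(library, n_cycles=3, depth=1000, seed=6)
        binder_rows = [i for i, c in enumerate(library) if c.clazz == "binder"]
        mass = screen.truth.expected_freqs[binder_rows].sum(axis=0)
        assert (np.diff(mass) >= -1e-15).all()

    def test_expected_entropy_nonincreasing_under_selection(self):
        library = build_library(n_clones=300, seed=8)
        screen = run_selection(library, n_cycles=3, depth=1000, seed=9)
        f = screen.truth.expected_freqs
        ent = [-(p[p > 0] * np.log2(p[p > 0])).sum() for p in f.T]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(ent, ent[1:]))

    def test_null_model_frequencies_stationary(self):
        """No selection, no stickiness, no growth advantage: observed cycle
        counts stay consistent with the initial frequencies."""
        mix = {"binder": 0.0, "neutral": 1.0, "tup": 0.0, "stop_codon": 0.0, "frameshift": 0.0}
        library = build_library(n_clones=20, class_mix=mix, seed=10)
        screen = run_selection(
            library, n_cycles=3, depth=50_000, lam=0.0, error_rate=0.0, seed=11
        )
        f0 = np.array([c.initial_freq for c in library])
        assert screen.truth.expected_freqs[:, -1] == pytest.approx(f0, abs=1e-12)
        last = screen.clone_counts[:, -1]
        _, p = stats.chisquare(last, f_exp=f0 * last.sum())
        assert p > 0.01

    def test_single_binder_trajectory_passes_delta_filter(self):
        mix = {"binder": 0.01, "neutral": 0.99, "tup": 0.0, "stop_codon": 0.0, "frameshift": 0.0}
        library = build_library(n_clones=100, class_mix=mix, seed=12)
        screen = run_selection(library, n_cycles=3, depth=20_000, error_rate=0.0, seed=13)
        table = screen.counts_table()
        passed = delta_filter(normalize_cpm(table))
        binder_dna = next(c.dna for c in library if c.clazz == "binder")
        assert passed[table.sequences.index(binder_dna)]

    def test_growth_advantaged_stop_clone_enriches_but_is_binned(self):
        """The propagation-advantage false positive: a stop-codon clone can
        out-grow the library yet is caught by the cascade."""
        mix = {"binder": 0.0, "neutral": 0.9, "tup": 0.0, "stop_codon": 0.1, "frameshift": 0.0}
        library = build_library(n_clones=100, class_mix=mix, seed=14)
        # no selection pressure: growth advantage is the only force
        screen = run_selection(library, n_cycles=3, depth=50_000, lam=0.0,
                               error_rate=0.0, seed=15)
        stop_rows = [i for i, c in enumerate(library) if c.clazz == "stop_codon"]
        f = screen.truth.expected_freqs
        assert f[stop_rows, -1].sum() > f[stop_rows, 0].sum()
        report = run_funnel(
            RunConfig(counts_path="<sim>", screen_id=screen.screen_id),
            counts_table=screen.counts_table(),
        )
        bins = dict(zip(report.sequence_bins["sequence"], report.sequence_bins["bin"]))
        enriching_stops = [
            library[i].dna for i in stop_rows if bins.get(library[i].dna) not in (None, "delta_fail")
        ]
        assert enriching_stops, "at least one stop clone passes the delta filter"
        assert all(bins[dna] == "has_stop" for dna in enriching_stops)

    def test_same_seed_byte_identical_fastq_and_truth(self, tmp_path):
        outs = []
        for name in ("a", "b"):
            library = build_library(n_clones=300, seed=20)
            screen = run_selection(library, depth=5_000, seed=21, screen_id="det")
            d = tmp_path / name
            screen.write_fastq(d)
            screen.truth.write(d / "truth.tsv")
            outs.append(d)
        for f in sorted(outs[0].iterdir()):
            assert f.read_bytes() == (outs[1] / f.name).read_bytes(), f.name

    def test_lambda_schedule_length_checked(self):
        library = build_library(n_clones=50, seed=22)
        with pytest.raises(ValueError, match="lambda_schedule"):
            run_selection(library, n_cycles=3, lambda_schedule=[1.0, 2.0], seed=0)


class TestScoreRecovery:
    def test_mismatched_run_ids_rejected(self, small_screen):
        report = run_funnel(
            RunConfig(counts_path="<sim>", screen_id="someone_else"),
            counts_table=small_screen.counts_table(),
        )
        with pytest.raises(ValueError, match="does not match"):
            score_recovery(report, small_screen)

    def test_noiseless_small_screen_recovers_all_binders(self):
        library = build_library(n_clones=1000, seed=30)
        screen = run_selection(library, depth=20_000, error_rate=0.0, seed=31,
                               screen_id="clean")
        report = run_funnel(
            RunConfig(counts_path="<sim>", screen_id="clean"),
            counts_table=screen.counts_table(),
        )
        metrics = score_recovery(report, screen, top_k=20)
        assert metrics["binder_recovery"] == 1.0
        assert metrics["cascade"]["sensitivity"] == 1.0
        assert metrics["cascade"]["specificity"] == 1.0
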