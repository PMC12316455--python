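"""Synthetic library generator: determinism, counting exactness, recovery."""

import numpy as np
import pytest

from teloend import (
    CANONICAL_LABEL,
    ConfigError,
    SimulationConfig,
    StrandClass,
    classify_stream,
    describe_truth,
    end_distribution,
    estimate_canonical_fraction,
    simulate_library,
    simulate_reads,
    tally_library,
    vtr_frequency,
)
from teloend.simulate import revcomp


def clean_config(**overrides):
    base = dict(
        n_telomeres=200,
        p_canonical=1.0,
        terminal_randomization="none",
        vtr_rate=0.0,
        error_rate=0.0,
        background_fraction=0.0,
        seed=42,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestValidation:
    def test_invalid_config_lists_offending_fields(self):
        config = SimulationConfig(
            n_telomeres=0, p_canonical=1.5, error_rate=-0.1, mode="both"
        )
        with pytest.raises(ConfigError) as excinfo:
            config.validate()
        message = str(excinfo.value)
        for name in ("n_telomeres", "p_canonical", "error_rate", "mode"):
            assert name in message


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_fastq(self, tmp_path):
        config = clean_config(
            mode="s1", cuts_law="poisson", cuts_per_telomere=2.0,
            vtr_rate=0.02, error_rate=0.001, background_fraction=0.3,
        )
        a, b = tmp_path / "a.fastq.gz", tmp_path / "b.fastq.gz"
        simulate_library(config, a)
        simulate_library(config, b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
        kwargs = dict(terminal_randomization="uniform_rotation", p_canonical=0.5)
        simulate_library(clean_config(seed=1, **kwargs), a)
        simulate_library(clean_config(seed=2, **kwargs), b)
        assert a.read_bytes() != b.read_bytes()


class TestEndCounting:
    def test_endseq_no_cuts_is_all_c_strand(self):
        reads, truth = simulate_reads(clean_config())
        counts = tally_library(reads)
        assert counts.c_rich == counts.total_reads == 200
        assert counts.g_rich == 0
        assert truth.n_g_reads == 0

    def test_s1_fixed_cuts_gives_exact_end_counts(self):
        """n cuts per telomere -> C:G reads exactly (n+1):n, cross-checked by
        an exhaustive tally of the truth sidecar."""
        n = 3
        reads, truth = simulate_reads(
            clean_config(mode="s1", cuts_law="fixed", cuts_per_telomere=n)
        )
        sidecar_c = sum(1 + len(t.cut_positions) for t in truth.telomeres)
        sidecar_g = sum(len(t.cut_positions) for t in truth.telomeres)
        assert sidecar_c == (n + 1) * 200 and sidecar_g == n * 200
        # emitted reads match the sidecar unless a fragment was size-dropped
        assert truth.n_c_reads <= sidecar_c and truth.n_g_reads <= sidecar_g
        counts = tally_library(reads)
        assert counts.c_rich == truth.n_c_reads
        assert counts.g_rich == truth.n_g_reads
        assert abs(counts.c_rich / (counts.c_rich + counts.g_rich) - 4 / 7) < 0.01

    def test_strand_orientation_is_clean_without_error(self):
        reads, _ = simulate_reads(
            clean_config(mode="s1", cuts_law="fixed", cuts_per_telomere=2)
        )
        for read, cls in classify_stream(reads):
            if read.read_id.endswith("/G"):
                assert cls == StrandClass.G_RICH
                assert "CCCTAA" not in read.sequence
            else:
                assert cls == StrandClass.C_RICH
                assert "TTAGGG" not in read.sequence

    def test_g_capture_efficiency_thins_g_reads(self):
        _, full = simulate_reads(
            clean_config(mode="s1", cuts_law="fixed", cuts_per_telomere=3)
        )
        _, thinned = simulate_reads(
            clean_config(
                mode="s1", cuts_law="fixed", cuts_per_telomere=3,
                g_capture_efficiency=0.5,
            )
        )
        assert thinned.n_g_reads < 0.75 * full.n_g_reads
        # C-read emission is independent of capture thinning (cut positions
        # shift with the random stream, so allow a handful of size-drops)
        assert abs(thinned.n_c_reads - full.n_c_reads) <= 20


class TestTerminalPhase:
    def test_pure_canonical_prefixes(self):
        reads, _ = simulate_reads(clean_config())
        assert all(r.sequence.startswith("CTAACC") for r in reads)

    def test_terminal_label_matches_read_prefix(self):
        from teloend import terminal_hexamer

        reads, truth = simulate_reads(
            clean_config(terminal_randomization="uniform_rotation", p_canonical=0.3)
        )
        by_id = {r.read_id: r for r in reads}
        for t, record in enumerate(truth.telomeres):
            read = by_id[f"tel{t:06d}/term/C"]
            assert terminal_hexamer(read) == record.terminal_label

    def test_canonical_fraction_recovery(self):
        reads, truth = simulate_reads(
            clean_config(
                n_telomeres=5000,
                terminal_randomization="uniform_rotation",
                p_canonical=0.45,
            )
        )
        dist = end_distribution(reads)
        estimate = estimate_canonical_fraction(dist)
        assert abs(estimate.p_hat - 0.45) <= 0.05
        expected = describe_truth(truth)["expected_end_distribution"]
        assert expected[CANONICAL_LABEL] == pytest.approx(0.45 + 0.55 / 6)


class TestNoiseAndBackground:
    def test_background_fraction_of_library(self):
        reads, truth = simulate_reads(clean_config(background_fraction=0.5))
        assert truth.n_background == 200
        counts = tally_library(reads)
        assert counts.non_telomeric == 200

    def test_vtr_rate_recovered_from_truth_classes(self):
        reads, truth = simulate_reads(
            clean_config(n_telomeres=3000, vtr_rate=0.02)
        )
        telomeric = [(r, StrandClass.C_RICH) for r in reads]
        result = vtr_frequency(telomeric)
        assert result.units_total >= 10000
        assert abs(result.frequency - 0.02) <= 0.005
        assert describe_truth(truth)["expected_vtr_rate"] == 0.02

    def test_error_rate_perturbs_bases(self):
        clean, _ = simulate_reads(clean_config(seed=5))
        noisy, _ = simulate_reads(clean_config(seed=5, error_rate=0.05))
        mismatches = sum(
            a != b
            for r1, r2 in zip(clean, noisy)
            for a, b in zip(r1.sequence, r2.sequence)
        )
        total = sum(len(r) for r in clean)
        assert 0.03 < mismatches / total < 0.07


class TestDescribeTruth:
    def test_expected_f_closed_form(self):
        _, truth = simulate_reads(
            clean_config(mode="s1", cuts_law="fixed", cuts_per_telomere=3)
        )
        assert describe_truth(truth)["expected_f"] == pytest.approx(4 / 7)

    def test_sidecar_roundtrip(self, tmp_path):
        config = clean_config(mode="s1", cuts_law="poisson", cuts_per_telomere=1.5)
        truth = simulate_library(
            config, tmp_path / "lib.fastq.gz", truth_path=tmp_path / "truth.json"
        )
        from teloend.simulate import TelomereTruth

        again = TelomereTruth.from_json(tmp_path / "truth.json")
        assert again.config == config
        assert again.expected_c_ends == truth.expected_c_ends
        assert [t.cut_positions for t in again.telomeres] == [
            t.cut_positions for t in truth.telomeres
        ]


def test_revcomp():
    assert revcomp("CCCTAA") == "TTAGGG"
    assert revcomp("ACGTN") == "NACGT"
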