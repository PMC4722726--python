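"""Bisulfite chemistry, read alignment, and methylation calling."""

import numpy as np
import pytest

from epicho import (
    METH,
    MISSING,
    UNMETH,
    EpialleleMatrix,
    SimulationConfig,
    align_read,
    bisulfite_convert,
    call_methylation,
    methylation_summary,
    simulate_epialleles,
)


class TestConvert:
    @pytest.mark.parametrize(
        "seq,methylated,expected",
        [
            ("ACGT", {2}, "ACGT"),       # methylated CpG retained
            ("ACGT", set(), "ATGT"),     # unmethylated CpG converts
            ("CCCC", set(), "TTTT"),     # non-CpG C fully converts
            ("AGTA", set(), "AGTA"),     # no C: untouched
        ],
    )
    def test_zero_error_chemistry(self, seq, methylated, expected):
        assert bisulfite_convert(seq, methylated) == expected

    def test_methylated_position_must_be_c(self):
        with pytest.raises(ValueError):
            bisulfite_convert("ACGT", {1})

    def test_error_rates_require_rng(self):
        with pytest.raises(ValueError):
            bisulfite_convert("CCCC", set(), failure_rate=0.5)

    def test_deterministic_and_non_c_idempotent(self):
        out = bisulfite_convert("ACGTCCAT", {2})
        assert out == bisulfite_convert("ACGTCCAT", {2})
        # converting again leaves non-C bases (now including the new Ts) fixed
        assert bisulfite_convert(out, {2}) == out

    def test_error_rates_are_applied(self, rng):
        seq = "C" * 2000
        out = bisulfite_convert(seq, set(), failure_rate=0.2, rng=rng)
        survived = out.count("C") / len(seq)
        assert 0.15 < survived < 0.25


class TestAlign:
    def test_error_free_read_is_ungapped_identity_one(self, annotation, default_config):
        cfg = SimulationConfig(seed=2, n_molecules=1,
                               conversion_failure_rate=0,
                               inappropriate_conversion_rate=0,
                               missing_call_rate=0)
        reads, _ = simulate_epialleles(annotation, cfg, "naked_dna")
        (read,) = reads.values()
        aligned = align_read(read, annotation)
        assert aligned is not None and not aligned.gapped
        assert aligned.identity == 1.0
        amp_start = annotation.amplicon[0]
        assert aligned.ref_positions[0] == amp_start

    def test_internal_deletion_recovers_downstream_coordinates(self, annotation):
        cfg = SimulationConfig(seed=2, n_molecules=1, conversion_failure_rate=0,
                               inappropriate_conversion_rate=0, missing_call_rate=0)
        reads, truth = simulate_epialleles(annotation, cfg, "naked_dna")
        (read,) = reads.values()
        # delete 31 bases mid-read: the anchored pass now mis-phases and the
        # gapped fallback must restore CpG coordinates after the deletion
        cut = 100
        mutated = read[:cut] + read[cut + 31:]
        aligned = align_read(mutated, annotation)
        assert aligned is not None and aligned.gapped
        amp_start, amp_end = annotation.amplicon
        for p in truth.cpg_positions:
            if p - amp_start >= cut + 31:   # downstream of the deletion
                base = aligned.base_at(p)
                assert base in ("C", "T")

    def test_random_sequence_rejected(self, annotation, rng):
        junk = "".join(rng.choice(list("ACGT"), size=231))
        assert align_read(junk, annotation) is None


class TestCalling:
    def _matrix(self, annotation, cfg, mode, clone=None):
        reads, truth = simulate_epialleles(annotation, cfg, mode, clone)
        return call_methylation(reads, annotation, mode), truth

    def test_planted_states_reproduced_cell_for_cell(self, annotation):
        """Zero-error round trip: calls equal planted methylation exactly."""
        cfg = SimulationConfig(seed=6, n_molecules=20,
                               conversion_failure_rate=0,
                               inappropriate_conversion_rate=0,
                               missing_call_rate=0)
        clone = cfg.clones[0]
        matrix, truth = self._matrix(annotation, cfg, "endogenous", clone)
        assert matrix.molecule_ids == truth.molecule_ids
        for i, meth in enumerate(truth.methylated_sites):
            expected = np.full(len(truth.cpg_positions), UNMETH)
            expected[meth] = METH
            assert (matrix.calls[i] == expected).all()

    def test_unreadable_cpg_called_missing(self, annotation):
        cfg = SimulationConfig(seed=6, n_molecules=1, conversion_failure_rate=0,
                               inappropriate_conversion_rate=0, missing_call_rate=0)
        reads, truth = simulate_epialleles(annotation, cfg, "naked_dna")
        ((mol, read),) = reads.items()
        amp_start = annotation.amplicon[0]
        # corrupt one CpG call with a G
        p = truth.cpg_positions[3]
        read = read[: p - amp_start] + "G" + read[p - amp_start + 1:]
        matrix = call_methylation({mol: read}, annotation, "naked_dna")
        assert matrix.calls[0, 3] == MISSING
        assert (matrix.calls[0, :3] != MISSING).all()

    def test_conversion_efficiency_is_one_at_zero_errors(self, annotation):
        cfg = SimulationConfig(seed=6, n_molecules=5, conversion_failure_rate=0,
                               inappropriate_conversion_rate=0, missing_call_rate=0)
        matrix, _ = self._matrix(annotation, cfg, "naked_dna")
        assert np.allclose(matrix.conversion_efficiency, 1.0)

    def test_csv_round_trip(self, annotation, tmp_path):
        cfg = SimulationConfig(seed=6, n_molecules=4)
        matrix, _ = self._matrix(annotation, cfg, "mssi", cfg.clones[1])
        p = tmp_path / "matrix.csv"
        matrix.to_csv(p)
        back = EpialleleMatrix.from_csv(p, mode="mssi")
        assert back.molecule_ids == matrix.molecule_ids
        assert back.cpg_positions == matrix.cpg_positions
        assert (back.calls == matrix.calls).all()


class TestSummary:
    def _make(self, calls, mode="endogenous", eff=None):
        calls = np.asarray(calls, dtype=np.int8)
        ids = [f"m{i}" for i in range(calls.shape[0])]
        eff = np.ones(calls.shape[0]) if eff is None else np.asarray(eff, float)
        positions = [2 * j + 1 for j in range(calls.shape[1])]
        return EpialleleMatrix(ids, positions, calls, mode, eff)

    def test_18_meth_cells_of_288_is_6_25_pct(self):
        """16 molecules x 18 sites with 18 methylated cells -> 6.25 %."""
        calls = np.full((16, 18), UNMETH)
        calls[0, :18] = METH
        m = self._make(calls)
        s = methylation_summary(m)
        assert s.overall_pct == pytest.approx(6.25)

    def test_all_unmethylated_is_zero(self):
        s = methylation_summary(self._make(np.full((4, 6), UNMETH)))
        assert s.overall_pct == 0.0

    def test_missing_excluded_from_denominator(self):
        calls = np.full((2, 4), UNMETH)
        calls[0, 0] = METH
        calls[1, :] = MISSING
        s = methylation_summary(self._make(calls))
        assert s.overall_pct == pytest.approx(100.0 / 4.0)

    def test_molecule_order_invariance(self, rng):
        calls = rng.choice([METH, UNMETH, MISSING], size=(12, 8))
        while not ((calls == METH) | (calls == UNMETH)).any():
            calls = rng.choice([METH, UNMETH, MISSING], size=(12, 8))
        a = methylation_summary(self._make(calls))
        perm = rng.permutation(12)
        b = methylation_summary(self._make(calls[perm]))
        assert a.overall_pct == pytest.approx(b.overall_pct)
        assert np.allclose(a.per_site_pct, b.per_site_pct, equal_nan=True)

    def test_duplicating_a_molecule_shifts_overall_predictably(self):
        calls = np.array([[METH, UNMETH], [UNMETH, UNMETH]], dtype=np.int8)
        base = methylation_summary(self._make(calls))
        dup = methylation_summary(self._make(np.vstack([calls, calls[:1]])))
        # duplicated all-informative molecule: overall moves toward its own 50 %
        assert base.overall_pct == pytest.approx(25.0)
        assert dup.overall_pct == pytest.approx(100.0 * 2 / 6)

    def test_low_conversion_molecules_excluded(self):
        calls = np.full((3, 5), METH)
        calls[2, :] = UNMETH
        s = methylation_summary(self._make(calls, eff=[1.0, 0.90, 1.0]))
        assert s.n_excluded_low_conversion == 1
        assert s.overall_pct == pytest.approx(50.0)

    def test_mssi_mode_rejected(self):
        with pytest.raises(ValueError):
            methylation_summary(self._make(np.full((2, 3), METH), mode="mssi"))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            methylation_summary(self._make(np.full((2, 3), MISSING)))
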