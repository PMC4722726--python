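"""Synthetic-data generator: planted structure, determinism, truth round-trips."""

import json
import math

import numpy as np
import pytest

from epicho import (
    SimulationConfig,
    fit_standard_curve,
    generate_promoter,
    simulate_ct_tables,
    simulate_epialleles,
    simulate_stability_study,
    write_dataset,
)
from epicho.simulate import CloneProfile, EpialleleTruth

from conftest import make_clone


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mssi_efficiency=1.2),
            dict(conversion_failure_rate=-0.1),
            dict(qpcr_efficiency=2.5),
            dict(qpcr_efficiency=1.0),
            dict(n_molecules=0),
            dict(n_passages=1),
            dict(ct_noise_sd=-1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_invalid_clone_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(clones=(make_clone(occupancy=(1.5, 0.5)),))


class TestPromoter:
    def test_amplicon_has_requested_cpg_count(self, annotation, default_config):
        n = default_config.cpg_site_count_in_amplicon
        assert len(annotation.amplicon_cpg_positions()) == n
        assert n == 18

    @pytest.mark.parametrize("n", [12, 24, 30])
    def test_other_cpg_counts(self, n):
        cfg = SimulationConfig(seed=5, cpg_site_count_in_amplicon=n)
        ann = generate_promoter(cfg)
        assert len(ann.amplicon_cpg_positions()) == n

    def test_two_adjacent_147bp_windows(self, annotation):
        w1, w2 = annotation.windows
        assert w1.span == 147 and w2.span == 147
        assert w2.start > w1.end
        # default length reproduces the canonical coordinates
        assert (w1.start, w1.end) == (853, 999)
        assert (w2.start, w2.end) == (1008, 1154)

    def test_deterministic_sequence(self, default_config):
        a = generate_promoter(default_config).sequence
        b = generate_promoter(SimulationConfig(seed=default_config.seed)).sequence
        assert a == b

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_promoter(SimulationConfig(promoter_length=650))
        with pytest.raises(ValueError):
            generate_promoter(SimulationConfig(cpg_site_count_in_amplicon=80))
        with pytest.raises(ValueError):
            generate_promoter(SimulationConfig(cpg_site_count_in_amplicon=5))


class TestEpialleles:
    def test_unknown_mode_rejected(self, annotation, default_config):
        with pytest.raises(ValueError):
            simulate_epialleles(annotation, default_config, "nome")

    def test_forced_protection(self, annotation):
        """Occupancy 1 with zero error rates: every window CpG unmethylated."""
        clone = make_clone(occupancy=(1.0, 1.0))
        cfg = SimulationConfig(seed=1, n_molecules=8, clones=(clone,),
                               conversion_failure_rate=0, mssi_efficiency=1.0,
                               inappropriate_conversion_rate=0, missing_call_rate=0)
        _, truth = simulate_epialleles(annotation, cfg, "mssi", clone)
        window_pos = {p for w in annotation.windows
                      for p in truth.cpg_positions if w.start <= p <= w.end}
        for meth in truth.methylated_sites:
            assert window_pos.isdisjoint(truth.cpg_positions[j] for j in meth)

    def test_forced_accessibility(self, annotation):
        """Occupancy 0, efficiency 1, zero errors: all CpGs methylated."""
        clone = make_clone(occupancy=(0.0, 0.0))
        cfg = SimulationConfig(seed=1, n_molecules=8, clones=(clone,),
                               mssi_efficiency=1.0, conversion_failure_rate=0,
                               inappropriate_conversion_rate=0, missing_call_rate=0)
        _, truth = simulate_epialleles(annotation, cfg, "mssi", clone)
        n = len(truth.cpg_positions)
        assert all(len(m) == n for m in truth.methylated_sites)

    def test_naked_dna_binomial_fraction(self, annotation):
        """Planted-truth methylated fraction matches the binomial expectation."""
        cfg = SimulationConfig(seed=4, n_molecules=600)
        _, truth = simulate_epialleles(annotation, cfg, "naked_dna")
        n_sites = len(truth.cpg_positions)
        calls = n_sites * cfg.n_molecules
        frac = sum(len(m) for m in truth.methylated_sites) / calls
        se = math.sqrt(0.98 * 0.02 / calls)
        assert abs(frac - 0.98) <= 3 * se
        assert all(iv == [] for iv in truth.intervals)

    def test_molecule_substreams_stable_under_growth(self, annotation):
        cfg10 = SimulationConfig(seed=9, n_molecules=10)
        cfg25 = SimulationConfig(seed=9, n_molecules=25)
        clone = cfg10.clones[2]
        r10, t10 = simulate_epialleles(annotation, cfg10, "mssi", clone)
        r25, t25 = simulate_epialleles(annotation, cfg25, "mssi", clone)
        assert {k: r25[k] for k in r10} == r10
        assert t25.methylated_sites[:10] == t10.methylated_sites

    def test_truth_round_trip(self, annotation, default_config, tmp_path):
        clone = default_config.clones[0]
        _, truth = simulate_epialleles(annotation, default_config, "mssi", clone)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        assert EpialleleTruth.from_json(p) == truth


class TestCtTables:
    def test_one_cycle_per_doubling_at_zero_noise(self, noise_free_config):
        tables, _ = simulate_ct_tables(noise_free_config)
        df = tables["expression"]
        std = df[(df["target"] == "LC") & df["known_log10_quantity"].notna()]
        by_q = std.groupby("known_log10_quantity")["ct"].mean()
        # 10-fold dilution at E=2: log2(10) cycles apart
        diffs = np.diff(by_q.sort_index().values)
        assert np.allclose(diffs, -math.log2(10))

    def test_downstream_curve_fit_recovers_analytic_slope(self, noise_free_config):
        tables, truth = simulate_ct_tables(noise_free_config)
        df = tables["expression"]
        std = df[(df["target"] == "HC") & df["known_log10_quantity"].notna()]
        pts = list(zip(std["known_log10_quantity"], std["ct"]))
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(-1 / math.log10(2), abs=1e-6)
        assert curve.slope == pytest.approx(truth.curve_slope, abs=1e-9)

    def test_non_positive_quantity_rejected(self):
        clone = make_clone(hc_lc=0.0)  # HC quantity would be zero
        cfg = SimulationConfig(clones=(clone,))
        with pytest.raises(ValueError):
            simulate_ct_tables(cfg)

    def test_chip_tables_have_paired_input_and_igg(self, default_config):
        tables, _ = simulate_ct_tables(default_config)
        chip = tables["chip"]
        for (sample, primer), grp in chip.groupby(["sample", "target"]):
            assert "input" in set(grp["fraction"])
            assert "igg" in set(grp["fraction"])

    def test_byte_identical_csv_for_same_seed(self, tmp_path, default_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_dataset(default_config, d1, modes=("mssi",))
        p2 = write_dataset(SimulationConfig(seed=default_config.seed), d2,
                           modes=("mssi",))
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


class TestStability:
    def test_endpoint_matches_configured_retention(self, noise_free_config):
        df, truth = simulate_stability_study(noise_free_config)
        for clone in noise_free_config.clones:
            grp = df[df["clone"] == clone.name].sort_values("passage")
            rel = grp["titer_ug_per_mL"].values / grp["titer_ug_per_mL"].values[0]
            assert rel[-1] == pytest.approx(clone.titer_retention, rel=1e-9)

    def test_zero_silencing_gives_flat_titer(self):
        clone = make_clone(retention=1.0)
        cfg = SimulationConfig(clones=(clone,), titer_noise_cv=0.0)
        df, _ = simulate_stability_study(cfg)
        rel = df["titer_ug_per_mL"].values / df["titer_ug_per_mL"].values[0]
        assert np.allclose(rel, 1.0)

    def test_same_seed_clones_differ_only_through_rates(self):
        a, b = make_clone("a", retention=0.2), make_clone("b", retention=0.8)
        cfg = SimulationConfig(seed=3, clones=(a, b))
        df, truth = simulate_stability_study(cfg)
        ga = df[df["clone"] == "a"].reset_index(drop=True)
        gb = df[df["clone"] == "b"].reset_index(drop=True)
        # densities share the same noise draws
        assert np.allclose(ga["viable_density_1e9_per_L"], gb["viable_density_1e9_per_L"])
        # titers differ exactly by the deterministic retention ratio
        ra = truth["a"]["relative_titer"]
        rb = truth["b"]["relative_titer"]
        ratio = np.array([rb[p] / ra[p] for p in ga["passage"]])
        assert np.allclose(gb["titer_ug_per_mL"] / ga["titer_ug_per_mL"], ratio)

    def test_truth_sidecar_round_trip(self, tmp_path, default_config):
        paths = write_dataset(default_config, tmp_path, modes=())
        stored = json.loads((tmp_path / "stability.truth.json").read_text())
        _, truth = simulate_stability_study(default_config)
        for clone, d in truth.items():
            assert stored[clone]["retention_per_passage"] == pytest.approx(
                d["retention_per_passage"])
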