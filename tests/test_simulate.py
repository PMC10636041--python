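"""Generative-model contracts: barcodes, signal model, counts, reads."""

import math

import numpy as np
import pytest

from plexquant import (NoiseModel, TargetSpec, WellSpec, expected_counts,
                       make_panel, make_plate_plan, simulate_counts,
                       simulate_dilution_series, simulate_reads)
from plexquant.simulate import NOISELESS, SimulationError

from conftest import levenshtein


def _well(conc, e=1.0, role="sample", smi="ACGTACGTAC"):
    return WellSpec(well_id="w", role=role, smi=smi, efficiency_e=e,
                    concentrations=conc)


def _target(**kw):
    base = dict(name="t", floor_D=10.0, amplitude_A=1000.0, half_max_C=1e-12,
                slope_B=1.0, hot_fraction_h=1.0, tmi_capture="A" * 12,
                tmi_detection="C" * 12)
    base.update(kw)
    return TargetSpec(**base)


class TestMakePanel:
    def test_single_target_barcodes_separated(self):
        panel = make_panel(1, seed=0, barcode_length=10, min_distance=5)
        t = panel.targets[0]
        assert levenshtein(t.tmi_capture, t.tmi_detection) >= 5

    def test_all_pairwise_distances_meet_floor(self):
        panel = make_panel(200, seed=7, barcode_length=12, min_distance=5)
        tmis = [s for t in panel.all_targets
                for s in (t.tmi_capture, t.tmi_detection)]
        assert len(tmis) == 402 and len(set(tmis)) == 402
        # independent all-pairs oracle on a deterministic subsample
        rng = np.random.default_rng(0)
        idx = rng.choice(len(tmis), size=40, replace=False)
        sub = [tmis[i] for i in idx]
        for i, a in enumerate(sub):
            for b in sub[i + 1:]:
                assert levenshtein(a, b) >= 5
        panel.validate_distances()  # full check via the package's own path

    def test_infeasible_distance_raises(self):
        with pytest.raises(SimulationError, match="edit distance"):
            make_panel(2, seed=1, barcode_length=2, min_distance=5)

    def test_deterministic_and_spans_six_logs(self):
        p1 = make_panel(50, seed=3)
        p2 = make_panel(50, seed=3)
        assert [t.tmi_capture for t in p1.targets] == \
            [t.tmi_capture for t in p2.targets]
        cs = [t.half_max_C for t in p1.targets]
        assert math.log10(max(cs) / min(cs)) >= 6.0


class TestExpectedCounts:
    def test_zero_concentration_gives_floor(self):
        t = _target()
        assert expected_counts(t, _well({"t": 0.0})) == pytest.approx(10.0)

    def test_half_max_by_construction(self):
        t = _target()
        v = expected_counts(t, _well({"t": 1e-12}))
        assert v == pytest.approx(10.0 + 1000.0 / 2)

    def test_hot_fraction_scales_signal_linearly(self):
        xs = 1e-12 * 10.0 ** np.arange(-2, 3)
        for x in xs:
            full = expected_counts(_target(hot_fraction_h=1.0), _well({"t": x}))
            half = expected_counts(_target(hot_fraction_h=0.5), _well({"t": x}))
            assert (half - 10.0) == pytest.approx((full - 10.0) / 2)

    def test_efficiency_is_multiplicative(self):
        t = _target()
        v1 = expected_counts(t, _well({"t": 1e-12}, e=1.0))
        v2 = expected_counts(t, _well({"t": 1e-12}, e=1.7))
        assert v2 == pytest.approx(1.7 * v1)

    def test_cross_affinity_adds_bound_fraction(self):
        t = _target(cross_affinity={"q": 0.5})
        v = expected_counts(t, _well({"t": 0.0, "q": 1e-12}))
        assert v == pytest.approx(10.0 + 0.5 * 1000.0 / 2)


class TestSimulateCounts:
    def test_poisson_means_converge_to_expectation(self):
        # law-of-large-numbers check across 1e4 replicate wells
        t = _target()
        wells = [WellSpec(well_id=f"w{i}", role="sample", smi=f"s{i}",
                          concentrations={"t": 1e-12})
                 for i in range(10_000)]
        from plexquant import PanelDefinition, PlatePlan
        ic = _target(name="mCherry", tmi_capture="G" * 12,
                     tmi_detection="T" * 12)
        panel = PanelDefinition(targets=[t], internal_control=ic,
                                barcode_length=12,
                                min_pairwise_edit_distance=1)
        plan = PlatePlan(wells=wells)
        counts = simulate_counts(panel, plan, noise=NOISELESS, seed=5)
        mean = counts.counts.loc["t"].mean()
        assert mean == pytest.approx(510.0, rel=0.01)

    def test_blank_wells_draw_around_floor(self, small_panel):
        plan = make_plate_plan(small_panel, seed=2, n_wells=96, n_blanks=90,
                               n_ipc=3, n_sample_controls=0)
        counts = simulate_counts(small_panel, plan, noise=NOISELESS, seed=3)
        blanks = [w.well_id for w in plan.wells if w.role == "blank"]
        es = {w.well_id: w.efficiency_e for w in plan.wells}
        for t in small_panel.targets[:2]:
            obs = counts.counts.loc[t.name, blanks].to_numpy()
            exp = np.array([es[w] * t.floor_D for w in blanks])
            assert obs.mean() == pytest.approx(exp.mean(), rel=0.15)

    def test_fixed_seed_reproduces_matrix(self, small_panel, small_plate):
        c1 = simulate_counts(small_panel, small_plate, seed=9)
        c2 = simulate_counts(small_panel, small_plate, seed=9)
        assert c1.counts.equals(c2.counts)


class TestSimulateReads:
    def test_read_count_conservation_and_layout(self, small_panel,
                                                small_plate, small_counts):
        reads = list(simulate_reads(small_counts, small_panel, small_plate,
                                    noise=NoiseModel(), seed=1))
        assert len(reads) == small_counts.counts.to_numpy().sum()
        smi_len = len(small_plate.wells[0].smi)
        k = small_panel.barcode_length
        read = reads[0]
        assert read[smi_len:smi_len + 4] == "TCAG"
        assert read[-4:] == "GATC"
        assert len(read) == smi_len + 8 + 2 * k

    def test_reads_per_count_multiplies_output(self, small_panel, small_plate,
                                               small_counts):
        reads = list(simulate_reads(small_counts, small_panel, small_plate,
                                    noise=NoiseModel(reads_per_count=3),
                                    seed=1))
        assert len(reads) == 3 * small_counts.counts.to_numpy().sum()

    def test_substitution_rate_binomial_mean(self, small_panel, small_plate,
                                             small_counts):
        rate = 0.005
        clean = list(simulate_reads(small_counts, small_panel, small_plate,
                                    noise=NoiseModel(), seed=1))
        noisy = list(simulate_reads(small_counts, small_panel, small_plate,
                                    noise=NoiseModel(substitution_rate=rate),
                                    seed=1))
        subs = sum(sum(a != b for a, b in zip(c, n))
                   for c, n in zip(clean, noisy))
        bases = sum(len(r) for r in clean)
        assert subs / bases == pytest.approx(rate, rel=0.05)

    def test_chimera_rate_fraction(self, small_panel, small_plate,
                                   small_counts):
        det = {t.name: t.tmi_detection for t in small_panel.all_targets}
        cap = {t.tmi_capture: t.name for t in small_panel.all_targets}
        smi_len = len(small_plate.wells[0].smi)
        k = small_panel.barcode_length
        reads = list(simulate_reads(small_counts, small_panel, small_plate,
                                    noise=NoiseModel(chimera_rate=0.01),
                                    seed=2))
        n_chim = 0
        for r in reads:
            t = cap[r[smi_len + 4:smi_len + 4 + k]]
            n_chim += r[smi_len + 4 + k:smi_len + 4 + 2 * k] != det[t]
        assert n_chim / len(reads) == pytest.approx(0.01, rel=0.15)


class TestDilutionSeries:
    def test_levels_span_and_blanks(self):
        t = _target(half_max_C=1e-13)
        plan, counts = simulate_dilution_series(t, top_conc=200e-12, fold=10,
                                                n_levels=12, noise=NOISELESS,
                                                seed=0)
        concs = sorted({w.concentrations["t"] for w in plan.wells
                        if w.role == "standard"})
        assert len(concs) == 12
        assert concs[-1] == pytest.approx(200e-12)
        assert concs[0] == pytest.approx(200e-12 / 10 ** 11)
        assert len([w for w in plan.wells if w.role == "blank"]) == 3

    def test_requires_blanks(self):
        with pytest.raises(SimulationError, match="limit of detection"):
            simulate_dilution_series(_target(), top_conc=1e-10, n_blanks=0)

    def test_noiseless_signal_monotone_in_concentration(self):
        t = _target(half_max_C=1e-13)
        plan, counts = simulate_dilution_series(t, top_conc=1e-10, fold=4,
                                                n_levels=8, n_reps=1,
                                                noise=NOISELESS, seed=1)
        by_conc = sorted(
            ((w.concentrations["t"], counts.counts.loc["t", w.well_id])
             for w in plan.wells if w.role == "standard"))
        means = [c for _, c in by_conc]
        # Poisson draws around a monotone expectation at well-separated
        # levels: allow small stochastic inversions only near the floor
        assert means[-1] > means[0]
        assert all(b >= a * 0.8 - 10 for a, b in zip(means, means[1:]))


def test_ic_ratio_independent_of_efficiency(small_panel):
    # internal-control correction removes the well factor on expectations
    from plexquant import expected_count_matrix
    from plexquant.simulate import PlatePlan
    wells = [WellSpec(well_id=f"w{i}", role="sample", smi=f"smi{i}",
                      efficiency_e=e, concentrations={
                          t.name: t.half_max_C for t in small_panel.targets})
             for i, e in enumerate([0.5, 1.0, 2.0])]
    mu = expected_count_matrix(small_panel, PlatePlan(wells=wells))
    ratio = mu.loc[small_panel.targets[0].name] / mu.loc["mCherry"]
    assert ratio.max() == pytest.approx(ratio.min(), rel=1e-12)
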