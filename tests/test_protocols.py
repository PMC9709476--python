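"""Arrhythmia-risk protocols: restitution, vulnerable window, critical
mass, population of models."""

import numpy as np
import pytest
from scipy import stats

from cardiosim.ord import CHANNELS
from cardiosim.pharmacology import (compose_factors, drug_factors,
                                    load_drug_library, load_remodeling)
from cardiosim.protocols import (PopulationSpec, critical_cell_number,
                                 cv_restitution, run_population,
                                 sample_population, vulnerable_window)
from cardiosim.strand import StrandConfig
from cardiosim.surrogate import SurrogateCellParams


class TestRestitution:
    def test_single_point_schedule(self, surrogate_strand_cfg):
        curve = cv_restitution(surrogate_strand_cfg, [1000.0], min_dvdt=1.0)
        assert len(curve.bcls) == 1
        assert curve.cvs[0] > 0
        assert curve.termination is None

    def test_cv_slows_at_short_cycle_lengths(self, surrogate_strand_cfg):
        curve = cv_restitution(surrogate_strand_cfg, [3000.0, 400.0],
                               min_dvdt=1.0)
        assert curve.cvs[0] >= curve.cvs[1]

    def test_doubling_diffusion_lifts_whole_curve(self, surrogate_strand_cfg):
        sched = [3000.0, 800.0, 400.0]
        lo = cv_restitution(surrogate_strand_cfg, sched, min_dvdt=1.0)
        cfg2 = StrandConfig(model="surrogate", dt=0.1, rec_dt=0.5,
                            bcl=2000.0, n_beats=1, D=2 * 0.127)
        hi = cv_restitution(cfg2, sched, min_dvdt=1.0)
        assert all(h > l for h, l in zip(hi.cvs, lo.cvs))

    def test_non_decreasing_schedule_rejected(self, surrogate_strand_cfg):
        with pytest.raises(ValueError):
            cv_restitution(surrogate_strand_cfg, [500.0, 800.0])


class TestVulnerableWindow:
    def test_refractory_s2_blocked_recovered_s2_bidirectional(
            self, surrogate_strand_cfg):
        res = vulnerable_window(surrogate_strand_cfg, [50],
                                (380.0, 900.0), ci_step=260.0)
        assert res.outcomes[50][380.0] == "blocked"
        assert res.outcomes[50][900.0] == "bidirectional"

    def test_unidirectional_band_between_block_and_recovery(
            self, surrogate_strand_cfg):
        res = vulnerable_window(surrogate_strand_cfg, [50], (405.0, 450.0),
                                ci_step=5.0)
        labels = list(res.outcomes[50].values())
        assert "unidirectional" in labels
        assert res.windows[50][2] > 0
        # classification is exhaustive and exclusive
        assert set(labels) <= {"blocked", "unidirectional", "bidirectional"}

    def test_fully_rested_tissue_has_zero_window(self, surrogate_strand_cfg):
        res = vulnerable_window(surrogate_strand_cfg, [50],
                                (900.0, 920.0), ci_step=10.0)
        assert all(lab == "bidirectional"
                   for lab in res.outcomes[50].values())
        assert res.mean_width == 0.0


class TestCriticalCellNumber:
    def test_linear_scan_matches_bisection(self, surrogate_critical_factory):
        linear = critical_cell_number(surrogate_critical_factory,
                                      method="linear", duration=1500.0)
        bisect = critical_cell_number(surrogate_critical_factory,
                                      method="bisect", duration=1500.0)
        assert linear.critical_count == bisect.critical_count
        assert linear.critical_count is not None

    def test_search_trace_is_monotone(self, surrogate_critical_factory):
        res = critical_cell_number(surrogate_critical_factory,
                                   method="linear", duration=1500.0)
        crit = res.critical_count
        assert all(fired == (count >= crit)
                   for count, fired in res.search_trace.items())
        assert res.length_mm == pytest.approx(crit * 0.15)

    def test_stronger_drive_never_raises_threshold(
            self, surrogate_critical_factory):
        weak = critical_cell_number(surrogate_critical_factory,
                                    method="bisect", duration=1500.0)
        strong_params = SurrogateCellParams(ead_current=0.06)
        strong = critical_cell_number(
            lambda c: surrogate_critical_factory(c, params=strong_params),
            method="bisect", duration=1500.0)
        assert strong.critical_count <= weak.critical_count

    def test_zero_affected_cells_never_fires(self, surrogate_critical_factory):
        from cardiosim.protocols import _ectopic
        from cardiosim.strand import simulate_strand
        tr = simulate_strand(surrogate_critical_factory(0), duration=1500.0)
        assert not _ectopic(tr)


class TestSamplePopulation:
    def test_seed_reproducibility(self):
        spec = PopulationSpec(n_variants=50, seed=11)
        a = sample_population(spec)
        b = sample_population(spec)
        assert all(dict(x) == dict(y) for x, y in zip(a, b))

    def test_moments_at_n_1000(self):
        pop = sample_population(PopulationSpec(n_variants=1000, seed=5))
        arr = np.array([f.as_array() for f in pop])
        assert arr.shape == (1000, 9)
        assert np.all(np.abs(arr.mean(axis=0) - 1.0) < 0.02)
        assert np.all(np.abs(arr.std(axis=0) - 0.2) < 0.02)
        assert np.all(arr >= 0.0)

    def test_per_channel_normality(self):
        # truncation at 0 is ~4 sigma away and should not break normality
        pop = sample_population(PopulationSpec(n_variants=1000, seed=5))
        arr = np.array([f.as_array() for f in pop])
        for j in range(9):
            assert stats.shapiro(arr[:, j]).pvalue > 1e-3

    def test_degenerate_sd_zero(self):
        pop = sample_population(PopulationSpec(n_variants=5, sd=0.0, seed=1))
        for fac in pop:
            assert all(v == 1.0 for v in fac.values())


class TestRunPopulation:
    def test_degenerate_population_identical_variants(self):
        spec = PopulationSpec(n_variants=3, sd=0.0, seed=2)
        res = run_population(spec, cell_type="ENDO", n_beats=2)
        assert res.ead_ratio in (0.0, 1.0)
        assert res.table["apd90_ms"].nunique() == 1

    def test_ead_ratio_reproducible_for_fixed_seed(self):
        hfco, _ = load_remodeling("HF+CO")
        spec = PopulationSpec(n_variants=4, seed=9)
        a = run_population(spec, condition_factors=hfco, n_beats=2)
        b = run_population(spec, condition_factors=hfco, n_beats=2)
        assert a.ead_ratio == b.ead_ratio
        assert a.table.equals(b.table)

    def test_ikr_activator_does_not_raise_ead_ratio(self):
        # paired-seed comparison on an EAD-prone background
        hfco, _ = load_remodeling("HF+CO")
        hw = drug_factors(load_drug_library()["hw-0168"], 0.5)
        spec = PopulationSpec(n_variants=8, seed=7)
        base = run_population(spec, condition_factors=hfco, n_beats=3)
        treat = run_population(spec,
                               condition_factors=compose_factors(hfco, hw),
                               n_beats=3)
        assert base.ead_ratio > 0
        assert treat.ead_ratio <= base.ead_ratio
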