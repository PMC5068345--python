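import numpy as np
import pytest

from colxscan import enthalpy as en
from colxscan import synthetic_collagen as sc
from colxscan.enthalpy import (
    AnalysisWindow,
    EnergyTrace,
    classify_sites,
    delta_enthalpy,
    equilibration_window,
    load_energy_table,
    mean_pair_distance,
    save_energy_table,
)


def constant_trace(value, total_ns=60.0, dt_ps=10.0, label=""):
    times = np.arange(dt_ps, total_ns * 1000 + dt_ps / 2, dt_ps)
    return EnergyTrace(times, np.full_like(times, float(value)), label)


class TestEnergyTableIO:
    def test_generator_output_round_trips(self, tmp_path):
        tr = sc.gen_energy_trace(
            sc.TraceParams(total_time=2.0, equil_time=1.0, seed=5), "x"
        )
        path = tmp_path / "x.tsv"
        save_energy_table(tr, path)
        back = load_energy_table(path)
        assert np.allclose(back.times, tr.times)
        assert np.allclose(back.energies, tr.energies)

    def test_shuffled_times_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("time_ps\ttotal_energy_kcal_mol\n2.0\t1.0\n1.0\t2.0\n")
        with pytest.raises(ValueError, match="increasing"):
            load_energy_table(p)

    def test_empty_data_section(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("time_ps\ttotal_energy_kcal_mol\n")
        with pytest.raises(ValueError, match="empty"):
            load_energy_table(p)

    def test_nan_energy_rejected(self, tmp_path):
        p = tmp_path / "nan.tsv"
        p.write_text("time_ps\ttotal_energy_kcal_mol\n1.0\t2.0\n2.0\t\n")
        with pytest.raises(ValueError, match="NaN"):
            load_energy_table(p)

    def test_ns_header_converted(self, tmp_path):
        p = tmp_path / "ns.tsv"
        p.write_text("time_ns\tenergy\n1.0\t5.0\n2.0\t6.0\n")
        assert load_energy_table(p).times[0] == pytest.approx(1000.0)


class TestEquilibrationWindow:
    def test_fixed_last_25_of_60(self):
        w = equilibration_window(constant_trace(1.0, total_ns=60.0), "fixed_last")
        assert (w.start, w.end) == (35.0, 60.0)

    def test_fixed_last_25_of_30(self):
        w = equilibration_window(constant_trace(1.0, total_ns=30.0), "fixed_last")
        assert (w.start, w.end) == pytest.approx((5.0, 30.0))

    def test_trace_too_short(self):
        with pytest.raises(ValueError, match="shorter"):
            equilibration_window(constant_trace(1.0, total_ns=10.0), "fixed_last")

    def test_auto_detects_generator_equilibration(self):
        """Drift ends at 35 ns; the heuristic should land in [30, 40] ns in
        at least 95 of 100 seeded traces."""
        hits = 0
        for seed in range(100):
            tr = sc.gen_energy_trace(sc.TraceParams(seed=seed))
            w = equilibration_window(tr, "auto")
            hits += 30.0 <= w.start <= 40.0
        assert hits >= 95


class TestDeltaEnthalpy:
    def test_constant_traces(self):
        est = delta_enthalpy(
            constant_trace(12.0), constant_trace(10.0), AnalysisWindow(35, 60)
        )
        assert est.delta_h == pytest.approx(2.0)
        assert est.sem == 0.0
        assert not est.favourable

    def test_identical_traces_zero(self):
        tr = sc.gen_energy_trace(sc.TraceParams(seed=3))
        est = delta_enthalpy(tr, tr, AnalysisWindow(35, 60))
        assert est.delta_h == 0.0
        assert est.sem == 0.0

    def test_shift_equivariance(self):
        x = sc.gen_energy_trace(sc.TraceParams(seed=4), "x")
        r = sc.gen_energy_trace(sc.TraceParams(seed=5), "r")
        w = AnalysisWindow(35, 60)
        base = delta_enthalpy(x, r, w).delta_h
        shifted = EnergyTrace(x.times, x.energies + 7.5, "x+c")
        assert delta_enthalpy(shifted, r, w).delta_h == pytest.approx(base + 7.5)

    def test_delta_independent_of_block_count(self):
        x = sc.gen_energy_trace(sc.TraceParams(seed=6), "x")
        r = sc.gen_energy_trace(sc.TraceParams(seed=7), "r")
        w = AnalysisWindow(35, 60)
        values = {delta_enthalpy(x, r, w, n_blocks=k).delta_h for k in (2, 5, 20, 100)}
        assert len(values) == 1

    def test_sem_scales_inverse_sqrt_n_white_noise(self):
        # the block SEM of a single realization is itself noisy (chi with
        # n_blocks-1 df), so the scaling law is checked on the mean SEM over
        # independent seeded realizations per series length
        sems = {}
        for n in (10**3, 10**4, 10**5):
            times = np.arange(n, dtype=float)
            w = AnalysisWindow(0, (n - 1) / 1000.0)
            vals = []
            for rep in range(50):
                rng = np.random.default_rng(1000 * n + rep)
                x = EnergyTrace(times, rng.normal(0, 1, n), "x")
                r = EnergyTrace(times, rng.normal(0, 1, n), "r")
                vals.append(delta_enthalpy(x, r, w, n_blocks=10).sem)
            sems[n] = np.mean(vals)
        assert sems[10**4] / sems[10**3] == pytest.approx(10**-0.5, rel=0.15)
        assert sems[10**5] / sems[10**4] == pytest.approx(10**-0.5, rel=0.15)

    def test_window_not_covered(self):
        with pytest.raises(ValueError, match="does not cover"):
            delta_enthalpy(
                constant_trace(1.0, total_ns=20.0),
                constant_trace(1.0, total_ns=20.0),
                AnalysisWindow(35, 60),
            )

    def test_per_frame_sem_smaller_under_autocorrelation(self):
        x = sc.gen_energy_trace(sc.TraceParams(seed=8), "x")
        r = sc.gen_energy_trace(sc.TraceParams(seed=9), "r")
        w = AnalysisWindow(35, 60)
        blocked = delta_enthalpy(x, r, w, n_blocks=100).sem
        naive = delta_enthalpy(x, r, w, sem_method="per_frame").sem
        assert naive < blocked


class TestClassifySites:
    def test_all_positive_empty(self):
        assert classify_sites({"D1": 1.0, "D2": 0.0}) == []

    def test_zero_is_unfavourable(self):
        assert classify_sites({"D1": 0.0, "D2": -0.01}) == ["D2"]

    def test_sign_flip_complement(self, table1):
        dh = dict(zip(table1["site"], table1["dogdic_dh"]))
        fav = set(classify_sites(dh))
        flipped = set(classify_sites({k: -v for k, v in dh.items() if v != 0}))
        assert fav | flipped == set(dh)
        assert fav & flipped == set()


class TestMeanPairDistance:
    def _frame(self, d):
        from colxscan.structure_io import AtomRecord, Residue, ResidueRef, Structure

        return Structure(chains={
            "α1a": [Residue(ResidueRef("α1a", "ARG", 901, 734),
                            [AtomRecord("NE", "N", (0, 0, 0))])],
            "α1b": [Residue(ResidueRef("α1b", "GLY", 900, 733),
                            [AtomRecord("O", "O", (d, 0, 0))])],
        })

    def test_identical_frames(self):
        frames = [self._frame(2.07)] * 3
        d = mean_pair_distance(frames, ("α1a", 734, "NE"), ("α1b", 733, "O"))
        assert d == pytest.approx(2.07)

    def test_two_frames_mean(self):
        frames = [self._frame(1.0), self._frame(3.0)]
        assert mean_pair_distance(
            frames, ("α1a", 734, "NE"), ("α1b", 733, "O")
        ) == pytest.approx(2.0)

    def test_noisy_frames_recover_planted_mean(self):
        rng = np.random.default_rng(2026)
        draws = rng.normal(2.07, 0.2, 200)
        frames = [self._frame(float(d)) for d in draws]
        est = mean_pair_distance(frames, ("α1a", 734, "NE"), ("α1b", 733, "O"))
        assert est == pytest.approx(draws.mean())
        assert abs(est - 2.07) < 3 * 0.2 / np.sqrt(200)

    def test_missing_atom_names_frame(self):
        frames = [self._frame(1.0), self._frame(2.0)]
        frames[1].chains["α1b"][0].atoms = []
        with pytest.raises(ValueError, match="frame 1"):
            mean_pair_distance(frames, ("α1a", 734, "NE"), ("α1b", 733, "O"))
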