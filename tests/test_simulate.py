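import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

import hoxtempo as ht
from hoxtempo.simulate import (
    QpcrNoiseModel,
    TissueMixture,
    TranscriptionParams,
    panel_reaction_copies,
    simulate_dilution_series,
    make_demo_dataset,
)
from hoxtempo.qpcr import plate_to_copies


def hoxlike(onset, rate=1000.0, splicing=0.5, leaky=0.0):
    return TranscriptionParams(
        onset_hpf=onset, rate=rate, splicing_rate=splicing,
        maternal_copies0=0.0, maternal_decay=0.0, leaky_rate=leaky,
    )


class TestTimecourse:
    def test_no_transcription_is_pure_maternal_decay(self):
        p = TranscriptionParams(rate=0.0, maternal_copies0=1000.0, maternal_decay=0.2)
        tc = ht.simulate_timecourse(p, [0.0, 5.0, 10.0])
        assert np.all(tc.premrna == 0.0)
        np.testing.assert_allclose(tc.mature, 1000.0 * np.exp(-0.2 * tc.hpf))

    def test_closed_form_value(self):
        # onset 6, rate 1000, splicing 0.5 at t=8: 2000*(1-exp(-1))
        tc = ht.simulate_timecourse(hoxlike(6.0), [8.0])
        np.testing.assert_allclose(tc.premrna[0], 2000.0 * (1 - np.exp(-1.0)))

    def test_matches_numerical_ode(self):
        p = hoxlike(6.0, rate=1234.0, splicing=0.37)

        def rhs(t, y):
            synth = p.rate if t >= 6.0 else 0.0
            return [synth - p.splicing_rate * y[0], p.splicing_rate * y[0]]

        sol = solve_ivp(rhs, (0, 15), [0.0, 0.0], t_eval=[8.0, 12.0, 15.0],
                        rtol=1e-10, atol=1e-8)
        tc = ht.simulate_timecourse(p, [8.0, 12.0, 15.0])
        np.testing.assert_allclose(tc.premrna, sol.y[0], rtol=1e-6)
        np.testing.assert_allclose(tc.mature, sol.y[1], rtol=1e-6, atol=1e-6)

    def test_instantaneous_splicing_limit(self):
        tc = ht.simulate_timecourse(hoxlike(6.0, splicing=1e8), [7.0, 10.0])
        assert np.all(tc.premrna < 1e-3)
        np.testing.assert_allclose(tc.mature, 1000.0 * (np.array([7.0, 10.0]) - 6.0), rtol=1e-6)

    def test_transcription_never_precedes_mbt(self):
        tc = ht.simulate_timecourse(TranscriptionParams(onset_hpf=1.0, mbt_hpf=4.0), [2.0, 3.9])
        assert np.all(tc.premrna == 0.0)

    def test_leaky_synthesis_from_zero(self):
        tc = ht.simulate_timecourse(hoxlike(10.0, leaky=50.0, splicing=0.0), [2.0])
        np.testing.assert_allclose(tc.premrna[0], 100.0)

    def test_conservation_without_decay(self):
        p = hoxlike(5.0, rate=800.0, splicing=0.3)
        p = TranscriptionParams(**{**p.__dict__, "maternal_copies0": 4000.0})
        t = np.linspace(0, 19.5, 40)
        tc = ht.simulate_timecourse(p, t)
        synthesized = 800.0 * np.clip(t - 5.0, 0, None)
        np.testing.assert_allclose(tc.premrna + tc.mature, 4000.0 + synthesized, rtol=1e-9)

    def test_nascent_pool_small_under_defaults(self):
        tc = ht.simulate_timecourse(TranscriptionParams(), [18.5])
        assert tc.premrna[0] / tc.mature[0] <= 0.05

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            ht.simulate_timecourse(TranscriptionParams(), [5.0, 3.0])


class TestQpcrPlate:
    def test_zero_template_all_censored(self, curve):
        copies = pd.DataFrame({"gene_id": ["g"], "hpf": [9.5], "copies": [0.0]})
        noise = QpcrNoiseModel(rtminus_contamination_copies=0.0)
        plate = ht.simulate_qpcr_plate(copies, noise, curve, seed=0)
        assert plate["censored"].all()

    def test_noiseless_round_trip(self, curve):
        copies = pd.DataFrame({"gene_id": ["g"] * 3, "hpf": [8.5, 9.5, 10.5],
                               "copies": [10.0, 1000.0, 12345.0]})
        noise = QpcrNoiseModel(cq_sd=0.0, rtminus_contamination_copies=0.0)
        plate = ht.simulate_qpcr_plate(copies, noise, curve, seed=0)
        got = plate_to_copies(plate, curve)
        plus = got[got.rt == "plus"].groupby("hpf")["copies"].mean()
        np.testing.assert_allclose(plus.to_numpy(), [10.0, 1000.0, 12345.0], rtol=1e-12)

    def test_seed_determinism(self, curve):
        copies = pd.DataFrame({"gene_id": ["g"], "hpf": [9.5], "copies": [500.0]})
        noise = QpcrNoiseModel()
        a = ht.simulate_qpcr_plate(copies, noise, curve, seed=7)
        b = ht.simulate_qpcr_plate(copies, noise, curve, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_copies_rejected(self, curve):
        copies = pd.DataFrame({"gene_id": ["g"], "hpf": [9.5], "copies": [-1.0]})
        with pytest.raises(ValueError, match="negative"):
            ht.simulate_qpcr_plate(copies, QpcrNoiseModel(), curve, seed=0)

    def test_replicate_count_validated(self):
        with pytest.raises(ValueError):
            QpcrNoiseModel(replicates=1)


class TestTrajectorySim:
    def test_noiseless_band_is_degenerate(self):
        t = ht.simulate_trajectory(hoxlike(6.0), noise_sd=0.0, n_draws=10, seed=0)
        np.testing.assert_allclose(t.lo95, t.mean)
        np.testing.assert_allclose(t.hi95, t.mean)
        ref = ht.simulate_timecourse(hoxlike(6.0), t.hpf)
        np.testing.assert_allclose(t.mean, ref.mature)

    def test_band_width_grows_with_noise(self):
        lo = ht.simulate_trajectory(hoxlike(5.0), noise_sd=0.05, n_draws=200, seed=3)
        hi = ht.simulate_trajectory(hoxlike(5.0), noise_sd=0.3, n_draws=200, seed=3)
        assert np.all(hi.hi95 - hi.lo95 >= lo.hi95 - lo.lo95)

    def test_zero_curve_stays_zero(self):
        p = TranscriptionParams(rate=0.0, maternal_copies0=0.0)
        t = ht.simulate_trajectory(p, noise_sd=0.5, n_draws=20, seed=1)
        assert np.all(t.mean == 0.0) and np.all(t.hi95 == 0.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            ht.simulate_trajectory(TranscriptionParams(), 0.1, n_draws=1, seed=0)


class TestWholeEmbryo:
    def test_single_tissue_equals_timecourse(self):
        params = {"g1": hoxlike(5.0), "g2": hoxlike(7.0)}
        mix = TissueMixture(fractions=(1.0,), tissues=(params,), detection_limit=10.0)
        t = np.linspace(0, 15, 31)
        res = ht.simulate_whole_embryo(mix, t)
        for g in params:
            np.testing.assert_allclose(res.premrna[g], ht.simulate_timecourse(params[g], t).premrna)

    def test_zero_fraction_contributes_nothing(self):
        a = {"g": hoxlike(5.0)}
        b = {"g": hoxlike(5.0, rate=1e6)}
        mix = TissueMixture(fractions=(1.0, 0.0), tissues=(a, b), detection_limit=10.0)
        t = np.linspace(0, 15, 31)
        res = ht.simulate_whole_embryo(mix, t)
        np.testing.assert_allclose(res.premrna["g"], ht.simulate_timecourse(a["g"], t).premrna)

    def test_bad_fractions_rejected(self):
        a = {"g": hoxlike(5.0)}
        with pytest.raises(ValueError, match="sum to 1"):
            TissueMixture(fractions=(0.6, 0.6), tissues=(a, a))

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="same genes"):
            TissueMixture(fractions=(0.5, 0.5), tissues=({"g": hoxlike(5.0)}, {"h": hoxlike(5.0)}))


class TestFixtureBuilders:
    def test_panel_copies_scaled_per_reaction(self):
        panel = {"g": hoxlike(6.0)}
        df = panel_reaction_copies(panel, times=(8.0,))
        expected = 2000.0 * (1 - np.exp(-1.0)) * 0.025
        np.testing.assert_allclose(df["copies"].iloc[0], expected)

    def test_dilution_series_noiseless_on_curve(self, curve):
        df = simulate_dilution_series(curve, cq_sd=0.0)
        np.testing.assert_allclose(df["cq"], curve.cq_of(df["copies"].to_numpy()))

    def test_demo_dataset_files(self, tmp_path):
        paths = make_demo_dataset(tmp_path, seed=0)
        for p in paths.values():
            assert p.exists()
        plate = pd.read_csv(paths["plate"])
        assert set(plate.columns) == {"gene_id", "hpf", "stage", "rt", "replicate", "cq", "censored"}
        assert plate["gene_id"].nunique() == 11
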