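"""Eyring fitting, panel averaging, screening, and the T_Hu search."""

import math

import numpy as np
import pytest

from foldkinetics.calibration import (
    CorrectionParams,
    Direction,
    EyringSeries,
    FoldClass,
    PairedRateObservation,
    calibrate_folding_panel,
    fit_eyring,
    optimize_t_hu,
    panel_mean_se,
    read_eyring_series,
    screen_overlarge_activation,
)
from foldkinetics.thermo import (
    R_GAS,
    EyringParams,
    Temperature,
    correct_rate,
    delta_cp_from_length,
    ln_k_over_t,
)


def make_series(c2, dcp, t_h, temps=None, noise_sd=0.0, rng=None, pid="X"):
    temps = np.asarray(temps if temps is not None else np.arange(280.0, 321.0, 5.0))
    params = EyringParams(delta_cp_act=dcp, t_h=Temperature(t_h), intercept=c2)
    ln_k = np.array([ln_k_over_t(params, t) + math.log(t) for t in temps])
    if noise_sd > 0:
        ln_k = ln_k + rng.normal(0, noise_sd, size=ln_k.shape)
    return EyringSeries(pid, Direction.FOLDING, tuple(temps), tuple(ln_k))


class TestFitEyring:
    @pytest.mark.parametrize(
        "c2, dcp, t_h",
        [
            (8.0, -2.8, 315.5),
            (3.0, -6.0, 300.0),
            (10.0, 4.0, 220.0),  # unfolding-like: concave, T_H below range
            (-2.0, -1.2, 340.0),  # extremum above sampled range
        ],
    )
    def test_noiseless_recovery(self, c2, dcp, t_h):
        fit = fit_eyring(make_series(c2, dcp, t_h))
        assert fit.intercept == pytest.approx(c2, rel=1e-6, abs=1e-6)
        assert fit.delta_cp_act == pytest.approx(dcp, rel=1e-6)
        assert fit.t_h.kelvin == pytest.approx(t_h, rel=1e-6)

    def test_noisy_recovery_on_average(self):
        """With sd 0.05 noise on ln k, the mean fitted T_H over replicates
        stays within 1 K of the generating value."""
        rng = np.random.default_rng(42)
        t_hs = [
            fit_eyring(make_series(8.0, -2.8, 315.5, noise_sd=0.05, rng=rng)).t_h.kelvin
            for _ in range(100)
        ]
        assert abs(np.mean(t_hs) - 315.5) < 1.0

    def test_noise_degrades_recovery(self):
        """Larger noise gives a larger spread of recovered T_H (seeded)."""
        spreads = []
        for sd in (0.01, 0.2):
            rng = np.random.default_rng(7)
            t_hs = [
                fit_eyring(make_series(8.0, -2.8, 315.5, noise_sd=sd, rng=rng)).t_h.kelvin
                for _ in range(40)
            ]
            spreads.append(np.std(t_hs))
        assert spreads[0] < spreads[1]

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_eyring(EyringSeries("X", Direction.FOLDING, (280.0, 290.0), (1.0, 2.0)))

    def test_degenerate_series(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_eyring(
                EyringSeries("X", Direction.FOLDING, (280.0, 280.4, 280.8), (2.0, 2.0, 2.0))
            )

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            EyringSeries("X", Direction.FOLDING, (280.0, 280.0, 290.0), (1.0, 1.1, 2.0))


class TestPanelMeanSe:
    def test_two_state_panel_column(self, panel_2s):
        """Printed T_Hf column of the two-state panel averages to
        314.70 +/- 1.44 with the n-1 sample SE."""
        mean, se = panel_mean_se(panel_2s["t_hf_printed_k"])
        assert mean == pytest.approx(314.70, abs=0.01)
        assert se == pytest.approx(1.44, abs=0.01)

    def test_non_two_state_panel_column(self, panel_n2s):
        mean, se = panel_mean_se(panel_n2s["t_hf_printed_k"])
        assert mean == pytest.approx(305.369, abs=0.01)
        assert se == pytest.approx(3.526, abs=0.01)

    def test_single_value_has_no_se(self):
        assert panel_mean_se([5.0]) == (5.0, None)

    def test_empty_panel(self):
        with pytest.raises(ValueError):
            panel_mean_se([])


class TestCalibrateFoldingPanel:
    def test_two_state_panel(self, panel_2s):
        triples = list(
            zip(panel_2s["temp_k"], panel_2s["delta_h_act_kj_mol"], panel_2s["delta_cp_act_kj_mol_k"])
        )
        params = calibrate_folding_panel(triples, list(panel_2s["l_pdb"]))
        assert params.n_proteins == 12
        assert params.t_h.kelvin == pytest.approx(314.70, abs=0.01)
        assert params.beta == pytest.approx(-0.62, abs=0.01)
        assert params.t_h_se == pytest.approx(1.44, abs=0.01)
        assert params.beta_se == pytest.approx(0.03, abs=0.01)

    def test_accepts_eyring_params_entries(self):
        entries = [
            EyringParams(delta_cp_act=-2.0, t_h=Temperature(310.0), intercept=5.0),
            EyringParams(delta_cp_act=-3.0, t_h=Temperature(320.0), intercept=6.0),
        ]
        params = calibrate_folding_panel(entries, [100, 100])
        assert params.t_h.kelvin == pytest.approx(315.0)
        dcp_eq = delta_cp_from_length(100)
        assert params.beta == pytest.approx((-2.0 / dcp_eq + -3.0 / dcp_eq) / 2)

    def test_single_protein_panel(self):
        params = calibrate_folding_panel([(301.15, 40.70, -2.57)], [98])
        assert params.n_proteins == 1
        assert params.t_h_se is None and params.beta_se is None
        assert params.t_h.kelvin == pytest.approx(316.99, abs=0.01)

    def test_rejects_positive_activation(self):
        with pytest.raises(ValueError, match="negative"):
            calibrate_folding_panel([(300.0, 10.0, 2.0)], [100])

    def test_rejects_misaligned_inputs(self):
        with pytest.raises(ValueError):
            calibrate_folding_panel([(300.0, 10.0, -2.0)], [100, 120])


class TestScreenOverlargeActivation:
    def test_partition(self):
        kept, excluded = screen_overlarge_activation(
            [("ok", -2.57, 98), ("too_big", -6.0, 60), ("edge", -3.18, 60)]
        )
        assert [c[0] for c in kept] == ["ok", "edge"]
        assert [c[0] for c in excluded] == ["too_big"]

    def test_empty(self):
        assert screen_overlarge_activation([]) == ([], [])

    def test_exhaustive_disjoint(self):
        cands = [(f"p{i}", -0.5 * i, 80) for i in range(1, 20)]
        kept, excluded = screen_overlarge_activation(cands)
        assert sorted(kept + excluded) == sorted(cands)
        assert not set(kept) & set(excluded)


def synth_pairs(t_h, beta_u, n=6, seed=3):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        l_pdb = int(rng.integers(40, 160))
        dcp_eq = delta_cp_from_length(l_pdb)
        t_x = float(rng.uniform(278, 352))
        ln_k_x = float(rng.uniform(-5, 10))
        ln_k_0 = correct_rate(ln_k_x, t_x, beta_u * dcp_eq, t_h)
        pairs.append(
            PairedRateObservation(f"p{i}", ln_k_x, t_x, ln_k_0, dcp_eq)
        )
    return pairs


class TestOptimizeTHu:
    def test_recovers_planted_t_h(self):
        pairs = synth_pairs(224.0, 0.38)
        t_hu, rmsd = optimize_t_hu(pairs, 0.38)
        assert t_hu.kelvin == pytest.approx(224.0, abs=0.1)
        assert rmsd < 1e-8

    def test_matches_dense_grid_bruteforce(self):
        """The returned minimum is at least as good as every point of an
        independent 0.1 K brute-force scan."""
        rng = np.random.default_rng(11)
        pairs = synth_pairs(180.0, 0.3, n=4, seed=5)
        # perturb so the minimum is not exactly zero
        pairs = [
            PairedRateObservation(
                p.protein_id, p.ln_k_x, p.t_x_k,
                p.ln_k_0_observed + float(rng.normal(0, 0.3)), p.delta_cp_eq,
            )
            for p in pairs
        ]
        t_hu, rmsd = optimize_t_hu(pairs, 0.3, (50.0, 298.0, 0.1))

        def objective(t_h):
            res = [
                correct_rate(p.ln_k_x, p.t_x_k, 0.3 * p.delta_cp_eq, t_h) - p.ln_k_0_observed
                for p in pairs
            ]
            return math.sqrt(np.mean(np.square(res)))

        grid = np.arange(50.0, 298.05, 0.1)
        assert rmsd <= min(objective(t) for t in grid) + 1e-12

    def test_equivariance_under_regenerated_targets(self):
        """Replacing every observed standard-temperature value by the
        correction under a common T_H* makes T_H* the zero-RMSD optimum."""
        pairs = synth_pairs(224.0, 0.38)
        t_star = 150.0
        shifted = [
            PairedRateObservation(
                p.protein_id, p.ln_k_x, p.t_x_k,
                correct_rate(p.ln_k_x, p.t_x_k, 0.38 * p.delta_cp_eq, t_star),
                p.delta_cp_eq,
            )
            for p in pairs
        ]
        t_hu, rmsd = optimize_t_hu(shifted, 0.38)
        assert t_hu.kelvin == pytest.approx(t_star, abs=0.1)
        assert rmsd < 1e-9

    def test_single_observation_solution_curve(self):
        """One observation is underdetermined; the optimizer still lands on
        a zero-residual point of the solution curve, and that point agrees
        with the closed-form T_H solving the correction identity."""
        dcp_eq = delta_cp_from_length(100)
        beta_u, t_h_true = 0.38, 224.0
        ln_k_x, t_x = 2.0, 310.0
        ln_k_0 = correct_rate(ln_k_x, t_x, beta_u * dcp_eq, t_h_true)
        pair = PairedRateObservation("solo", ln_k_x, t_x, ln_k_0, dcp_eq)
        t_hu, rmsd = optimize_t_hu([pair], beta_u)
        assert rmsd < 1e-8
        # closed form: residual is linear in T_H
        dcp = beta_u * dcp_eq
        base = ln_k_x + (1 + dcp / R_GAS) * math.log(298.15 / t_x)
        slope = dcp / R_GAS * (1 / 298.15 - 1 / t_x)
        t_closed = (ln_k_0 - base) / slope
        assert t_hu.kelvin == pytest.approx(t_closed, abs=1e-4)

    def test_error_cases(self):
        with pytest.raises(ValueError):
            optimize_t_hu([], 0.38)
        pairs = synth_pairs(224.0, 0.38, n=2)
        with pytest.raises(ValueError):
            optimize_t_hu(pairs, 0.38, (298.0, 50.0, 0.1))
        with pytest.raises(ValueError):
            optimize_t_hu(pairs, -0.1)

    def test_paired_observation_rejects_standard_t_x(self):
        with pytest.raises(ValueError, match="298.15"):
            PairedRateObservation("x", 1.0, 298.15, 1.0, 3.0)


class TestCorrectionParams:
    def test_se_requires_multiple_proteins(self):
        with pytest.raises(ValueError, match="standard errors"):
            CorrectionParams(
                direction=Direction.FOLDING,
                fold_class=FoldClass.TWO_STATE,
                t_h=Temperature(315.0),
                beta=-0.62,
                t_h_se=1.0,
                n_proteins=1,
            )


class TestSeriesReader:
    def test_reads_kelvin_ln_k(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("# temperature: K\n# rate: ln_k\n280 5.7\n285, 6.0\n290\t6.2\n")
        s = read_eyring_series(f)
        assert s.temperatures_k == (280.0, 285.0, 290.0)
        assert s.ln_k == (5.7, 6.0, 6.2)
        assert s.protein_id == "s"

    def test_reads_celsius_raw_k(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("# temperature: C\n# rate: k\n25 100.0\n30 200.0\n35 400.0\n")
        s = read_eyring_series(f)
        assert s.temperatures_k[0] == pytest.approx(298.15)
        assert s.ln_k[0] == pytest.approx(math.log(100.0))

    @pytest.mark.parametrize(
        "content",
        [
            "280 5.7\n",  # no unit declaration
            "# temperature: K\n# rate: ln_k\n280 5.7 9\n",  # 3 columns
            "# temperature: K\n# rate: ln_k\n280 abc\n",  # non-numeric
            "# temperature: K\n# rate: ln_k\n",  # no data
        ],
    )
    def test_malformed_is_an_error(self, tmp_path, content):
        f = tmp_path / "bad.tsv"
        f.write_text(content)
        with pytest.raises(ValueError):
            read_eyring_series(f)
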