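"""QC metrics, t-test/BH statistics, DE, PCA, treatment comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from scpepkit.errors import ValidationError
from scpepkit.matrix import QuantMatrix
from scpepkit.sc_stats import (
    bh_adjust,
    cv_percent,
    differential_expression,
    housekeeping_fraction,
    pca_scores,
    qc_summary,
    student_t_test,
    treatment_site_comparison,
)

from conftest import brute_force_bh


def quant(data, groups):
    frame = pd.DataFrame(data)
    return QuantMatrix(frame, pd.Series(groups))


class TestCvPercent:
    def test_zero_variance(self):
        assert cv_percent([5, 5, 5]) == 0.0

    def test_direct_formula(self):
        assert cv_percent([1, 2, 3]) == pytest.approx(50.0)

    def test_single_value_undefined(self):
        assert math.isnan(cv_percent([3.0]))


class TestQcSummary:
    def test_identical_coordinates_give_zero_cv(self):
        from test_report_ingest import make_obs

        observations = [
            make_obs(run=f"c{i}", modseq=m, rt=10.0, im=1.0)
            for i in range(3)
            for m in ("AAASK", "CCCDK")
        ]
        summary = qc_summary(observations, min_samples=2)
        assert summary.median_rt_cv == 0.0
        assert summary.median_im_cv == 0.0
        assert (summary.per_sample_counts["n_peptides"] == 2).all()

    def test_empty_report(self):
        summary = qc_summary([])
        assert math.isnan(summary.median_rt_cv)
        assert summary.per_sample_counts.empty

    def test_recovers_injected_jitter(self, rng):
        """Median CV approximates 100 * jitter_sd / center."""
        from test_report_ingest import make_obs

        sd, center = 0.1, 20.0
        observations = [
            make_obs(
                run=f"c{i}", modseq=m,
                rt=float(center + rng.normal(0, sd)), im=1.0,
            )
            for i in range(200)
            for m in ("AAASK", "CCCDK", "EEEFK")
        ]
        summary = qc_summary(observations)
        assert summary.median_rt_cv == pytest.approx(
            100 * sd / center, rel=0.2
        )


class TestHousekeepingFraction:
    def test_direct_fraction(self):
        fraction, _ = housekeeping_fraction(
            {"A", "B", "C", "D"}, {"A"}
        )
        assert fraction == 0.25

    def test_empty_housekeeping_list(self):
        fraction, _ = housekeeping_fraction({"A", "B"}, set())
        assert fraction == 0.0

    def test_empty_detected_undefined(self):
        fraction, _ = housekeeping_fraction(set(), {"A"})
        assert math.isnan(fraction)

    def test_case_insensitive_and_per_sample(self):
        fraction, per_sample = housekeeping_fraction(
            {"actb", "TP53"}, {"ACTB"},
            per_sample_detected={"c1": {"ACTB"}, "c2": {"actb", "tp53"}},
        )
        assert fraction == 0.5
        assert per_sample.loc["c2"].tolist() == [1, 1]


class TestStudentT:
    def test_identical_samples(self):
        t, p = student_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        t, p = student_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_closed_form_agreement(self, rng):
        """Pooled-variance t and its Student-t CDF p-value, computed from
        first principles, match to 1e-10."""
        for _ in range(50):
            n1, n2 = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1.3, n2)
            t, p = student_t_test(x, y)
            df = n1 + n2 - 2
            sp2 = (
                (n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)
            ) / df
            t_manual = (x.mean() - y.mean()) / math.sqrt(
                sp2 * (1 / n1 + 1 / n2)
            )
            p_manual = 2 * special.stdtr(df, -abs(t_manual))
            assert t == pytest.approx(t_manual, abs=1e-10)
            assert p == pytest.approx(p_manual, abs=1e-10)

    def test_insufficient_observations(self):
        t, p = student_t_test([1.0], [1.0, 2.0, 3.0])
        assert math.isnan(t) and math.isnan(p)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p))

    def test_procedure_properties(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()
        order_p = np.argsort(p, kind="stable")
        assert (np.diff(q[order_p]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestDifferentialExpression:
    def _simulated(self, seed=3):
        rng = np.random.default_rng(seed)
        n_a, n_b = 15, 15
        features, truth = {}, {}
        for i in range(40):
            name = f"F{i:03d}"
            effect = 2.0 if i < 5 else (-2.0 if i < 10 else 0.0)
            truth[name] = (
                "up" if effect > 0 else "down" if effect < 0 else ""
            )
            features[name] = np.concatenate([
                rng.normal(12 + effect, 0.4, n_a),
                rng.normal(12, 0.4, n_b),
            ])
        frame = pd.DataFrame(
            features,
            index=[f"a{i}" for i in range(n_a)]
            + [f"b{i}" for i in range(n_b)],
        ).T
        groups = {f"a{i}": "A" for i in range(n_a)}
        groups.update({f"b{i}": "B" for i in range(n_b)})
        return QuantMatrix(frame, pd.Series(groups)), truth

    def test_recovers_planted_effects(self):
        matrix, truth = self._simulated()
        results = differential_expression(matrix, "A", "B")
        for name, label in truth.items():
            expected = label or "ns"
            assert results.loc[name, "status"] == expected

    def test_swap_symmetry(self):
        matrix, _ = self._simulated()
        ab = differential_expression(matrix, "A", "B")
        ba = differential_expression(matrix, "B", "A")
        assert ab["log2_fc"].to_numpy() == pytest.approx(
            -ba["log2_fc"].to_numpy()
        )
        assert ab["p"].to_numpy() == pytest.approx(
            ba["p"].to_numpy(), abs=1e-12
        )

    def test_identical_groups_make_no_calls(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            rng.normal(10, 1, size=(50, 20)),
            index=[f"F{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(20)],
        )
        groups = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        results = differential_expression(
            QuantMatrix(frame, pd.Series(groups)), "A", "B"
        )
        assert (results["status"] == "ns").all()

    def test_sparse_feature_filtered(self):
        matrix, _ = self._simulated()
        matrix.values.iloc[0, 6:] = np.nan  # observed in 6/30 = 20%
        results = differential_expression(matrix, "A", "B")
        assert results.iloc[0]["status"] == "filtered"

    def test_small_group_rejected(self):
        matrix, _ = self._simulated()
        with pytest.raises(ValidationError):
            differential_expression(matrix, "A", "missing-group")


class TestPCA:
    def test_constant_matrix_gives_zero_scores(self):
        frame = pd.DataFrame(
            7.0, index=[f"F{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(4)],
        )
        matrix = QuantMatrix(
            frame, pd.Series({f"s{i}": "g" for i in range(4)})
        )
        scores, explained = pca_scores(matrix, 2)
        assert np.allclose(scores[["PC1", "PC2"]].to_numpy(), 0.0)

    def test_duplicated_samples_get_identical_scores(self, rng):
        frame = pd.DataFrame(
            rng.normal(10, 1, size=(30, 5)),
            index=[f"F{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(5)],
        )
        doubled = pd.concat(
            [frame, frame.rename(columns=lambda c: c + "_dup")], axis=1
        )
        groups = pd.Series({c: "g" for c in doubled.columns})
        scores, _ = pca_scores(QuantMatrix(doubled, groups), 2)
        for c in frame.columns:
            assert scores.loc[c, ["PC1", "PC2"]].to_numpy() == pytest.approx(
                scores.loc[c + "_dup", ["PC1", "PC2"]].to_numpy()
            )

    def test_deterministic_sign_convention(self, rng):
        frame = pd.DataFrame(
            rng.normal(0, 1, size=(20, 8)),
            index=[f"F{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(8)],
        )
        matrix = QuantMatrix(
            frame, pd.Series({f"s{i}": "g" for i in range(8)})
        )
        first, _ = pca_scores(matrix, 3)
        second, _ = pca_scores(matrix, 3)
        pd.testing.assert_frame_equal(first, second)

    def test_too_many_components_rejected(self):
        frame = pd.DataFrame(
            np.ones((5, 3)), columns=["a", "b", "c"]
        )
        matrix = QuantMatrix(
            frame, pd.Series({"a": "g", "b": "g", "c": "g"})
        )
        with pytest.raises(ValidationError):
            pca_scores(matrix, 4)


class TestTreatmentComparison:
    def _matrices(self, site_effect, rng):
        n = 15
        samples = [f"ctl{i}" for i in range(n)] + [
            f"trt{i}" for i in range(n)
        ]
        groups = pd.Series(
            {s: ("control" if s.startswith("ctl") else "treated")
             for s in samples}
        )
        site_vals = np.concatenate([
            rng.normal(10, 0.5, n), rng.normal(10 + site_effect, 0.5, n)
        ])
        prot_vals = np.concatenate([
            rng.normal(14, 0.5, n), rng.normal(14, 0.5, n)
        ])
        sites = QuantMatrix(
            pd.DataFrame([site_vals], index=["H3-1:K27me3"],
                         columns=samples),
            groups,
            pd.DataFrame({"accession": ["H31_SYN"]},
                         index=["H3-1:K27me3"]),
        )
        proteins = QuantMatrix(
            pd.DataFrame([prot_vals], index=["H31_SYN"], columns=samples),
            groups,
        )
        return sites, proteins

    def test_site_specific_effect_flagged(self, rng):
        sites, proteins = self._matrices(-1.32, rng)
        results = treatment_site_comparison(
            sites, proteins, "control", "treated"
        )
        assert results.loc["H3-1:K27me3", "significant"]
        assert results.loc["H3-1:K27me3", "site_specific"]
        assert not results.loc["H31_SYN", "significant"]

    def test_empty_group_rejected(self, rng):
        sites, proteins = self._matrices(0.0, rng)
        with pytest.raises(ValidationError):
            treatment_site_comparison(
                sites, proteins, "control", "absent"
            )
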