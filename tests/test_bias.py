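import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_gene
from oracles import pearson_oracle
from plastcub import bias
from plastcub.indices import expected_nc
from plastcub.metrics import gene_metrics


def _metrics_frame(**columns):
    n = len(next(iter(columns.values())))
    base = {"gene_id": [f"g{i}" for i in range(n)]}
    base.update(columns)
    return pd.DataFrame(base)


class TestPr2:
    def test_equal_a3_t3_counts_give_center_coordinate(self):
        metrics = gene_metrics([make_gene(["AAA", "AAT", "TAA"], "g0")])
        assert metrics.loc[0, "pr2_at"] == pytest.approx(0.5)

    def test_genome_means_are_unweighted_gene_means(self):
        frame = _metrics_frame(pr2_at=[0.4, 0.6, 0.2], pr2_gc=[0.5, 0.7, 0.6])
        summary = bias.pr2_summary(frame)
        assert summary.mean_at == pytest.approx(0.4)
        assert summary.mean_gc == pytest.approx(0.6)

    def test_quadrant_label_reflects_means(self):
        frame = _metrics_frame(pr2_at=[0.4, 0.45], pr2_gc=[0.45, 0.4])
        assert bias.pr2_summary(frame).quadrant == "T/C bias"

    def test_undefined_coordinate_is_missing_and_skipped_in_means(self):
        frame = _metrics_frame(pr2_at=[0.4, math.nan], pr2_gc=[0.5, math.nan])
        summary = bias.pr2_summary(frame)
        assert summary.mean_at == pytest.approx(0.4)

    def test_hand_counted_two_codon_gene(self):
        # AAA (Lys, A3) + AAT (Asn, T3): one A, one T at synonymous sites
        metrics = gene_metrics([make_gene(["AAA", "AAT", "AAA", "AAT"], "g0")])
        assert metrics.loc[0, "pr2_at"] == pytest.approx(0.5)


class TestNeutrality:
    def test_identity_relation_recovers_slope_one(self):
        x = np.linspace(0.2, 0.5, 10)
        fit = bias.neutrality_fit(_metrics_frame(gc3s=x, gc12=x))
        assert fit.slope == pytest.approx(1.0)
        assert fit.mutation_pct == pytest.approx(100.0)

    def test_constant_gc12_gives_zero_slope_full_selection(self):
        x = np.linspace(0.2, 0.5, 10)
        fit = bias.neutrality_fit(_metrics_frame(gc3s=x, gc12=np.full(10, 0.4)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.selection_pct == pytest.approx(100.0)

    def test_mutation_and_selection_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        fit = bias.neutrality_fit(
            _metrics_frame(gc3s=rng.random(30), gc12=rng.random(30))
        )
        assert fit.mutation_pct + fit.selection_pct == pytest.approx(100.0)

    def test_slope_invariant_under_common_shift(self):
        rng = np.random.default_rng(4)
        x = rng.random(25)
        y = 0.4 * x + 0.1 + rng.normal(0, 0.01, 25)
        f1 = bias.neutrality_fit(_metrics_frame(gc3s=x, gc12=y))
        f2 = bias.neutrality_fit(_metrics_frame(gc3s=x + 0.1, gc12=y + 0.1))
        assert f1.slope == pytest.approx(f2.slope)

    def test_zero_variance_gc3s_raises(self):
        with pytest.raises(ValueError):
            bias.neutrality_fit(
                _metrics_frame(gc3s=[0.3] * 5, gc12=[0.1, 0.2, 0.3, 0.4, 0.5])
            )


class TestNcDeviation:
    def test_gene_on_the_expected_curve_has_zero_deviation(self):
        frame = _metrics_frame(nc=[expected_nc(0.3)], gc3s=[0.3])
        out = bias.nc_deviation(frame)
        assert out.loc[0, "deviation"] == pytest.approx(0.0)
        assert not out.loc[0, "below_curve"]

    def test_selection_pushes_genes_below_the_curve(self):
        from plastcub.synthetic import sample_cds

        genes, _ = sample_cds(30, mean_len=300, theta=0.5, seed=9)
        out = bias.nc_deviation(gene_metrics(genes))
        assert (out["deviation"] < 0).mean() > 0.9


class TestCorrelations:
    def test_self_and_negated_columns(self):
        rng = np.random.default_rng(5)
        x = rng.random(20)
        frame = _metrics_frame(a=x, b=x, c=-x)
        out = bias.correlation_matrix(frame, [("a", "b"), ("a", "c")])
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert out.loc[1, "pearson_r"] == pytest.approx(-1.0)

    def test_agrees_with_covariance_oracle_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x, y = rng.random(15), rng.random(15)
            out = bias.correlation_matrix(_metrics_frame(x=x, y=y), [("x", "y")])
            assert out.loc[0, "pearson_r"] == pytest.approx(
                pearson_oracle(x, y), abs=1e-12
            )

    def test_constant_column_reports_missing_r(self):
        out = bias.correlation_matrix(
            _metrics_frame(x=[1.0] * 5, y=[1, 2, 3, 4, 5]), [("x", "y")]
        )
        assert math.isnan(out.loc[0, "pearson_r"])


class TestPheCall:
    def test_no_variance_means_no_phe_genes(self):
        call = bias.phe_call(_metrics_frame(cai=[0.7] * 5))
        assert call.threshold_cai == pytest.approx(0.7)
        assert (call.per_gene["label"] == "typical").all()

    def test_single_outlier_is_the_only_phe_gene(self):
        # 20 zeros and one 1: z(1) = (1 - 1/21)/sd ~ 4.36 > 2
        call = bias.phe_call(_metrics_frame(cai=[0.0] * 20 + [1.0]))
        assert (call.per_gene["label"] == "PHE").sum() == 1
        assert call.per_gene.loc[20, "label"] == "PHE"
        sd = np.std([0.0] * 20 + [1.0], ddof=1)
        assert call.threshold_cai == pytest.approx(1 / 21 + 2 * sd)

    def test_labels_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(7)
        x = rng.random(40)
        a = bias.phe_call(_metrics_frame(cai=x))
        b = bias.phe_call(_metrics_frame(cai=3.0 * x + 2.0))
        assert (a.per_gene["label"] == b.per_gene["label"]).all()
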