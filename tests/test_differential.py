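"""Loss/gain classification, expression integration and profiles."""

import math

import numpy as np
import pytest

from silencerkit.core import CoverageTrack, GeneModel
from silencerkit.differential import (
    activation_summary,
    classify_h3k27me3_change,
    gene_binned_profile,
    integrate_expression_changes,
    internal_differential_expression,
    quantify_gene_signal,
    region_mark_profiles,
)


class TestGeneBinnedProfile:
    def _gene(self, strand="+"):
        if strand == "+":
            return GeneModel("g1", "chr1", "+", 10_000, 20_000)
        return GeneModel("g1", "chr1", "-", 20_000, 10_000)

    def test_constant_coverage(self):
        track = CoverageTrack()
        track.add_run("chr1", 0, 30_000, 4.0)
        prof = gene_binned_profile(self._gene(), track)
        assert len(prof.values) == 70
        assert np.allclose(prof.values, 4.0)

    def test_minus_strand_is_reverse_of_plus(self):
        track = CoverageTrack()
        for i in range(30):
            track.add_run("chr1", i * 1000, (i + 1) * 1000, float(i))
        plus = gene_binned_profile(self._gene("+"), track)
        minus = gene_binned_profile(self._gene("-"), track)
        assert np.allclose(minus.values, plus.values[::-1])

    def test_step_aligned_to_body(self):
        track = CoverageTrack()
        track.add_run("chr1", 10_000, 20_000, 5.0)
        prof = gene_binned_profile(self._gene(), track, body_bins=50,
                                   flank=2000, flank_bins=10)
        assert np.allclose(prof.values[:10], 0.0)
        assert np.allclose(prof.values[10:60], 5.0)
        assert np.allclose(prof.values[60:], 0.0)


class TestClassifyChange:
    def test_hand_arithmetic_loss(self):
        res = classify_h3k27me3_change({"g1": 4.0}, {"g1": 1.0})
        fc, cls = res["g1"]
        assert fc == pytest.approx(math.log2(1.25 / 4.25))
        assert fc == pytest.approx(-1.7655, abs=1e-3)
        assert cls == "loss"

    def test_equal_signal_stable(self):
        assert classify_h3k27me3_change({"g": 3.0}, {"g": 3.0})["g"][1] == "stable"

    def test_gain(self):
        assert classify_h3k27me3_change({"g": 1.0}, {"g": 10.0})["g"][1] == "gain"

    def test_antisymmetry_swapping_conditions(self, rng):
        normal = {f"g{i}": float(v) for i, v in
                  enumerate(rng.uniform(0, 30, size=200))}
        tumor = {f"g{i}": float(v) for i, v in
                 enumerate(rng.uniform(0, 30, size=200))}
        fwd = classify_h3k27me3_change(normal, tumor)
        rev = classify_h3k27me3_change(tumor, normal)
        swap = {"loss": "gain", "gain": "loss", "stable": "stable"}
        for g in fwd:
            assert rev[g][1] == swap[fwd[g][1]]
            assert rev[g][0] == pytest.approx(-fwd[g][0])

    def test_negative_signal_rejected(self):
        with pytest.raises(Exception):
            classify_h3k27me3_change({"g": -1.0}, {"g": 1.0})


class TestIntegration:
    def _k27(self):
        return {"a": (-2.0, "loss"), "b": (-2.0, "loss"),
                "c": (2.0, "gain"), "d": (0.1, "stable")}

    def test_rule_application(self):
        de = {"a": (2.0, 0.01), "b": (2.0, 0.2), "c": (-2.0, 0.01)}
        calls = {c.gene_id: c for c in integrate_expression_changes(
            self._k27(), {}, {}, de)}
        assert calls["a"].activation_class == "activated"
        assert calls["b"].activation_class == "loss_only"  # FDR gate
        assert calls["c"].activation_class == "silenced"
        assert calls["d"].activation_class == "stable"

    def test_gene_absent_from_de_table_falls_back(self):
        calls = {c.gene_id: c for c in integrate_expression_changes(
            self._k27(), {}, {}, {})}
        assert calls["a"].activation_class == "loss_only"
        assert calls["c"].activation_class == "gain_only"
        assert calls["a"].expr_log2fc is None

    def test_internal_external_round_trip(self, rng, tmp_path):
        # labels from the internal test must match labels from consuming the
        # same test's output as an external DE table
        genes = [f"g{i}" for i in range(40)]
        cn = {g: rng.negative_binomial(50, 0.5, size=9).tolist() for g in genes}
        ct = {g: (rng.negative_binomial(50, 0.5, size=9)
                  * (8 if i < 10 else 1)).tolist()
              for i, g in enumerate(genes)}
        de_internal = internal_differential_expression(cn, ct)
        p = tmp_path / "de.tsv"
        with open(p, "w") as fh:
            fh.write("gene_id\tlog2fc\tfdr\n")
            for g, (fc, fdr) in de_internal.items():
                fh.write(f"{g}\t{fc:.10g}\t{fdr:.10g}\n")
        from silencerkit.io import read_de_table
        k27 = {g: (-2.0, "loss") for g in genes}
        internal = integrate_expression_changes(k27, {}, {}, de_internal)
        external = integrate_expression_changes(k27, {}, {}, read_de_table(p))
        assert [c.activation_class for c in internal] == \
            [c.activation_class for c in external]


class TestActivationSummary:
    def _calls_from_counts(self, n_total=844, n_loss=557, n_gain=155,
                           n_act=208, n_sil=30):
        k27, de = {}, {}
        for i in range(n_total):
            g = f"g{i:04d}"
            if i < n_loss:
                k27[g] = (-2.0, "loss")
                if i < n_act:
                    de[g] = (2.0, 0.01)
            elif i < n_loss + n_gain:
                k27[g] = (2.0, "gain")
                if i < n_loss + n_sil:
                    de[g] = (-2.0, 0.01)
            else:
                k27[g] = (0.0, "stable")
        return integrate_expression_changes(k27, {}, {}, de)

    def test_printed_counts_reproduce_percentages(self):
        s = activation_summary(self._calls_from_counts())
        assert s.pct_loss == 66.0
        assert s.pct_gain == 18.4
        assert s.pct_activated_of_loss == 37.3
        assert s.pct_silenced_of_gain == 19.4

    def test_self_consistency_property(self, rng):
        for _ in range(10):
            n = int(rng.integers(50, 500))
            n_loss = int(rng.integers(0, n))
            n_gain = int(rng.integers(0, n - n_loss))
            n_act = int(rng.integers(0, n_loss + 1))
            n_sil = int(rng.integers(0, n_gain + 1))
            s = activation_summary(self._calls_from_counts(
                n, n_loss, n_gain, n_act, n_sil))
            assert s.pct_loss == round(100 * s.n_loss / s.n_genes, 1)
            assert s.n_loss == n_loss and s.n_activated == n_act
            assert s.n_genes == n

    def test_all_stable(self):
        s = activation_summary(self._calls_from_counts(100, 0, 0, 0, 0))
        assert s.pct_loss == 0.0 and s.pct_activated_of_loss == 0.0

    def test_shift_test_and_cumulative(self):
        calls = self._calls_from_counts(100, 60, 10, 30, 5)
        bg = list(np.random.default_rng(0).normal(0, 0.5, 500))
        s = activation_summary(calls, background_expr_log2fc=bg)
        assert s.shift_test["p_value"] < 1e-6  # activated fc = 2 vs ~N(0,.5)
        assert s.cumulative is not None
        assert s.cumulative["activated_cdf"][-1] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            activation_summary([])


class TestRegionProfiles:
    def _gene(self):
        return GeneModel("g1", "chr1", "+", 20_000, 40_000)

    def test_uniform_methylation_zero_deltas(self):
        g = self._gene()
        meth_n = CoverageTrack(value_bounds=(0, 1))
        meth_t = CoverageTrack(value_bounds=(0, 1))
        for t in (meth_n, meth_t):
            t.add_run("chr1", 0, 60_000, 0.5)
        track = CoverageTrack()
        track.add_run("chr1", 0, 60_000, 1.0)
        res = region_mark_profiles(
            [g], {"h3k4me3": {"normal": track, "tumor": track}},
            methylation={"normal": meth_n, "tumor": meth_t})
        assert res["methylation"]["promoter_delta_mean"] == pytest.approx(0.0)
        assert res["methylation"]["body_delta_mean"] == pytest.approx(0.0)

    def test_body_shift_without_promoter_shift(self):
        g = self._gene()
        meth_n = CoverageTrack(value_bounds=(0, 1))
        meth_n.add_run("chr1", 0, 60_000, 0.5)
        meth_t = CoverageTrack(value_bounds=(0, 1))
        meth_t.add_run("chr1", 0, 22_000, 0.5)       # promoter unchanged
        meth_t.add_run("chr1", 22_000, 40_000, 0.8)  # body shifted
        meth_t.add_run("chr1", 40_000, 60_000, 0.5)
        track = CoverageTrack()
        track.add_run("chr1", 0, 60_000, 1.0)
        res = region_mark_profiles(
            [g], {"h3k4me3": {"normal": track, "tumor": track}},
            methylation={"normal": meth_n, "tumor": meth_t})
        m = res["methylation"]
        assert m["body_delta_mean"] == pytest.approx(0.3)
        assert m["promoter_delta_mean"] == pytest.approx(0.0)
        assert m["body_hyper_without_promoter_hypo"]

    def test_missing_mark_skipped(self, caplog):
        g = self._gene()
        track = CoverageTrack()
        track.add_run("chr1", 0, 60_000, 2.0)
        res = region_mark_profiles(
            [g], {"h3k4me3": {"normal": track, "tumor": None}})
        assert "normal" in res["profiles"]["h3k4me3"]
        assert "tumor" not in res["profiles"]["h3k4me3"]

    def test_profile_orientation_and_length(self):
        gplus = GeneModel("gp", "chr1", "+", 20_000, 40_000)
        track = CoverageTrack()
        track.add_run("chr1", 15_000, 20_000, 9.0)  # upstream of + TSS
        res = region_mark_profiles([gplus],
                                   {"m": {"normal": track}}, n_bins=60)
        prof = res["profiles"]["m"]["normal"]
        assert len(prof) == 60
        # upstream signal concentrates at the 5' end of the profile
        assert np.argmax(prof) < 10


class TestQuantifyGeneSignal:
    def test_body_extension_window(self):
        g = GeneModel("g1", "chr1", "+", 10_000, 20_000)
        treat = CoverageTrack(total_mapped=10_000_000)
        treat.add_run("chr1", 8_000, 22_000, 0.1)  # exactly body +/- 2 kb
        inp = CoverageTrack(total_mapped=10_000_000)
        sig = quantify_gene_signal(g, treat, inp)
        # 1400 read-bases over 14 kb at 10 M -> RPKM = 1400/(14*10) = 10
        assert sig == pytest.approx(10.0)
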