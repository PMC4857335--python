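"""Normalization chain: factor algebra, background arithmetic, missing
filters, ledger bookkeeping, and the lane-rescaling gauge identity."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import gmean

from stromatsp import (
    CodeSet,
    CountMatrix,
    SimulationParams,
    content_factors,
    filter_missing,
    generate_codeset,
    normalize,
    positive_factors,
    simulate_cohort,
    subtract_background,
    tsp_preprocess,
)


def _matrix_from_lanes(codeset, lane_values: dict[str, dict[str, int]],
                       groups=None) -> CountMatrix:
    counts = pd.DataFrame(lane_values)
    counts = counts.loc[[p for p in codeset.annotation.index if p in counts.index]]
    meta = pd.DataFrame({
        "binding_density": 1.0, "fov_counted": 280, "fov_attempted": 280,
        "group": groups if groups is not None else "unknown",
    }, index=counts.columns)
    return CountMatrix(counts, codeset, meta)


def _controls_cohort(pos_per_lane: dict[str, int], neg: int = 0) -> CountMatrix:
    """Cohort whose positive probes are constant within each lane."""
    cs = generate_codeset(1, 0)
    lanes = {}
    for lane, c in pos_per_lane.items():
        lanes[lane] = {**{p: c for p in cs.positive},
                       **{n: neg for n in cs.negative},
                       "GENE_001": 100}
    return _matrix_from_lanes(cs, lanes)


class TestPositiveFactors:
    def test_hand_geometric_means(self):
        cm = _controls_cohort({"L1": 50, "L2": 200})  # (c, 4c) -> G = 2c
        factors, ok = positive_factors(cm)
        assert factors["L1"] == pytest.approx(2.0)
        assert factors["L2"] == pytest.approx(0.5)
        assert ok.all()

    def test_identical_lanes_give_unit_factors(self):
        cm = _controls_cohort({"L1": 80, "L2": 80, "L3": 80})
        factors, _ = positive_factors(cm)
        assert np.allclose(factors, 1.0)

    def test_out_of_range_factor_flagged(self):
        # nine lanes at c, one dim lane at c/4^(10/9) -> its factor ~3.5
        lanes = {f"L{i}": 100 for i in range(9)}
        lanes["DIM"] = int(round(100 / 3.5 ** (10 / 9)))
        cm = _controls_cohort(lanes)
        factors, ok = positive_factors(cm)
        assert factors["DIM"] > 3.0
        assert not ok["DIM"]
        assert ok.drop("DIM").all()

    def test_zero_positive_count_names_lane(self):
        cm = _controls_cohort({"L1": 50, "BAD": 0})
        with pytest.raises(ValueError, match="BAD"):
            positive_factors(cm)

    @pytest.mark.parametrize("seed", range(5))
    def test_geometric_mean_of_factors_is_one(self, codeset, seed):
        cm, _ = simulate_cohort(codeset, SimulationParams(seed=seed))
        factors, _ = positive_factors(cm)
        assert gmean(factors.to_numpy()) == pytest.approx(1.0, abs=1e-12)


class TestBackground:
    def test_mean_of_negatives_subtracted(self):
        cs = generate_codeset(2, 0)
        lane = {**dict(zip(cs.negative, [4, 6, 8, 2, 4, 6, 8, 2])),
                **{p: 1000 for p in cs.positive},
                "GENE_001": 12, "GENE_002": 3}
        cm = _matrix_from_lanes(cs, {"L1": lane})
        corrected, missing, background = subtract_background(cm.counts, cs)
        assert background["L1"] == 5.0
        assert corrected.at["GENE_001", "L1"] == 7.0
        assert corrected.at["GENE_002", "L1"] == 0.0  # floored at zero
        assert bool(missing.at["GENE_002", "L1"])
        assert not missing.at["GENE_001", "L1"]

    def test_zero_background_leaves_positive_counts_unmasked(self):
        cs = generate_codeset(2, 0)
        lane = {**{n: 0 for n in cs.negative}, **{p: 1000 for p in cs.positive},
                "GENE_001": 12, "GENE_002": 3}
        cm = _matrix_from_lanes(cs, {"L1": lane})
        corrected, missing, _ = subtract_background(cm.counts, cs)
        assert corrected.at["GENE_001", "L1"] == 12.0
        assert not missing.any().any()


class TestContentFactors:
    def test_identical_lanes_unit_factors(self):
        vals = pd.DataFrame(np.tile(np.arange(1, 101.0)[:, None], 3),
                            columns=["L1", "L2", "L3"])
        factors, ok = content_factors(vals, top_n=75)
        assert np.allclose(factors, 1.0)
        assert ok.all()

    def test_doubled_lane_hand_factors(self):
        base = np.arange(1, 101.0)
        vals = pd.DataFrame({"L1": base, "L2": 2 * base})
        factors, _ = content_factors(vals, top_n=75)
        assert factors["L1"] == pytest.approx(np.sqrt(2))
        assert factors["L2"] == pytest.approx(1 / np.sqrt(2))

    def test_out_of_range_factor_flagged(self):
        base = np.arange(1, 101.0)
        lanes = {f"L{i}": base for i in range(8)}
        lanes["BRIGHT"] = 20 * base
        factors, ok = content_factors(pd.DataFrame(lanes), top_n=75)
        assert factors["BRIGHT"] < 0.1
        assert not ok["BRIGHT"]
        assert ok.drop("BRIGHT").all()

    def test_sparse_lane_unevaluable(self):
        base = np.arange(1, 101.0)
        sparse = np.zeros(100)
        sparse[:10] = 5.0
        factors, ok = content_factors(pd.DataFrame({"L1": base, "L2": base,
                                                    "SPARSE": sparse}), top_n=75)
        assert np.isnan(factors["SPARSE"])
        assert not ok["SPARSE"]

    @pytest.mark.parametrize("seed", range(5))
    def test_geometric_mean_of_factors_is_one(self, codeset, seed):
        cm, _ = simulate_cohort(codeset, SimulationParams(seed=100 + seed))
        corrected, _, _ = subtract_background(cm.counts.astype(float), codeset)
        factors, ok = content_factors(corrected)
        assert gmean(factors[ok].to_numpy()) == pytest.approx(1.0, abs=1e-12)


def _hand_missing_fixture():
    """3 genes x 4 samples whose survivor sets differ between filter orders."""
    values = pd.DataFrame(1.0, index=["g1", "g2", "g3"],
                          columns=["s1", "s2", "s3", "s4"])
    missing = pd.DataFrame(False, index=values.index, columns=values.columns)
    missing.loc["g1", ["s1", "s2", "s3"]] = True
    missing.loc["g2", "s1"] = True
    values[missing] = 0.0
    return values, missing


class TestFilterMissing:
    def test_sample_exceeding_half_removed(self):
        values = pd.DataFrame(1.0, index=list("abcd"), columns=list("wxyz"))
        missing = pd.DataFrame(False, index=values.index, columns=values.columns)
        missing.loc[["a", "b", "c"], "w"] = True  # 3/4 > 0.5
        out = filter_missing(values, missing)
        assert out.excluded("sample") == ["w"]
        assert "w" not in out.values.columns

    def test_second_pass_on_remaining_matrix(self):
        # after removing the bad sample, a gene missing 2/3 remaining goes too
        values = pd.DataFrame(1.0, index=list("abc"), columns=list("wxyz"))
        missing = pd.DataFrame(False, index=values.index, columns=values.columns)
        missing.loc[["a", "b"], "w"] = True
        missing.loc["a", ["x", "y"]] = True
        out = filter_missing(values, missing)
        assert out.excluded("sample") == ["w"]
        assert out.excluded("gene") == ["a"]

    def test_filter_orders_verified_against_hand_enumeration(self):
        values, missing = _hand_missing_fixture()
        stg = filter_missing(values, missing, order="samples_then_genes")
        assert list(stg.values.index) == ["g2", "g3"]
        assert list(stg.values.columns) == ["s2", "s3", "s4"]
        gts = filter_missing(values, missing, order="genes_then_samples")
        assert list(gts.values.index) == ["g2", "g3"]
        assert list(gts.values.columns) == ["s1", "s2", "s3", "s4"]

    def test_empty_after_filtering_raises(self):
        values = pd.DataFrame(0.0, index=["g1"], columns=["s1"])
        missing = pd.DataFrame(True, index=["g1"], columns=["s1"])
        with pytest.raises(RuntimeError, match="empty after filtering"):
            filter_missing(values, missing)

    def test_unknown_order_rejected(self):
        values, missing = _hand_missing_fixture()
        with pytest.raises(ValueError, match="order"):
            filter_missing(values, missing, order="diagonal")


class TestNormalizeChain:
    def test_equals_manual_composition(self, default_cohort):
        cm, _ = default_cohort
        auto = normalize(cm)
        pos_f, _ = positive_factors(cm)
        corrected, missing, _ = subtract_background(cm.counts.mul(pos_f, axis=1),
                                                    cm.codeset)
        cont_f, _ = content_factors(corrected)
        manual = filter_missing(corrected.mul(cont_f, axis=1), missing)
        pd.testing.assert_frame_equal(auto.values, manual.values)

    def test_planted_scaling_inverted_exactly(self):
        """A noiseless cohort whose lanes are integer multiples of one base
        profile normalizes to identical per-gene lane profiles."""
        cs = generate_codeset(80, 0)
        base = {**{g: 8 * (i + 2) for i, g in enumerate(cs.endogenous)},
                **{p: 400 * (j + 1) for j, p in enumerate(cs.positive)},
                **{n: 0 for n in cs.negative}}
        lanes = {f"L{k}": {probe: v * f for probe, v in base.items()}
                 for k, f in enumerate([1, 2, 4])}
        cm = _matrix_from_lanes(cs, lanes)
        out = normalize(cm)
        spread = out.values.max(axis=1) - out.values.min(axis=1)
        assert (spread < 1e-9 * out.values.max(axis=1)).all()

    def test_planted_bright_lane_lands_in_ledger(self, codeset):
        cm, _ = simulate_cohort(codeset, SimulationParams(seed=11, dropout_prob=0.0))
        counts = cm.counts.copy()
        lane = cm.lanes[3]
        content = codeset.content_probes
        counts.loc[content, lane] = counts.loc[content, lane] * 20
        bright = CountMatrix(counts, codeset, cm.lane_meta.copy())
        out = normalize(bright)
        entries = [e for e in out.ledger if e["name"] == str(lane)]
        assert len(entries) == 1
        assert "content factor" in entries[0]["reason"]
        assert lane not in out.values.columns

    def test_planted_dead_entities_listed_exactly(self, codeset):
        cm, _ = simulate_cohort(codeset, SimulationParams(
            seed=13, dropout_prob=0.0, baseline_log2=8.0))
        counts = cm.counts.copy()
        dead_gene, dead_lane = "GENE_042", cm.lanes[5]
        counts.loc[dead_gene] = 0
        n_kill = int(0.6 * len(codeset.content_probes))
        counts.loc[codeset.content_probes[:n_kill], dead_lane] = 0
        out = normalize(CountMatrix(counts, codeset, cm.lane_meta.copy()))
        assert out.excluded("gene") == [dead_gene]
        assert out.excluded("sample") == [str(dead_lane)]

    def test_lane_rescaling_gauge_identity(self, default_cohort):
        """Multiplying one lane's raw counts by c shifts the normalized
        matrix by exactly the single global constant c**(1/L); all ratios
        between entries are unchanged."""
        cm, _ = default_cohort
        ref = normalize(cm)
        counts = cm.counts.copy()
        # dimmest lane has the largest factor; doubling keeps it in range
        lane = positive_factors(cm)[0].idxmax()
        counts[lane] = counts[lane] * 2  # integer c keeps counts exact
        scaled = CountMatrix(counts, cm.codeset, cm.lane_meta.copy())
        out = normalize(scaled)
        gauge = 2.0 ** (1.0 / len(cm.lanes))
        pd.testing.assert_frame_equal(out.values, ref.values * gauge,
                                      check_exact=False, rtol=1e-9)
        pd.testing.assert_frame_equal(out.missing, ref.missing)

    def test_ledger_conservation(self, codeset):
        for seed in range(3):
            cm, _ = simulate_cohort(codeset, SimulationParams(
                seed=seed, dropout_prob=0.3, background_lambda=8.0))
            out = normalize(cm)
            n_genes_in = len(codeset.content_probes)
            n_lanes_in = len(cm.lanes)
            assert n_genes_in == out.values.shape[0] + len(out.excluded("gene"))
            assert n_lanes_in == out.values.shape[1] + len(out.excluded("sample"))


class TestTspPreprocess:
    def test_background_only_no_rescaling(self, default_cohort):
        cm, _ = default_cohort
        out = tsp_preprocess(cm)
        corrected, _, _ = subtract_background(cm.counts.astype(float), cm.codeset)
        common = out.values.index
        pd.testing.assert_frame_equal(out.values,
                                      corrected.loc[common, out.values.columns])
        assert out.factors.positive is None
        assert out.factors.content is None

    def test_genes_filtered_before_samples(self, codeset):
        cm, _ = simulate_cohort(codeset, SimulationParams(seed=21, dropout_prob=0.0))
        counts = cm.counts.copy()
        counts.loc["GENE_007"] = 0
        out = tsp_preprocess(CountMatrix(counts, codeset, cm.lane_meta.copy()))
        gene_steps = [e["step"] for e in out.ledger if e["axis"] == "gene"]
        sample_steps = [e["step"] for e in out.ledger if e["axis"] == "sample"]
        assert all(s == 1 for s in gene_steps)
        assert all(s == 2 for s in sample_steps)
        assert "GENE_007" in out.excluded("gene")
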