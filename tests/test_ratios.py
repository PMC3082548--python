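import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyeswapde import (
    PairRatios,
    PipelineError,
    concordance_filter,
    lowess_normalize,
    orient_and_collapse,
    pair_ratios,
    pattern_consistency_filter,
    summarize_patient,
)
from dyeswapde.ratios import (
    STATUS_CONCORDANCE,
    STATUS_KEPT,
    STATUS_MISSING,
    STATUS_PATTERN,
    RatioMatrix,
    build_ratio_matrix,
)

from conftest import make_design, make_normalized


def make_pair(o1, o2, genes=None, pair_id="pair1", patient_id="PT1"):
    genes = genes or [f"g{i}" for i in range(len(o1))]
    table = pd.DataFrame({"o1": o1, "o2": o2},
                         index=pd.Index(genes, name="gene_id"))
    table["delta"] = table["o1"] - table["o2"]
    return PairRatios(pair_id=pair_id, patient_id=patient_id, table=table)


class TestOrientAndCollapse:
    @pytest.mark.parametrize(
        "orientation_slide, expected",
        [("slide1", 1.1), ("slide2", -1.1)],
    )
    def test_duplicates_average_with_orientation_sign(self, orientation_slide,
                                                      expected):
        norm = make_normalized(orientation_slide, ["gA", "gA"], [1.0, 1.2])
        out = orient_and_collapse(
            {orientation_slide: norm}, _single(make_design(1),
                                               orientation_slide))
        assert out.loc["gA", orientation_slide] == pytest.approx(expected)

    def test_flagged_duplicate_is_ignored(self):
        norm = make_normalized("slide1", ["gA", "gA"], [0.8, 5.0],
                               outlier=[False, True])
        out = orient_and_collapse({"slide1": norm}, _single(make_design(1),
                                                            "slide1"))
        assert out.loc["gA", "slide1"] == pytest.approx(0.8)

    def test_gene_missing_when_all_spots_flagged(self):
        norm = make_normalized("slide1", ["gA", "gA", "gB", "gB"],
                               [0.8, 1.0, 0.5, 0.6],
                               low=[True, True, False, False])
        out = orient_and_collapse({"slide1": norm}, _single(make_design(1),
                                                            "slide1"))
        assert np.isnan(out.loc["gA", "slide1"])
        assert out.loc["gB", "slide1"] == pytest.approx(0.55)

    def test_missing_slide_is_an_error(self):
        with pytest.raises(PipelineError, match="missing"):
            orient_and_collapse({}, make_design(1))


def _single(design, slide_id):
    """Single-slide design view that keeps orientation lookup intact."""
    view = design.data[design.data["slide_id"] == slide_id]

    class _View:
        slide_ids = list(view["slide_id"])
        data = view

        def orientation_sign(self, sid):
            return 1 if view["orientation"].iloc[0] == "patient_in_ch1" else -1

    return _View()


class TestConcordanceFilter:
    def test_identical_replicates_always_retained(self):
        pair = concordance_filter(make_pair([1.0, 0.2, -0.3], [1.0, 0.1, -0.2]))
        assert pair.table.loc["g0", "concordant"]

    def test_exactly_the_planted_outlier_is_removed(self):
        """Oracle: recompute mean/SD (outlier included) and apply the rule."""
        rng = np.random.default_rng(0)
        o1 = rng.normal(0, 1, 1001)
        o2 = o1 - rng.normal(0, 0.1, 1001)
        o2[500] = o1[500] - 10.0
        pair = concordance_filter(make_pair(o1, o2), k_sd=3.0)

        delta = o1 - o2
        expected_bad = np.abs(delta - delta.mean()) > 3 * delta.std(ddof=1)
        assert expected_bad.sum() == 1 and expected_bad[500]
        flagged = ~pair.table["concordant"].to_numpy()
        np.testing.assert_array_equal(flagged, expected_bad)

    def test_zero_sd_keeps_everything(self):
        pair = concordance_filter(make_pair([1.0, 2.0, 3.0], [0.5, 1.5, 2.5]))
        assert pair.table["concordant"].all()

    def test_fewer_than_two_defined_deltas_is_an_error(self):
        pair = make_pair([1.0, np.nan], [0.5, 0.2])
        with pytest.raises(PipelineError, match="SD undefined"):
            concordance_filter(pair)


class TestSummarizePatient:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [(2.0, 8.0, 2.0), (0.5, 2.0, 0.0), (1.0, 1.0, 0.0)],
    )
    def test_geometric_mean_of_ratios(self, r1, r2, expected):
        pair = concordance_filter(
            make_pair([np.log2(r1), 0.1, -0.1], [np.log2(r2), 0.1, -0.1]))
        value = summarize_patient(pair)
        assert value.iloc[0] == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=6))
    def test_log_mean_equals_geometric_mean(self, ratios):
        """exp2(mean log2 r) == (prod r)^(1/n) to floating tolerance."""
        logs = np.log2(ratios)
        gm = float(np.prod(ratios)) ** (1.0 / len(ratios))
        assert 2.0 ** logs.mean() == pytest.approx(gm, rel=1e-9)


class TestPatternConsistency:
    @pytest.mark.parametrize(
        "values, expected_status",
        [
            ((0.4, 1.1, 0.2, 0.9), STATUS_KEPT),
            ((-0.4, -1.1, -0.2, -0.9), STATUS_KEPT),
            ((0.4, 1.1, -0.2, 0.9), STATUS_PATTERN),
            ((0.4, 0.0, 0.2, 0.9), STATUS_PATTERN),
        ],
    )
    def test_sign_agreement_rule(self, values, expected_status):
        matrix = RatioMatrix(
            values=pd.DataFrame([values], index=["gX"],
                                columns=["PT1", "PT2", "PT3", "PT4"]),
            status=pd.Series([STATUS_KEPT], index=["gX"]),
        )
        out = pattern_consistency_filter(matrix)
        assert out.status["gX"] == expected_status


class TestFilterChain:
    def test_dye_swap_symmetry(self, clean_experiment):
        """Swapping the channel columns of both slides of a pair while
        flipping the orientation labels leaves oriented ratios unchanged."""
        _, slides, design, _ = clean_experiment
        norm = {s.slide_id: lowess_normalize(s) for s in slides}
        oriented = orient_and_collapse(norm, design)

        swapped_slides = []
        for s in slides:
            df = s.data.rename(columns={
                "ch1_fg": "ch2_fg", "ch2_fg": "ch1_fg",
                "ch1_bg": "ch2_bg", "ch2_bg": "ch1_bg",
            })[s.data.columns]
            swapped_slides.append(type(s)(slide_id=s.slide_id, data=df))
        flipped = design.data.copy()
        flipped["orientation"] = flipped["orientation"].map({
            "patient_in_ch1": "patient_in_ch2",
            "patient_in_ch2": "patient_in_ch1",
        })
        design2 = type(design)(data=flipped)
        norm2 = {s.slide_id: lowess_normalize(s) for s in swapped_slides}
        oriented2 = orient_and_collapse(norm2, design2)
        pd.testing.assert_frame_equal(oriented, oriented2)

    def test_statuses_partition_and_chain_is_monotone(self, small_experiment):
        _, slides, design, _ = small_experiment
        norm = {s.slide_id: lowess_normalize(s) for s in slides}
        oriented = orient_and_collapse(norm, design)
        pairs = [concordance_filter(p) for p in pair_ratios(oriented, design)]
        matrix = build_ratio_matrix(pairs,
                                    [summarize_patient(p) for p in pairs])
        after = pattern_consistency_filter(matrix)

        statuses = set(after.status.unique())
        assert statuses <= {STATUS_KEPT, STATUS_CONCORDANCE, STATUS_MISSING,
                            STATUS_PATTERN}
        survivors_concordance = set(
            after.status.index[~after.status.eq(STATUS_CONCORDANCE)])
        survivors_missing = survivors_concordance - set(
            after.status.index[after.status.eq(STATUS_MISSING)])
        kept = set(after.kept.index)
        assert kept <= survivors_missing <= survivors_concordance
        # every kept gene has a finite value for every patient, same sign
        signs = np.sign(after.kept.to_numpy())
        assert np.isfinite(after.kept.to_numpy()).all()
        assert (np.abs(signs.sum(axis=1)) == signs.shape[1]).all()
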