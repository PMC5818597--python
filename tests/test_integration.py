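import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iscpipe.integration import (DEFAULT_SCALING_GROUPS, ENDPOINT_TECHNIQUES,
                                 ENDPOINTS, EndpointFoldChange, ISCProfile,
                                 assign_weights, build_profile, compute_isc,
                                 fold_at_dose, rank_chemicals, render_profile,
                                 transform_fold)

folds_strategy = st.floats(min_value=0.01, max_value=100.0)


class TestAssignWeights:
    def test_standard_panel_weights(self):
        w = assign_weights()
        assert w["MN"] == 3.0
        assert w["seahorse"] == 3.0
        assert w["cell_area"] == w["nuclear_area"] == 1.5
        assert w["p53"] == w["phospho_p53"] == 1.5
        for e in ("CDKN1A", "CHKA", "SGK1", "G1", "S", "G2"):
            assert w[e] == 1.0

    def test_every_technique_carries_equal_total_weight(self):
        w = assign_weights()
        totals = {}
        for e, t in ENDPOINT_TECHNIQUES.items():
            totals[t] = totals.get(t, 0.0) + w[e]
        assert len(set(totals.values())) == 1
        assert next(iter(totals.values())) == 3.0

    def test_all_single_endpoint_techniques_give_unit_weights(self):
        w = assign_weights({"a": "t1", "b": "t2", "c": "t3"})
        assert all(v == 1.0 for v in w.values())

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            assign_weights({})


class TestTransformFold:
    def test_square_root_applied(self):
        assert transform_fold(4.0, "CDKN1A") == 2.0

    def test_down_regulation_inverted_before_root(self):
        assert transform_fold(0.25, "CDKN1A") == 2.0

    def test_area_endpoints_exempt_from_root(self):
        assert transform_fold(2.0, "cell_area") == 2.0
        assert transform_fold(0.5, "nuclear_area") == 2.0

    def test_non_positive_fold_rejected(self):
        with pytest.raises(ValueError):
            transform_fold(0.0, "MN")

    @given(fold=folds_strategy, endpoint=st.sampled_from(ENDPOINTS))
    @settings(max_examples=200, deadline=None)
    def test_inversion_symmetry(self, fold, endpoint):
        """fold f and 1/f give identical slice values for every endpoint."""
        assert transform_fold(fold, endpoint) == pytest.approx(
            transform_fold(1.0 / fold, endpoint))

    @given(fold=folds_strategy, endpoint=st.sampled_from(ENDPOINTS))
    @settings(max_examples=100, deadline=None)
    def test_slice_value_never_below_baseline(self, fold, endpoint):
        assert transform_fold(fold, endpoint) >= 1.0 - 1e-12


class TestComputeISC:
    def test_all_unit_folds_give_panelwide_baseline(self):
        slices = {e: transform_fold(1.0, e) for e in ENDPOINTS}
        # sum of weights: 3 + 3 + 4 x 1.5 + 6 x 1 = 18
        assert compute_isc(slices) == pytest.approx(18.0)

    def test_increasing_any_fold_increases_total(self):
        base = {e: 1.0 for e in ENDPOINTS}
        t0 = compute_isc({e: transform_fold(f, e) for e, f in base.items()})
        for e in ENDPOINTS:
            bumped = dict(base, **{e: 2.5})
            t1 = compute_isc({k: transform_fold(f, k) for k, f in bumped.items()})
            assert t1 > t0

    @given(folds=st.lists(folds_strategy, min_size=len(ENDPOINTS),
                          max_size=len(ENDPOINTS)))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_weighted_sum(self, folds):
        """Independent summation oracle on random 12-endpoint profiles."""
        w = assign_weights()
        slices = {e: transform_fold(f, e) for e, f in zip(ENDPOINTS, folds)}
        total = compute_isc(slices, w)
        oracle = 0.0
        for e, f in zip(ENDPOINTS, folds):
            fp = f if f >= 1 else 1 / f
            s = fp if e in ("cell_area", "nuclear_area") else fp**0.5
            oracle += w[e] * s
        assert total == pytest.approx(oracle)

    def test_incomplete_slice_set_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compute_isc({"MN": 2.0})

    def test_rank_invariance_under_common_scale(self):
        rng = np.random.default_rng(5)
        panel = {f"chem{i}": rng.uniform(0.2, 5, size=len(ENDPOINTS))
                 for i in range(6)}
        def scores(scale):
            gs = {g: scale for g in ("major", "cellular", "molecular")}
            return {
                c: compute_isc({e: transform_fold(f, e, group_scales=gs)
                                for e, f in zip(ENDPOINTS, fs)})
                for c, fs in panel.items()
            }
        r1 = rank_chemicals(scores(1.0))
        r2 = rank_chemicals(scores(7.3))
        assert list(r1.chemical) == list(r2.chemical)
        assert list(r1["rank"]) == list(r2["rank"])


class TestRankChemicals:
    def test_descending_dense_ranks(self):
        r = rank_chemicals({"MNU": 60.2, "H2O2": 52.7, "TCDD": 42.3})
        assert list(r.chemical) == ["MNU", "H2O2", "TCDD"]
        assert list(r["rank"]) == [1, 2, 3]

    def test_ties_share_rank_with_deterministic_order(self):
        r = rank_chemicals({"b": 10.0, "a": 10.0, "c": 5.0})
        assert list(r.chemical) == ["a", "b", "c"]
        assert list(r["rank"]) == [1, 1, 2]


class TestFoldAtDose:
    def test_tested_dose_returned_exactly(self):
        assert fold_at_dose([0, 1, 10, 100], [1, 1.2, 2.0, 3.0], 10.0) == 2.0

    def test_log_dose_interpolation_between_brackets(self):
        # halfway between 10 and 100 on the log axis
        f = fold_at_dose([0, 10, 100], [1.0, 2.0, 4.0], 10**1.5)
        assert f == pytest.approx(3.0)

    def test_clamped_outside_ladder(self):
        assert fold_at_dose([0, 10, 100], [1.0, 2.0, 4.0], 500.0) == 4.0


class TestProfiles:
    def _fcs(self, fold=2.0):
        return [EndpointFoldChange("x", e, fold, 50.0, "interpolated_50pct")
                for e in ENDPOINTS]

    def test_profile_total_is_sum_of_weighted_slices(self):
        p = build_profile(self._fcs())
        assert p.total == pytest.approx(
            sum(p.weights[e] * p.slices[e] for e in ENDPOINTS))

    def test_missing_endpoint_never_raises_score(self):
        fcs = self._fcs()
        fcs[0] = EndpointFoldChange("x", "MN", 1.0, 50.0,
                                    "interpolated_50pct", missing=True)
        observed_at_1 = list(fcs)
        observed_at_1[0] = EndpointFoldChange("x", "MN", 1.0, 50.0,
                                              "interpolated_50pct")
        assert build_profile(fcs).total <= build_profile(observed_at_1).total

    def test_json_round_trip(self):
        p = build_profile(self._fcs(1.7))
        p.rank = 3
        q = ISCProfile.from_json(p.to_json())
        assert q == p

    def test_angular_widths_proportional_to_weights(self):
        w = assign_weights()
        widths = 2 * np.pi * np.array(list(w.values())) / sum(w.values())
        assert widths.sum() == pytest.approx(2 * np.pi)
        # 3 : 1.5 : 1 ratios carry through
        assert w["MN"] / w["CDKN1A"] == pytest.approx(3.0)
        assert w["cell_area"] / w["CDKN1A"] == pytest.approx(1.5)

    def test_render_writes_svg(self, tmp_path):
        p = build_profile(self._fcs(2.4))
        out = tmp_path / "profile.svg"
        render_profile(p, str(out))
        content = out.read_text()
        assert content.lstrip().startswith("<?xml")
        assert "svg" in content
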