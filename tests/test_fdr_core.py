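"""Score-grid construction, lFDR formula, priors and thresholding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from newance.fdr_core import (
    DegenerateScoreError,
    build_score_grid,
    build_score_grid_arrays,
    estimate_group_priors,
    lfdr,
    run_newance_fdr,
    select_threshold,
    stratify_by_charge,
)
from newance.io_formats import Group, PsmRecord
from newance.synth import config_for_total, simulate_psms

from oracles import oracle_box_mean, oracle_pipeline_lfdr, oracle_threshold


def _psm(key, charge=2, xcorr=1.0, delta_cn=0.1, sp_score=10.0, decoy=False,
         group=Group.proteome):
    return PsmRecord(
        spectrum_key=key, peptide="PEPTIDEK", charge=charge, xcorr=xcorr,
        delta_cn=delta_cn, sp_score=sp_score, protein_ids=("P",),
        is_decoy=decoy, group=group,
    )


class TestStratify:
    def test_partition_by_charge(self):
        psms = [_psm(f"s{z}", charge=z) for z in (1, 2, 3, 4, 5)]
        strata = stratify_by_charge(psms)
        assert {k: len(v) for k, v in strata.items()} == {"Z1": 1, "Z2": 1, "Z3plus": 3}

    def test_single_charge_leaves_others_empty(self):
        strata = stratify_by_charge([_psm(f"s{i}") for i in range(4)])
        assert len(strata["Z2"]) == 4 and not strata["Z1"] and not strata["Z3plus"]

    def test_empty_input(self):
        strata = stratify_by_charge([])
        assert all(v == [] for v in strata.values())


class TestBuildScoreGrid:
    def test_raw_counting_rule(self):
        # all 12 PSMs fall in the same cell of a 2-bin grid; one spread PSM
        # per corner fixes the range
        psms = [_psm(f"t{i}", xcorr=3.0, delta_cn=0.8, sp_score=100.0) for i in range(10)]
        psms += [_psm(f"d{i}", xcorr=3.0, delta_cn=0.8, sp_score=100.0, decoy=True) for i in range(2)]
        psms += [_psm("lo", xcorr=0.0, delta_cn=0.0, sp_score=0.0)]
        grid = build_score_grid(psms, bins=2, smooth=False)
        assert grid.n0[1, 1, 1] == 2
        assert grid.n1[1, 1, 1] == 8

    def test_uniform_counts_unchanged_by_smoothing(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, size=(4000, 3))
        grid_s = build_score_grid_arrays(scores, np.zeros(4000, bool), bins=3, smooth=True)
        # constant array: border-clipped box mean leaves it unchanged
        smoothed = oracle_box_mean(np.full((3, 3, 3), 7.0), 3)
        assert np.allclose(smoothed, 7.0)
        assert np.allclose(grid_s.p1.sum(), 1.0)

    def test_smoothing_matches_bruteforce_box_mean(self):
        rng = np.random.default_rng(42)
        scores = rng.normal(size=(600, 3))
        decoy = rng.random(600) < 0.5
        grid = build_score_grid_arrays(scores, decoy, bins=5, smooth=True)
        raw = build_score_grid_arrays(scores, decoy, bins=5, smooth=False)
        assert np.allclose(grid.n0, oracle_box_mean(raw.n0, 3), rtol=1e-9, atol=1e-12)

    def test_probabilities_normalised(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(2000, 3))
        decoy = rng.random(2000) < 0.4
        grid = build_score_grid_arrays(scores, decoy, bins=6)
        assert grid.p0.sum() == pytest.approx(1.0, abs=1e-9)
        assert grid.p1.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.isfinite(grid.gamma))

    def test_degenerate_dimension_suggests_1d(self):
        psms = [_psm(f"s{i}", xcorr=float(i), delta_cn=0.5, sp_score=float(i)) for i in range(10)]
        with pytest.raises(DegenerateScoreError, match="1D"):
            build_score_grid(psms)

    def test_upper_edge_value_in_last_bin(self):
        scores = np.array([[0.0], [1.0], [2.0]])
        grid = build_score_grid_arrays(scores, np.zeros(3, bool), bins=4, smooth=False)
        assert grid.cell_index(np.array([[2.0]]))[0][0] == 3


class TestLfdrFormula:
    def test_symmetric_case(self):
        assert lfdr(1.0, 1.0) == pytest.approx(0.5)

    def test_pure_noise_cell(self):
        assert lfdr(0.0, 5.0) == 1.0

    def test_direct_substitution(self):
        assert lfdr(9.0, 3.0) == pytest.approx(1.0 / 28.0, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            lfdr(-1.0, 1.0)
        with pytest.raises(ValueError):
            lfdr(1.0, -1.0)

    @given(
        st.floats(1e-6, 1e6), st.floats(1e-6, 1e6), st.floats(min_value=1e-3, max_value=10)
    )
    def test_strictly_decreasing_in_gamma_and_pi(self, gamma, pi, bump):
        assert lfdr(gamma + bump, pi) < lfdr(gamma, pi)
        assert lfdr(gamma, pi + bump) < lfdr(gamma, pi)


class TestGroupPriors:
    def test_target_decoy_estimate(self):
        psms = [_psm(f"t{i}") for i in range(900)] + [
            _psm(f"d{i}", decoy=True) for i in range(100)
        ]
        assert estimate_group_priors(psms).pi_ratio == pytest.approx(8.0)

    def test_all_noise_group_floored_at_zero(self):
        psms = [_psm(f"t{i}") for i in range(100)] + [
            _psm(f"d{i}", decoy=True) for i in range(100)
        ]
        assert estimate_group_priors(psms).pi_ratio == 0.0

    def test_no_decoys_guarded_and_warned(self):
        psms = [_psm(f"t{i}") for i in range(50)]
        with pytest.warns(UserWarning):
            priors = estimate_group_priors(psms)
        assert priors.pi_ratio == 50.0  # denominator floored at one decoy

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="one_group"):
            estimate_group_priors([_psm("t", group=Group.proteome)], group="noncanonical")


class TestSelectThreshold:
    def test_cumulative_mean_enumeration(self):
        values = [0.001] * 97 + [0.9] * 3
        psms = [_psm(f"s{i}") for i in range(100)]
        result = select_threshold(psms, np.array(values), alpha=0.03)
        expected_thr = oracle_threshold(values, 0.03)
        assert result.thresholds["all"] == pytest.approx(expected_thr)
        assert int(result.accepted.sum()) == sum(v <= expected_thr for v in values)
        # the strict-alpha variant genuinely truncates at the cheap prefix
        tight = select_threshold(psms, np.array(values), alpha=0.01)
        assert int(tight.accepted.sum()) == 97

    def test_alpha_one_accepts_all_targets(self):
        psms = [_psm(f"s{i}") for i in range(5)]
        result = select_threshold(psms, np.linspace(0.1, 0.9, 5), alpha=1.0)
        assert int(result.accepted.sum()) == 5

    def test_alpha_below_min_accepts_none(self):
        psms = [_psm(f"s{i}") for i in range(5)]
        with pytest.warns(UserWarning):
            result = select_threshold(psms, np.full(5, 0.5), alpha=0.4)
        assert int(result.accepted.sum()) == 0

    def test_decoys_never_accepted(self):
        psms = [_psm("t"), _psm("d", decoy=True)]
        result = select_threshold(psms, np.array([0.001, 0.001]), alpha=0.5)
        assert result.accepted.tolist() == [True, False]

    def test_achieved_estimate_bounded_by_nominal(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 1, 500)
        psms = [_psm(f"s{i}") for i in range(500)]
        result = select_threshold(psms, values, alpha=0.1)
        assert result.achieved_fdr_estimate["all"] <= 0.1

    def test_acceptance_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 0.5, 300)
        psms = [_psm(f"s{i}") for i in range(300)]
        prev = None
        for alpha in (0.01, 0.05, 0.1, 0.3):
            acc = set(np.nonzero(select_threshold(psms, values, alpha).accepted)[0])
            if prev is not None:
                assert prev <= acc
            prev = acc


class TestRunPipeline:
    def _tiny_dataset(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        psms = []
        for i in range(n):
            group = Group.noncanonical if rng.random() < 0.3 else Group.proteome
            true = rng.random() < (0.3 if group is Group.noncanonical else 0.8)
            decoy = (not true) and rng.random() < 0.5
            loc = 2.5 if true else 1.2
            psms.append(
                _psm(
                    f"s{i}",
                    charge=int(rng.choice([1, 2, 3])),
                    xcorr=float(rng.normal(loc, 0.6)),
                    delta_cn=float(rng.uniform(0, 1)),
                    sp_score=float(rng.normal(loc * 100, 60)),
                    decoy=decoy,
                    group=group,
                )
            )
        return psms

    @pytest.mark.parametrize("grouping", ["one_group", "two_group"])
    @pytest.mark.parametrize("score_dims", [1, 3])
    def test_matches_bruteforce_oracle(self, grouping, score_dims):
        psms = self._tiny_dataset()
        result = run_newance_fdr(
            psms, grouping=grouping, score_dims=score_dims, alpha=0.1, bins=3,
            min_psm_warning=0,
        )
        lfdr_o, accepted_o = oracle_pipeline_lfdr(
            psms, grouping, score_dims, 0.1, 3, True, 3, 0.05, 0.05
        )
        assert np.allclose(result.lfdr, lfdr_o, rtol=1e-9, atol=1e-12)
        assert np.array_equal(result.accepted, accepted_o)

    def test_identical_priors_collapse_modes(self):
        # mirror the dataset into both groups: per-group and pooled running
        # means then coincide, so the two modes accept the same keys
        base = self._tiny_dataset(seed=3)
        mirrored = []
        for r in base:
            for g in (Group.proteome, Group.noncanonical):
                c = PsmRecord(
                    spectrum_key=f"{r.spectrum_key}:{g.value}", peptide=r.peptide,
                    charge=r.charge, xcorr=r.xcorr, delta_cn=r.delta_cn,
                    sp_score=r.sp_score, protein_ids=r.protein_ids,
                    is_decoy=r.is_decoy, group=g,
                )
                mirrored.append(c)
        r1 = run_newance_fdr(mirrored, grouping="one_group", alpha=0.1, bins=3, min_psm_warning=0)
        r2 = run_newance_fdr(mirrored, grouping="two_group", alpha=0.1, bins=3, min_psm_warning=0)
        keys1 = {p.spectrum_key for p in r1.accepted_psms}
        keys2 = {p.spectrum_key for p in r2.accepted_psms}
        assert keys1 == keys2

    def test_group_imbalance_restrains_noncanonical(self):
        data = simulate_psms(config_for_total(30_000, seed=17))
        r2 = run_newance_fdr(data.psms_engineA, grouping="two_group", min_psm_warning=0)
        r1 = run_newance_fdr(data.psms_engineA, grouping="one_group", min_psm_warning=0)
        nc2 = len(r2.accepted_in_group(Group.noncanonical))
        nc1 = len([r for r in r1.accepted_psms if r.group is Group.noncanonical])
        assert nc2 < nc1

    def test_unassigned_group_rejected_in_two_group(self):
        psms = [_psm("s", group=Group.unassigned)]
        with pytest.raises(ValueError, match="group"):
            run_newance_fdr(psms, grouping="two_group", min_psm_warning=0)
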