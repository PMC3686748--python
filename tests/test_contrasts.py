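import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytohier import (
    ChainConfig,
    PosteriorDraws,
    contrast,
    fold_change_from_ct,
    housekeeping_stability_check,
    livak_ddct,
    percent_lower_from_fold,
    relative_expression_table,
)
from cytohier.exceptions import DomainError, OrientationError

finite_ct = st.floats(min_value=5.0, max_value=45.0)


def make_mu_draws(cell_values: dict, scale: str = "ct", noise_sd: float = 0.0,
                  n: int = 4000, seed: int = 5) -> PosteriorDraws:
    rng = np.random.default_rng(seed)
    arrays = {}
    for cell, centre in cell_values.items():
        g, c = cell
        arrays[f"mu[{g},{c}]"] = (
            centre + noise_sd * rng.standard_normal(n)
        ).reshape(1, n)
    cfg = ChainConfig(n_chains=1, n_iter=n, burn_in=0, seeds=(0,))
    return PosteriorDraws(
        draws=arrays, config=cfg, seeds=(0,),
        cells=tuple(cell_values), scale=scale,
    )


class TestFoldChangeFromCt:
    def test_identity_for_equal_ct(self):
        assert fold_change_from_ct(24.0, 24.0) == 1.0

    def test_one_cycle_is_a_doubling(self):
        assert fold_change_from_ct(23.0, 22.0) == pytest.approx(2.0)

    @given(finite_ct, finite_ct)
    def test_reciprocal_property(self, a, b):
        assert fold_change_from_ct(a, b) * fold_change_from_ct(b, a) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            fold_change_from_ct(float("nan"), 22.0)


class TestPercentLower:
    @pytest.mark.parametrize("fold,expected", [(0.5, 50.0), (0.13, 87.0), (0.99, 1.0)])
    def test_arithmetic(self, fold, expected):
        assert percent_lower_from_fold(fold) == pytest.approx(expected)

    def test_fold_of_one_is_an_orientation_error(self):
        with pytest.raises(OrientationError):
            percent_lower_from_fold(1.0)

    def test_increase_is_an_orientation_error(self):
        with pytest.raises(OrientationError):
            percent_lower_from_fold(1.6)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(DomainError):
            percent_lower_from_fold(0.0)


class TestLivakDdct:
    def test_null_case(self):
        assert livak_ddct(20.0, 20.0, 20.0, 20.0) == 1.0

    def test_one_cycle_drop_with_stable_housekeeping_doubles(self):
        assert livak_ddct(21.0, 18.0, 22.0, 18.0) == pytest.approx(2.0)

    @given(finite_ct, finite_ct, finite_ct, finite_ct,
           st.floats(min_value=-5, max_value=5))
    def test_invariant_to_shifting_both_treated_cts(self, t, hk, tc, hkc, k):
        base = livak_ddct(t, hk, tc, hkc)
        assert livak_ddct(t + k, hk + k, tc, hkc) == pytest.approx(base, rel=1e-9)

    @given(finite_ct, finite_ct, finite_ct, finite_ct,
           st.floats(min_value=-5, max_value=5))
    def test_invariant_to_shifting_all_four_cts(self, t, hk, tc, hkc, k):
        base = livak_ddct(t, hk, tc, hkc)
        assert livak_ddct(t + k, hk + k, tc + k, hkc + k) == pytest.approx(
            base, rel=1e-9
        )


class TestContrast:
    def test_self_contrast_is_null(self):
        draws = make_mu_draws(
            {("adult", "Control"): 22.0, ("adult", "LPS"): 21.0}, noise_sd=0.2
        )
        res = contrast(draws, ("adult", "Control"), ("adult", "Control"))
        assert res.delta_mean == 0.0
        assert not res.significant
        assert res.fold == 1.0

    def test_clear_separation_is_significant(self):
        draws = make_mu_draws(
            {("adult", "Control"): 25.0, ("adult", "LPS"): 20.0}, noise_sd=0.3
        )
        res = contrast(draws, ("adult", "Control"), ("adult", "LPS"))
        assert res.significant
        assert res.delta_mean == pytest.approx(5.0, abs=0.1)

    def test_symmetric_delta_is_not_significant(self, rng):
        x = rng.normal(0, 1, 2000)
        arrays = {
            "mu[adult,Control]": np.concatenate([x, -x]).reshape(1, -1),
            "mu[adult,LPS]": np.zeros((1, 4000)),
        }
        cfg = ChainConfig(n_chains=1, n_iter=4000, burn_in=0, seeds=(0,))
        draws = PosteriorDraws(
            draws=arrays, config=cfg, seeds=(0,),
            cells=(("adult", "Control"), ("adult", "LPS")), scale="ct",
        )
        res = contrast(draws, ("adult", "Control"), ("adult", "LPS"))
        assert not res.significant
        assert res.delta_mean == 0.0

    def test_exchanging_cells_flips_sign_but_not_significance(self):
        draws = make_mu_draws(
            {("adult", "Control"): 23.0, ("foal", "Control"): 21.9}, noise_sd=0.25
        )
        ab = contrast(draws, ("adult", "Control"), ("foal", "Control"))
        ba = contrast(draws, ("foal", "Control"), ("adult", "Control"))
        assert ab.significant == ba.significant
        assert ab.delta_mean == pytest.approx(-ba.delta_mean)
        assert ab.lower == pytest.approx(-ba.upper)
        assert ab.fold * ba.fold == pytest.approx(1.0, rel=1e-9)

    def test_ct_fold_orientation_lower_ct_means_higher_expression(self):
        draws = make_mu_draws(
            {("adult", "Control"): 21.0, ("foal", "Control"): 22.0}
        )
        res = contrast(draws, ("adult", "Control"), ("foal", "Control"))
        # adult is one cycle lower -> 2-fold higher expression than foal
        assert res.fold == pytest.approx(2.0)

    def test_log_concentration_fold_is_exp_of_delta(self):
        draws = make_mu_draws(
            {("adult", "LPS"): 7.0, ("foal", "LPS"): 5.0}, scale="log_concentration"
        )
        res = contrast(draws, ("adult", "LPS"), ("foal", "LPS"))
        assert res.fold == pytest.approx(np.exp(2.0))
        inv = contrast(draws, ("foal", "LPS"), ("adult", "LPS"))
        assert inv.percent_lower == pytest.approx(100 * (1 - np.exp(-2.0)))

    def test_unknown_cell_raises_key_error(self):
        draws = make_mu_draws({("adult", "Control"): 22.0})
        with pytest.raises(KeyError):
            contrast(draws, ("adult", "Control"), ("foal", "LPS"))


class TestHousekeepingStability:
    def test_stable_gene_has_no_significant_contrasts(self):
        cells = {
            (g, c): 18.0
            for g in ("adult", "foal")
            for c in ("Control", "LPS", "PCSK", "LPS_PCSK")
        }
        draws = make_mu_draws(cells, noise_sd=0.4)
        report = housekeeping_stability_check({"ACTB_qPCR": draws})
        assert len(report) == 12  # 6 condition pairs per age group
        assert report["significant"].sum() == 0

    def test_shifted_condition_is_detected(self):
        cells = {
            (g, c): 18.0
            for g in ("adult", "foal")
            for c in ("Control", "LPS", "PCSK", "LPS_PCSK")
        }
        cells[("adult", "LPS")] = 14.0
        report = housekeeping_stability_check(
            {"ACTB_qPCR": make_mu_draws(cells, noise_sd=0.3)}
        )
        hits = report[report["significant"]]
        assert set(hits["age_group"]) == {"adult"}
        assert all(
            "LPS" in (row.condition_a, row.condition_b)
            for row in hits.itertuples()
        )
        assert len(hits) == 3

    def test_single_condition_gives_empty_report(self):
        draws = make_mu_draws({("adult", "Control"): 18.0, ("foal", "Control"): 18.0})
        report = housekeeping_stability_check({"ACTB_qPCR": draws})
        assert report.empty


def test_relative_expression_table_reference_row_is_unity():
    cells = {("adult", "Control"): 24.0, ("adult", "LPS"): 22.0}
    table = relative_expression_table(
        make_mu_draws(cells, noise_sd=0.2), ("adult", "Control")
    )
    ref = table[(table["age_group"] == "adult") & (table["condition"] == "Control")]
    assert ref["fold_vs_reference"].iloc[0] == pytest.approx(1.0)
    lps = table[table["condition"] == "LPS"]
    assert lps["fold_vs_reference"].iloc[0] == pytest.approx(4.0, rel=0.1)
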