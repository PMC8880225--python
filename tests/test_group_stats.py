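"""One-way ANOVA and Duncan letters, checked against independent oracles."""

import math
import warnings

import pytest
from scipy import stats

from seedqual import duncan_mrt, from_summary, one_way_anova
from seedqual.group_stats import GroupedMeasurements
from seedqual.model import ValidationError

B, H = "Bialobrzeskie", "Henola"


def _gm(groups, analyte="x", alpha=0.05):
    return GroupedMeasurements(analyte=analyte, groups=groups, alpha=alpha)


# ---------------------------------------------------------------------------
# ANOVA against scipy's independent implementation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "groups",
    [
        {B: [1.78, 2.02, 2.26], H: [4.23, 4.48, 4.73]},  # clearly separated
        {B: [22.95, 23.54, 24.13], H: [23.01, 23.39, 23.77]},  # overlapping
        {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.0, 4.0], "g3": [10.0, 11.0, 9.0]},
    ],
)
def test_anova_matches_scipy(groups):
    res = one_way_anova(_gm(groups))
    f_ref, p_ref = stats.f_oneway(*groups.values())
    assert res.f == pytest.approx(f_ref, rel=1e-10)
    assert res.p == pytest.approx(p_ref, rel=1e-10)


def test_anova_verdicts_on_summary_rows():
    sig = one_way_anova(_gm({B: [1.78, 2.02, 2.26], H: [4.23, 4.48, 4.73]}))
    assert sig.p < 0.05
    ns = one_way_anova(_gm({B: [22.95, 23.54, 24.13], H: [23.01, 23.39, 23.77]}))
    assert ns.p > 0.05


def test_identical_groups_give_f0_p1():
    res = one_way_anova(_gm({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}))
    assert (res.f, res.p) == (0.0, 1.0)


def test_zero_variance_unequal_means_gives_p0():
    res = one_way_anova(_gm({"a": [1.0, 1.0], "b": [2.0, 2.0]}))
    assert res.p == 0.0 and math.isinf(res.f)


def test_group_validation():
    with pytest.raises(ValidationError):
        _gm({"only": [1.0, 2.0]})
    with pytest.raises(ValidationError):
        _gm({"a": [1.0], "b": [1.0, 2.0]})


# ---------------------------------------------------------------------------
# Duncan letters
# ---------------------------------------------------------------------------

def test_two_group_letters_match_published_examples():
    carb = duncan_mrt(
        from_summary("digestible carbohydrates", {B: (2.02, 0.24), H: (4.48, 0.25)})
    )
    assert carb.letters == {B: "a", H: "b"}
    protein = duncan_mrt(
        from_summary("protein", {B: (23.54, 0.59), H: (23.39, 0.38)})
    )
    assert protein.letters == {B: "a", H: "a"}
    gla = duncan_mrt(
        from_summary("gamma-linolenic", {B: (3.33, 0.41), H: (1.56, 0.13)})
    )
    assert gla.letters[B] != gla.letters[H]


def test_two_group_verdict_equals_anova_decision():
    """With k=2 Duncan reduces to a protected LSD: same verdict as p < alpha."""
    cases = [
        {B: (2.02, 0.24), H: (4.48, 0.25)},
        {B: (23.54, 0.59), H: (23.39, 0.38)},
        {B: (2.65, 0.08), H: (2.84, 0.11)},   # borderline, t ~ 2.42
        {B: (14.60, 1.85), H: (19.15, 2.06)},  # borderline, t ~ 2.85
        {B: (3.86, 0.33), H: (2.87, 0.61)},
    ]
    for summary in cases:
        disp = duncan_mrt(from_summary("row", summary))
        assert disp.same_letter(B, H) == (disp.anova.p >= 0.05), summary


def test_two_group_verdict_matches_ttest_oracle():
    """Independent oracle: pooled two-sample t-test at alpha = 0.05."""
    cases = [
        {B: (2.02, 0.24), H: (4.48, 0.25)},
        {B: (14.60, 1.85), H: (19.15, 2.06)},
        {B: (3.86, 0.33), H: (2.87, 0.61)},
        {B: (1860.0, 18.83), H: (1905.0, 11.31)},
    ]
    for summary in cases:
        gm = from_summary("row", summary)
        disp = duncan_mrt(gm)
        t, p = stats.ttest_ind(*gm.groups.values())
        assert disp.same_letter(B, H) == (p >= 0.05), summary


def test_letter_partition_invariant_to_group_order():
    groups = {
        "g1": [10.0, 11.0, 12.0],
        "g2": [10.5, 11.5, 12.5],
        "g3": [20.0, 21.0, 22.0],
    }
    fwd = duncan_mrt(_gm(groups))
    rev = duncan_mrt(_gm(dict(reversed(groups.items()))))
    for a in groups:
        for b in groups:
            assert fwd.same_letter(a, b) == rev.same_letter(a, b)


def test_letters_anchor_to_first_listed_group():
    """'a' goes to the first-listed group even when its mean is lower."""
    disp = duncan_mrt(
        from_summary("lignoceric", {B: (0.14, 0.0), H: (0.17, 0.0)})
    )
    assert disp.letters == {B: "a", H: "b"}


def test_zero_group_excluded_from_pooling_and_demoted():
    """A below-detection group takes the later letter and a degeneracy note."""
    disp = duncan_mrt(
        from_summary("erucic", {B: (0.00, 0.00), H: (0.07, 0.00)})
    )
    assert disp.letters == {B: "b", H: "a"}
    assert any("zero" in n for n in disp.notes)
    disp = duncan_mrt(
        from_summary("stearidonic", {B: (0.87, 0.11), H: (0.00, 0.00)})
    )
    assert disp.letters == {B: "a", H: "b"}


def test_identical_groups_share_letter_a():
    disp = duncan_mrt(_gm({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]}))
    assert disp.letters == {"x": "a", "y": "a"}


def test_unequal_n_uses_harmonic_mean_with_warning():
    gm = _gm({"a": [1.0, 2.0, 3.0], "b": [10.0, 11.0, 12.0, 13.0]})
    with pytest.warns(UserWarning, match="harmonic"):
        disp = duncan_mrt(gm)
    assert disp.letters["a"] != disp.letters["b"]


def test_three_group_middle_overlap():
    """Middle group can share letters with both extremes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        disp = duncan_mrt(
            _gm({
                "low": [1.0, 2.0, 3.0],
                "mid": [2.5, 3.5, 4.5],
                "high": [4.0, 5.0, 6.0],
            })
        )
    assert disp.same_letter("low", "mid")
    assert disp.same_letter("mid", "high")
    assert not disp.same_letter("low", "high")
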