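"""Lipid health indices: published values, oracle equivalence, properties."""

import dataclasses
import warnings

import pytest

from seedqual import (
    atherogenicity,
    compute_indices,
    hypo_hyper,
    n6_n3,
    parse_fa_notation,
    pufa_sfa,
    thrombogenicity,
)
from seedqual.lipid_indices import UndefinedRatioError
from seedqual.model import FattyAcidProfile, FattyAcidRecord


# ---------------------------------------------------------------------------
# Independent brute-force oracle: literal term-by-term translation of the
# index formulas over a plain {(carbons, db, family): pct} dictionary.
# ---------------------------------------------------------------------------

def _table(profile):
    d = {}
    for r in profile:
        k = (r.notation.carbons, r.notation.double_bonds, r.notation.family)
        d[k] = d.get(k, 0.0) + r.pct_total_fa
    return d


def _get(d, c, db, fam=None):
    if fam is not None:
        return d.get((c, db, fam), 0.0)
    return sum(v for (kc, kdb, _), v in d.items() if kc == c and kdb == db)


def oracle_indices(profile):
    d = _table(profile)
    sfa = sum(v for (_, db, _), v in d.items() if db == 0)
    mufa = sum(v for (_, db, _), v in d.items() if db == 1)
    pufa = sum(v for (_, db, _), v in d.items() if db >= 2)
    ufa = mufa + pufa
    n6 = sum(v for (_, _, f), v in d.items() if f == "n-6")
    n3 = sum(v for (_, _, f), v in d.items() if f == "n-3")
    return {
        "pufa_sfa_ratio": pufa / sfa,
        "n6_n3_ratio": (_get(d, 18, 2, "n-6") + _get(d, 18, 3, "n-6"))
        / (_get(d, 18, 3, "n-3") + _get(d, 18, 4, "n-3")),
        "ai": (_get(d, 12, 0) + 4 * _get(d, 14, 0) + _get(d, 16, 0)) / ufa,
        "ti": (_get(d, 14, 0) + _get(d, 16, 0) + _get(d, 18, 0))
        / (0.5 * mufa + 0.5 * n6 + 3 * n3 + n3 / n6),
        "h_to_h": (
            _get(d, 18, 1, "n-9") + _get(d, 18, 1, "n-7")
            + _get(d, 18, 2, "n-6") + _get(d, 18, 3, "n-6")
            + _get(d, 18, 3, "n-3") + _get(d, 20, 3, "n-6")
            + _get(d, 20, 4, "n-6") + _get(d, 20, 5, "n-3")
            + _get(d, 22, 4, "n-6") + _get(d, 22, 5, "n-3")
            + _get(d, 22, 6, "n-3")
        ) / (_get(d, 14, 0) + _get(d, 16, 0)),
    }


def _mini_profile(acids, sample_id="mini"):
    return FattyAcidProfile(
        sample_id=sample_id,
        records=[
            FattyAcidRecord(key, parse_fa_notation(key), pct)
            for key, pct in acids.items()
        ],
    )


# ---------------------------------------------------------------------------
# Published values (2-decimal table reports)
# ---------------------------------------------------------------------------

def test_published_index_values(bialobrzeskie, henola):
    b = compute_indices(bialobrzeskie).rounded()
    h = compute_indices(henola).rounded()
    assert b["n6_n3_ratio"] == 3.86 and h["n6_n3_ratio"] == 2.87
    assert b["ai"] == 0.08 and h["ai"] == 0.09
    assert b["h_to_h"] == 12.98 and h["h_to_h"] == 11.21
    # input rounding leaves +-0.02 play on the published PUFA/SFA values
    assert b["pufa_sfa_ratio"] == pytest.approx(7.06, abs=0.02)
    assert h["pufa_sfa_ratio"] == pytest.approx(6.17, abs=0.02)


def test_ti_formula_value_not_printed_value(bialobrzeskie, henola):
    """The printed TI of 0.03 is not what the stated formula yields (~0.11)."""
    assert thrombogenicity(bialobrzeskie) == pytest.approx(0.1127, abs=0.001)
    assert thrombogenicity(henola) == pytest.approx(0.1151, abs=0.001)
    assert abs(thrombogenicity(bialobrzeskie) - 0.03) > 0.05


def test_n6_n3_family_sum_variant(bialobrzeskie):
    assert n6_n3(bialobrzeskie, family_sums=True) == pytest.approx(
        59.79 / 15.47
    )


# ---------------------------------------------------------------------------
# Degenerate and symmetric cases
# ---------------------------------------------------------------------------

def test_zero_pufa_gives_zero_ratio():
    p = _mini_profile({"C16:0": 40.0, "C18:1 n-9": 60.0})
    assert pufa_sfa(p) == 0.0


def test_equal_n6_n3_gives_one():
    p = _mini_profile(
        {"C18:2 n-6": 30.0, "C18:3 n-3": 30.0, "C16:0": 40.0}
    )
    assert n6_n3(p) == 1.0


def test_ai_zero_without_atherogenic_acids():
    p = _mini_profile({"C18:0": 10.0, "C18:1 n-9": 90.0})
    assert atherogenicity(p) == 0.0


def test_hh_equal_shares_give_one():
    p = _mini_profile({"C16:0": 50.0, "C18:1 n-9": 50.0})
    assert hypo_hyper(p) == 1.0


def test_undefined_ratios_raise():
    no_sfa = _mini_profile({"C18:1 n-9": 50.0, "C18:2 n-6": 50.0})
    with pytest.raises(UndefinedRatioError):
        pufa_sfa(no_sfa)
    with pytest.raises(UndefinedRatioError):
        hypo_hyper(no_sfa)
    no_n3 = _mini_profile({"C16:0": 50.0, "C18:2 n-6": 50.0})
    with pytest.raises(UndefinedRatioError):
        n6_n3(no_n3)
    all_sfa = _mini_profile({"C16:0": 100.0})
    with pytest.raises(UndefinedRatioError):
        atherogenicity(all_sfa)


# ---------------------------------------------------------------------------
# Property suites on seeded random profiles
# ---------------------------------------------------------------------------

def test_oracle_equivalence_on_random_profiles(random_profiles):
    """Implementation vs literal brute-force oracle: agree to 1e-12."""
    for profile in random_profiles:
        ours = compute_indices(profile)
        ref = oracle_indices(profile)
        for name, value in ref.items():
            assert abs(getattr(ours, name) - value) < 1e-12, (
                profile.sample_id, name
            )


def _rescaled(profile, factor):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-95 sums are expected here
        return FattyAcidProfile(
            sample_id=profile.sample_id,
            records=[
                dataclasses.replace(r, pct_total_fa=r.pct_total_fa * factor)
                for r in profile.records
            ],
            total_fat_pct_dm=profile.total_fat_pct_dm,
        )


def test_scale_invariance(random_profiles):
    """All indices except TI are ratios of degree-1 sums, hence scale-free.

    TI's inner n-3/n-6 term is already degree 0, so TI is only checked to be
    invariant when shares that sum to a constant are renormalised to the
    same constant (i.e. under the identity on proper %-share profiles).
    """
    for profile in random_profiles[:25]:
        for factor in (0.5, 0.831):
            scaled = _rescaled(profile, factor)
            assert pufa_sfa(scaled) == pytest.approx(
                pufa_sfa(profile), rel=1e-12
            )
            assert n6_n3(scaled) == pytest.approx(n6_n3(profile), rel=1e-12)
            assert atherogenicity(scaled) == pytest.approx(
                atherogenicity(profile), rel=1e-12
            )
            assert hypo_hyper(scaled) == pytest.approx(
                hypo_hyper(profile), rel=1e-12
            )
        # shares already sum to 100; renormalising to 100 is the identity
        total = profile.total_pct
        renorm = _rescaled(profile, 100.0 / total)
        assert thrombogenicity(renorm) == pytest.approx(
            thrombogenicity(profile), rel=1e-9
        )


def _scale_unsaturated(profile, factor):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return FattyAcidProfile(
            sample_id=profile.sample_id,
            records=[
                dataclasses.replace(
                    r,
                    pct_total_fa=r.pct_total_fa
                    * (factor if r.notation.double_bonds >= 1 else 1.0),
                )
                for r in profile.records
            ],
        )


def test_ai_decreases_when_any_ufa_increases(random_profiles):
    """AI has UFA alone in its denominator: any UFA increase lowers it."""
    for profile in random_profiles[:25]:
        base = _rescaled(profile, 0.9)  # headroom for the bump
        for i, rec in enumerate(base.records):
            if rec.notation.double_bonds < 1:
                continue
            records = list(base.records)
            records[i] = dataclasses.replace(
                rec, pct_total_fa=rec.pct_total_fa + 1.0
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bumped = FattyAcidProfile(base.sample_id, records)
            assert atherogenicity(bumped) < atherogenicity(base)


def test_ai_ti_decrease_under_proportional_ufa_increase(random_profiles):
    """Scaling all unsaturated acids up together (SFA fixed) lowers AI and TI.

    Proportional scaling keeps the n-3/n-6 balance term of TI's denominator
    fixed, so the whole denominator grows.  (TI is *not* monotone under
    arbitrary single-acid increases: inflating n-6 alone can shrink the
    n-3/n-6 term faster than the weighted sums grow.)
    """
    for profile in random_profiles[:25]:
        base = _rescaled(profile, 0.9)
        bumped = _scale_unsaturated(base, 1.1)
        assert atherogenicity(bumped) < atherogenicity(base)
        assert thrombogenicity(bumped) < thrombogenicity(base)
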