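"""Gradient normalization, peak finding, window selection, cross-feeding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipautotroph import (
    DensityWindow,
    Fraction,
    GradientProfile,
    RunConfig,
    classify_fractions,
    crossfeed_check,
    normalize_profile,
    peak_density,
    select_fractions,
)


def make_profile(copies, densities=None, treatment="13C"):
    if densities is None:
        densities = [round(1.68 + 0.004 * i, 4) for i in range(len(copies))]
    fractions = tuple(
        Fraction(f"F{i + 1}", d, c) for i, (d, c) in enumerate(zip(densities, copies))
    )
    return GradientProfile("s1", treatment, fractions)


class TestNormalize:
    def test_minmax_by_definition(self):
        norm = normalize_profile(make_profile([2.0, 8.0, 4.0]))
        assert list(norm.copies) == pytest.approx([0.0, 1.0, 1.0 / 3.0])

    def test_idempotent_and_bounds(self, rng):
        prof = make_profile(list(rng.uniform(0, 1e8, 12)))
        once = normalize_profile(prof)
        twice = normalize_profile(once)
        assert once.copies.min() == 0.0 and once.copies.max() == 1.0
        assert np.allclose(once.copies, twice.copies)
        assert np.array_equal(once.densities, prof.densities)

    def test_order_preserving(self, rng):
        copies = list(rng.uniform(0, 1e8, 10))
        norm = normalize_profile(make_profile(copies))
        assert list(np.argsort(copies)) == list(np.argsort(norm.copies))

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError, match="all copies equal"):
            normalize_profile(make_profile([5.0, 5.0, 5.0]))


class TestPeak:
    def test_argmax(self):
        prof = make_profile([100, 500, 300], densities=[1.70, 1.72, 1.74])
        assert peak_density(prof) == 1.72

    def test_tie_breaks_heavy(self):
        prof = make_profile([100, 500, 200, 500, 100],
                            densities=[1.69, 1.71, 1.72, 1.73, 1.74])
        assert peak_density(prof) == 1.73


class TestClassify:
    def test_interval_membership_and_partition(self, config):
        prof = make_profile(
            [1, 2, 3, 4, 5],
            densities=[1.680, 1.700, 1.713, 1.720, 1.740],
        )
        labels = classify_fractions(prof, config)
        assert labels == ["outside", "L", "outside", "H", "UH"]

    def test_boundary_belongs_to_upper_window(self):
        cfg = RunConfig(
            density_windows={
                "L": DensityWindow(1.690, 1.715),
                "H": DensityWindow(1.715, 1.735),
                "UH": DensityWindow(1.735, 1.760),
            }
        )
        prof = make_profile([1, 1, 1], densities=[1.714, 1.715, 1.735])
        assert classify_fractions(prof, cfg) == ["L", "H", "UH"]


def brute_force_select(copies, in_window_idx, k):
    """Enumerate every contiguous run of length k; ties go heavy."""
    best = None
    for s in range(len(in_window_idx) - k + 1):
        run = in_window_idx[s : s + k]
        total = sum(copies[i] for i in run)
        if best is None or total >= best[0]:
            best = (total, run)
    return best


class TestSelect:
    def test_length_two_window(self, config):
        # all fractions inside H
        prof = make_profile([1, 5, 4, 2], densities=[1.716, 1.720, 1.724, 1.728])
        sel = select_fractions(prof, "H", config, k=2)
        assert sel.fraction_ids == ("F2", "F3")
        assert sel.summed_copies == 9

    def test_k1_reduces_to_window_argmax(self, config):
        prof = make_profile([1, 5, 4, 2], densities=[1.716, 1.720, 1.724, 1.728])
        sel = select_fractions(prof, "H", config, k=1)
        assert sel.fraction_ids == ("F2",)

    def test_empty_window_rejected(self, config):
        prof = make_profile([1, 2, 3], densities=[1.68, 1.682, 1.684])
        with pytest.raises(ValueError, match="no fractions"):
            select_fractions(prof, "UH", config)

    def test_agrees_with_exhaustive_search(self, config, rng):
        for _ in range(300):
            n = int(rng.integers(3, 31))
            densities = np.sort(rng.uniform(1.69, 1.76, n))
            densities += np.arange(n) * 1e-6  # guarantee strict increase
            copies = rng.integers(0, 1000, n).astype(float)
            prof = make_profile(list(copies), densities=list(densities))
            for window in ("L", "H", "UH"):
                labels = classify_fractions(prof, config)
                idx = [i for i, lab in enumerate(labels) if lab == window]
                if not idx:
                    continue
                for k in (1, 2, 3):
                    kk = min(k, len(idx))
                    sel = select_fractions(prof, window, config, k=k)
                    total, run = brute_force_select(list(copies), idx, kk)
                    assert sel.summed_copies == pytest.approx(total)
                    assert sel.fraction_ids == tuple(f"F{i + 1}" for i in run)


class TestCrossfeed:
    def test_heavier_dual_peak_is_negligible(self):
        dual = make_profile([1, 9, 2], densities=[1.72, 1.735, 1.75], treatment="13C+15N")
        c13 = make_profile([1, 9, 2], densities=[1.715, 1.730, 1.745])
        v = crossfeed_check(dual, c13)
        assert v.verdict == "negligible"
        assert v.density_shift == pytest.approx(0.005)

    def test_lighter_dual_peak_is_suspected(self):
        dual = make_profile([1, 9, 2], densities=[1.71, 1.725, 1.74], treatment="13C+15N")
        c13 = make_profile([1, 9, 2], densities=[1.715, 1.730, 1.745])
        assert crossfeed_check(dual, c13).verdict == "suspected"

    def test_identical_profiles_suspected(self):
        prof = make_profile([1, 9, 2], densities=[1.715, 1.730, 1.745])
        assert crossfeed_check(prof, prof).verdict == "suspected"

    def test_multimodal_profile_warns(self):
        bumpy = make_profile([9, 1, 1, 9, 1, 1, 9])
        single = make_profile([1, 9, 2])
        with pytest.warns(UserWarning, match="single-peaked"):
            crossfeed_check(bumpy, single)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    st.lists(st.integers(min_value=0, max_value=10**6), min_size=3, max_size=30).filter(
        lambda xs: len(set(xs)) > 1
    )
)
def test_normalization_contract_holds_for_any_profile(copies):
    norm = normalize_profile(make_profile([float(c) for c in copies]))
    assert norm.copies.min() == 0.0
    assert norm.copies.max() == 1.0
    assert np.all((norm.copies >= 0) & (norm.copies <= 1))
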