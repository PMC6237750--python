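"""Shift-vector metrics, classification rules and full-state comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polb_landscape.shiftvec import (
    DEFAULT_SUBDOMAINS,
    DegenerateReference,
    MethylPeak,
    MethylPeakList,
    ShiftVecError,
    ShiftVector,
    classify_residue,
    combined_shift,
    compare_states,
    cos_theta,
    normalized_magnitude,
    rereference,
    rmsd_one,
    significance_threshold,
    vector_magnitude,
)

finite = st.floats(min_value=-5.0, max_value=5.0, allow_nan=False)


@pytest.mark.parametrize(
    "d_H,d_C,expected",
    [
        (0.0, 0.0, 0.0),
        (0.05, 0.2, 0.07906),  # sqrt((0.0025 + 0.01)/2)
        (0.025, 0.0, 0.01768),  # below the 0.025 ppm significance threshold
    ],
)
def test_combined_shift_values(d_H, d_C, expected):
    assert combined_shift(d_H, d_C) == pytest.approx(expected, abs=1e-5)


@pytest.mark.parametrize(
    "d_H,d_C,expected",
    [(0.0, 0.0, 0.0), (0.1, 0.0, 0.1), (0.0, 1.0, 0.2514)],
)
def test_vector_magnitude_values(d_H, d_C, expected):
    assert vector_magnitude(d_H, d_C) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("func", [combined_shift, vector_magnitude])
def test_nonfinite_inputs_rejected(func):
    with pytest.raises(ShiftVecError):
        func(float("nan"), 0.0)
    with pytest.raises(ShiftVecError):
        func(0.0, float("inf"))


@settings(derandomize=True, max_examples=100)
@given(finite, finite, st.floats(min_value=-3.0, max_value=3.0))
def test_shift_metrics_absolutely_homogeneous(d_H, d_C, a):
    """f(a*x, a*y) = |a| * f(x, y) for both shift magnitudes."""
    for f in (combined_shift, vector_magnitude):
        assert f(a * d_H, a * d_C) == pytest.approx(abs(a) * f(d_H, d_C), abs=1e-9)


class TestVectorGeometry:
    def test_normalized_magnitude_identity_and_scaling(self):
        ref = ShiftVector(0.1, 0.4)
        assert normalized_magnitude(ref, ref) == pytest.approx(1.0)
        half = ShiftVector(0.05, 0.2)
        assert normalized_magnitude(half, ref) == pytest.approx(0.5)

    def test_degenerate_reference_signalled(self):
        with pytest.raises(DegenerateReference):
            normalized_magnitude(ShiftVector(0.1, 0.0), ShiftVector(1e-9, 0.0))

    @pytest.mark.parametrize(
        "exp,ref,expected",
        [
            (ShiftVector(0.2, 0.8), ShiftVector(0.1, 0.4), 1.0),  # collinear
            (ShiftVector(0.1, 0.0), ShiftVector(0.0, 0.4), 0.0),  # orthogonal
            (ShiftVector(-0.1, -0.4), ShiftVector(0.1, 0.4), -1.0),  # antiparallel
        ],
    )
    def test_cos_theta_reference_angles(self, exp, ref, expected):
        assert cos_theta(exp, ref) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(finite, finite, finite, finite, st.floats(min_value=0.1, max_value=10.0))
    def test_cos_theta_scale_invariant_sign_flips(self, eh, ec, rh, rc, a):
        exp, ref = ShiftVector(eh, ec), ShiftVector(rh, rc)
        try:
            base = cos_theta(exp, ref)
        except DegenerateReference:
            return
        assert cos_theta(ShiftVector(a * eh, a * ec), ref) == pytest.approx(base, abs=1e-9)
        assert cos_theta(ShiftVector(-eh, -ec), ref) == pytest.approx(-base, abs=1e-9)


class TestRmsd:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            ([(1.0, 1.0), (1.0, 1.0)], 0.0),
            ([(0.8, 0.5)], 0.53852),  # sqrt(0.04 + 0.25)
            ([(1.0, 1.0), (0.8, 0.5)], 0.38079),  # sqrt(0.29/2)
        ],
    )
    def test_frozen_values(self, rows, expected):
        assert rmsd_one(rows) == pytest.approx(expected, abs=1e-5)

    def test_empty_rejected(self):
        with pytest.raises(ShiftVecError):
            rmsd_one([])

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 8))
            rows = [(float(rng.normal(1, 0.5)), float(rng.normal(1, 0.5))) for _ in range(n)]
            brute = math.sqrt(
                sum((1 - c) ** 2 + (1 - d) ** 2 for c, d in rows) / len(rows)
            )
            assert rmsd_one(rows) == pytest.approx(brute, rel=1e-12)


def _list(name, positions):
    peaks = [
        MethylPeak(res, "I", "CD1", h, c) for res, h, c in positions
    ]
    return MethylPeakList(name, peaks)


class TestSignificanceThreshold:
    def test_identical_replicates_give_zero(self):
        a = _list("rep1", [(10, 0.5, 12.0), (20, 0.8, 15.0)])
        b = _list("rep2", [(10, 0.5, 12.0), (20, 0.8, 15.0)])
        assert significance_threshold([[a, b]]) == 0.0

    def test_constant_offset_replicates(self):
        # dH offset 0.02 everywhere, factor 1.5 -> 1.5 * 0.01414
        a = _list("rep1", [(10, 0.50, 12.0), (20, 0.80, 15.0)])
        b = _list("rep2", [(10, 0.52, 12.0), (20, 0.82, 15.0)])
        assert significance_threshold([[a, b]], factor=1.5) == pytest.approx(0.02121, abs=1e-5)

    def test_single_replicate_rejected(self):
        a = _list("rep1", [(10, 0.5, 12.0)])
        with pytest.raises(ShiftVecError):
            significance_threshold([[a]])


class TestClassification:
    @pytest.mark.parametrize(
        "combined,ct,expected",
        [
            (0.03, 0.9, "on_pathway"),
            (0.02, 0.9, "not_significant"),
            (0.025, 0.9, "not_significant"),  # threshold is strict
            (0.03, 0.5, "off_pathway"),
            (0.03, 0.8, "on_pathway"),  # boundary cosine counts as on-pathway
        ],
    )
    def test_rule(self, combined, ct, expected):
        assert classify_residue(combined, ct, 0.025, 0.8) == expected

    def test_counts_conserved(self):
        """Every matched peak lands in exactly one class."""
        rng = np.random.default_rng(1)
        n = 30
        mk = lambda name, f: _list(
            name,
            [(i + 1, 0.5 + f * 0.1 * rng.standard_normal(), 12.0 + f) for i in range(n)],
        )
        open_ref = _list("open", [(i + 1, 0.5, 12.0) for i in range(n)])
        closed_ref = _list("closed", [(i + 1, 0.6, 12.5) for i in range(n)])
        test = mk("test", 0.7)
        comp = compare_states(test, open_ref, closed_ref)
        assert sum(comp.counts.values()) == len(comp.rows) == n


class TestCompareStates:
    def _refs(self, n=25, seed=0):
        rng = np.random.default_rng(seed)
        open_pos = [(i * 13 % 334 + 1, float(rng.uniform(0, 1.5)), float(rng.uniform(9, 27))) for i in range(n)]
        closed_pos = [
            (res, h + float(rng.uniform(0.05, 0.3)) * (1 if i % 2 else -1), c + float(rng.uniform(0.2, 1.0)))
            for i, (res, h, c) in enumerate(open_pos)
        ]
        return _list("open", open_pos), _list("closed", closed_pos)

    def test_test_equals_closed_is_fully_closed(self):
        open_ref, closed_ref = self._refs()
        test = MethylPeakList("test", list(closed_ref.peaks))
        comp = compare_states(test, open_ref, closed_ref)
        sig = [r for r in comp.rows if r.classification == "on_pathway"]
        assert sig, "expected significant on-pathway rows"
        for r in sig:
            assert r.delta_n == pytest.approx(1.0, abs=1e-12)
            assert r.cos_theta == pytest.approx(1.0, abs=1e-12)
        assert comp.rmsd_global == pytest.approx(0.0, abs=1e-12)

    def test_test_equals_open_all_not_significant(self):
        open_ref, closed_ref = self._refs()
        test = MethylPeakList("test", list(open_ref.peaks))
        comp = compare_states(test, open_ref, closed_ref)
        assert comp.counts["n_not_significant"] == len(comp.rows)
        assert comp.rmsd_global is None

    def test_no_common_peaks_rejected(self):
        open_ref, closed_ref = self._refs()
        test = _list("test", [(334, 0.1, 10.0)])
        with pytest.raises(ShiftVecError):
            compare_states(test, open_ref, closed_ref)

    def test_unmatched_peaks_reported(self):
        open_ref, closed_ref = self._refs()
        peaks = list(closed_ref.peaks) + [MethylPeak(333, "V", "CG9", 0.2, 11.0)]
        comp = compare_states(MethylPeakList("t", peaks), open_ref, closed_ref)
        assert comp.unmatched_keys == [(333, "CG9")]


def test_subdomain_assignment_and_default_map():
    assert DEFAULT_SUBDOMAINS.assign(190) == "palm"  # catalytic aspartate region
    assert DEFAULT_SUBDOMAINS.assign(277) == "fingers"
    assert DEFAULT_SUBDOMAINS.assign(1) == "lyase"
    with pytest.raises(ShiftVecError):
        DEFAULT_SUBDOMAINS.assign(400)


def test_rereference_subtracts_anchor_offset():
    ref = _list("apo", [(221, 0.70, 20.0), (10, 0.50, 12.0)])
    shifted = _list("test", [(221, 0.72, 20.1), (10, 0.55, 12.3)])
    fixed = rereference(shifted, (221, "CD1"), ref)
    by = fixed.by_key()
    assert by[(221, "CD1")].delta_H == pytest.approx(0.70)
    assert by[(10, "CD1")].delta_H == pytest.approx(0.53)
    assert by[(10, "CD1")].delta_C == pytest.approx(12.2)
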