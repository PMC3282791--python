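"""Admixture model: forward predictions, grid back-calculation, interpretation table."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytocn.allelic import (
    Admixture,
    CellPopulation,
    Mechanism,
    UndefinedBafError,
    enumerate_mosaicism,
    expected_baf,
    expected_cn,
    table2_label,
)


def adm(b1, n1, p, b2=1, n2=2):
    return Admixture(CellPopulation(b1, n1), CellPopulation(b2, n2), p)


class TestForwardModel:
    @pytest.mark.parametrize(
        "b1,n1,p,want",
        [
            (1, 3, 0.9, 1 / 2.9),    # trisomic clone in 90% of cells
            (0, 1, 0.8, 0.2 / 1.2),  # monosomic clone in 80% of cells
            (1, 2, 0.0, 0.5),        # zero admixture: plain heterozygote
        ],
    )
    def test_expected_baf(self, b1, n1, p, want):
        assert expected_baf(adm(b1, n1, p)) == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize(
        "n1,p,want", [(4, 0.3, 2.6), (3, 0.9, 2.9), (3, 0.0, 2.0)]
    )
    def test_expected_cn(self, n1, p, want):
        assert expected_cn(adm(0, n1, p)) == pytest.approx(want)

    def test_nullisomic_mixture_has_no_baf(self):
        with pytest.raises(UndefinedBafError):
            expected_baf(adm(0, 0, 1.0, b2=0, n2=0))

    def test_population_invariants_enforced(self):
        with pytest.raises(ValueError):
            CellPopulation(3, 2)
        with pytest.raises(ValueError):
            Admixture(CellPopulation(1, 2), p_aberrant=1.5)

    @given(n1=st.integers(0, 4), b1=st.integers(0, 4), p=st.floats(0.0, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_ab_symmetry(self, n1, b1, p):
        """Relabelling A<->B mirrors the expected BAF about 0.5."""
        if n1 == 0 and p == 1.0:
            return  # nullisomic mixture: BAF undefined
        b1 = min(b1, n1)
        assert expected_baf(adm(b1, n1, p)) + expected_baf(adm(n1 - b1, n1, p)) \
            == pytest.approx(1.0, abs=1e-12)

    def test_pure_aneuploidy_boundaries(self):
        """At P1=1 the model reduces to textbook trisomy/monosomy values."""
        tri = adm(1, 3, 1.0)
        assert expected_cn(tri) == 3.0
        assert expected_baf(tri) == pytest.approx(1 / 3, abs=5e-3)
        mono = adm(0, 1, 1.0)
        assert expected_cn(mono) == 1.0
        assert expected_baf(mono) == 0.0

    @pytest.mark.parametrize("b1,n1", [(0, 1), (2, 3)])
    def test_monotonicity_in_aberrant_fraction(self, b1, n1):
        ps = np.linspace(0.05, 1.0, 20)
        cns = [expected_cn(adm(b1, n1, p)) for p in ps]
        seps = [abs(expected_baf(adm(b1, n1, p)) - 0.5) for p in ps]
        if n1 < 2:  # deletion: CN falls, band separation grows
            assert np.all(np.diff(cns) < 0)
        else:       # amplification: CN rises
            assert np.all(np.diff(cns) > 0)
        assert np.all(np.diff(seps) > 0)


class TestBackCalculation:
    @pytest.mark.parametrize(
        "bands,cn,mech,p",
        [
            ((0.34, 0.66), 2.9, Mechanism.MONOALLELIC_AMP, 0.90),
            ((0.5,), 2.6, Mechanism.BIALLELIC_AMP, 0.30),
            ((0.17, 0.83), 1.2, Mechanism.MONOALLELIC_DEL, 0.80),
            ((0.38, 0.62), 2.65, Mechanism.MONOALLELIC_AMP, 0.65),
            ((0.25, 0.75), 2.0, Mechanism.CNLOH, 0.50),
        ],
    )
    def test_published_worked_examples(self, bands, cn, mech, p):
        call = enumerate_mosaicism(bands, cn)
        assert call.mechanism == mech
        assert call.p_aberrant_est == pytest.approx(p, abs=0.005)

    def test_identity_case_is_normal(self):
        call = enumerate_mosaicism([0.5], 2.0)
        assert call.mechanism == Mechanism.NORMAL
        assert call.p_aberrant_est is None

    def test_empty_band_list_is_indeterminate(self):
        assert enumerate_mosaicism([], 2.0).mechanism == Mechanism.INDETERMINATE

    def test_cn_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enumerate_mosaicism([0.5], 0.0)
        with pytest.raises(ValueError):
            enumerate_mosaicism([0.5], 4.5)

    def test_candidates_sorted_by_residual(self):
        call = enumerate_mosaicism([0.38, 0.62], 2.65)
        residuals = [c.residual for c in call.candidates]
        assert residuals == sorted(residuals)
        assert all(c.residual >= 0 for c in call.candidates)

    def test_near_monosomy_labelled_mosaic_monosomy(self):
        """A monosomic clone in essentially all cells is whole-copy loss."""
        call = enumerate_mosaicism([0.01, 0.99], 1.01)
        assert call.mechanism == Mechanism.MOSAIC_MONOSOMY
        assert call.p_aberrant_est >= 0.95

    @pytest.mark.parametrize(
        "b1,n1",
        [(0, 1), (1, 1), (0, 2), (2, 2), (1, 3), (2, 3), (0, 3), (3, 3), (2, 4)],
    )
    def test_forward_inverse_round_trip(self, b1, n1):
        """Feeding exact forward predictions back recovers clone and fraction.

        Fractions below the 5% reporting floor are indistinguishable from
        normal and excluded; monosomy above 95% is relabelled by design.
        """
        for p in np.arange(0.05, 0.951, 0.05):
            a = adm(b1, n1, p)
            baf = expected_baf(a)
            bands = sorted({round(baf, 12), round(1 - baf, 12)})
            call = enumerate_mosaicism(bands, expected_cn(a))
            assert call.p_aberrant_est == pytest.approx(p, abs=0.0101), (b1, n1, p)
            best = call.candidates[0]
            assert {best.b_count, best.n_copies - best.b_count} == {b1, n1 - b1} \
                and best.n_copies == n1, (b1, n1, p, best)


class TestInterpretationTable:
    @pytest.mark.parametrize(
        "state,split,want",
        [
            ("UNCHANGED", "NO_SPLIT", "Normal"),
            ("AMPLIFIED", "MODERATE", "Mono-allelic Amplification"),
            ("AMPLIFIED", "LARGE", "Mono-allelic amplification superimposed on cnLOH"),
            ("AMPLIFIED", "NO_SPLIT", "Bi-allelic amplification"),
            ("DELETED", "LARGE", "Mono-allelic deletion"),
            ("DELETED", "MODERATE", "Mono-allelic deletion in small proportion of cells"),
            ("UNCHANGED", "MODERATE", "cnLOH"),
        ],
    )
    def test_rows(self, state, split, want):
        assert table2_label(state, split) == want

    def test_unmapped_combination_is_indeterminate(self):
        assert table2_label("DELETED", "NO_SPLIT") == "Indeterminate"
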