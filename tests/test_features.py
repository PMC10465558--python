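"""Spectral-feature computation, including the ratio-distance features."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_psm
from fpf.features import (
    avg_reporter_intensity,
    count_ptms,
    featurize,
    ipepdist,
    iprotdist,
    psm_ratios,
)
from fpf.model import ChannelDesign, Modification


def brute_force_distance(j, ratio_vectors):
    """Independent evaluation of the ratio-distance definition."""
    m = len(ratio_vectors)
    if m == 1:
        return 0.0
    n = len(ratio_vectors[0])
    total = 0.0
    for i in range(n):
        avg = sum(v[i] for v in ratio_vectors) / m
        rest = sum(v[i] for k, v in enumerate(ratio_vectors) if k != j) / (m - 1)
        total += ((ratio_vectors[j][i] - rest) / avg) ** 2
    return math.sqrt(total)


class TestPsmRatios:
    def test_equal_channels_give_unit_ratios(self, design3):
        psm = make_psm(1, (100.0, 100.0, 100.0))
        assert psm_ratios(psm, design3) == (1.0, 1.0)

    def test_hand_arithmetic(self, design3):
        psm = make_psm(1, (200.0, 100.0, 50.0))
        assert psm_ratios(psm, design3) == (0.5, 0.25)

    def test_missing_channel_voids_whole_vector(self, design3):
        psm = make_psm(1, (100.0, None, 100.0))
        assert psm_ratios(psm, design3) is None

    def test_zero_denominator_voids_vector(self, design3):
        psm = make_psm(1, (0.0, 100.0, 100.0))
        assert psm_ratios(psm, design3) is None


class TestAvgReporterIntensity:
    @pytest.mark.parametrize(
        "intensities,expected",
        [((10000.0, 10000.0, 10000.0), 10000.0), ((5000.0, 7000.0), 6000.0)],
    )
    def test_mean(self, intensities, expected):
        assert avg_reporter_intensity(make_psm(1, intensities)) == expected

    def test_missing_channel_bypasses(self):
        assert avg_reporter_intensity(make_psm(1, (5000.0, None))) is None


class TestIProtDist:
    def test_single_psm_protein_is_zero(self, design2):
        psm = make_psm(1, (100.0, 100.0))
        assert iprotdist(psm, [psm], design2) == 0.0

    def test_identical_ratio_vectors_give_zero(self, design2):
        a = make_psm(1, (100.0, 150.0))
        b = make_psm(2, (200.0, 300.0))
        assert iprotdist(a, [a, b], design2) == pytest.approx(0.0)
        assert iprotdist(b, [a, b], design2) == pytest.approx(0.0)

    def test_two_psm_hand_value(self, design2):
        # ratios 1.0 and 2.0: |(1 - 2) / 1.5| = 0.6667
        a = make_psm(1, (100.0, 100.0))
        b = make_psm(2, (100.0, 200.0))
        assert iprotdist(a, [a, b], design2) == pytest.approx(2.0 / 3.0)

    def test_missing_reporter_bypasses(self, design2):
        a = make_psm(1, (100.0, None))
        b = make_psm(2, (100.0, 200.0))
        assert iprotdist(a, [a, b], design2) is None


class TestIPepDist:
    def test_lone_single_hit_peptide_is_zero(self, design2):
        psm = make_psm(1, (100.0, 100.0), peptide="AAAAAAAK")
        assert ipepdist(psm, [psm], design2) == 0.0

    def test_identical_ratios_same_peptide(self, design2):
        a = make_psm(1, (100.0, 100.0), peptide="AAAAAAAK")
        b = make_psm(2, (300.0, 300.0), peptide="AAAAAAAK")
        assert ipepdist(a, [a, b], design2) == pytest.approx(0.0)

    def test_pseudo_peptide_merges_single_hit_peptides(self, design2):
        # three single-hit peptides, ratios 1.0 / 1.0 / 4.0:
        # for the 4.0 PSM AvgRest = 1.0, Avg = 2.0 -> |4 - 1| / 2 = 1.5
        a = make_psm(1, (100.0, 100.0), peptide="AAAAAAAK")
        b = make_psm(2, (100.0, 100.0), peptide="CCCCCCCK")
        c = make_psm(3, (100.0, 400.0), peptide="DDDDDDDK")
        assert ipepdist(c, [a, b, c], design2) == pytest.approx(1.5)

    def test_multi_hit_peptide_ignores_pseudo_peptide(self, design2):
        a = make_psm(1, (100.0, 100.0), peptide="AAAAAAAK")
        b = make_psm(2, (100.0, 100.0), peptide="AAAAAAAK")
        c = make_psm(3, (100.0, 400.0), peptide="DDDDDDDK")
        # a's peptide has 2 PSMs with equal ratios -> 0, unaffected by c
        assert ipepdist(a, [a, b, c], design2) == pytest.approx(0.0)
        # c is a lone single-hit peptide (only member of the pseudo-peptide)
        assert ipepdist(c, [a, b, c], design2) == 0.0


class TestCountPtms:
    def test_unmodified(self):
        assert count_ptms(make_psm(1, (1.0, 1.0))) == 0

    def test_labels_excluded(self):
        mods = (
            Modification(0, 229.162932, True),
            Modification(8, 229.162932, True),
        )
        assert count_ptms(make_psm(1, (1.0, 1.0), modifications=mods)) == 0

    def test_ptm_ratio(self, design3):
        mods = (Modification(3, 15.994915, False),)
        psm = make_psm(1, (1.0, 1.0, 1.0), peptide="AAAAAAAAAK", modifications=mods)
        fv = featurize([psm], design3)[psm.key]
        assert fv.n_ptm == 1
        assert fv.ptm_ratio == pytest.approx(0.1)


class TestFeaturize:
    def test_single_psm_dataset_zero_distances(self, design3):
        psm = make_psm(1, (100.0, 100.0, 100.0))
        fv = featurize([psm], design3)[psm.key]
        assert fv.iprotdist == 0.0
        assert fv.ipepdist == 0.0

    def test_missing_reporter_propagates(self, design3):
        psm = make_psm(1, (100.0, None, 100.0))
        fv = featurize([psm], design3)[psm.key]
        assert fv.avg_reporter_intensity is None
        assert fv.iprotdist is None
        assert fv.ipepdist is None

    def test_abs_mass_diff(self, design3):
        psm = make_psm(1, (1.0, 1.0, 1.0), observed=1501.0, theoretical=1500.2)
        fv = featurize([psm], design3)[psm.key]
        assert fv.abs_mass_diff_da == pytest.approx(0.8)

    def test_sl_fields_missing_without_scores(self, design3):
        fv = featurize([make_psm(1, (1.0, 1.0, 1.0))], design3)[make_psm(1, (1.0, 1.0, 1.0)).key]
        assert fv.sl_dot is None and fv.sl_hit_std is None


def _random_protein(rng, n_psms, n_channels):
    """Random PSM group sharing one protein, with random peptide sharing."""
    n_peptides = int(rng.integers(1, n_psms + 1))
    peptides = [f"PEP{i}AAK" for i in range(n_peptides)]
    psms = []
    for s in range(n_psms):
        psms.append(
            make_psm(
                s + 1,
                tuple(float(v) for v in rng.uniform(10, 1000, size=n_channels)),
                peptide=peptides[int(rng.integers(n_peptides))],
            )
        )
    return psms


def test_distance_formula_matches_brute_force_oracle():
    """1000 random small instances agree with a from-scratch evaluation."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n_channels = int(rng.integers(2, 11))
        design = ChannelDesign(
            tuple(f"c{i}" for i in range(n_channels)), 0, (1.0,) * (n_channels - 1)
        )
        psms = _random_protein(rng, int(rng.integers(1, 9)), n_channels)
        from fpf.features import psm_ratios as ratios_of

        vectors = [ratios_of(p, design) for p in psms]
        for j, target in enumerate(psms):
            expected = brute_force_distance(j, vectors)
            got = iprotdist(target, psms, design)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

        # peer-set oracle for the intra-peptide distance
        counts = {}
        for p in psms:
            counts[p.peptide] = counts.get(p.peptide, 0) + 1
        for j, target in enumerate(psms):
            if counts[target.peptide] >= 2:
                peer_idx = [k for k, p in enumerate(psms) if p.peptide == target.peptide]
            else:
                peer_idx = [k for k, p in enumerate(psms) if counts[p.peptide] == 1]
            peer_vectors = [vectors[k] for k in peer_idx]
            expected = brute_force_distance(peer_idx.index(j), peer_vectors)
            got = ipepdist(target, psms, design)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)


def test_distance_invariant_to_peer_order(design3):
    rng = np.random.default_rng(5)
    psms = _random_protein(rng, 6, 3)
    target = psms[2]
    base = iprotdist(target, psms, design3)
    shuffled = [psms[i] for i in (4, 0, 5, 2, 1, 3)]
    assert iprotdist(target, shuffled, design3) == pytest.approx(base, rel=1e-12)


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_distance_invariant_to_global_intensity_scaling(scale):
    design = ChannelDesign(("a", "b", "c"), 0, (1.0, 1.0))
    rng = np.random.default_rng(7)
    psms = _random_protein(rng, 5, 3)
    scaled = [p.with_intensities(tuple(v * scale for v in p.reporter_intensities)) for p in psms]
    for j in range(len(psms)):
        a = iprotdist(psms[j], psms, design)
        b = iprotdist(scaled[j], scaled, design)
        assert b == pytest.approx(a, rel=1e-9)


def test_ipepdist_equals_iprotdist_for_single_peptide_protein(design3):
    rng = np.random.default_rng(9)
    psms = [
        make_psm(s + 1, tuple(float(v) for v in rng.uniform(10, 1000, 3)), peptide="SAMEPEPK")
        for s in range(5)
    ]
    for p in psms:
        assert ipepdist(p, psms, design3) == pytest.approx(
            iprotdist(p, psms, design3), rel=1e-12
        )
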