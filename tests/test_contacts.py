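"""Contact matrices, P_c(s) curves, log-binned profiles, compartments."""

import numpy as np
import pytest

from musicpipe.clusters import ContactEnd, WeightedContact
from musicpipe.contacts import (
    BinScheme,
    LOGBIN_MAX,
    LOGBIN_MIN,
    LOGBIN_N,
    compartment_track,
    compare_compartments,
    contact_matrix,
    fit_decay_exponent,
    logbin_edges,
    logbin_profile,
    normalize_map_pair,
    pc_curve,
    pc_curve_from_distances,
    visual_transform,
)
from musicpipe.synthdata import simulate_powerlaw_distances


def _wc(pos_a, pos_b, weight, cell="c1", size=2, chrom="hs_chr1"):
    return WeightedContact(
        ContactEnd(chrom, pos_a, "DNA", "+"),
        ContactEnd(chrom, pos_b, "DNA", "+"),
        weight, (1, 2, 3, "G" * 16, 1), cell, size,
    )


def test_contact_matrix_single_pair_in_one_bin():
    scheme = BinScheme("hs_chr1", 1_000, 0, 10_000)
    m = contact_matrix([_wc(3_100, 3_900, 0.5)], scheme)
    assert m.weights == {(3, 3): 0.5}
    assert m.total == pytest.approx(0.5)


def test_contact_matrix_size3_cluster_spanning_bins():
    scheme = BinScheme("hs_chr1", 1_000, 0, 10_000)
    contacts = [
        _wc(1_500, 2_500, 1 / 3, size=3),
        _wc(1_500, 4_500, 1 / 3, size=3),
        _wc(2_500, 4_500, 1 / 3, size=3),
    ]
    m = contact_matrix(contacts, scheme)
    assert set(m.weights) == {(1, 2), (1, 4), (2, 4)}
    assert all(w == pytest.approx(1 / 3) for w in m.weights.values())


def test_contact_matrix_mass_conservation_and_drops():
    scheme = BinScheme("hs_chr1", 1_000, 0, 10_000)
    inside = [_wc(100, 200, 0.5), _wc(5_000, 9_999, 0.25)]
    outside = [_wc(100, 20_000, 0.5), _wc(0, 5, 1.0, chrom="hs_chr2")]
    m = contact_matrix(inside + outside, scheme)
    assert m.total == pytest.approx(0.75)
    assert m.n_dropped == 2


def test_size_class_filter():
    scheme = BinScheme("hs_chr1", 1_000, 0, 10_000)
    contacts = [_wc(100, 200, 0.5, size=2), _wc(100, 200, 1 / 30, size=30)]
    small = contact_matrix(contacts, scheme, size_class=(2, 10))
    mid = contact_matrix(contacts, scheme, size_class=(11, 50))
    assert small.total == pytest.approx(0.5)
    assert mid.total == pytest.approx(1 / 30)


def test_visual_transform_values_and_monotonicity():
    assert visual_transform(np.array([0.0]))[0] == 0.0
    assert visual_transform(np.array([0.5]), 100)[0] == pytest.approx(np.log10(51))
    rng = np.random.default_rng(0)
    w = np.sort(rng.random(100))
    t = visual_transform(w, 1000)
    assert (np.diff(t) >= 0).all()


def test_normalize_map_pair():
    rng = np.random.default_rng(1)
    a = rng.random((20, 20))
    a1, a2 = normalize_map_pair(a, a.copy())
    assert np.allclose(a1, a2)
    assert a1.max() == pytest.approx(1.0)
    b1, b2 = normalize_map_pair(a, 7.0 * a)
    assert b1.max() == b2.max() == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        z1, _ = normalize_map_pair(np.zeros((3, 3)), a[:3, :3])
    assert (z1 == 0).all()


def test_pc_curve_single_pair_unit_mass():
    c = pc_curve([_wc(1_000, 51_000, 1.0)], n_bins=1_000)
    assert c.freq.sum() == pytest.approx(1.0)
    d = 50_000
    assert c.freq[np.searchsorted(c.edges, d) - 1] == pytest.approx(1.0)


def test_pc_curve_additive_over_cells():
    contacts_a = [_wc(0, 10_000, 0.5, cell="a"), _wc(0, 2_000_000, 0.5, cell="a")]
    contacts_b = [_wc(0, 500_000, 1 / 3, cell="b")]
    merged = pc_curve(contacts_a + contacts_b, n_bins=2_000)
    pa = pc_curve(contacts_a, n_bins=2_000)
    pb = pc_curve(contacts_b, n_bins=2_000)
    assert np.allclose(merged.freq, pa.freq + pb.freq)


def test_pc_curve_excludes_out_of_range_and_interchromosomal():
    contacts = [
        _wc(0, 5, 1.0),              # distance 5 < 10
        _wc(0, 1_000, 1.0),
        WeightedContact(ContactEnd("hs_chr1", 0, "DNA", "+"),
                        ContactEnd("hs_chr2", 0, "DNA", "+"),
                        1.0, (1, 2, 3, "G" * 16, 1), "c1", 2),
    ]
    c = pc_curve(contacts, n_bins=1_000)
    assert c.n_excluded == 1  # the 5 bp pair; trans pair silently ignored
    assert c.freq.sum() == pytest.approx(1.0)


def test_pc_curve_arm_filter():
    arms = {"hs_chr1": 50_000}
    contacts = [_wc(40_000, 60_000, 1.0), _wc(10_000, 20_000, 1.0)]
    c = pc_curve(contacts, arms=arms, n_bins=1_000)
    assert c.n_excluded == 1
    assert c.freq.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("alpha", [1.0, 1.5])
def test_powerlaw_slope_recovery(alpha):
    d = simulate_powerlaw_distances(alpha, 100_000, seed=3)
    curve = pc_curve_from_distances(d)
    slope = fit_decay_exponent(curve, s_range=(2e4, 5e7))
    assert abs(slope - (-alpha)) <= 0.1


# ------------------------------------------------------- log-bin profile

def test_logbin_edges_closed_form():
    edges = logbin_edges()
    assert len(edges) == LOGBIN_N + 1
    step = (np.log2(LOGBIN_MAX) - np.log2(LOGBIN_MIN)) / LOGBIN_N
    for n in (1, 75, 150):
        assert edges[n] == pytest.approx(2 ** (np.log2(5_000) + step * n), rel=1e-12)
    assert edges[0] == pytest.approx(5_000, rel=1e-9)
    assert edges[-1] == pytest.approx(1.5e8, rel=1e-9)
    assert (np.diff(edges) > 0).all()


def test_logbin_profile_unit_mass_and_single_contact():
    p = logbin_profile(np.array([1e6]))
    assert p.values.sum() == pytest.approx(1.0)
    assert p.n_nonempty == 1
    bin_idx = np.searchsorted(p.edges, 1e6) - 1
    assert p.values[bin_idx] == pytest.approx(1.0)


def test_logbin_width_normalisation_favours_narrow_bins():
    edges = logbin_edges()
    # one count in bin 10 (narrow) and one in bin 100 (wide)
    d = np.array([np.sqrt(edges[10] * edges[11]), np.sqrt(edges[100] * edges[101])])
    p = logbin_profile(d)
    assert p.values[10] > p.values[100]


# --------------------------------------------------------- compartments

def _checkerboard(n=40, block=5, strong=4.0, weak=0.5):
    lab = (np.arange(n) // block) % 2
    same = lab[:, None] == lab[None, :]
    m = np.where(same, strong, weak)
    return m * np.exp(-np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) / 50)


def test_compartment_checkerboard_sign_pattern():
    n, block = 40, 5
    m = _checkerboard(n, block)
    ref = np.where((np.arange(n) // block) % 2 == 0, 1.0, -1.0)
    pc1 = compartment_track(m, reference=ref)
    sign = np.sign(pc1)
    assert (sign == ref).mean() > 0.95


def test_compare_with_self_and_shuffled():
    m = _checkerboard(200, 10)
    ref = np.where((np.arange(200) // 10) % 2 == 0, 1.0, -1.0)
    pc1 = compartment_track(m, reference=ref)
    rs, med = compare_compartments({"chr1": pc1}, {"chr1": pc1.copy()})
    assert med == pytest.approx(1.0)
    rng = np.random.default_rng(4)
    perm = rng.permutation(200)
    m_shuf = m[np.ix_(perm, perm)]
    pc1_shuf = compartment_track(m_shuf, reference=ref)
    _, med2 = compare_compartments({"chr1": pc1}, {"chr1": pc1_shuf})
    assert abs(med2) < 0.3


def test_compartment_degenerate_input_rejected():
    with pytest.raises(ValueError):
        compartment_track(np.ones((20, 20)))
    with pytest.raises(ValueError, match="informative"):
        compartment_track(np.zeros((20, 20)))
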