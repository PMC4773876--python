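import numpy as np
import pytest

from promarch import (
    MotifModel,
    Scaffold,
    TSSRecord,
    anchored_on_motif,
    cumulative_motif_frequency,
    motif_hit_anchors,
    revcomp,
)
from promarch.u1_pas_axis import directional_flank

PAS = MotifModel.from_iupac("PAS", "AWTAAA")


def flat_genome(length=5_000, base="G", sid="s1"):
    return Scaffold(sid, base * length)


class TestSingleAnchor:
    def test_pas_at_plus125_sense(self):
        seq = list("G" * 3_000)
        seq[1_125 : 1_131] = list("AATAAA")  # distance 125 from anchor at 1000
        sc = Scaffold("s1", "".join(seq))
        prof = cumulative_motif_frequency(
            [TSSRecord("s1", 1_000, "+")], {"s1": sc}, PAS, "sense_downstream"
        )
        # distance 125 -> bin index 12 covering (120, 130]
        assert np.all(prof.cumulative[:12] == 0)
        assert np.all(prof.cumulative[12:] == 1.0)

    def test_motif_absent_everywhere(self):
        prof = cumulative_motif_frequency(
            [TSSRecord("s1", 1_000, "+")], {"s1": flat_genome()}, PAS, "sense_downstream"
        )
        assert np.all(prof.cumulative == 0)

    def test_truncated_anchor_dropped_and_counted(self):
        sc = flat_genome(2_000)
        anchors = [TSSRecord("s1", 100, "+"), TSSRecord("s1", 1_000, "+")]
        prof = cumulative_motif_frequency(anchors, {"s1": sc}, PAS, "antisense_upstream")
        assert prof.n_anchors == 1
        assert prof.n_dropped == 1

    def test_all_anchors_truncated_raises(self):
        with pytest.raises(ValueError, match="complete flanks"):
            cumulative_motif_frequency(
                [TSSRecord("s1", 10, "+")], {"s1": flat_genome(400)}, PAS,
                "antisense_upstream",
            )


class TestDirectionalFlank:
    def test_four_quadrants_read_away_from_anchor(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        sc = Scaffold("s1", seq)
        p = 1_500
        plus, minus = TSSRecord("s1", p, "+"), TSSRecord("s1", p, "-")
        down_p = directional_flank(plus, sc, "sense_downstream", 500)
        up_p = directional_flank(plus, sc, "antisense_upstream", 500)
        down_m = directional_flank(minus, sc, "sense_downstream", 500)
        up_m = directional_flank(minus, sc, "antisense_upstream", 500)
        assert down_p == seq[p + 1 : p + 501]
        assert up_p == revcomp(seq[p - 500 : p])
        assert down_m == revcomp(seq[p - 500 : p])
        assert up_m == seq[p + 1 : p + 501]
        # index 0 is adjacent to the anchor in every direction
        assert down_p[0] == seq[p + 1]
        assert up_p[0] == revcomp(seq[p - 1])


def brute_force_profile(anchors, sc_map, motif, direction, span=500, bin_size=10):
    """Oracle: per-anchor, per-offset recount from the flank definition."""
    counts = np.zeros(span // bin_size)
    used = 0
    for a in anchors:
        flank = directional_flank(a, sc_map[a.scaffold_id], direction, span)
        if flank is None:
            continue
        used += 1
        w = motif.width
        for i in range(span - w + 1):
            window = flank[i : i + w]
            from promarch.motif_scan import IUPAC_CLASSES

            if all(b in IUPAC_CLASSES[c] for b, c in zip(window, motif.consensus)):
                counts[i // bin_size] += 1
    return counts / used, used


class TestOracleEquivalence:
    def test_profiles_equal_direct_recount(self):
        rng = np.random.default_rng(33)
        seq = "".join(rng.choice(list("ACGT"), size=60_000, p=[0.32, 0.18, 0.18, 0.32]))
        sc = Scaffold("s1", seq)
        anchors = [
            TSSRecord("s1", int(p), "+-"[i % 2])
            for i, p in enumerate(rng.integers(600, 59_400, size=100))
        ]
        for direction in ("sense_downstream", "antisense_upstream"):
            prof = cumulative_motif_frequency(anchors, {"s1": sc}, PAS, direction)
            oracle, used = brute_force_profile(anchors, {"s1": sc}, PAS, direction)
            assert prof.n_anchors == used
            np.testing.assert_allclose(prof.per_bin_frequency, oracle)
            np.testing.assert_allclose(prof.cumulative, np.cumsum(oracle))
            assert np.all(np.diff(prof.cumulative) >= 0)


class TestStrandAntisymmetry:
    def test_revcomp_genome_swaps_directions(self):
        rng = np.random.default_rng(55)
        seq = "".join(rng.choice(list("ACGT"), size=20_000, p=[0.32, 0.18, 0.18, 0.32]))
        sc = Scaffold("s1", seq)
        rc = Scaffold("s1", revcomp(seq))
        anchors = [TSSRecord("s1", int(p), "+") for p in rng.integers(600, 19_400, 40)]
        flipped = [
            TSSRecord("s1", sc.length - 1 - a.position, "-") for a in anchors
        ]
        down = cumulative_motif_frequency(anchors, {"s1": sc}, PAS, "sense_downstream")
        up = cumulative_motif_frequency(anchors, {"s1": sc}, PAS, "antisense_upstream")
        down_f = cumulative_motif_frequency(flipped, {"s1": rc}, PAS, "sense_downstream")
        up_f = cumulative_motif_frequency(flipped, {"s1": rc}, PAS, "antisense_upstream")
        np.testing.assert_allclose(down.per_bin_frequency, down_f.per_bin_frequency)
        np.testing.assert_allclose(up.per_bin_frequency, up_f.per_bin_frequency)


class TestAnchoredOnMotif:
    def test_tss_anchors_give_identical_output(self):
        rng = np.random.default_rng(77)
        seq = "".join(rng.choice(list("ACGT"), size=20_000, p=[0.32, 0.18, 0.18, 0.32]))
        sc = Scaffold("s1", seq)
        anchors = [TSSRecord("s1", int(p), "+") for p in rng.integers(600, 19_400, 20)]
        direct = cumulative_motif_frequency(anchors, {"s1": sc}, PAS, "sense_downstream")
        via = anchored_on_motif(anchors, {"s1": sc}, PAS, "sense_downstream")
        np.testing.assert_allclose(direct.per_bin_frequency, via.per_bin_frequency)

    def test_downstream_site_at_known_bin(self):
        seq = list("G" * 30_000)
        anchors = []
        for i in range(10):
            p = 1_000 + i * 2_000
            seq[p + 35 : p + 41] = list("AATAAA")  # distance 35 -> bin 3
            anchors.append(TSSRecord("s1", p, "+"))
        sc = Scaffold("s1", "".join(seq))
        prof = anchored_on_motif(anchors, {"s1": sc}, PAS, "sense_downstream")
        assert prof.cumulative[2] == 0
        assert prof.cumulative[3] == 1.0
        assert prof.cumulative[-1] == 1.0

    def test_empty_hit_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            anchored_on_motif([], {}, PAS, "sense_downstream")

    def test_hit_anchor_positions_on_both_strands(self):
        seq = list("G" * 4_000)
        seq[1_900 : 1_906] = list("AATAAA")  # sense hit upstream of + TSS at 2000
        sc = Scaffold("s1", "".join(seq))
        anchors = [TSSRecord("s1", 2_000, "+")]
        hits = motif_hit_anchors(anchors, {"s1": sc}, PAS, window=(-400, 100))
        (h,) = hits
        assert (h.position, h.strand) == (1_900, "+")
        minus_sc = Scaffold("s1", revcomp(sc.sequence))
        minus_anchor = [TSSRecord("s1", sc.length - 1 - 2_000, "-")]
        mh = motif_hit_anchors(minus_anchor, {"s1": minus_sc}, PAS, window=(-400, 100))
        (m,) = mh
        assert m.position == sc.length - 1 - 1_900
        assert m.strand == "-"


def test_null_symmetry_random_genome():
    """On a random genome with random anchors the sense and antisense final
    cumulative values agree within 3 binomial standard errors."""
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=400_000, p=[0.32, 0.18, 0.18, 0.32]))
    sc = Scaffold("s1", seq)
    anchors = [
        TSSRecord("s1", int(p), "+-"[i % 2])
        for i, p in enumerate(rng.integers(600, 399_400, size=800))
    ]
    down = cumulative_motif_frequency(anchors, {"s1": sc}, PAS, "sense_downstream")
    up = cumulative_motif_frequency(anchors, {"s1": sc}, PAS, "antisense_upstream")
    n = down.n_anchors
    rate = (down.cumulative[-1] + up.cumulative[-1]) / 2
    se = np.sqrt(rate / n)  # Poisson-count standard error per anchor mean
    assert abs(down.cumulative[-1] - up.cumulative[-1]) < 3 * se
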