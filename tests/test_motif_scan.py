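import numpy as np
import pytest

from promarch import (
    MotifModel,
    Scaffold,
    TSSRecord,
    build_pwm,
    composition_profile,
    positional_profile,
    read_jaspar_pfm,
    read_meme_motifs,
    scan_iupac,
    scan_pwm,
    revcomp,
)
from promarch.motif_scan import IUPAC_CLASSES

RNG = np.random.default_rng(2024)


def random_seq(length, rng=RNG, p=None):
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


TEST_MOTIFS = [
    MotifModel.from_iupac("PAS", "AWTAAA"),
    MotifModel.from_iupac("SP1", "GGGGCGGGG"),
    MotifModel.from_pfm(
        "TATA",
        np.array(
            [
                [1, 18, 1, 18, 12, 17, 14],
                [16, 0, 1, 0, 1, 0, 1],
                [2, 0, 1, 0, 2, 2, 4],
                [1, 2, 17, 2, 5, 1, 1],
            ]
        ),
    ),
    MotifModel.from_pfm("GCBOX", np.array(
        [[0, 0, 1, 0, 9, 0], [2, 1, 0, 0, 0, 1], [8, 9, 9, 10, 1, 9], [0, 0, 0, 0, 0, 0]]
    )),
    MotifModel.from_pfm(
        "DONOR",
        # splice-donor-like PFM with invariant GT at columns 4-5
        np.array(
            [
                [3, 6, 1, 0, 0, 5, 1, 2],
                [4, 1, 1, 0, 0, 0, 1, 2],
                [2, 2, 7, 10, 0, 4, 7, 3],
                [1, 1, 1, 0, 10, 1, 1, 3],
            ]
        ),
    ),
]


class TestBuildPWM:
    def test_stated_log_odds_arithmetic(self):
        pfm = np.array([[10], [0], [0], [0]])
        lod = build_pwm(pfm, pseudocount=1.0)
        assert lod[0, 0] == pytest.approx(np.log2((10.25 / 11) / 0.25), abs=1e-9)
        assert lod[0, 0] == pytest.approx(1.898, abs=1e-3)

    def test_equal_counts_uniform_background_scores_zero(self):
        lod = build_pwm(np.full((4, 3), 5.0))
        assert np.allclose(lod, 0.0)

    def test_background_equal_to_frequencies_scores_zero(self):
        pfm = np.array([[6.0], [2.0], [1.0], [1.0]])
        lod = build_pwm(pfm, background=pfm[:, 0] / 10.0, pseudocount=0.0)
        assert np.allclose(lod, 0.0)

    def test_zero_column_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(np.zeros((4, 2)), pseudocount=0.0)


class TestScanIUPAC:
    @pytest.mark.parametrize(
        "seq,hit", [("AATAAA", True), ("ATTAAA", True), ("AAAAAA", False)]
    )
    def test_degenerate_w_position(self, seq, hit):
        hits = scan_iupac(seq, "AWTAAA")
        assert bool(hits) == hit
        if hit:
            assert hits[0].offset == 0 and hits[0].strand == "sense"

    def test_n_in_window_never_matches(self):
        assert scan_iupac("AANAAA", "AWTAAA") == []
        assert scan_iupac("ANTAAA", "ANTAAA") == []  # consensus N matches ACGT only

    def test_overlapping_hits_reported(self):
        hits = scan_iupac("AAAA", "AA")
        assert [h.offset for h in hits] == [0, 1, 2]

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            scan_iupac("ACGT", "AXGT")

    def test_both_strand_coordinates(self):
        # GGGCGG sense at 2; its reverse complement CCGCCC antisense
        seq = "ATGGGCGGTA"
        hits = scan_iupac(seq, "CCGCCC", "both")
        (h,) = hits
        assert h.strand == "antisense"
        assert h.offset == 2  # 5'-most sense base of the site


def brute_force_pwm_scan(seq, motif):
    """Independent oracle: rescore every window from the log-odds definition."""
    w = motif.width
    lod = motif.logodds
    out = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if "N" in window:
            continue
        score = sum(lod["ACGT".index(b), j] for j, b in enumerate(window))
        if score >= motif.score_threshold * motif.max_score - 1e-9:
            out.append((i, pytest.approx(score)))
    return out


class TestScanPWM:
    def test_consensus_window_found(self):
        m = TEST_MOTIFS[2]  # TATA pwm, consensus CATATAA-ish; take argmax string
        consensus = "".join("ACGT"[i] for i in np.argmax(m.pfm, axis=0))
        seq = "GGGG" + consensus + "GGGG"
        hits = scan_pwm(seq, m)
        assert any(h.offset == 4 for h in hits)

    def test_sequence_shorter_than_motif(self):
        assert scan_pwm("ACG", TEST_MOTIFS[2]) == []

    @pytest.mark.parametrize("motif", TEST_MOTIFS, ids=lambda m: m.name)
    def test_matches_brute_force_oracle(self, motif):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = random_seq(rng.integers(50, 400), rng)
            if motif.kind == "pwm":
                got = [(h.offset, h.score) for h in scan_pwm(seq, motif)]
                assert got == brute_force_pwm_scan(seq, motif)
            else:
                got = [h.offset for h in scan_iupac(seq, motif.consensus)]
                oracle = [
                    i
                    for i in range(len(seq) - motif.width + 1)
                    if all(
                        b in IUPAC_CLASSES[c]
                        for b, c in zip(seq[i :], motif.consensus)
                    )
                ]
                assert got == oracle

    @pytest.mark.parametrize("motif", TEST_MOTIFS[:3], ids=lambda m: m.name)
    def test_revcomp_symmetry_both_strands(self, motif):
        rng = np.random.default_rng(13)
        seq = random_seq(500, rng)
        fwd = scan_pwm(seq, motif, "both") if motif.kind == "pwm" else scan_iupac(
            seq, motif.consensus, "both"
        )
        rev = scan_pwm(revcomp(seq), motif, "both") if motif.kind == "pwm" else scan_iupac(
            revcomp(seq), motif.consensus, "both"
        )
        L, w = len(seq), motif.width
        reflect = sorted(
            (L - h.offset - w, {"sense": "antisense", "antisense": "sense"}[h.strand])
            for h in rev
        )
        assert sorted((h.offset, h.strand) for h in fwd) == reflect

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        seq = random_seq(2_000, rng)
        base = TEST_MOTIFS[2]
        prev = None
        for thr in (0.5, 0.7, 0.9, 1.0):
            m = MotifModel.from_pfm("t", base.pfm, score_threshold=thr)
            hits = {h.offset for h in scan_pwm(seq, m)}
            if prev is not None:
                assert hits <= prev
            prev = hits


class TestPositionalProfile:
    def make_anchor_genome(self, window_seq):
        pad = "C" * 500
        seq = pad + window_seq + pad
        sc = Scaffold("s1", seq)
        tss = TSSRecord("s1", 500 + 400, "+")  # window [-400,100) spans window_seq
        return {"s1": sc}, [tss]

    def test_single_hit_single_bin(self):
        seq = ["G"] * 500
        # plant AATAAA with 5' base at offset -35 -> window index 365
        seq[365:371] = list("AATAAA")
        sc_map, anchors = self.make_anchor_genome("".join(seq))
        prof = positional_profile(anchors, sc_map, MotifModel.from_iupac("PAS", "AWTAAA"))
        assert prof.n_regions == 1
        assert prof.argmax_bin() == (-40, -30)
        assert prof.frequency.sum() == pytest.approx(1.0)

    def test_no_hits_zero_profile(self):
        sc_map, anchors = self.make_anchor_genome("G" * 500)
        prof = positional_profile(anchors, sc_map, MotifModel.from_iupac("PAS", "AWTAAA"))
        assert np.all(prof.frequency == 0)

    def test_gap_containing_anchor_excluded(self):
        sc_map, anchors = self.make_anchor_genome("G" * 250 + "N" + "G" * 249)
        with pytest.raises(ValueError, match="complete flanks"):
            positional_profile(anchors, sc_map, MotifModel.from_iupac("PAS", "AWTAAA"))

    def test_mass_conservation(self):
        rng = np.random.default_rng(8)
        seqs = [random_seq(500, rng, p=[0.32, 0.18, 0.18, 0.32]) for _ in range(30)]
        sc = Scaffold("s1", "C" * 100 + "".join(seqs) + "C" * 100)
        anchors = [
            TSSRecord("s1", 100 + i * 500 + 400, "+") for i in range(30)
        ]
        m = MotifModel.from_iupac("PAS", "AWTAAA")
        prof = positional_profile(anchors, {"s1": sc}, m)
        total_hits = sum(
            len(scan_iupac(sc.sequence[100 + i * 500 : 100 + (i + 1) * 500], "AWTAAA"))
            for i in range(30)
        )
        assert prof.frequency.sum() * prof.n_regions == pytest.approx(total_hits)


class TestCompositionProfile:
    def test_periodic_sequence(self):
        sc = Scaffold("s1", "ACGT" * 300)
        anchors = [TSSRecord("s1", 600, "+")]
        prof = composition_profile(anchors, {"s1": sc}, window=(-400, 100))
        # offset 0 sits at genomic 600 -> 'A'; A at offsets == 0 mod 4
        a_freq = prof.base_freq["A"]
        assert all(a_freq.loc[off] == 1.0 for off in range(-400, 99, 4))

    def test_cg_dinucleotide_phase(self):
        sc = Scaffold("s1", "CG" * 600)
        anchors = [TSSRecord("s1", 600, "+")]
        prof = composition_profile(anchors, {"s1": sc}, window=(-400, 100))
        cg = prof.dinuc_freq["CG"]
        assert all(cg.loc[off] == 1.0 for off in range(-400, 98, 2))
        assert all(cg.loc[off] == 0.0 for off in range(-399, 98, 2))


class TestMotifReaders:
    def test_jaspar_raw(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(
            ">TBP test\nA [ 16 0 0 ]\nC [ 0 16 0 ]\nG [ 0 0 16 ]\nT [ 0 0 0 ]\n"
        )
        (m,) = read_jaspar_pfm(p)
        assert m.name == "TBP"
        assert m.pfm.shape == (4, 3)
        assert np.argmax(m.pfm, axis=0).tolist() == [0, 1, 2]

    def test_meme_minimal(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF PAS\nletter-probability matrix: alength= 4 w= 2 nsites= 10 E= 0\n"
            " 1.0 0.0 0.0 0.0\n 0.0 0.0 0.0 1.0\n"
        )
        (m,) = read_meme_motifs(p)
        assert m.name == "PAS"
        assert m.pfm[0, 0] == pytest.approx(10.0)
        assert m.pfm[3, 1] == pytest.approx(10.0)
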