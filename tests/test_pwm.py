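import math

import numpy as np
import pytest

from promoterlab.pwm import (
    PWMModel,
    build_pwm,
    encode,
    patser_threshold,
    predicted_sites,
    proto_sites,
    reverse_complement,
    scan_scores,
    score_window,
)
from promoterlab.synth import DEFAULT_ACTIVATOR_CONSENSUS, profile_pwm

SITES = ["ACGT", "ACGT", "AAGT", "ACGA"]
LOG2_3 = math.log2(3.0)


def test_build_pwm_probabilities_by_hand():
    pwm = build_pwm(SITES, "toy", "tf", pseudocount=0.0)
    expected = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.25, 0.75, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.25, 0.0, 0.0, 0.75],
        ]
    )
    np.testing.assert_allclose(pwm.prob_matrix, expected)
    assert pwm.consensus == "ACGT"


def test_logodds_and_negative_infinity():
    pwm = build_pwm(SITES, "toy", "tf", pseudocount=0.0)
    lo = pwm.logodds_matrix
    assert lo[0, 0] == pytest.approx(2.0)
    assert lo[1, 1] == pytest.approx(LOG2_3)
    assert lo[1, 0] == pytest.approx(0.0)
    assert np.isneginf(lo[0, 1])  # never-seen base with pseudocount 0


def test_information_content_by_hand():
    pwm = build_pwm(SITES, "toy", "tf", pseudocount=0.0)
    # conserved columns carry 2 bits; 0.25/0.75 columns carry
    # 2 + 0.25 log2 0.25 + 0.75 log2 0.75 bits
    col = 2.0 + 0.25 * math.log2(0.25) + 0.75 * math.log2(0.75)
    assert pwm.information_content == pytest.approx(4.0 + 2.0 * col, abs=1e-12)


def test_patser_threshold_units():
    ic = 10.0
    assert patser_threshold(ic, "nats") == pytest.approx(
        math.log(ic * math.log(2.0))
    )
    assert patser_threshold(ic, "bits") == pytest.approx(math.log(ic))
    assert patser_threshold(0.0) == math.inf


def test_score_window_by_hand():
    pwm = build_pwm(SITES, "toy", "tf", pseudocount=0.0)
    assert score_window(pwm, "ACGT") == pytest.approx(4.0 + 2.0 * LOG2_3)
    assert score_window(pwm, "AAGT") == pytest.approx(4.0 + LOG2_3)
    assert np.isneginf(score_window(pwm, "CCGT"))
    with pytest.raises(ValueError):
        score_window(pwm, "ACGTT")


def test_scores_match_biopython_pssm():
    from Bio import motifs
    from Bio.Seq import Seq

    pc = 0.5
    pwm = build_pwm(SITES, "toy", "tf", pseudocount=pc)
    motif = motifs.create([Seq(s) for s in SITES])
    pssm = motif.counts.normalize(pseudocounts=pc).log_odds()
    seq = "GACGTAAGTACGAT"
    theirs = np.asarray(pssm.calculate(Seq(seq)), dtype=float)
    ours = scan_scores(pwm, [seq])["top"][0]
    np.testing.assert_allclose(ours, theirs, atol=1e-5)


def test_bottom_strand_equals_reverse_complement_scan():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    pwm = build_pwm(SITES, "toy", "tf", pseudocount=0.5)
    sc = scan_scores(pwm, [seq])
    # window starting at top position w covers rc-sequence positions
    # L - w - X .. L - w - 1, so the bottom scores are the reversed
    # top-strand scores of the reverse complement
    rc = scan_scores(pwm, [reverse_complement(seq)])
    np.testing.assert_allclose(sc["bottom"][0], rc["top"][0][::-1], atol=1e-12)
    # and per-window brute force: bottom score w = forward score of the
    # reverse complement of that window
    for w in range(len(seq) - pwm.length + 1):
        window = seq[w : w + pwm.length]
        assert sc["bottom"][0][w] == pytest.approx(
            score_window(pwm, reverse_complement(window)), abs=1e-12
        )


def test_predicted_site_coordinates_both_strands():
    sigma = profile_pwm(
        DEFAULT_ACTIVATOR_CONSENSUS["sigma_composite"], "sigma", "sigma"
    )
    seq = "C" * 20 + sigma.consensus + "C" * 20
    hits = predicted_sites(sigma, seq)
    assert len(hits) == 1
    assert (hits[0].start, hits[0].strand, hits[0].kind) == (21, "top", "predicted")
    assert hits[0].score == pytest.approx(
        13 * math.log2(0.94 / 0.25), abs=1e-12
    )
    rc_hits = predicted_sites(sigma, reverse_complement(seq))
    assert len(rc_hits) == 1
    assert (rc_hits[0].start, rc_hits[0].strand) == (21, "bottom")


def test_proto_site_is_subthreshold_and_positive():
    from promoterlab.simstudies import PLANTED_PROTO_WINDOW

    sigma = profile_pwm(
        DEFAULT_ACTIVATOR_CONSENSUS["sigma_composite"], "sigma", "sigma"
    )
    seq = "C" * 20 + PLANTED_PROTO_WINDOW + "C" * 20
    assert predicted_sites(sigma, seq) == []
    protos = proto_sites(sigma, seq)
    assert len(protos) == 1
    hit = protos[0]
    assert hit.start == 21 and hit.kind == "proto"
    assert 0.0 < hit.score < sigma.patser_threshold


def test_encode_decode_and_reverse_complement():
    np.testing.assert_array_equal(encode("ACGTN"), [0, 1, 2, 3, -1])
    assert reverse_complement("AACGT") == "ACGTT"
    assert reverse_complement(reverse_complement("GATTACA")) == "GATTACA"


def test_build_pwm_validation():
    with pytest.raises(ValueError):
        build_pwm([], "empty")
    with pytest.raises(ValueError):
        build_pwm(["ACGT", "ACG"], "ragged")
    with pytest.raises(ValueError):
        build_pwm(["ACGN"], "bad_base")
    with pytest.raises(ValueError):
        PWMModel("bad", "tf", np.array([[0.5, 0.5, 0.5, 0.5]]))


def test_site_list_roundtrip(tmp_path):
    from promoterlab.pwm import load_site_lists, pwms_to_tsv
    import pandas as pd

    (tmp_path / "facA.txt").write_text("ACGT\nACGT\nAAGT\n")
    (tmp_path / "facB.txt").write_text("TTTT\nTTTA\n")
    models = load_site_lists(str(tmp_path), pseudocount=0.5)
    assert [m.factor_id for m in models] == ["facA", "facB"]
    out = tmp_path / "pwms.tsv"
    pwms_to_tsv(models, str(out))
    df = pd.read_csv(out, sep="\t")
    assert set(df["factor_id"]) == {"facA", "facB"}
    assert len(df) == 8  # 4 positions per factor
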