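import numpy as np
import pytest

from promoterlab.screen import proto_site_census
from promoterlab.synth import (
    DEFAULT_ACTIVATOR_CONSENSUS,
    DEFAULT_REPRESSOR_CONSENSUS,
    GroundTruthModel,
    bin_probabilities,
    default_ground_truth,
    generate_parents,
    inactive_parents,
    make_experiment,
    mutagenize,
    profile_pwm,
    simulate_sort_reads,
    true_activities,
    true_activity,
)
from promoterlab.synth import _truncated_binomial_pmf
from promoterlab.pwm import reverse_complement, score_window


def test_generate_parents_at_content_and_validation():
    parents = generate_parents(30, 150, 0.6, seed=0)
    assert len(parents) == 30 and all(len(p) == 150 for p in parents)
    for p in parents:
        at = (p.count("A") + p.count("T")) / 150
        assert abs(at - 0.6) <= 0.05
    with pytest.raises(ValueError):
        generate_parents(0, 150, 0.5)
    with pytest.raises(ValueError):
        generate_parents(5, 150, 1.5)
    with pytest.raises(ValueError):
        generate_parents(5, 90, 0.5)  # outside [100, 200] bp
    with pytest.raises(ValueError):
        generate_parents(5, 150, 0.5, "genomic_like")  # needs a pwm_set


def test_genomic_like_parents_have_fewer_proto_sites():
    model = default_ground_truth(0)
    pwms = [p for p, _ in model.activator_pwms]
    random_lib = generate_parents(60, 150, 0.5, seed=1)
    depleted = generate_parents(
        60, 150, 0.5, "genomic_like", pwm_set=pwms, seed=1,
        proto_quantile=0.5,
    )
    c_rand = [proto_site_census(s, pwms)[0] for s in random_lib]
    c_dep = [proto_site_census(s, pwms)[0] for s in depleted]
    assert np.median(c_dep) < np.median(c_rand)
    assert np.mean(c_dep) < np.mean(c_rand)


def test_mutagenize_counts_positions_and_determinism():
    parent = "ACGT" * 30
    daughters = mutagenize(parent, 200, 0.02, max_mutations=5, seed=3)
    assert len(daughters) == 200
    for d in daughters:
        n_mut = sum(1 for a, b in zip(parent, d) if a != b)
        assert 1 <= n_mut <= 5  # truncated binomial support
    assert mutagenize(parent, 50, 0.02, seed=4) == mutagenize(
        parent, 50, 0.02, seed=4
    )
    assert mutagenize(parent, 50, 0.02, seed=4) != mutagenize(
        parent, 50, 0.02, seed=5
    )
    with pytest.raises(ValueError):
        mutagenize(parent, 10, 0.0)


def test_truncated_binomial_pmf_normalized():
    pmf = _truncated_binomial_pmf(150, 0.02, 10)
    assert pmf.sum() == pytest.approx(1.0)
    assert pmf.size == 10 and (pmf > 0).all()


def test_true_activity_weight_arithmetic():
    weight = 0.1
    model = default_ground_truth(0, activator_weight=weight)
    sigma = model.activator_pwms[0][0]
    seq = "C" * 60 + sigma.consensus + "C" * 60
    excess = score_window(sigma, sigma.consensus) - sigma.patser_threshold
    # only the sigma site scores above any panel threshold in this
    # construct, so activity is basal + weight * excess, unclamped
    assert true_activity(seq, model, "GFP") == pytest.approx(
        1.0 + weight * excess, abs=1e-9
    )
    assert true_activity(seq, model, "RFP") == pytest.approx(1.0)
    # the reverse complement drives RFP instead
    assert true_activity(
        reverse_complement(seq), model, "RFP"
    ) == pytest.approx(1.0 + weight * excess, abs=1e-9)
    # strong weights clamp at the 4.0 a.u. ceiling
    strong = default_ground_truth(0, activator_weight=0.6)
    assert true_activity(seq, strong, "GFP") == 4.0


def test_repressor_subtracts_on_either_strand():
    act_w, rep_w = 0.1, 0.7
    model = default_ground_truth(
        0, activator_weight=act_w, repressor_weight=rep_w
    )
    sigma = model.activator_pwms[0][0]
    rep = model.repressor_pwms[0][0]
    excess = score_window(sigma, sigma.consensus) - sigma.patser_threshold
    seq = ("C" * 30 + sigma.consensus + "C" * 30 + rep.consensus + "C" * 30)
    expected = 1.0 + act_w * excess - rep_w
    assert true_activity(seq, model, "GFP") == pytest.approx(expected, abs=1e-9)
    # repression is orientation-independent: the reverse-complemented
    # repressor site still silences the GFP reporter
    flipped = ("C" * 30 + sigma.consensus + "C" * 30
               + reverse_complement(rep.consensus) + "C" * 30)
    assert true_activity(flipped, model, "GFP") == pytest.approx(
        expected, abs=1e-9
    )


def test_profile_pwm_matrix_shape_and_consensus():
    pwm = profile_pwm("ACGTAC", "x", "tf", conservation=0.9)
    assert pwm.consensus == "ACGTAC"
    np.testing.assert_allclose(pwm.prob_matrix.sum(axis=1), 1.0)
    assert pwm.prob_matrix[0, 0] == pytest.approx(0.9)
    with pytest.raises(ValueError):
        profile_pwm("ACGT", "x", "tf", conservation=0.2)


def test_default_panel_composition():
    model = default_ground_truth(0, repressor_weight=1.0)
    ids = [p.factor_id for p, _ in model.activator_pwms]
    assert ids == list(DEFAULT_ACTIVATOR_CONSENSUS)
    classes = {p.factor_id: p.factor_class for p, _ in model.activator_pwms}
    assert classes["sigma_composite"] == "sigma"
    assert all(v == "tf" for k, v in classes.items() if k != "sigma_composite")
    assert model.repressor_pwms[0][0].consensus == DEFAULT_REPRESSOR_CONSENSUS


def test_bin_probabilities_rows_sum_to_one():
    model = default_ground_truth(0)
    acts = np.array([1.0, 1.6, 2.4, 3.9, 4.0])
    probs = bin_probabilities(acts, model)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert (probs >= 0).all()
    # stronger activity shifts mass to higher bins
    assert probs[0, 0] > probs[-1, 0] and probs[-1, 3] > probs[0, 3]


def test_bin_probabilities_zero_noise_is_indicator():
    model = GroundTruthModel(cell_noise_sd=0.0)
    acts = np.array([1.0, 1.75, 2.0, 3.25, 4.0])
    probs = bin_probabilities(acts, model)
    np.testing.assert_array_equal(probs.argmax(axis=1), [0, 1, 1, 3, 3])
    np.testing.assert_allclose(probs.max(axis=1), 1.0)


def test_simulate_sort_reads_budgets():
    model = GroundTruthModel(cell_noise_sd=0.0)
    acts = {"GFP": np.full(5, 1.0), "RFP": np.full(5, 1.0)}
    table = simulate_sort_reads(
        acts, [f"s{i}" for i in range(5)], cells_per_sequence=50,
        reads_per_bin=1000, model=model, seed=0,
    )
    df = table.data
    by_bin = df[df["channel"] == "GFP"].groupby("bin")["reads"].sum()
    assert by_bin[1] == 1000  # every cell sits in bin 1
    assert by_bin[2] == by_bin[3] == by_bin[4] == 0  # empty bins get no reads


def test_inactive_parents_are_inactive():
    model = default_ground_truth(0, activator_weight=0.6)
    parents = inactive_parents(10, 150, 0.5, model, seed=5)
    acts = true_activities(parents, model)
    assert (acts["GFP"] < 1.5).all() and (acts["RFP"] < 1.5).all()


def test_make_experiment_deterministic_and_structured():
    model = default_ground_truth(0)
    kwargs = dict(n_parents=3, n_daughters=20, reads_per_bin=2000,
                  cells_per_sequence=50, seed=42)
    exp1 = make_experiment(model, **kwargs)
    exp2 = make_experiment(model, **kwargs)
    assert exp1.parents == exp2.parents
    assert exp1.daughters == exp2.daughters
    assert exp1.read_counts.data.equals(exp2.read_counts.data)
    assert exp1.true_activity.equals(exp2.true_activity)
    exp3 = make_experiment(model, **{**kwargs, "seed": 43})
    assert exp3.parents != exp1.parents
    assert len(exp1.sequence_ids()) == 3 * 21
    seqs = exp1.sequences()
    assert seqs["p0000"] == exp1.parents[0]
    assert len(seqs["p0001_d00005"]) == 150
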