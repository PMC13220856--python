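"""End-to-end validation studies on synthetic Sort-Seq experiments.

Each study generates data with :mod:`promoterlab.synth` under a known
ground truth, runs the downstream estimators, and reports a recovery or
calibration metric.  The studies double as executable documentation of
what the pipeline can and cannot resolve at realistic problem sizes:

* rank agreement between true activity and the bin-weighted
  fluorescence estimator;
* recovery of a planted proto-site that point mutations convert into an
  activating site (hotspot + gain_activating call at the right place);
* recovery of a planted repressor site whose destruction derepresses
  the reporter (loss_repressing call);
* the P_new contrast between proto-site-rich and proto-site-poor parent
  classes;
* false-positive calibration of the screen and of hotspot calling under
  a null with no sequence-function relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, spearmanr

from .families import MutantFamily
from .hotspots import call_hotspots, mi_profile, smooth_profile
from .pwm import PWMModel, build_pwm, predicted_sites, score_window
from .readproc import fluor_from_counts, rescale_two_bin
from .screen import association_scan
from .synth import (
    GroundTruthModel,
    default_ground_truth,
    generate_parents,
    inactive_parents,
    mutagenize,
    simulate_count_matrices,
    true_activities,
)

#: proto-site for the default sigma-composite PWM: four mismatches from
#: its consensus, scoring 2.62 bits (just under the 2.65-bit Patser
#: threshold), where correcting any one mismatch yields a predicted site
PLANTED_PROTO_WINDOW = "TGGATATCTAGTG"

#: repressor with an all-or-nothing site: zero pseudocount makes any
#: point mutation in the site drop its score to -inf
REPRESSOR_SITE = "GCGGCC"


def _repressor_pwm() -> PWMModel:
    return build_pwm([REPRESSOR_SITE] * 8, "gc_repressor", "tf", pseudocount=0.0)


def _family_fluor(
    sequences: list[str],
    model: GroundTruthModel,
    cells: int,
    reads_per_bin: int,
    seed: int,
    channels: tuple[str, ...] = ("GFP",),
    scheme: str = "four_bin",
) -> dict[str, np.ndarray]:
    """Simulate sorting + sequencing and return estimated scores.

    ``scheme='two_bin'`` reproduces the OFF/ON sorting used for pooled
    mutagenesis libraries: bins 2-4 are pooled into ON, scores are
    computed on the codes {1, 2} and rescaled onto [1, 4].
    """
    acts = true_activities(sequences, model)
    mats = simulate_count_matrices(acts, cells, reads_per_bin, model, 1, seed)
    out = {}
    for ch in channels:
        mat = mats[(ch, 1)]
        if scheme == "two_bin":
            pooled = np.column_stack([mat[:, 0], mat[:, 1:].sum(axis=1)])
            out[ch] = rescale_two_bin(fluor_from_counts(pooled))
        else:
            out[ch] = fluor_from_counts(mat)
    return out


def fluorescence_rank_recovery(
    n_sequences: int = 200,
    cell_noise_sd: float = 0.1,
    reads_per_bin: int = 10_000,
    cells_per_sequence: int = 200,
    seed: int = 0,
) -> float:
    """Spearman correlation between true activity and estimated fluorescence.

    Activities are spread evenly over [1, 4]; reads are simulated at the
    given depth and scored with the bin-weighted estimator.
    """
    model = GroundTruthModel(cell_noise_sd=cell_noise_sd, seed=seed)
    acts = np.linspace(1.0, 4.0, n_sequences)
    mats = simulate_count_matrices(
        {"GFP": acts, "RFP": acts}, cells_per_sequence, reads_per_bin,
        model, 1, seed,
    )
    est = fluor_from_counts(mats[("GFP", 1)])
    return float(spearmanr(acts, est).statistic)


def _splice(seq: str, insert: str, start: int) -> str:
    return seq[:start] + insert + seq[start + len(insert):]


def build_activator_family(
    seed: int,
    n_daughters: int = 1500,
    activator_weight: float = 0.6,
    cell_noise_sd: float = 0.1,
    reads_per_bin: int = 20_000,
    scheme: str = "four_bin",
) -> tuple[MutantFamily, GroundTruthModel, int]:
    """An inactive parent with one planted proto-site, plus daughters.

    Returns (family with estimated GFP scores, ground-truth model,
    1-based window start of the planted proto-site).  The parent is
    GC-leaning so accidental -10 box sites are rare; candidates where
    splicing the proto window still leaves predicted sites or promoter
    activity are redrawn.
    """
    model = default_ground_truth(
        seed, activator_weight=activator_weight, cell_noise_sd=cell_noise_sd
    )
    pwm = model.activator_pwms[0][0]
    rng = np.random.default_rng(seed)
    window_start = 70  # 0-based splice position, away from the ends
    for _ in range(50):
        cand = inactive_parents(
            1, 150, 0.40, model, seed=int(rng.integers(2**31))
        )[0]
        parent = _splice(cand, PLANTED_PROTO_WINDOW, window_start)
        acts = true_activities([parent], model)
        inactive = acts["GFP"][0] <= model.basal_activity and (
            acts["RFP"][0] <= model.basal_activity
        )
        if inactive and not predicted_sites(pwm, parent):
            break
    else:
        raise RuntimeError("could not build a clean planted-activator parent")
    daughters = mutagenize(
        parent, n_daughters, 0.02, 10, seed=int(rng.integers(2**31))
    )
    fluor = _family_fluor(
        daughters, model, 200, reads_per_bin, int(rng.integers(2**31)),
        scheme=scheme,
    )
    fam = MutantFamily("planted_act", parent, daughters, fluor)
    return fam, model, window_start + 1


def activator_recovery(
    n_replicates: int = 100,
    n_daughters: int = 1500,
    tolerance_bp: int = 2,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of simulations recovering the planted activating site.

    Per replicate, checks (a) a mutual-information hotspot within the
    planted window +/- tolerance and (b) a gain_activating call whose
    window start is within tolerance of the planted start.
    """
    rng = np.random.default_rng(seed)
    pwm_len = len(PLANTED_PROTO_WINDOW)
    hot_ok = call_ok = 0
    for _ in range(n_replicates):
        fam, model, start = build_activator_family(
            int(rng.integers(2**31)), n_daughters
        )
        smoothed = smooth_profile(mi_profile(fam, "GFP"))
        hits = call_hotspots(smoothed)
        lo, hi = start - tolerance_bp, start + pwm_len - 1 + tolerance_bp
        if any(lo <= h <= hi for h in hits):
            hot_ok += 1
        calls = association_scan(
            [fam], [model.activator_pwms[0][0]], channels=("GFP",)
        )
        gained = calls[calls["direction"] == "gain_activating"]
        if (abs(gained["window_start"] - start) <= tolerance_bp).any():
            call_ok += 1
    return {
        "hotspot_rate": hot_ok / n_replicates,
        "gain_call_rate": call_ok / n_replicates,
        "n_replicates": n_replicates,
    }


def build_repressor_family(
    seed: int,
    n_daughters: int = 1500,
    activator_weight: float = 0.6,
    repressor_weight: float | None = None,
    cell_noise_sd: float = 0.1,
    reads_per_bin: int = 20_000,
) -> tuple[MutantFamily, GroundTruthModel, int]:
    """An inactive parent carrying an activator silenced by a repressor.

    The parent holds a consensus activator motif and, downstream, a
    consensus repressor site; daughters that destroy the repressor site
    (any point mutation in it) derepress the reporter.  The repressor
    weight defaults to the consensus activator contribution plus a 1
    a.u. margin, so repression cancels the activation exactly as long
    as the site is intact.  Returns (family, model, 1-based repressor
    window start).
    """
    base = default_ground_truth(seed, activator_weight=activator_weight,
                                cell_noise_sd=cell_noise_sd)
    act_pwm = base.activator_pwms[0][0]
    rep_pwm = _repressor_pwm()
    if repressor_weight is None:
        consensus_excess = (
            score_window(act_pwm, act_pwm.consensus) - act_pwm.patser_threshold
        )
        repressor_weight = activator_weight * consensus_excess + 1.0
    model = GroundTruthModel(
        activator_pwms=[(act_pwm, activator_weight)],
        repressor_pwms=[(rep_pwm, repressor_weight)],
        cell_noise_sd=cell_noise_sd,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    act_start, rep_start = 60, 90  # 0-based splice positions
    for _ in range(50):
        cand = inactive_parents(1, 150, 0.40, base,
                                seed=int(rng.integers(2**31)))[0]
        parent = _splice(cand, act_pwm.consensus, act_start)
        parent = _splice(parent, REPRESSOR_SITE, rep_start)
        acts = true_activities([parent], model)
        # exactly one repressor site, and the parent stays inactive
        if len(predicted_sites(rep_pwm, parent)) == 1 and (
            acts["GFP"][0] < 1.5 and acts["RFP"][0] < 1.5
        ):
            break
    else:
        raise RuntimeError("could not build a clean planted-repressor parent")
    daughters = mutagenize(
        parent, n_daughters, 0.02, 10, seed=int(rng.integers(2**31))
    )
    fluor = _family_fluor(
        daughters, model, 200, reads_per_bin, int(rng.integers(2**31))
    )
    fam = MutantFamily("planted_rep", parent, daughters, fluor)
    return fam, model, rep_start + 1


def repressor_recovery(
    n_replicates: int = 100,
    n_daughters: int = 1500,
    tolerance_bp: int = 2,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of simulations recovering the planted repressing site."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_replicates):
        fam, model, start = build_repressor_family(
            int(rng.integers(2**31)), n_daughters
        )
        calls = association_scan(
            [fam], [model.repressor_pwms[0][0]], channels=("GFP",)
        )
        lost = calls[calls["direction"] == "loss_repressing"]
        if (abs(lost["window_start"] - start) <= tolerance_bp).any():
            ok += 1
    return {"loss_call_rate": ok / n_replicates, "n_replicates": n_replicates}


def p_new_class_contrast(
    n_parents_per_class: int = 50,
    n_daughters: int = 300,
    activator_weight: float = 0.6,
    proto_quantile: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """P_new for proto-site-rich (random) vs proto-site-poor parents.

    Parents of the poor class are rejection-sampled below the
    ``proto_quantile`` quantile of the random-class proto-site count at
    matched AT content; all parents start transcriptionally inactive.
    Reports per-class median P_new on the GFP channel and the one-sided
    Mann-Whitney p-value for rich > poor.
    """
    model = default_ground_truth(seed, activator_weight=activator_weight)
    rng = np.random.default_rng(seed)
    p_new_by_class: dict[str, list[float]] = {}
    for cls in ("random", "genomic_like"):
        parents = inactive_parents(
            n_parents_per_class, 150, 0.5, model, parent_class=cls,
            seed=int(rng.integers(2**31)), proto_quantile=proto_quantile,
        )
        vals = []
        for parent in parents:
            daughters = mutagenize(
                parent, n_daughters, 0.02, 10, seed=int(rng.integers(2**31))
            )
            fluor = _family_fluor(
                daughters, model, 100, 5000, int(rng.integers(2**31))
            )["GFP"]
            defined = fluor[~np.isnan(fluor)]
            vals.append(float((defined >= 1.5).mean()))
        p_new_by_class[cls] = vals
    rich, poor = p_new_by_class["random"], p_new_by_class["genomic_like"]
    p = float(
        mannwhitneyu(rich, poor, alternative="greater").pvalue
    )
    return {
        "median_p_new_rich": float(np.median(rich)),
        "median_p_new_poor": float(np.median(poor)),
        "mwu_p_one_sided": p,
        "n_per_class": n_parents_per_class,
    }


def _weak_pwms() -> list[PWMModel]:
    """Low-information PWMs whose predicted sites are common by chance."""
    sites_a = ["ACGT", "ACGA", "ACTT", "AGGT", "CCGT", "ACGG", "TCGT", "ACAT"]
    sites_b = ["TGCA", "TGCC", "TACA", "TGTA", "CGCA", "TGCG", "AGCA", "TTCA"]
    sites_c = ["GATC", "GATA", "GCTC", "GTTC", "AATC", "GAGC", "TATC", "GACC"]
    sites_d = ["CTAG", "CTAA", "CCAG", "CGAG", "TTAG", "CTGG", "ATAG", "CTCG"]
    return [
        build_pwm(sites_a, "weak_a", "tf", pseudocount=1.0),
        build_pwm(sites_b, "weak_b", "tf", pseudocount=1.0),
        build_pwm(sites_c, "weak_c", "tf", pseudocount=1.0),
        build_pwm(sites_d, "weak_d", "tf", pseudocount=1.0),
    ]


def null_screen_calibration(
    n_daughters: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Screen false-positive rate when sequence and fluorescence are unlinked.

    A zero-effect model (no activators or repressors) makes every
    daughter's activity basal; low-information PWMs give many windows
    with both groups populated.  Reports the BH-significant fraction of
    tests and the number of tests run.
    """
    model = GroundTruthModel(cell_noise_sd=0.1, seed=seed)
    rng = np.random.default_rng(seed)
    parent = generate_parents(1, 150, 0.5, seed=int(rng.integers(2**31)))[0]
    daughters = mutagenize(parent, n_daughters, 0.02, 10,
                           seed=int(rng.integers(2**31)))
    fluor = _family_fluor(daughters, model, 100, 20_000,
                          int(rng.integers(2**31)))
    fam = MutantFamily("null", parent, daughters, fluor)
    calls = association_scan([fam], _weak_pwms(), channels=("GFP",))
    n_tests = int(calls["p_value"].notna().sum())
    n_sig = int((calls["q_value"] < 0.05).sum())
    return {
        "significant_fraction": n_sig / max(n_tests, 1),
        "n_tests": n_tests,
    }


def shuffled_fluorescence_hotspot_rate(
    n_shuffles: int = 100,
    n_daughters: int = 5000,
    seed: int = 0,
) -> dict[str, float]:
    """How often a fluorescence-shuffled family shows any hotspot.

    Shuffling breaks the sequence-fluorescence link, so residual
    hotspots measure the false-positive behaviour of the smoothed
    mutual-information peak caller.  The family is scored through the
    pooled OFF/ON path of the mutagenesis libraries.  The default
    family size keeps the plug-in estimator's upward bias -- about
    (levels-1)(bases-1)/(2 N ln 2) bits -- at roughly half the hotspot
    threshold; much smaller families would trip the caller on bias
    alone.  Returns the fraction of shuffles with zero hotspots at the
    default threshold and smoothing.
    """
    fam, _, _ = build_activator_family(
        seed, n_daughters=n_daughters, scheme="two_bin",
        reads_per_bin=50_000,
    )
    rng = np.random.default_rng(seed)
    scores = fam.fluor["GFP"]
    clean = 0
    for _ in range(n_shuffles):
        shuffled = MutantFamily(
            fam.parent_id, fam.parent_sequence, fam.daughters,
            {"GFP": rng.permutation(scores)},
        )
        smoothed = smooth_profile(mi_profile(shuffled, "GFP"))
        if not call_hotspots(smoothed):
            clean += 1
    return {"no_hotspot_fraction": clean / n_shuffles, "n_shuffles": n_shuffles}
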