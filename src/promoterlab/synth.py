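"""Synthetic Sort-Seq experiments with known ground truth.

The generator emulates the structure of a dual-reporter promoter assay:
parent sequences without promoter activity, error-prone-PCR point-mutant
daughters, a planted PWM model that maps sequence to expression on each
strand, log-normal cell-to-cell noise, multinomial sorting of cells
into four fluorescence bins per channel, and multinomial read sampling
per bin.  Every stochastic draw flows from a single integer seed, so a
fixed configuration reproduces byte-identical outputs.

Expression follows a clamped linear model: activity in arbitrary units
is the basal level, plus for each activator PWM a weight times the
excess of the best top-strand window score over the Patser threshold,
minus for each repressor PWM a weight when a predicted site is present,
clamped to [1, 4].  The GFP channel reads the sequence as given and the
RFP channel reads its reverse complement (the bottom strand drives the
red reporter).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pwm import PWMModel, encode, reverse_complement, scan_scores
from .readproc import BinCountTable, COUNT_COLUMNS

Channel = Literal["GFP", "RFP"]
CHANNELS: tuple[Channel, Channel] = ("GFP", "RFP")

ACTIVITY_MIN, ACTIVITY_MAX = 1.0, 4.0


@dataclass
class GroundTruthModel:
    """Planted sequence-to-expression model for the generator.

    ``activator_pwms`` and ``repressor_pwms`` pair each PWM with an
    effect weight: a.u. per bit of score above the Patser threshold for
    activators, and a flat a.u. penalty per factor with a predicted
    site for repressors.  ``bin_boundaries`` are the three cut points
    (a.u.) shared by both channels that partition fluorescence into
    four sorting bins.
    """

    activator_pwms: list[tuple[PWMModel, float]] = field(default_factory=list)
    repressor_pwms: list[tuple[PWMModel, float]] = field(default_factory=list)
    basal_activity: float = 1.0
    cell_noise_sd: float = 0.1
    bin_boundaries: tuple[float, float, float] = (1.75, 2.5, 3.25)
    seed: int = 0

    def __post_init__(self) -> None:
        b = self.bin_boundaries
        if not (b[0] < b[1] < b[2]):
            raise ValueError("bin_boundaries must be strictly increasing")
        if self.basal_activity < 1.0:
            raise ValueError("basal_activity must be >= 1")
        for pwm, w in self.activator_pwms + self.repressor_pwms:
            if not math.isfinite(w):
                raise ValueError(f"{pwm.factor_id}: non-finite effect weight")
        if self.cell_noise_sd < 0:
            raise ValueError("cell_noise_sd must be >= 0")


def generate_parents(
    n: int,
    length: int,
    at_content: float,
    parent_class: Literal["random", "genomic_like"] = "random",
    pwm_set: Sequence[PWMModel] = (),
    seed: int = 0,
    at_tolerance: float = 0.05,
    proto_quantile: float = 0.5,
    n_reference: int = 200,
    max_attempts_per_parent: int = 2000,
) -> list[str]:
    """Sample parent sequences with a target AT content.

    Bases are drawn i.i.d. with P(A) = P(T) = at/2; sequences whose
    realized AT content strays more than ``at_tolerance`` from the
    request are redrawn.  ``genomic_like`` parents additionally pass
    rejection sampling that keeps only candidates whose total
    proto-site count over ``pwm_set`` falls below the
    ``proto_quantile`` quantile of a matched random-class sample --
    an operational stand-in for a genome depleted of near-sites.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < at_content < 1:
        raise ValueError("at_content must be in (0, 1)")
    if not 100 <= length <= 200:
        raise ValueError("parent length must be within [100, 200] bp")
    rng = np.random.default_rng(seed)

    def draw() -> str:
        for _ in range(max_attempts_per_parent):
            probs = [at_content / 2, (1 - at_content) / 2,
                     (1 - at_content) / 2, at_content / 2]
            codes = rng.choice(4, size=length, p=probs)
            seq = "".join("ACGT"[c] for c in codes)
            at = (seq.count("A") + seq.count("T")) / length
            if abs(at - at_content) <= at_tolerance:
                return seq
        raise RuntimeError(
            f"could not sample a sequence with AT content within "
            f"{at_tolerance:.0%} of {at_content:.0%} in "
            f"{max_attempts_per_parent} attempts"
        )

    if parent_class == "random":
        return [draw() for _ in range(n)]

    if not pwm_set:
        raise ValueError("genomic_like parents require a pwm_set")
    from .screen import proto_site_census

    reference = [proto_site_census(draw(), pwm_set)[0] for _ in range(n_reference)]
    cutoff = float(np.quantile(reference, proto_quantile))
    parents: list[str] = []
    attempts = 0
    cap = n * max_attempts_per_parent
    while len(parents) < n:
        if attempts >= cap:
            raise RuntimeError(
                f"rejection sampling exhausted {cap} attempts without "
                f"finding {n} sequences with proto-site count < {cutoff:g} "
                f"(quantile {proto_quantile:g} of the random-class distribution)"
            )
        attempts += 1
        cand = draw()
        if proto_site_census(cand, pwm_set)[0] < cutoff:
            parents.append(cand)
    return parents


def inactive_parents(
    n: int,
    length: int,
    at_content: float,
    model: GroundTruthModel,
    parent_class: Literal["random", "genomic_like"] = "random",
    seed: int = 0,
    proto_quantile: float = 0.5,
    activity_threshold: float = 1.5,
    max_rounds: int = 200,
) -> list[str]:
    """Parents without promoter activity on either strand.

    Emulates the sorting step that selects non-fluorescent sequences as
    mutagenesis parents: candidates are drawn with
    :func:`generate_parents` and kept only when their ground-truth
    activity stays below the promoter threshold on both channels.
    """
    pwm_set = [p for p, _ in model.activator_pwms + model.repressor_pwms]
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for _ in range(max_rounds):
        cand = generate_parents(
            max(n, 8), length, at_content, parent_class, pwm_set,
            seed=int(rng.integers(2**31)), proto_quantile=proto_quantile,
        )
        acts = true_activities(cand, model)
        ok = (acts["GFP"] < activity_threshold) & (
            acts["RFP"] < activity_threshold
        )
        kept.extend(s for s, good in zip(cand, ok) if good)
        if len(kept) >= n:
            return kept[:n]
    raise RuntimeError(
        f"could not find {n} transcriptionally inactive parents in "
        f"{max_rounds} sampling rounds"
    )


def _truncated_binomial_pmf(
    length: int, rate: float, max_mutations: int
) -> np.ndarray:
    """PMF of the mutation count: Binomial(L, rate) restricted to [1, cap]."""
    from scipy.stats import binom

    ks = np.arange(1, max_mutations + 1)
    pmf = binom.pmf(ks, length, rate)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("mutation_rate leaves no mass on 1..max_mutations")
    return pmf / total


def mutagenize(
    parent: str,
    n_daughters: int,
    mutation_rate: float,
    max_mutations: int = 10,
    seed: int = 0,
) -> list[str]:
    """Point-mutant daughters of a parent (no indels).

    Each daughter's mutation count is drawn from a binomial truncated
    to [1, ``max_mutations``]; mutated positions are sampled without
    replacement and each substituted base is uniform over the three
    alternatives.
    """
    if not 0 < mutation_rate < 1:
        raise ValueError("mutation_rate must be in (0, 1)")
    if max_mutations < 1:
        raise ValueError("max_mutations must be >= 1")
    L = len(parent)
    if mutation_rate * L > 2 * max_mutations:
        warnings.warn(
            "expected mutation count far exceeds max_mutations; the "
            "truncation will bias the realized mutation spectrum",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    pmf = _truncated_binomial_pmf(L, mutation_rate, max_mutations)
    counts = rng.choice(np.arange(1, max_mutations + 1), size=n_daughters, p=pmf)
    parent_codes = encode(parent)
    daughters = []
    for m in counts:
        codes = parent_codes.copy()
        pos = rng.choice(L, size=int(m), replace=False)
        # uniform over the three alternative bases at each position
        shift = rng.integers(1, 4, size=int(m))
        codes[pos] = (codes[pos] + shift) % 4
        daughters.append("".join("ACGT"[c] for c in codes))
    return daughters


def _activity_components(
    sequences: Sequence[str], model: GroundTruthModel
) -> np.ndarray:
    """Clamped linear activity of each (already channel-oriented) sequence."""
    acts = np.full(len(sequences), model.basal_activity, dtype=float)
    if not sequences:
        return acts
    lengths = {len(s) for s in sequences}
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        groups.setdefault(len(s), []).append(i)
    for idx in groups.values():
        codes = np.vstack([encode(sequences[i]) for i in idx])
        total = np.zeros(len(idx))
        for pwm, w in model.activator_pwms:
            if codes.shape[1] < pwm.length:
                continue
            best = scan_scores(pwm, codes)["top"].max(axis=1)
            total += w * np.maximum(0.0, best - pwm.patser_threshold)
        for pwm, w in model.repressor_pwms:
            if codes.shape[1] < pwm.length:
                continue
            sc = scan_scores(pwm, codes)
            present = (
                (sc["top"] >= pwm.patser_threshold).any(axis=1)
                | (sc["bottom"] >= pwm.patser_threshold).any(axis=1)
            )
            total -= w * present
        acts[idx] = model.basal_activity + total
    return np.clip(acts, ACTIVITY_MIN, ACTIVITY_MAX)


def true_activity(
    sequence: str, model: GroundTruthModel, channel: Channel = "GFP"
) -> float:
    """Ground-truth expression of one sequence on one channel (a.u.).

    GFP reads the sequence as given; RFP reads the reverse complement.
    Activator PWMs contribute through their best top-strand window,
    repressor PWMs through predicted-site presence on either strand.
    """
    oriented = sequence if channel == "GFP" else reverse_complement(sequence)
    return float(_activity_components([oriented], model)[0])


def true_activities(
    sequences: Sequence[str], model: GroundTruthModel
) -> dict[Channel, np.ndarray]:
    """Vectorized :func:`true_activity` for both channels."""
    return {
        "GFP": _activity_components(list(sequences), model),
        "RFP": _activity_components(
            [reverse_complement(s) for s in sequences], model
        ),
    }


def bin_probabilities(
    activities: np.ndarray, model: GroundTruthModel
) -> np.ndarray:
    """Probability that a cell of each sequence sorts into each of 4 bins.

    A cell's log fluorescence is normal around log(activity) with the
    model's noise sd; bin probabilities are the normal mass between the
    log-transformed boundaries.  With zero noise the containing bin
    gets probability 1 (cells on a boundary go to the bin above it).
    """
    a = np.asarray(activities, dtype=float)
    cuts = np.log(np.asarray(model.bin_boundaries))
    if model.cell_noise_sd == 0:
        idx = np.searchsorted(cuts, np.log(a), side="right")
        probs = np.zeros((a.size, 4))
        probs[np.arange(a.size), idx] = 1.0
        return probs
    z = (cuts[None, :] - np.log(a)[:, None]) / model.cell_noise_sd
    cdf = norm.cdf(z)
    probs = np.empty((a.size, 4))
    probs[:, 0] = cdf[:, 0]
    probs[:, 1] = cdf[:, 1] - cdf[:, 0]
    probs[:, 2] = cdf[:, 2] - cdf[:, 1]
    probs[:, 3] = 1.0 - cdf[:, 2]
    return probs


def simulate_count_matrices(
    activities: dict[Channel, np.ndarray],
    cells_per_sequence: int,
    reads_per_bin: int,
    model: GroundTruthModel,
    replicates: int = 1,
    seed: int = 0,
) -> dict[tuple[Channel, int], np.ndarray]:
    """Simulated read counts as (n_sequences, 4) matrices per (channel, replicate).

    Per replicate, each sequence's cells are sorted multinomially into
    bins; each bin's fixed read budget is then sampled multinomially
    over sequences in proportion to their cell occupancy.  A bin with
    no cells yields zero reads.
    """
    if cells_per_sequence <= 0 or reads_per_bin <= 0 or replicates < 1:
        raise ValueError("counts and replicates must be positive")
    rng = np.random.default_rng(seed)
    out: dict[tuple[Channel, int], np.ndarray] = {}
    for channel in CHANNELS:
        probs = bin_probabilities(activities[channel], model)
        for rep in range(1, replicates + 1):
            occupancy = rng.multinomial(cells_per_sequence, probs)
            reads = np.zeros_like(occupancy)
            for b in range(4):
                col = occupancy[:, b].astype(float)
                total = col.sum()
                if total == 0:
                    continue
                reads[:, b] = rng.multinomial(reads_per_bin, col / total)
            out[(channel, rep)] = reads
    return out


def counts_to_table(
    matrices: dict[tuple[Channel, int], np.ndarray], sequence_ids: Sequence[str]
) -> BinCountTable:
    """Assemble per-(channel, replicate) count matrices into a long table."""
    frames = []
    for (channel, rep), mat in sorted(matrices.items()):
        n = mat.shape[0]
        frames.append(
            pd.DataFrame(
                {
                    "sequence_id": np.repeat(sequence_ids, 4),
                    "channel": channel,
                    "bin": np.tile([1, 2, 3, 4], n),
                    "replicate": rep,
                    "reads": mat.reshape(-1),
                }
            )
        )
    return BinCountTable(pd.concat(frames, ignore_index=True)[COUNT_COLUMNS])


def simulate_sort_reads(
    activities: dict[Channel, np.ndarray],
    sequence_ids: Sequence[str],
    cells_per_sequence: int,
    reads_per_bin: int,
    model: GroundTruthModel,
    replicates: int = 1,
    seed: int = 0,
) -> BinCountTable:
    """Simulate a full Sort-Seq read-count table (see simulate_count_matrices)."""
    mats = simulate_count_matrices(
        activities, cells_per_sequence, reads_per_bin, model, replicates, seed
    )
    return counts_to_table(mats, sequence_ids)


@dataclass
class SyntheticExperiment:
    """A complete generated experiment: sequences, truth, and read counts."""

    parents: list[str]
    parent_class: str
    daughters: dict[str, list[str]]  # parent id -> daughter sequences
    true_activity: pd.DataFrame  # sequence_id, channel, true_activity
    read_counts: BinCountTable
    model: GroundTruthModel

    def sequence_ids(self) -> list[str]:
        ids = [f"p{i:04d}" for i in range(len(self.parents))]
        for pid in list(ids):
            ids.extend(
                f"{pid}_d{j:05d}" for j in range(len(self.daughters[pid]))
            )
        return ids

    def sequences(self) -> dict[str, str]:
        seqs = {f"p{i:04d}": s for i, s in enumerate(self.parents)}
        for pid, ds in self.daughters.items():
            for j, d in enumerate(ds):
                seqs[f"{pid}_d{j:05d}"] = d
        return seqs


def make_experiment(
    model: GroundTruthModel,
    n_parents: int = 10,
    parent_length: int = 150,
    at_content: float = 0.5,
    parent_class: Literal["random", "genomic_like"] = "random",
    n_daughters: int = 500,
    mutation_rate: float = 0.02,
    max_mutations: int = 10,
    cells_per_sequence: int = 100,
    reads_per_bin: int = 100_000,
    replicates: int = 1,
    seed: int = 0,
) -> SyntheticExperiment:
    """Generate parents, daughters, ground-truth activities and reads.

    All randomness derives from ``seed`` through spawned child
    generators, so repeated calls with identical arguments are
    bit-identical.
    """
    root = np.random.SeedSequence(seed)
    s_parents, s_mut, s_reads = root.spawn(3)
    parents = generate_parents(
        n_parents, parent_length, at_content, parent_class,
        pwm_set=[p for p, _ in model.activator_pwms + model.repressor_pwms],
        seed=int(np.random.default_rng(s_parents).integers(2**31)),
    )
    mut_rng = np.random.default_rng(s_mut)
    daughters = {}
    all_ids, all_seqs = [], []
    for i, parent in enumerate(parents):
        pid = f"p{i:04d}"
        all_ids.append(pid)
        all_seqs.append(parent)
        ds = mutagenize(
            parent, n_daughters, mutation_rate, max_mutations,
            seed=int(mut_rng.integers(2**31)),
        )
        daughters[pid] = ds
        for j, d in enumerate(ds):
            all_ids.append(f"{pid}_d{j:05d}")
            all_seqs.append(d)

    acts = true_activities(all_seqs, model)
    truth = pd.DataFrame(
        {
            "sequence_id": np.repeat(all_ids, 2),
            "channel": np.tile(CHANNELS, len(all_ids)),
            "true_activity": np.column_stack(
                [acts["GFP"], acts["RFP"]]
            ).reshape(-1),
        }
    )
    table = simulate_sort_reads(
        acts, all_ids, cells_per_sequence, reads_per_bin, model,
        replicates, seed=int(np.random.default_rng(s_reads).integers(2**31)),
    )
    return SyntheticExperiment(
        parents, parent_class, daughters, truth, table, model
    )


def write_experiment(exp: SyntheticExperiment, outdir: str) -> None:
    """Write parents/daughters FASTA, read-count TSV and ground-truth TSV."""
    import os

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    os.makedirs(outdir, exist_ok=True)
    seqs = exp.sequences()
    parent_records = [
        SeqRecord(Seq(seqs[i]), id=i, description="")
        for i in sorted(seqs) if "_d" not in i
    ]
    daughter_records = [
        SeqRecord(Seq(seqs[i]), id=i, description="")
        for i in sorted(seqs) if "_d" in i
    ]
    SeqIO.write(parent_records, os.path.join(outdir, "parents.fasta"), "fasta")
    SeqIO.write(daughter_records, os.path.join(outdir, "daughters.fasta"), "fasta")
    exp.read_counts.to_tsv(os.path.join(outdir, "read_counts.tsv"))
    exp.true_activity.sort_values(["sequence_id", "channel"]).to_csv(
        os.path.join(outdir, "ground_truth.tsv"), sep="\t", index=False
    )


def profile_pwm(
    consensus: str,
    factor_id: str,
    factor_class: str,
    conservation: float = 0.94,
) -> PWMModel:
    """PWM with a fixed per-position conservation level.

    Each column puts ``conservation`` probability on the consensus base
    and splits the remainder evenly over the three alternatives.  At
    the default level a 13-bp motif carries ~20.5 bits; windows with
    three mismatches from the consensus score above the Patser
    threshold (predicted sites, ~3.5% of random 150-mers per factor
    over both strands) and four-mismatch windows land just below it
    (proto-sites, ~0.25 per sequence per factor), so random libraries
    contain near-sites without being saturated with sites.
    """
    if not 0.25 < conservation < 1:
        raise ValueError("conservation must be in (0.25, 1)")
    codes = encode(consensus)
    off = (1.0 - conservation) / 3.0
    probs = np.full((len(consensus), 4), off)
    probs[np.arange(len(consensus)), codes] = conservation
    return PWMModel(factor_id, factor_class, probs)


#: consensus sequences of the default ground-truth activator panel; the
#: first is the sigma-class composite (-35 spacer-less fused to -10),
#: the rest are TF-class motifs with mixed base composition
DEFAULT_ACTIVATOR_CONSENSUS: dict[str, str] = {
    "sigma_composite": "TTGACATATAATG",
    "tf_marA_like": "ATGCAAGTCGCAT",
    "tf_crp_like": "GGATTACCGTAAC",
    "tf_fnr_like": "CCGTGCAATGGAC",
    "tf_lrp_like": "TGACGTCATTGCA",
}

DEFAULT_REPRESSOR_CONSENSUS = "GCGGCCGCTCCGA"


def default_ground_truth(
    seed: int = 0,
    activator_weight: float = 0.35,
    repressor_weight: float = 0.0,
    cell_noise_sd: float = 0.1,
) -> GroundTruthModel:
    """A ready-made ground-truth model for tests and examples.

    The activator panel holds five fixed-conservation 13-bp motifs
    (one sigma-class, four TF-class; see
    ``DEFAULT_ACTIVATOR_CONSENSUS``), each contributing
    ``activator_weight`` a.u. per bit of best-window score above its
    Patser threshold.  An optional GC-rich TF repressor is switched on
    by a positive ``repressor_weight``.
    """
    activators = [
        (profile_pwm(cons, fid, "sigma" if fid.startswith("sigma") else "tf"),
         activator_weight)
        for fid, cons in DEFAULT_ACTIVATOR_CONSENSUS.items()
    ]
    repressors = []
    if repressor_weight > 0:
        rep = profile_pwm(DEFAULT_REPRESSOR_CONSENSUS, "gc_repressor", "tf")
        repressors = [(rep, repressor_weight)]
    return GroundTruthModel(
        activator_pwms=activators,
        repressor_pwms=repressors,
        cell_noise_sd=cell_noise_sd,
        seed=seed,
    )
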