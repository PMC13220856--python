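"""Library-level statistics for promoter-incidence analysis.

Covers promoter incidence stratified by AT content, expected-promoter
and per-coding-sequence arithmetic, hexamer enrichment between sequence
sets (Fisher's exact test, BH corrected), predicted-site frequency
versus PWM information content, and empirical-quantile calibration of
an alternative promoter threshold.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pwm import PWMModel, predicted_sites

DEFAULT_AT_EDGES = tuple(40.0 + 5.0 * k for k in range(7))  # [40, 70)% in 5% steps

MINUS10_HEXAMERS = ("TATAAT", "ATTATA")  # -10 box and its reverse complement


def at_content(sequence: str) -> float:
    """Fraction of A/T bases in a sequence."""
    seq = sequence.upper()
    return (seq.count("A") + seq.count("T")) / len(seq)


def at_bin_incidence(
    records: Sequence[tuple[str, str]],
    edges: Sequence[float] = DEFAULT_AT_EDGES,
) -> pd.DataFrame:
    """Promoter incidence per half-open AT-content bin.

    ``records`` are (sequence, promoter_class) pairs; a sequence counts
    as a promoter when its class is not 'none'.  ``edges`` are percent
    AT; bins are [e_k, e_{k+1}).  Sequences outside the range land in an
    'overflow' row rather than being dropped.  Empty bins have NaN
    incidence.
    """
    edges = list(edges)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    n = np.zeros(len(labels) + 1, dtype=int)
    k = np.zeros(len(labels) + 1, dtype=int)
    for seq, cls in records:
        at = 100.0 * at_content(seq)
        idx = len(labels)  # overflow by default
        if edges[0] <= at < edges[-1]:
            idx = int(np.searchsorted(edges, at, side="right")) - 1
        n[idx] += 1
        if cls != "none":
            k[idx] += 1
    with np.errstate(invalid="ignore"):
        inc = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {"at_bin": labels + ["overflow"], "n": n, "n_promoters": k, "incidence": inc}
    )


def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal round-half-up at the given precision (for printed values)."""
    factor = 10.0 ** digits
    return math.floor(x * factor + 0.5) / factor


def expected_promoters(
    n_genes: int, coverage: float, constitutive_fraction: float
) -> int:
    """Expected promoter count in a library: genes x coverage x fraction.

    E.g. a genome of 4639 genes sequenced at 2.7-fold coverage with 25%
    of promoters constitutively active predicts 3131 promoters.
    """
    if min(n_genes, coverage, constitutive_fraction) <= 0:
        raise ValueError("all inputs must be positive")
    return int(round_half_up(n_genes * coverage * constitutive_fraction))


def per_cds_rate(
    n_intragenic_promoters: int, n_cds: int, coverage: float
) -> tuple[float, float]:
    """Promoters per coding sequence, corrected for coverage.

    Returns (full precision, value rounded half-up to 1 decimal place).
    """
    if n_cds <= 0 or coverage <= 0:
        raise ValueError("n_cds and coverage must be positive")
    rate = n_intragenic_promoters / n_cds / coverage
    return rate, round_half_up(rate, 1)


def count_hexamers(sequences: Sequence[str]) -> tuple[dict[str, int], int]:
    """Overlapping hexamer counts over the forward strand of each record.

    Returns (counts keyed by hexamer, total windows).
    """
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - 5):
            h = s[i : i + 6]
            counts[h] = counts.get(h, 0) + 1
            total += 1
    return counts, total


def hexamer_enrichment(
    set_a: Sequence[str], set_b: Sequence[str]
) -> pd.DataFrame:
    """Per-hexamer 2x2 Fisher's exact tests between two sequence sets.

    Each hexamer's table is (count_a, windows_a - count_a; count_b,
    windows_b - count_b); q-values are BH over all 4096 hexamers.  The
    -10 box hexamers (TATAAT, ATTATA) are always present in the output
    even when unobserved.
    """
    from statsmodels.stats.multitest import multipletests

    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    counts_a, total_a = count_hexamers(set_a)
    counts_b, total_b = count_hexamers(set_b)
    hexamers = sorted(
        set(counts_a) | set(counts_b) | set(MINUS10_HEXAMERS)
    )
    rows = []
    for h in hexamers:
        a, b = counts_a.get(h, 0), counts_b.get(h, 0)
        table = [[a, total_a - a], [b, total_b - b]]
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        rows.append(
            {"hexamer": h, "count_a": a, "count_b": b,
             "total_a": total_a, "total_b": total_b,
             "odds_ratio": odds, "p_value": p,
             "is_minus10": h in MINUS10_HEXAMERS}
        )
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = q
    return df


def pwm_site_frequency(
    library: Sequence[str], pwm_set: Sequence[PWMModel]
) -> pd.DataFrame:
    """Per-PWM fraction of sequences carrying >= 1 predicted site (both strands)."""
    rows = []
    for pwm in pwm_set:
        hits = sum(
            1 for seq in library
            if len(seq) >= pwm.length and predicted_sites(pwm, seq)
        )
        rows.append(
            {
                "factor_id": pwm.factor_id,
                "information_content": pwm.information_content,
                "fraction_with_site": hits / len(library),
            }
        )
    return pd.DataFrame(rows)


def pwm_site_frequency_vs_ic(
    library_a: Sequence[str],
    library_b: Sequence[str],
    pwm_set: Sequence[PWMModel],
) -> dict:
    """Compare per-PWM predicted-site frequencies between two libraries.

    Returns the per-library frequency tables, a paired t test across
    PWMs of the two frequency vectors, and the least-squares slope of
    site frequency against information content in each library.
    Zero-variance paired differences are reported with NaN statistics.
    """
    if len(pwm_set) < 2:
        raise ValueError("paired comparison needs at least 2 PWMs")
    fa = pwm_site_frequency(library_a, pwm_set)
    fb = pwm_site_frequency(library_b, pwm_set)
    diffs = fa["fraction_with_site"].to_numpy() - fb["fraction_with_site"].to_numpy()
    if np.allclose(diffs.std(ddof=1), 0.0):
        t_stat, p = float("nan"), float("nan")
    else:
        t_stat, p = sps.ttest_rel(
            fa["fraction_with_site"], fb["fraction_with_site"]
        )
    out = {"freq_a": fa, "freq_b": fb, "t_statistic": float(t_stat),
           "p_value": float(p)}
    for key, frame in (("slope_a", fa), ("slope_b", fb)):
        ic = frame["information_content"].to_numpy()
        if np.ptp(ic) == 0:  # identical-IC panel: slope undefined
            out[key] = float("nan")
            continue
        fit = sps.linregress(ic, frame["fraction_with_site"])
        out[key] = float(fit.slope)
    return out


def calibrate_threshold(
    scores: Sequence[float], target_active_fraction: float
) -> float:
    """Fluorescence threshold leaving ``target_active_fraction`` of scores above.

    The (1 - target) empirical quantile; classifying with it recovers
    the target fraction to within 1/n.
    """
    if not 0 < target_active_fraction < 1:
        raise ValueError("target fraction must be in (0, 1)")
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("scores must be non-empty")
    return float(np.quantile(arr, 1.0 - target_active_fraction))


def classify_location(
    seq_start: int, seq_end: int, cds_intervals: Sequence[tuple[int, int]]
) -> str:
    """Label a sequence interval against CDS intervals (1-based inclusive).

    'intragenic' when wholly inside one CDS, 'intergenic' when wholly
    outside all CDS, otherwise 'mixed'.
    """
    if seq_end < seq_start:
        raise ValueError("interval end before start")
    inside = any(s <= seq_start and seq_end <= e for s, e in cds_intervals)
    if inside:
        return "intragenic"
    overlaps = any(not (seq_end < s or seq_start > e) for s, e in cds_intervals)
    return "mixed" if overlaps else "intergenic"


def library_summary(
    sequences: Mapping[str, str],
    classes: Mapping[str, str],
    pwm_set: Sequence[PWMModel] = (),
    at_edges: Sequence[float] = DEFAULT_AT_EDGES,
) -> dict:
    """Headline numbers for one library: class counts, AT-binned
    incidence, mean AT content, and per-PWM site frequencies."""
    ids = sorted(sequences)
    class_counts = {c: 0 for c in ("none", "top", "bottom", "both")}
    for i in ids:
        class_counts[classes[i]] += 1
    records = [(sequences[i], classes[i]) for i in ids]
    summary = {
        "n_sequences": len(ids),
        "class_counts": class_counts,
        "promoter_fraction": 1.0 - class_counts["none"] / max(len(ids), 1),
        "mean_at": float(np.mean([at_content(sequences[i]) for i in ids])),
        "at_incidence": at_bin_incidence(records, at_edges),
    }
    if pwm_set:
        summary["pwm_site_frequency"] = pwm_site_frequency(
            [sequences[i] for i in ids], pwm_set
        )
    return summary
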