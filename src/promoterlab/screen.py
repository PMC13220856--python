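"""Sliding-window screen for activating and repressing binding sites.

For every PWM, window offset, strand, and fluorescence channel, the
daughters of a parent are split into carriers of a predicted site at
that window ("positives") and non-carriers ("negatives").  When both
groups exceed a minimum size, a two-sided Mann-Whitney U test asks
whether site presence associates with fluorescence; all p-values of a
run are corrected together with Benjamini-Hochberg.

Significant calls are then classified against the parent's own window:

* ``gain_activating`` -- the parent lacks the site, the site emerged on
  the strand whose reporter responds (top/GFP, bottom/RFP), and the
  carriers' median fluorescence exceeds the non-carriers' by >= 0.1 a.u.
* ``loss_repressing`` -- the parent carries the site (TF sites only;
  sigma-factor losses are excluded as confounded), on either strand,
  and losing it raises median fluorescence by > 0 a.u.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .families import MutantFamily
from .pwm import PWMModel, SiteHit, scan_scores

MIN_GROUP = 10  # both groups must be strictly larger than this
FDR = 0.05
ACTIVATING_DELTA = 0.1
_EXACT_MAX = 25  # use the exact U distribution when min group size allows

CALL_COLUMNS = [
    "parent_id", "factor_id", "window_start", "strand", "channel",
    "n_pos", "n_neg", "median_pos", "median_neg", "delta",
    "p_value", "q_value", "parent_has_site", "direction",
]


def mwu_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    The exact null distribution is used whenever the data are tie-free
    and the smaller group is modest; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if no_ties and min(x.size, y.size) <= _EXACT_MAX else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def site_presence_matrix(
    codes: np.ndarray, pwm: PWMModel
) -> dict[str, np.ndarray]:
    """Predicted-site presence per daughter per window on each strand.

    ``codes`` is an (n, L) encoded sequence matrix; returns boolean
    (n, L - X + 1) arrays keyed by strand.
    """
    scores = scan_scores(pwm, codes)
    return {s: sc >= pwm.patser_threshold for s, sc in scores.items()}


def site_presence_groups(
    family: MutantFamily,
    pwm: PWMModel,
    window_start: int,
    strand: str,
    channel: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Fluorescence scores of site carriers vs non-carriers at one window.

    ``window_start`` is 1-based on the parent's coordinates.
    """
    presence = site_presence_matrix(family.daughter_matrix(), pwm)[strand]
    w = window_start - 1
    if not 0 <= w < presence.shape[1]:
        raise ValueError(f"window {window_start} out of range")
    scores = np.asarray(family.fluor[channel], dtype=float)
    ok = ~np.isnan(scores)
    carrier = presence[:, w] & ok
    return scores[carrier], scores[~presence[:, w] & ok]


def association_scan(
    families: Sequence[MutantFamily],
    pwm_set: Sequence[PWMModel],
    channels: Sequence[str] = ("GFP", "RFP"),
    min_group: int = MIN_GROUP,
    fdr: float = FDR,
    include_untested: bool = False,
) -> pd.DataFrame:
    """Run the full screen and BH-correct all tests of the run together.

    Returns one row per (parent, factor, window, strand, channel) test
    with group sizes, medians, delta (median_pos - median_neg), p and q
    values, and the parent's own site status at the window.  Windows
    where either group has <= ``min_group`` scores are untested and only
    appear when ``include_untested`` is set (with NaN p and q).
    """
    rows: list[dict] = []
    for fam in families:
        codes = fam.daughter_matrix()
        parent_codes = np.array([list(map("ACGT".index, fam.parent_sequence))],
                                dtype=np.int8)
        for pwm in pwm_set:
            if codes.shape[1] < pwm.length:
                continue
            presence = site_presence_matrix(codes, pwm)
            parent_presence = site_presence_matrix(parent_codes, pwm)
            for channel in channels:
                if channel not in fam.fluor:
                    continue
                scores = np.asarray(fam.fluor[channel], dtype=float)
                ok = ~np.isnan(scores)
                for strand in ("top", "bottom"):
                    pres = presence[strand]
                    for w in range(pres.shape[1]):
                        carriers = pres[:, w] & ok
                        non = ~pres[:, w] & ok
                        n_pos, n_neg = int(carriers.sum()), int(non.sum())
                        tested = n_pos > min_group and n_neg > min_group
                        if not tested and not include_untested:
                            continue
                        pos = scores[carriers]
                        neg = scores[non]
                        med_pos = float(np.median(pos)) if n_pos else np.nan
                        med_neg = float(np.median(neg)) if n_neg else np.nan
                        rows.append(
                            {
                                "parent_id": fam.parent_id,
                                "factor_id": pwm.factor_id,
                                "factor_class": pwm.factor_class,
                                "window_start": w + 1,
                                "strand": strand,
                                "channel": channel,
                                "n_pos": n_pos,
                                "n_neg": n_neg,
                                "median_pos": med_pos,
                                "median_neg": med_neg,
                                "delta": med_pos - med_neg,
                                "p_value": mwu_pvalue(pos, neg) if tested else np.nan,
                                "parent_has_site": bool(
                                    parent_presence[strand][0, w]
                                ),
                            }
                        )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=CALL_COLUMNS[:-1])
    df["q_value"] = np.nan
    tested_mask = df["p_value"].notna()
    if tested_mask.any():
        _, q, _, _ = multipletests(
            df.loc[tested_mask, "p_value"].to_numpy(), alpha=fdr, method="fdr_bh"
        )
        df.loc[tested_mask, "q_value"] = q
    return classify_sites(df, fdr=fdr)


def classify_sites(
    calls: pd.DataFrame,
    fdr: float = FDR,
    activating_delta: float = ACTIVATING_DELTA,
) -> pd.DataFrame:
    """Assign gain_activating / loss_repressing / none to screened windows.

    Gain and loss are judged against the parent's own window status (the
    only available reference): a significant window where the parent
    lacks the site is a gain by the carriers, one where the parent has
    the site is a loss by the non-carriers.
    """
    df = calls.copy()
    if df.empty:
        df["direction"] = pd.Series(dtype=object)
        return df
    significant = df["q_value"] < fdr
    strand_matches = (
        ((df["strand"] == "top") & (df["channel"] == "GFP"))
        | ((df["strand"] == "bottom") & (df["channel"] == "RFP"))
    )
    gained = ~df["parent_has_site"].astype(bool)
    activating = (
        significant & gained & strand_matches & (df["delta"] >= activating_delta)
    )
    # delta for a lost site is measured on the losing (non-carrier) group
    repressing = (
        significant
        & ~gained
        & (df["factor_class"] != "sigma")
        & (df["median_neg"] - df["median_pos"] > 0.0)
    )
    df["direction"] = "none"
    df.loc[activating, "direction"] = "gain_activating"
    df.loc[repressing, "direction"] = "loss_repressing"
    return df


def proto_site_census(
    parent: str, pwm_set: Sequence[PWMModel]
) -> tuple[int, dict[str, int]]:
    """Total and per-factor proto-site counts on both strands of a parent."""
    from .pwm import proto_sites

    per_factor = {}
    for pwm in pwm_set:
        if len(parent) < pwm.length:
            per_factor[pwm.factor_id] = 0
            continue
        per_factor[pwm.factor_id] = len(proto_sites(pwm, parent))
    return sum(per_factor.values()), per_factor


def relative_position(
    site_start: int, site_strand: str, minus10_hits: Sequence[SiteHit]
) -> float:
    """Signed bp offset from the nearest -10 box on the site's strand.

    Positive offsets point downstream in the transcribed direction of
    the strand (rightward on top, leftward on bottom).  Undefined (NaN)
    when the strand carries no -10 hit.
    """
    starts = [h.start for h in minus10_hits if h.strand == site_strand]
    if not starts:
        return float("nan")
    nearest = min(starts, key=lambda s: abs(site_start - s))
    offset = site_start - nearest
    return float(offset if site_strand == "top" else -offset)
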