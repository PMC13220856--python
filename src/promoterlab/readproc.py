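"""Binned read-count processing and fluorescence-score estimation.

Sort-Seq assigns each cell to one of four fluorescence bins per channel
(GFP bins G1-G4, RFP bins R1-R4), and each sequence variant is then
represented by its read counts across bins.  The fluorescence score of
a variant is the read-weighted mean of the integer bin codes,

    fluor_r = sum_f f * Reads_f / sum_f Reads_f,   f in {1..4},

computed per technical replicate and averaged across replicates.  The
score lives on an arbitrary-unit scale from 1.0 (no expression) to 4.0
(strongest expression).  A sequence is classified as a promoter on a
strand when its score on the corresponding channel reaches 1.5 a.u.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

Channel = Literal["GFP", "RFP"]
PromoterClass = Literal["none", "top", "bottom", "both"]

#: canonical column order of the read-count TSV interchange format
COUNT_COLUMNS = ["sequence_id", "channel", "bin", "replicate", "reads"]

# mutagenesis libraries are sorted into only OFF/ON bins; for scoring we
# give them the integer codes 1 and 2 (see two-bin rescaling below)
TWO_BIN_CODES = {"OFF": 1, "ON": 2}


@dataclass
class BinCountTable:
    """Per-sequence read counts keyed by (channel, bin, replicate).

    Thin wrapper around a long-format DataFrame with columns
    ``sequence_id, channel, bin, replicate, reads``.  ``bin`` is either
    an integer 1-4 or the string 'OFF'/'ON'.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if (self.data["reads"] < 0).any():
            raise ValueError("read counts must be non-negative")
        bins = set(self.data["bin"].unique())
        if not (bins <= {1, 2, 3, 4} or bins <= {"OFF", "ON"}):
            raise ValueError(f"mixed or unknown bin scheme: {bins}")

    @property
    def scheme(self) -> str:
        return "two_bin" if self.data["bin"].dtype == object else "four_bin"

    def sequence_ids(self) -> list[str]:
        return sorted(self.data["sequence_id"].unique())

    @classmethod
    def from_tsv(cls, path: str) -> "BinCountTable":
        df = pd.read_csv(path, sep="\t")
        # bins arrive as strings when the scheme is OFF/ON
        if df["bin"].dtype == object and set(df["bin"]) <= {"1", "2", "3", "4"}:
            df["bin"] = df["bin"].astype(int)
        return cls(df)

    def to_tsv(self, path: str) -> None:
        self.data.sort_values(COUNT_COLUMNS[:4]).to_csv(
            path, sep="\t", index=False
        )


def filter_reads(
    table: BinCountTable,
    unsorted_library: set[str] | None,
    sequence_lengths: Mapping[str, int],
    min_bins: int = 4,
    length_range: tuple[int, int] = (100, 200),
    whitelist: set[str] | None = None,
) -> tuple[BinCountTable, dict[str, int]]:
    """Apply the wild-type library quality filters.

    A sequence is dropped if it (i) is absent from the unsorted library,
    (ii) has nonzero reads in fewer than ``min_bins`` distinct bins
    (pooled over channels and replicates), or (iii) falls outside
    ``length_range`` in bp.  ``whitelist``, when given, stands in for a
    genome-mapping requirement.  Returns the filtered table and per-rule
    removal counts.
    """
    df = table.data
    ids = df["sequence_id"].unique()
    report = {"unsorted_library": 0, "min_bins": 0, "length": 0, "whitelist": 0}
    keep = set(ids)
    if unsorted_library is not None:
        bad = {i for i in keep if i not in unsorted_library}
        report["unsorted_library"] = len(bad)
        keep -= bad
    nz = df[df["reads"] > 0].groupby("sequence_id")["bin"].nunique()
    bad = {i for i in keep if nz.get(i, 0) < min_bins}
    report["min_bins"] = len(bad)
    keep -= bad
    lo, hi = length_range
    bad = {i for i in keep if not lo <= sequence_lengths[i] <= hi}
    report["length"] = len(bad)
    keep -= bad
    if whitelist is not None:
        bad = {i for i in keep if i not in whitelist}
        report["whitelist"] = len(bad)
        keep -= bad
    out = BinCountTable(df[df["sequence_id"].isin(keep)].reset_index(drop=True))
    return out, report


def pool_on_off(table: BinCountTable) -> BinCountTable:
    """Pool 4-bin counts into the OFF/ON scheme (OFF = bin 1; ON = bins 2-4)."""
    df = table.data
    if table.scheme != "four_bin":
        raise ValueError("pool_on_off requires a 4-bin table")
    pooled = df.copy()
    pooled["bin"] = np.where(pooled["bin"] == 1, "OFF", "ON")
    pooled = (
        pooled.groupby(["sequence_id", "channel", "bin", "replicate"], as_index=False)[
            "reads"
        ].sum()
    )
    return BinCountTable(pooled)


def fluor_replicate(reads: Sequence[float]) -> float:
    """Read-weighted mean bin code for one replicate; NaN if all bins empty.

    ``reads`` holds the counts for bin codes 1..len(reads) in order.
    """
    reads = np.asarray(reads, dtype=float)
    total = reads.sum()
    if total == 0:
        return float("nan")
    codes = np.arange(1, len(reads) + 1)
    return float((codes * reads).sum() / total)


def fluor_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorized :func:`fluor_replicate` over a (n_sequences, n_bins) matrix.

    Column j holds the reads for bin code j+1.  Rows with zero total
    reads yield NaN.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    codes = np.arange(1, counts.shape[1] + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, (counts * codes).sum(axis=1) / totals, np.nan)


def fluor_mean(replicate_scores: Iterable[float]) -> float:
    """Mean over the replicates with defined scores; NaN if none defined."""
    vals = [v for v in replicate_scores if not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def rescale_two_bin(score: float) -> float:
    """Map a two-bin score on [1, 2] onto the standard [1, 4] a.u. interval.

    OFF/ON-sorted mutagenesis libraries yield scores between the codes 1
    and 2; the affine map fluor' = 1 + 3 (fluor - 1) is the unique one
    carrying [1, 2] onto [1, 4].
    """
    return 1.0 + 3.0 * (score - 1.0)


def fluorescence_scores(
    table: BinCountTable, rescale: bool | None = None
) -> pd.DataFrame:
    """Per-sequence, per-channel fluorescence scores from a count table.

    Returns a DataFrame with columns ``sequence_id, channel,
    fluor_r<rep>.., fluor``.  Two-bin (OFF/ON) tables are scored with
    codes 1/2 and, unless ``rescale=False``, rescaled to [1, 4].
    Sequences with zero reads in every bin of a replicate get NaN for
    that replicate; ``fluor`` averages the defined replicates only.
    """
    df = table.data.copy()
    two_bin = table.scheme == "two_bin"
    if two_bin:
        df["bin_code"] = df["bin"].map(TWO_BIN_CODES)
        n_codes = 2
    else:
        df["bin_code"] = df["bin"].astype(int)
        n_codes = 4
    if rescale is None:
        rescale = two_bin

    grp = df.groupby(["sequence_id", "channel", "replicate"])
    weighted = grp.apply(
        lambda g: fluor_replicate(
            np.bincount(g["bin_code"], weights=g["reads"], minlength=n_codes + 1)[1:]
        ),
        include_groups=False,
    ).rename("fluor_r")
    wide = weighted.reset_index().pivot_table(
        index=["sequence_id", "channel"],
        columns="replicate",
        values="fluor_r",
        dropna=False,
    )
    wide.columns = [f"fluor_r{c}" for c in wide.columns]
    wide["fluor"] = wide.apply(lambda row: fluor_mean(row.values), axis=1)
    if rescale and two_bin:
        for c in wide.columns:
            wide[c] = rescale_two_bin(wide[c])
    return wide.reset_index()


def classify_promoter(
    fluor_gfp: float, fluor_rfp: float, threshold: float = 1.5
) -> PromoterClass:
    """Promoter class from the two channel scores (threshold inclusive).

    GFP reports top-strand activity and RFP bottom-strand activity.
    """
    top = fluor_gfp >= threshold
    bottom = fluor_rfp >= threshold
    if top and bottom:
        return "both"
    if top:
        return "top"
    if bottom:
        return "bottom"
    return "none"


def promoter_classes(scores: pd.DataFrame, threshold: float = 1.5) -> pd.Series:
    """Vectorized promoter classification from a fluorescence-score frame.

    ``scores`` is the output of :func:`fluorescence_scores`; sequences
    missing a channel or with undefined scores are classified from the
    channels they do have (a missing channel counts as inactive).
    """
    wide = scores.pivot(index="sequence_id", columns="channel", values="fluor")
    gfp = wide.get("GFP", pd.Series(np.nan, index=wide.index)).fillna(1.0)
    rfp = wide.get("RFP", pd.Series(np.nan, index=wide.index)).fillna(1.0)
    out = pd.Series("none", index=wide.index, name="promoter_class")
    out[(gfp >= threshold) & (rfp < threshold)] = "top"
    out[(gfp < threshold) & (rfp >= threshold)] = "bottom"
    out[(gfp >= threshold) & (rfp >= threshold)] = "both"
    return out
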