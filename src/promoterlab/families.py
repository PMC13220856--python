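"""Mutant-family reconstruction and the promoter-emergence statistic P_new.

Error-prone PCR daughters are pooled across parents before sequencing,
so the parent of each daughter must be reconstructed: sequences are
grouped by exact length, clustered by Hamming distance (single linkage,
connected components of the graph joining pairs within ``max_dist``),
and each cluster's per-position consensus is taken as its parent.

P_new for a parent is the fraction of its daughters whose fluorescence
crosses the promoter threshold (1.5 a.u.) -- the probability that a
random mutant of the parent is a promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pwm import ALPHABET, encode, decode


@dataclass
class MutantFamily:
    """One reconstructed parent with its daughter sequences and scores.

    ``fluor`` maps channel name to a per-daughter array of fluorescence
    scores (a.u.), aligned with ``daughters``.
    """

    parent_id: str
    parent_sequence: str
    daughters: list[str]
    fluor: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_daughters(self) -> int:
        return len(self.daughters)

    def __post_init__(self) -> None:
        L = len(self.parent_sequence)
        if any(len(d) != L for d in self.daughters):
            raise ValueError(f"{self.parent_id}: daughters must match parent length")
        for ch, arr in self.fluor.items():
            if len(arr) != len(self.daughters):
                raise ValueError(f"{self.parent_id}: {ch} scores misaligned")

    def daughter_matrix(self) -> np.ndarray:
        """Daughters as an (n, L) int8 code matrix (A=0, C=1, G=2, T=3)."""
        return np.vstack([encode(d) for d in self.daughters])


@dataclass(frozen=True)
class EmergenceSummary:
    parent_id: str
    channel: str
    p_new: float
    n_active: int
    n_total: int


def hamming_matrix(codes: np.ndarray) -> np.ndarray:
    """All-pairs Hamming distances of equal-length encoded sequences.

    Uses a one-hot inner product so the n^2 L comparison runs in BLAS.
    """
    n, L = codes.shape
    onehot = np.zeros((n, L, 4), dtype=np.float32)
    valid = codes >= 0
    onehot[np.nonzero(valid)[0], np.nonzero(valid)[1], codes[valid]] = 1.0
    flat = onehot.reshape(n, L * 4)
    matches = flat @ flat.T
    return (L - np.rint(matches)).astype(np.int32)


def cluster_daughters(
    sequences: Sequence[str], max_dist: int = 10
) -> list[list[int]]:
    """Partition sequences into mutant families by Hamming distance.

    Sequences are first grouped by exact length; within a length group,
    clusters are the connected components of the graph joining every
    pair at Hamming distance <= ``max_dist`` (single linkage).  Returns
    clusters as lists of indices into ``sequences``, ordered by first
    member.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    by_length: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        by_length.setdefault(len(s), []).append(i)

    clusters: list[list[int]] = []
    for length in sorted(by_length):
        idx = np.array(by_length[length])
        codes = np.vstack([encode(sequences[i]) for i in idx])
        dist = hamming_matrix(codes)
        labels = _connected_components(dist <= max_dist)
        for lab in range(labels.max() + 1):
            clusters.append([int(i) for i in idx[labels == lab]])
    clusters.sort(key=lambda c: c[0])
    return clusters


def _connected_components(adj: np.ndarray) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    # relabel components in order of first appearance for determinism
    order = {lab: k for k, lab in enumerate(pd.unique(labels))}
    return np.array([order[lab] for lab in labels])


def consensus_parent(cluster: Sequence[str]) -> str:
    """Per-position majority base of a cluster; ties break alphabetically.

    Alphabetical tie-breaking (A < C < G < T) makes the consensus
    deterministic and order-independent.
    """
    if not cluster:
        raise ValueError("empty cluster")
    codes = np.vstack([encode(s) for s in cluster])
    counts = np.zeros((codes.shape[1], 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (codes == b).sum(axis=0)
    # argmax returns the first maximum, and columns are in A,C,G,T order
    return decode(counts.argmax(axis=1))


def build_families(
    sequences: Sequence[str],
    fluor: Mapping[str, Sequence[float]] | None = None,
    max_dist: int = 10,
    keep_parent_reads: bool = True,
) -> list[MutantFamily]:
    """Cluster pooled daughters and attach fluorescence scores per family.

    Reads identical to the consensus are retained as daughters by
    default (a distance-0 read is the parent resequenced).
    """
    clusters = cluster_daughters(sequences, max_dist=max_dist)
    families = []
    for k, members in enumerate(clusters):
        seqs = [sequences[i] for i in members]
        parent = consensus_parent(seqs)
        if not keep_parent_reads:
            keep = [i for i, s in zip(members, seqs) if s != parent]
            seqs = [sequences[i] for i in keep]
            members = keep
        fl = {}
        if fluor is not None:
            for ch, vals in fluor.items():
                fl[ch] = np.asarray([vals[i] for i in members], dtype=float)
        families.append(
            MutantFamily(f"family{k:04d}", parent, list(seqs), fl)
        )
    return families


def filter_families(
    families: Sequence[MutantFamily],
    wildtype_library: set[str],
    min_daughters: int = 500,
    length_range: tuple[int, int] = (100, 200),
) -> tuple[list[MutantFamily], dict[str, int]]:
    """Drop families whose parent is not in the wild-type library, that
    have fewer than ``min_daughters`` daughters, or whose sequences fall
    outside ``length_range`` bp.  Returns kept families and per-rule
    removal counts."""
    report = {"wildtype_library": 0, "min_daughters": 0, "length": 0}
    kept = []
    lo, hi = length_range
    for fam in families:
        if fam.parent_sequence not in wildtype_library:
            report["wildtype_library"] += 1
        elif fam.n_daughters < min_daughters:
            report["min_daughters"] += 1
        elif not lo <= len(fam.parent_sequence) <= hi:
            report["length"] += 1
        else:
            kept.append(fam)
    return kept, report


def p_new(
    family: MutantFamily, channel: str, threshold: float = 1.5
) -> EmergenceSummary:
    """Fraction of daughters at or above the promoter threshold.

    Daughters with undefined (NaN) scores are excluded from both
    numerator and denominator.
    """
    scores = np.asarray(family.fluor[channel], dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        raise ValueError(f"{family.parent_id}: no defined {channel} scores")
    n_active = int((scores >= threshold).sum())
    return EmergenceSummary(
        family.parent_id, channel, n_active / scores.size, n_active, scores.size
    )


def emergence_table(
    families: Sequence[MutantFamily],
    channels: Sequence[str] = ("GFP", "RFP"),
    threshold: float = 1.5,
) -> pd.DataFrame:
    """P_new per family and channel as a tidy DataFrame."""
    rows = []
    for fam in families:
        for ch in channels:
            if ch not in fam.fluor:
                continue
            s = p_new(fam, ch, threshold)
            rows.append(
                {
                    "parent_id": s.parent_id,
                    "channel": s.channel,
                    "p_new": s.p_new,
                    "n_active": s.n_active,
                    "n_total": s.n_total,
                }
            )
    return pd.DataFrame(rows)
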