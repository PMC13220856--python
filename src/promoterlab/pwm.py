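"""Position weight matrices: construction, scoring, and site classification.

A PWM models the per-position nucleotide preferences of a transcription
factor or sigma factor.  Scores are summed log2 odds against a uniform
25% background.  A window is a *predicted site* when its score (bits)
reaches the matrix's Patser threshold, and a *proto-site* when the score
is positive but sub-threshold (roughly one mutation away from a
predicted site).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

Strand = Literal["top", "bottom"]
FactorClass = Literal["sigma", "tf"]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3; other = -1)."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] if c >= 0 else "N" for c in codes)


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(comp)[::-1]


@dataclass(frozen=True)
class PWMModel:
    """A per-position nucleotide probability model with log-odds scoring.

    ``prob_matrix`` and ``logodds_matrix`` are (length, 4) arrays in
    A/C/G/T order; log-odds are log2(p / 0.25) in bits.  The Patser
    threshold is derived from the matrix's own information content (see
    :func:`patser_threshold`).
    """

    factor_id: str
    factor_class: FactorClass
    prob_matrix: np.ndarray
    pseudocount: float = 0.0
    patser_ic_units: Literal["nats", "bits"] = "nats"
    logodds_matrix: np.ndarray = field(init=False, repr=False)
    information_content: float = field(init=False)
    patser_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.prob_matrix, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError(f"{self.factor_id}: prob_matrix must be (L, 4)")
        colsums = p.sum(axis=1)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"{self.factor_id}: probability columns must sum to 1")
        object.__setattr__(self, "prob_matrix", p)
        with np.errstate(divide="ignore"):
            lo = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0) / 0.25), -np.inf)
        object.__setattr__(self, "logodds_matrix", lo)
        # information content in bits: sum over positions of 2 - H(column)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        ic = float((2.0 + plogp.sum(axis=1)).sum())
        object.__setattr__(self, "information_content", max(ic, 0.0))
        object.__setattr__(
            self,
            "patser_threshold",
            patser_threshold(self.information_content, self.patser_ic_units),
        )

    @property
    def length(self) -> int:
        return self.prob_matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.prob_matrix.argmax(axis=1))


def patser_threshold(ic_bits: float, units: Literal["nats", "bits"] = "nats") -> float:
    """Score cut-off for predicted sites, derived from information content.

    The cut-off is the natural logarithm of the matrix's information
    content.  With ``units='nats'`` (default) the information content is
    first converted to nats (ic_bits * ln 2); with ``units='bits'`` the
    bit value is used directly as the ln argument.
    """
    arg = ic_bits * math.log(2.0) if units == "nats" else ic_bits
    if arg <= 0:
        return math.inf  # zero-information matrix can never call a site
    return math.log(arg)


@dataclass(frozen=True)
class SiteHit:
    """One scoring window on a sequence.

    ``start`` is 1-based on the scanned (top-strand) coordinate system;
    bottom-strand hits are reported at the top-strand start of the window
    they cover.
    """

    factor_id: str
    start: int
    strand: Strand
    score: float
    kind: Literal["predicted", "proto"]


def build_pwm(
    sites: Sequence[str],
    factor_id: str,
    factor_class: FactorClass = "tf",
    pseudocount: float = 0.0,
    patser_ic_units: Literal["nats", "bits"] = "nats",
) -> PWMModel:
    """Build a PWM from aligned, equal-length binding sites.

    Counts plus ``pseudocount`` per cell are normalised to probabilities.
    With pseudocount 0, a base never observed at a position has
    probability 0 and log-odds -inf; windows containing it are neither
    predicted nor proto-sites.
    """
    if not sites:
        raise ValueError(f"{factor_id}: empty site list")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError(f"{factor_id}: aligned sites must all have equal length")
    counts = np.zeros((length, 4), dtype=float)
    for s in sites:
        codes = encode(s)
        if (codes < 0).any():
            raise ValueError(f"{factor_id}: sites must be over A/C/G/T")
        counts[np.arange(length), codes] += 1.0
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    return PWMModel(
        factor_id=factor_id,
        factor_class=factor_class,
        prob_matrix=probs,
        pseudocount=pseudocount,
        patser_ic_units=patser_ic_units,
    )


def score_window(pwm: PWMModel, window: str) -> float:
    """Score one window of exactly the PWM's length, in bits."""
    codes = encode(window)
    if codes.shape[0] != pwm.length:
        raise ValueError(
            f"window length {codes.shape[0]} != PWM length {pwm.length}"
        )
    return float(_score_codes(pwm, codes[None, :])[0, 0])


def _rc_logodds(pwm: PWMModel) -> np.ndarray:
    # scoring the reverse complement of a window with the forward matrix
    # equals scoring the window with the position- and base-reversed matrix
    return pwm.logodds_matrix[::-1, ::-1]


def _window_scores(lo: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of every window of len(lo) along each row of ``codes``.

    codes: (n, L) int8; returns (n, L - X + 1) float with -inf where a
    window contains an invalid base or a zero-probability cell.
    """
    x, L = lo.shape[0], codes.shape[1]
    n_win = L - x + 1
    if n_win <= 0:
        return np.zeros((codes.shape[0], 0))
    scores = np.zeros((codes.shape[0], n_win))
    for j in range(x):
        col = codes[:, j : j + n_win]
        cell = np.where(col >= 0, lo[j][np.clip(col, 0, 3)], -np.inf)
        scores += cell
    return scores


def scan_scores(pwm: PWMModel, sequences: Iterable[str] | np.ndarray) -> dict[Strand, np.ndarray]:
    """Window scores for a batch of equal-length sequences on both strands.

    Returns ``{'top': (n, W), 'bottom': (n, W)}`` where W = L - X + 1 and
    column w corresponds to the window starting at top-strand position
    w + 1 (1-based).
    """
    if isinstance(sequences, np.ndarray):
        codes = sequences
    else:
        codes = np.vstack([encode(s) for s in sequences])
    return {
        "top": _window_scores(pwm.logodds_matrix, codes),
        "bottom": _window_scores(_rc_logodds(pwm), codes),
    }


def _score_codes(pwm: PWMModel, codes: np.ndarray) -> np.ndarray:
    return _window_scores(pwm.logodds_matrix, codes)


def _hits(pwm: PWMModel, sequence: str, kind: Literal["predicted", "proto"]) -> list[SiteHit]:
    codes = encode(sequence)[None, :]
    if codes.shape[1] < pwm.length:
        raise ValueError("sequence shorter than the PWM")
    thr = pwm.patser_threshold
    out: list[SiteHit] = []
    for strand, lo in (("top", pwm.logodds_matrix), ("bottom", _rc_logodds(pwm))):
        scores = _window_scores(lo, codes)[0]
        if kind == "predicted":
            mask = scores >= thr
        else:
            mask = (scores > 0.0) & (scores < thr)
        for w in np.nonzero(mask)[0]:
            out.append(
                SiteHit(pwm.factor_id, int(w) + 1, strand, float(scores[w]), kind)
            )
    out.sort(key=lambda h: (h.start, h.strand))
    return out


def predicted_sites(pwm: PWMModel, sequence: str) -> list[SiteHit]:
    """All windows on either strand scoring at or above the Patser threshold."""
    return _hits(pwm, sequence, "predicted")


def proto_sites(pwm: PWMModel, sequence: str) -> list[SiteHit]:
    """All windows on either strand with 0 < score < Patser threshold."""
    return _hits(pwm, sequence, "proto")


def load_site_lists(directory: str, factor_classes: dict[str, FactorClass] | None = None,
                    pseudocount: float = 0.0) -> list[PWMModel]:
    """Build one PWM per plain-text file of aligned sites (one per line).

    The file stem is the factor id; ``factor_classes`` maps ids to
    'sigma' or 'tf' (default 'tf').
    """
    models = []
    for name in sorted(os.listdir(directory)):
        path = os.path.join(directory, name)
        if not os.path.isfile(path):
            continue
        factor_id = os.path.splitext(name)[0]
        with open(path) as fh:
            sites = [line.strip().upper() for line in fh if line.strip()]
        cls = (factor_classes or {}).get(factor_id, "tf")
        models.append(build_pwm(sites, factor_id, cls, pseudocount))
    return models


def load_jaspar(path: str, factor_class: FactorClass = "tf",
                pseudocount: float = 0.0) -> list[PWMModel]:
    """Read JASPAR-format count matrices into PWM models (via Biopython)."""
    from Bio import motifs

    models = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([[m.counts[b][i] for b in ALPHABET]
                               for i in range(m.length)], dtype=float)
            counts += pseudocount
            probs = counts / counts.sum(axis=1, keepdims=True)
            models.append(PWMModel(m.name or m.matrix_id, factor_class, probs,
                                   pseudocount=pseudocount))
    return models


def pwms_to_tsv(models: Sequence[PWMModel], path: str) -> None:
    """Serialize a PWM set to a provenance TSV (long format)."""
    import pandas as pd

    rows = []
    for m in models:
        for i in range(m.length):
            rows.append(
                {
                    "factor_id": m.factor_id,
                    "factor_class": m.factor_class,
                    "position": i + 1,
                    **{b: m.prob_matrix[i, j] for j, b in enumerate(ALPHABET)},
                    "information_content": m.information_content,
                    "patser_threshold": m.patser_threshold,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
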