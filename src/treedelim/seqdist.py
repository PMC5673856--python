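"""Alignment-based distances: uncorrected p, K2P, and GTR-corrected.

All distances use pairwise deletion: a site contributes to a pair only when
both sequences carry an unambiguous A/C/G/T there.  IUPAC ambiguity codes,
``-``, ``N`` and ``?`` are treated as missing (no fractional matching).
Internally distances are proportions; report writers multiply by 100.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.linalg import logm

from .delimitation import HaplogroupAssignment

__all__ = [
    "Alignment",
    "PairwiseCounts",
    "GroupedDistanceMatrix",
    "SaturationProfile",
    "read_alignment",
    "pairwise_counts",
    "p_distance",
    "k2p_distance",
    "gtr_distance",
    "grouped_distance_matrix",
    "saturation_profile",
    "missing_fraction",
]

logger = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: everything that is not an unambiguous base
MISSING_CHARS = frozenset("-N?RYSWKMBDHV")


class Alignment:
    """Equal-length DNA sequences with unique labels (uppercased on load)."""

    def __init__(self, labels: list[str], sequences: list[str]):
        if not labels:
            raise ValueError("empty alignment")
        if len(labels) != len(sequences):
            raise ValueError("labels and sequences differ in number")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate sequence labels: {dupes}")
        length = len(sequences[0])
        if length == 0:
            raise ValueError("zero-length sequences")
        for lab, seq in zip(labels, sequences):
            if len(seq) != length:
                raise ValueError(
                    f"ragged alignment: {lab!r} has length {len(seq)}, "
                    f"expected {length}"
                )
        self.labels = list(labels)
        self.sequences = [s.upper() for s in sequences]
        # uint8 codes: A,C,G,T -> 0..3, anything else -> 255
        self.codes = np.vstack(
            [_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
             for s in self.sequences]
        )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.labels)

    def row(self, label: str) -> np.ndarray:
        return self.codes[self.labels.index(label)]

    def write_fasta(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for lab, seq in zip(self.labels, self.sequences):
                fh.write(f">{lab}\n{seq}\n")


def read_alignment(path: Union[str, Path]) -> Alignment:
    """Load a FASTA alignment, enforcing uniform length and unique labels."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


@dataclass(frozen=True)
class PairwiseCounts:
    """Site counts for one sequence pair under pairwise deletion."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self):
        if min(self.n_compared, self.n_transitions, self.n_transversions) < 0:
            raise ValueError("negative count")
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("more differences than compared sites")


def _codes(seq: Union[str, np.ndarray]) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def pairwise_counts(
    a: Union[str, np.ndarray], b: Union[str, np.ndarray]
) -> PairwiseCounts:
    """Compared/transition/transversion site counts for two aligned rows.

    Transitions are A<->G and C<->T; every other difference is a
    transversion.  Sites with a gap, N or ambiguity code in either sequence
    are excluded.
    """
    ca, cb = _codes(a), _codes(b)
    if ca.shape != cb.shape:
        raise ValueError(
            f"length mismatch: {ca.shape[0]} vs {cb.shape[0]}"
        )
    valid = (ca < 4) & (cb < 4)
    diff = valid & (ca != cb)
    # with A=0,C=1,G=2,T=3 a transition is exactly an absolute-difference of 2
    ts = diff & (np.abs(ca.astype(int) - cb.astype(int)) == 2)
    return PairwiseCounts(
        int(valid.sum()), int(ts.sum()), int((diff & ~ts).sum())
    )


def p_distance(counts: PairwiseCounts) -> float:
    """Uncorrected proportion of differing sites; NaN if nothing to compare."""
    if counts.n_compared == 0:
        warnings.warn("no comparable sites; p-distance undefined")
        return math.nan
    return (counts.n_transitions + counts.n_transversions) / counts.n_compared


def k2p_distance(counts: PairwiseCounts) -> float:
    """Kimura 2-parameter distance, d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    P and Q are the transition and transversion proportions.  Outside the
    formula's domain (saturated pair) the distance is NaN with a warning.
    """
    if counts.n_compared == 0:
        warnings.warn("no comparable sites; K2P distance undefined")
        return math.nan
    p = counts.n_transitions / counts.n_compared
    q = counts.n_transversions / counts.n_compared
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        warnings.warn(f"saturated pair (P={p:.3f}, Q={q:.3f}); K2P undefined")
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def gtr_distance(
    a: Union[str, np.ndarray],
    b: Union[str, np.ndarray],
    frequencies: Optional[np.ndarray] = None,
) -> float:
    """General time-reversible (log-det style) corrected distance.

    Builds the 4x4 joint divergence matrix F over compared sites,
    symmetrizes it, and evaluates ``-trace(Pi @ logm(Pi^-1 F))`` with Pi the
    diagonal of the base frequencies (estimated from the pooled pair unless
    supplied).  Returns NaN with a warning when the matrix log does not
    exist (non-positive eigenvalues).
    """
    ca, cb = _codes(a), _codes(b)
    if ca.shape != cb.shape:
        raise ValueError("length mismatch")
    valid = (ca < 4) & (cb < 4)
    n = int(valid.sum())
    if n == 0:
        warnings.warn("no comparable sites; GTR distance undefined")
        return math.nan
    joint = np.zeros((4, 4))
    np.add.at(joint, (ca[valid], cb[valid]), 1.0)
    f = (joint + joint.T) / (2.0 * n)
    if frequencies is None:
        freqs = f.sum(axis=1)
    else:
        freqs = np.asarray(frequencies, dtype=float)
        freqs = freqs / freqs.sum()
    if np.any(freqs <= 0):
        warnings.warn("zero base frequency; GTR distance undefined")
        return math.nan
    pi = np.diag(freqs)
    m = np.linalg.inv(pi) @ f
    eigvals = np.linalg.eigvals(m)
    if np.any(eigvals.real <= 0) or np.any(np.abs(eigvals.imag) > 1e-8):
        warnings.warn("non-positive eigenvalues; GTR distance undefined")
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logmat = logm(m)
    d = -np.trace(pi @ logmat)
    return float(np.real(d))


@dataclass
class GroupedDistanceMatrix:
    """Within-group diagonal plus between-group p / K2P triangles."""

    group_names: list[str]
    within: np.ndarray        # mean within-group p-distance, NaN for singletons
    between_p: np.ndarray     # symmetric mean cross-group p-distance
    between_k2p: np.ndarray   # symmetric mean cross-group K2P distance

    def to_table(self, percent: bool = True, decimals: int = 1) -> pd.DataFrame:
        """Matrix layout: diagonal = within, lower = p, upper = K2P."""
        k = len(self.group_names)
        scale = 100.0 if percent else 1.0
        out = np.full((k, k), np.nan)
        for i in range(k):
            out[i, i] = self.within[i] * scale
            for j in range(i):
                out[i, j] = self.between_p[i, j] * scale
                out[j, i] = self.between_k2p[i, j] * scale
        frame = pd.DataFrame(out, index=self.group_names,
                             columns=self.group_names)
        return frame.round(decimals)


def grouped_distance_matrix(
    alignment: Alignment, assignment: HaplogroupAssignment
) -> GroupedDistanceMatrix:
    """Mean within/between haplogroup distances (p within, p and K2P between).

    Within-group means are NaN for singleton groups.  Pairs whose distance
    is undefined (no overlap, K2P saturation) are dropped from the mean with
    a warning from the underlying distance function.
    """
    unknown = sorted(set(alignment.labels) - set(assignment.mapping))
    if unknown:
        raise ValueError(f"alignment labels without assignment: {unknown}")
    groups = assignment.groups()
    names = list(groups)
    k = len(names)
    rows = {lab: alignment.codes[i] for i, lab in enumerate(alignment.labels)}

    def pair_p_k2p(la: str, lb: str) -> tuple[float, float]:
        counts = pairwise_counts(rows[la], rows[lb])
        return p_distance(counts), k2p_distance(counts)

    within = np.full(k, np.nan)
    between_p = np.zeros((k, k))
    between_k2p = np.zeros((k, k))
    for i, gi in enumerate(names):
        mi = groups[gi]
        if len(mi) > 1:
            vals = [
                pair_p_k2p(mi[x], mi[y])[0]
                for x in range(len(mi))
                for y in range(x + 1, len(mi))
            ]
            within[i] = np.nanmean(vals)
        for j in range(i + 1, k):
            mj = groups[names[j]]
            ps, ks = zip(*(pair_p_k2p(a, b) for a in mi for b in mj))
            between_p[i, j] = between_p[j, i] = np.nanmean(ps)
            between_k2p[i, j] = between_k2p[j, i] = np.nanmean(ks)
    return GroupedDistanceMatrix(names, within, between_p, between_k2p)


@dataclass
class SaturationProfile:
    """Per-pair corrected distance vs transition/transversion proportions."""

    records: pd.DataFrame  # columns: a, b, gtr_distance, prop_ts, prop_tv
    n_pairs: int
    n_transversion_dominated: int

    @property
    def transitions_dominate(self) -> bool:
        return self.n_transversion_dominated == 0


def saturation_profile(alignment: Alignment) -> SaturationProfile:
    """Data for a saturation plot: s and v proportions against GTR distance."""
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    rows = []
    n_v_dom = 0
    for i in range(len(alignment)):
        for j in range(i + 1, len(alignment)):
            counts = pairwise_counts(alignment.codes[i], alignment.codes[j])
            if counts.n_compared:
                s = counts.n_transitions / counts.n_compared
                v = counts.n_transversions / counts.n_compared
            else:
                s = v = math.nan
            d = gtr_distance(alignment.codes[i], alignment.codes[j])
            if v > s:
                n_v_dom += 1
            rows.append(
                (alignment.labels[i], alignment.labels[j], d, s, v)
            )
    frame = pd.DataFrame(
        rows, columns=["a", "b", "gtr_distance", "prop_ts", "prop_tv"]
    )
    return SaturationProfile(frame, len(rows), n_v_dom)


def missing_fraction(
    alignment: Alignment, missing_chars: frozenset = MISSING_CHARS
) -> float:
    """Fraction of alignment cells that are gaps, N/?, or ambiguity codes."""
    total = len(alignment) * alignment.length
    n_missing = sum(
        1 for seq in alignment.sequences for c in seq if c in missing_chars
    )
    return n_missing / total
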