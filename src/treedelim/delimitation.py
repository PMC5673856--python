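"""Per-haplogroup species-delimitation statistics on a rooted gene tree.

Given a tree and a tip -> haplogroup assignment, computes for every
haplogroup: the support of its MRCA node, Intra (mean pairwise patristic
distance among members), Inter (mean pairwise patristic distance to the
closest other haplogroup), their ratio, Av(MRCA-tips) (mean MRCA-to-member
path length), and Monte-Carlo identification probabilities P ID (strict:
a hypothetical new member must attach within the group's clade; liberal:
within or sister to it).

Singleton conventions: Intra, ratio, Av(MRCA-tips), P ID (strict) and
support are all NA; P ID (liberal) is still estimated.  NA values are
excluded (never imputed) from column means.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .treeio import RootedTree, TreeNode, clade_tips, mrca, patristic_matrix

__all__ = [
    "HaplogroupAssignment",
    "PidEstimate",
    "DelimitationRecord",
    "SummaryMeans",
    "load_assignments",
    "intra_distance",
    "inter_and_closest",
    "intra_inter_ratio",
    "av_mrca_tips",
    "pid_estimate",
    "delimit_table",
    "summarize_table",
    "records_from_frame",
    "write_report",
    "REPORT_COLUMNS",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "focal",
    "closest",
    "support",
    "intra",
    "inter",
    "ratio",
    "pid_strict_mean",
    "pid_strict_low",
    "pid_strict_high",
    "pid_liberal_mean",
    "pid_liberal_low",
    "pid_liberal_high",
    "av_mrca_tips",
]

_HEADER_WORDS = {"tip", "label", "terminal", "sequence", "taxon", "name"}


class HaplogroupAssignment:
    """Mapping from tip label to haplogroup (putative species) name."""

    def __init__(self, mapping: dict[str, str]):
        bad = [t for t, g in mapping.items() if not g]
        if bad:
            raise ValueError(f"empty haplogroup name for tips: {sorted(bad)}")
        self.mapping = dict(mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, tip: str) -> str:
        return self.mapping[tip]

    @property
    def haplogroups(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def members(self, group: str) -> list[str]:
        tips = sorted(t for t, g in self.mapping.items() if g == group)
        if not tips:
            raise KeyError(f"unknown haplogroup: {group!r}")
        return tips

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tip in sorted(self.mapping):
            out.setdefault(self.mapping[tip], []).append(tip)
        return {g: out[g] for g in sorted(out)}

    def unassigned_tips(self, tree: RootedTree) -> list[str]:
        """Tree tips absent from the table; these are excluded from statistics."""
        return sorted(set(tree.tip_labels) - set(self.mapping))

    def validate_against(self, tree: RootedTree) -> None:
        missing = sorted(set(self.mapping) - set(tree.tip_labels))
        if missing:
            raise ValueError(f"assigned tips not in tree: {missing}")
        if len(self.haplogroups) < 2:
            raise ValueError("need at least 2 haplogroups")
        extra = self.unassigned_tips(tree)
        if extra:
            logger.warning(
                "%d tree tips are unassigned and will be ignored: %s",
                len(extra), extra,
            )


def load_assignments(path: Union[str, Path]) -> HaplogroupAssignment:
    """Read a two-column (tip, haplogroup) TSV; a header row is optional.

    Duplicate tip rows with identical groups are deduplicated; conflicting
    duplicates are an error naming the tip.
    """
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"line {i + 1}: expected 2 columns, got {row!r}")
            tip, group = row[0].strip(), row[1].strip()
            if i == 0 and tip.lower() in _HEADER_WORDS:
                continue
            if tip in mapping and mapping[tip] != group:
                raise ValueError(
                    f"tip {tip!r} assigned to both {mapping[tip]!r} and {group!r}"
                )
            mapping[tip] = group
    if not mapping:
        raise ValueError(f"no assignments found in {path}")
    return HaplogroupAssignment(mapping)


# ---------------------------------------------------------------------------
# distance statistics


def _dmat(tree: RootedTree, dmat: Optional[pd.DataFrame]) -> pd.DataFrame:
    return patristic_matrix(tree) if dmat is None else dmat


def intra_distance(
    tree: RootedTree,
    assignment: HaplogroupAssignment,
    focal: str,
    dmat: Optional[pd.DataFrame] = None,
) -> Optional[float]:
    """Mean pairwise patristic distance among members; None for singletons."""
    members = assignment.members(focal)
    if len(members) < 2:
        return None
    d = _dmat(tree, dmat)
    sub = d.loc[members, members].to_numpy()
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def inter_and_closest(
    tree: RootedTree,
    assignment: HaplogroupAssignment,
    focal: str,
    dmat: Optional[pd.DataFrame] = None,
) -> tuple[str, float]:
    """Closest other haplogroup by mean cross-pair patristic distance.

    Exact ties are broken by lexicographically smallest group name, with a
    logged warning.
    """
    members = assignment.members(focal)
    d = _dmat(tree, dmat)
    best: Optional[tuple[float, str]] = None
    tied: list[str] = []
    for other in assignment.haplogroups:
        if other == focal:
            continue
        val = float(d.loc[members, assignment.members(other)].to_numpy().mean())
        if best is None or val < best[0]:
            best = (val, other)
            tied = [other]
        elif val == best[0]:
            tied.append(other)
    if best is None:
        raise ValueError("need at least 2 haplogroups")
    if len(tied) > 1:
        logger.warning(
            "closest-haplogroup tie for %r among %s; choosing %r",
            focal, sorted(tied), min(tied),
        )
        best = (best[0], min(tied))
    return best[1], best[0]


def intra_inter_ratio(
    intra: Optional[float], inter: float
) -> Optional[float]:
    """Intra/Inter; None when Intra is undefined.  Requires inter > 0."""
    if not inter > 0:
        raise ValueError(f"inter distance must be positive, got {inter}")
    if intra is None or (isinstance(intra, float) and math.isnan(intra)):
        return None
    return intra / inter


def av_mrca_tips(
    tree: RootedTree,
    assignment: HaplogroupAssignment,
    focal: str,
) -> Optional[float]:
    """Mean path length from the group's MRCA down to each member tip."""
    members = assignment.members(focal)
    if len(members) < 2:
        return None
    anc = mrca(tree, members)
    anc_depth = anc.depth()
    return float(
        np.mean([tree.tip(m).depth() - anc_depth for m in members])
    )


# ---------------------------------------------------------------------------
# P ID Monte-Carlo estimator


@dataclass(frozen=True)
class PidEstimate:
    mean: float
    low: float
    high: float

    def __iter__(self):
        return iter((self.mean, self.low, self.high))


def _attachment_zone(point_node: TreeNode, group_mrca: TreeNode) -> str:
    """Classify the edge above ``point_node`` relative to the focal clade."""
    if point_node is group_mrca:
        return "sister"  # the clade's subtending branch
    for anc in point_node.ancestors():
        if anc is group_mrca:
            return "within"
    return "outside"


def pid_estimate(
    tree: RootedTree,
    assignment: HaplogroupAssignment,
    focal: str,
    mode: str = "strict",
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> Optional[PidEstimate]:
    """Monte-Carlo probability of correctly identifying a new group member.

    Each replicate simulates the gene-tree attachment point of a
    hypothetical, previously unsampled member of the focal haplogroup: a
    member tip is drawn uniformly, the query's divergence from it is drawn
    exponentially with mean half a random within-group pairwise patristic
    distance (the coalescent-motivated scale on which existing members find
    their ancestors), and the attachment point is located by walking that
    distance rootward from the member tip.  The replicate succeeds if the
    point lies on a branch inside the group's clade (``strict``) or inside
    or on its subtending branch (``liberal``).  For singletons the
    within-group scale is unobservable and half the tip's subtending branch
    length is used instead; ``strict`` is undefined (None) for singletons.

    Returns the success frequency with a percentile 95% CI over batches of
    replicates; deterministic for a fixed seed.
    """
    if mode not in ("strict", "liberal"):
        raise ValueError(f"mode must be 'strict' or 'liberal', got {mode!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    members = assignment.members(focal)
    singleton = len(members) == 1
    if singleton and mode == "strict":
        return None

    rng = np.random.default_rng(seed)
    group_mrca = mrca(tree, members)
    member_nodes = [tree.tip(m) for m in members]
    dmat = patristic_matrix(tree).loc[members, members].to_numpy()

    successes = np.zeros(n_reps, dtype=bool)
    for rep in range(n_reps):
        i = rng.integers(len(members))
        if singleton:
            scale = member_nodes[0].length / 2.0
        else:
            j = rng.integers(len(members) - 1)
            if j >= i:
                j += 1
            scale = dmat[i, j] / 2.0
        w = rng.exponential(scale) if scale > 0 else 0.0

        node = member_nodes[i]
        remaining = w
        zone = "outside"
        while True:
            if remaining <= node.length or node.is_root:
                if node.is_root and remaining > node.length:
                    zone = "outside"  # walked past the root
                else:
                    zone = _attachment_zone(node, group_mrca)
                break
            remaining -= node.length
            node = node.parent
        if mode == "strict":
            successes[rep] = zone == "within"
        else:
            successes[rep] = zone in ("within", "sister")

    mean = float(successes.mean())
    n_batches = min(20, n_reps)
    batch_means = [
        float(chunk.mean()) for chunk in np.array_split(successes, n_batches)
    ]
    low, high = np.percentile(batch_means, [2.5, 97.5])
    low = min(float(low), mean)
    high = max(float(high), mean)
    return PidEstimate(mean, max(0.0, low), min(1.0, high))


# ---------------------------------------------------------------------------
# table assembly


@dataclass
class DelimitationRecord:
    """One row of the per-haplogroup delimitation report."""

    focal: str
    closest: Optional[str]
    support: Optional[float]
    intra: Optional[float]
    inter: float
    ratio: Optional[float]
    pid_strict: Optional[PidEstimate]
    pid_liberal: Optional[PidEstimate]
    av_mrca_tips: Optional[float]


@dataclass(frozen=True)
class SummaryMeans:
    mean_intra: Optional[float]
    mean_inter: Optional[float]
    mean_pid_strict: Optional[float]
    mean_pid_liberal: Optional[float]
    mean_av_mrca_tips: Optional[float]


def delimit_table(
    tree: RootedTree,
    assignment: HaplogroupAssignment,
    n_reps: int = 1000,
    seed: Optional[int] = 0,
) -> list[DelimitationRecord]:
    """One :class:`DelimitationRecord` per haplogroup, in sorted name order.

    The support column is the support value of the focal MRCA node (None for
    singletons, for the root, and for unannotated nodes).  Per-group P ID
    seeds are spawned from ``seed`` in sorted group order, so results are
    invariant to input tip ordering.
    """
    assignment.validate_against(tree)
    dmat = patristic_matrix(tree)
    groups = assignment.haplogroups
    child_seeds = np.random.SeedSequence(seed).spawn(len(groups))
    records = []
    for group, ss in zip(groups, child_seeds):
        members = assignment.members(group)
        singleton = len(members) == 1
        if singleton:
            support = None
            logger.info("%s: singleton; intra/ratio/av/strict reported NA", group)
        else:
            node = mrca(tree, members)
            support = None if node.is_root else node.support
        intra = intra_distance(tree, assignment, group, dmat)
        closest, inter = inter_and_closest(tree, assignment, group, dmat)
        seed_strict, seed_liberal = ss.spawn(2)
        records.append(
            DelimitationRecord(
                focal=group,
                closest=closest,
                support=support,
                intra=intra,
                inter=inter,
                ratio=intra_inter_ratio(intra, inter),
                pid_strict=pid_estimate(
                    tree, assignment, group, "strict", n_reps, seed_strict
                ),
                pid_liberal=pid_estimate(
                    tree, assignment, group, "liberal", n_reps, seed_liberal
                ),
                av_mrca_tips=av_mrca_tips(tree, assignment, group),
            )
        )
    return records


def _mean_or_none(values: Iterable[Optional[float]]) -> Optional[float]:
    kept = [v for v in values if v is not None and not math.isnan(v)]
    return float(np.mean(kept)) if kept else None


def summarize_table(records: Sequence[DelimitationRecord]) -> SummaryMeans:
    """Arithmetic column means over records, NA entries excluded."""
    if not records:
        raise ValueError("no records to summarize")
    return SummaryMeans(
        mean_intra=_mean_or_none(r.intra for r in records),
        mean_inter=_mean_or_none(r.inter for r in records),
        mean_pid_strict=_mean_or_none(
            r.pid_strict.mean if r.pid_strict else None for r in records
        ),
        mean_pid_liberal=_mean_or_none(
            r.pid_liberal.mean if r.pid_liberal else None for r in records
        ),
        mean_av_mrca_tips=_mean_or_none(r.av_mrca_tips for r in records),
    )


def records_from_frame(frame: pd.DataFrame) -> list[DelimitationRecord]:
    """Build records from a report-format table (e.g. a transcribed fixture).

    Expects the :data:`REPORT_COLUMNS` numeric columns; NaN maps to None.
    The support column may be non-numeric (e.g. ``"<50"``) and is kept as-is.
    """

    def opt(value) -> Optional[float]:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return float(value)

    def pid(row, prefix) -> Optional[PidEstimate]:
        m = opt(row[f"{prefix}_mean"])
        if m is None:
            return None
        return PidEstimate(m, opt(row[f"{prefix}_low"]), opt(row[f"{prefix}_high"]))

    records = []
    for _, row in frame.iterrows():
        sup = row["support"]
        try:
            sup = opt(float(sup))
        except (TypeError, ValueError):
            pass  # categorical support like "<50" is preserved verbatim
        records.append(
            DelimitationRecord(
                focal=str(row["focal"]),
                closest=str(row["closest"]),
                support=sup,
                intra=opt(row["intra"]),
                inter=float(row["inter"]),
                ratio=opt(row.get("ratio")),
                pid_strict=pid(row, "pid_strict"),
                pid_liberal=pid(row, "pid_liberal"),
                av_mrca_tips=opt(row["av_mrca_tips"]),
            )
        )
    return records


def _cell(value: Optional[float], decimals: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, str):
        return value
    return f"{value:.{decimals}f}"


def write_report(
    records: Sequence[DelimitationRecord],
    path: Union[str, Path],
    distance_decimals: int = 3,
    ratio_decimals: int = 2,
    pid_decimals: int = 2,
    av_decimals: int = 4,
) -> None:
    """Write the delimitation table as TSV with the literal ``NA``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(REPORT_COLUMNS)
        for r in records:
            strict = r.pid_strict or (None, None, None)
            liberal = r.pid_liberal or (None, None, None)
            writer.writerow(
                [
                    r.focal,
                    r.closest or "NA",
                    _cell(r.support, 2),
                    _cell(r.intra, distance_decimals),
                    _cell(r.inter, distance_decimals),
                    _cell(r.ratio, ratio_decimals),
                    *(_cell(v, pid_decimals) for v in strict),
                    *(_cell(v, pid_decimals) for v in liberal),
                    _cell(r.av_mrca_tips, av_decimals),
                ]
            )


def write_summary(summary: SummaryMeans, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["mean_intra", "mean_inter", "mean_pid_strict",
             "mean_pid_liberal", "mean_av_mrca_tips"]
        )
        writer.writerow(
            [
                _cell(summary.mean_intra, 3),
                _cell(summary.mean_inter, 3),
                _cell(summary.mean_pid_strict, 3),
                _cell(summary.mean_pid_liberal, 3),
                _cell(summary.mean_av_mrca_tips, 3),
            ]
        )
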