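"""Synthetic gene trees and alignments with known species boundaries.

Gene trees come from a multispecies coalescent (a ladder species tree with
per-species effective sizes, simulated with msprime); sequences evolve down
the gene tree under a Kimura 2-parameter model with optional gamma rate
heterogeneity and a proportion of invariant sites.  A configurable fraction
of cells can be masked as missing.  Every stochastic draw descends from one
seed per dataset, so outputs are bit-reproducible.

Time units: species divergence times are given in coalescent units of
2N_ref generations (N_ref = the first species' effective size); the
simulated gene tree carries branch lengths in generations, in which the
mean within-species pairwise coalescence time is 2N.  ``make_dataset``
rescales branch lengths to expected substitutions/site via the supplied
per-generation rate before writing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import msprime
import numpy as np

from .delimitation import HaplogroupAssignment
from .seqdist import Alignment
from .treeio import RootedTree, TreeNode, parse_newick, write_newick

__all__ = [
    "SpeciesTreeSpec",
    "SeqParams",
    "SimulatedDataset",
    "simulate_gene_tree",
    "simulate_alignment",
    "inject_missing",
    "make_dataset",
    "assignment_from_labels",
    "scale_branch_lengths",
    "preset",
    "PRESETS",
]


@dataclass
class SpeciesTreeSpec:
    """A ladder ("caterpillar") species tree for the coalescent simulator.

    ``divergence_times`` (coalescent units of 2*N_ref generations, strictly
    increasing, length ``n_species - 1``) are the successive join times:
    species 0 and 1 join first, their ancestor joins species 2 next, etc.
    ``n_species == 1`` is allowed for single-population calibration runs.
    """

    n_species: int
    divergence_times: Sequence[float] = field(default_factory=tuple)
    tips_per_species: Union[int, Sequence[int]] = 5
    pop_sizes: Union[float, Sequence[float]] = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("need at least 1 species")
        if len(self.divergence_times) != self.n_species - 1:
            raise ValueError(
                f"need {self.n_species - 1} divergence times, "
                f"got {len(self.divergence_times)}"
            )
        times = list(self.divergence_times)
        if any(t <= 0 for t in times) or any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise ValueError("divergence times must be positive and increasing")
        if isinstance(self.tips_per_species, int):
            self.tips_per_species = [self.tips_per_species] * self.n_species
        if any(n < 1 for n in self.tips_per_species):
            raise ValueError("every species needs at least one tip")
        if isinstance(self.pop_sizes, (int, float)):
            self.pop_sizes = [float(self.pop_sizes)] * self.n_species
        if any(n <= 0 for n in self.pop_sizes):
            raise ValueError("effective sizes must be positive")


@dataclass
class SeqParams:
    """Substitution / missing-data parameters for alignment simulation."""

    length: int = 1140
    rate: float = 0.005          # substitutions/site/generation
    kappa: float = 8.0           # expected ts:tv ratio is kappa/2
    gamma_alpha: Optional[float] = None
    p_invariant: float = 0.0
    missing_fraction: float = 0.0


@dataclass
class SimulatedDataset:
    tree: RootedTree             # branch lengths in substitutions/site
    alignment: Alignment
    assignment: HaplogroupAssignment
    truth: dict


def _msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_gene_tree(spec: SpeciesTreeSpec) -> RootedTree:
    """One coalescent gene tree; branch lengths in generations.

    Tips are labelled ``sp{i}_{j}`` for the j-th sample of species i.  With
    haploid lineages at rate 1/(2N) per pair, the mean pairwise coalescence
    time within a species of effective size N is 2N generations.
    """
    rng = np.random.default_rng(spec.seed)
    n_ref = spec.pop_sizes[0]
    demography = msprime.Demography()
    for i, size in enumerate(spec.pop_sizes):
        # ploidy-1 pair rate is 1/initial_size: use 2N for diploid scaling
        demography.add_population(name=f"sp{i}", initial_size=2.0 * size)
    prev = "sp0"
    for i, t in enumerate(spec.divergence_times):
        anc = f"anc{i}"
        demography.add_population(name=anc, initial_size=2.0 * n_ref)
        demography.add_population_split(
            time=t * 2.0 * n_ref, derived=[prev, f"sp{i + 1}"], ancestral=anc
        )
        prev = anc
    samples = [
        msprime.SampleSet(n, population=f"sp{i}", ploidy=1)
        for i, n in enumerate(spec.tips_per_species)
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        ploidy=1,
        random_seed=_msprime_seed(rng),
    )
    gtree = ts.first()

    labels: dict[int, str] = {}
    counters = [0] * spec.n_species
    pops = ts.tables.nodes.population
    for u in ts.samples():
        pop = int(pops[u])
        labels[u] = f"sp{pop}_{counters[pop]}"
        counters[pop] += 1

    def build(u: int) -> TreeNode:
        node = TreeNode(length=float(gtree.branch_length(u)))
        kids = list(gtree.children(u))
        if not kids:
            node.label = labels[u]
        for v in kids:
            node.add_child(build(v))
        return node

    root = build(gtree.root)
    root.length = 0.0
    return RootedTree(root)


def assignment_from_labels(labels: Sequence[str]) -> HaplogroupAssignment:
    """Recover the species assignment from ``sp{i}_{j}`` tip labels."""
    return HaplogroupAssignment(
        {lab: lab.rsplit("_", 1)[0] for lab in labels}
    )


def scale_branch_lengths(tree: RootedTree, factor: float) -> RootedTree:
    """A copy of the tree with every branch length multiplied by ``factor``."""
    copy = parse_newick(write_newick(tree), support_kind=tree.support_kind,
                        default_branch_length=0.0)
    for node in copy.preorder():
        node.length *= factor
    return copy


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _k2p_step(
    states: np.ndarray, d: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve site states over a branch of per-site expected lengths ``d``.

    Closed-form K80 transition probabilities with rates normalized so that
    the expected number of substitutions per unit branch length is 1:
    alpha = kappa/(kappa+2) (transition), beta = 1/(kappa+2) (each
    transversion).
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    u = rng.random(states.shape[0])
    out = states.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2_mask = u >= p_same + p_ts + p_tv
    # codes A=0,C=1,G=2,T=3: transition partner is code^2, transversions ^1, ^3
    out[ts_mask] ^= 2
    out[tv1_mask] ^= 1
    out[tv2_mask] ^= 3
    return out


def simulate_alignment(
    tree: RootedTree,
    length: int,
    rate: float = 1.0,
    kappa: float = 2.0,
    gamma_alpha: Optional[float] = None,
    p_invariant: float = 0.0,
    seed: Optional[int] = None,
) -> Alignment:
    """Evolve sequences site-independently down ``tree`` under K2P(+G+I).

    ``rate`` converts branch lengths to expected substitutions/site (use 1.0
    when the tree is already in substitutions/site).  Site-specific rate
    multipliers are 0 with probability ``p_invariant``, otherwise 1 or a
    mean-1 gamma draw when ``gamma_alpha`` is given.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if not 0 <= p_invariant < 1:
        raise ValueError("p_invariant must be in [0, 1)")
    rng = np.random.default_rng(seed)
    multipliers = np.ones(length)
    if gamma_alpha is not None:
        if gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be positive")
        multipliers = rng.gamma(gamma_alpha, 1.0 / gamma_alpha, size=length)
    if p_invariant > 0:
        multipliers[rng.random(length) < p_invariant] = 0.0

    states = {id(tree.root): rng.integers(0, 4, size=length, dtype=np.uint8)}
    for node in tree.preorder():
        if node.is_root:
            continue
        parent_states = states[id(node.parent)]
        d = node.length * rate * multipliers
        states[id(node)] = _k2p_step(parent_states, d, kappa, rng)

    labels, seqs = [], []
    for tip in tree.tips:
        labels.append(tip.label)
        seqs.append(_BASES[states[id(tip)]].tobytes().decode())
    return Alignment(labels, seqs)


def inject_missing(
    alignment: Alignment, fraction: float, seed: Optional[int] = None
) -> Alignment:
    """Mask exactly ``round(fraction * n_cells)`` seeded uniform cells as N."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return Alignment(list(alignment.labels), list(alignment.sequences))
    rng = np.random.default_rng(seed)
    n_rows, n_cols = len(alignment), alignment.length
    n_mask = round(fraction * n_rows * n_cols)
    flat = rng.choice(n_rows * n_cols, size=n_mask, replace=False)
    grid = np.frombuffer(
        "".join(alignment.sequences).encode(), dtype=np.uint8
    ).copy()
    grid[flat] = ord("N")
    seqs = [
        grid[i * n_cols:(i + 1) * n_cols].tobytes().decode()
        for i in range(n_rows)
    ]
    return Alignment(list(alignment.labels), seqs)


def make_dataset(
    spec: SpeciesTreeSpec,
    seq_params: SeqParams,
    out_dir: Optional[Union[str, Path]] = None,
) -> SimulatedDataset:
    """Simulate a full dataset; optionally write the four artifact files.

    Writes ``tree.nwk`` (branch lengths rescaled to substitutions/site),
    ``alignment.fasta``, ``assignments.tsv`` and ``truth.json``.
    """
    ss = np.random.SeedSequence(spec.seed)
    seed_tree, seed_aln, seed_missing = (
        int(s.generate_state(1)[0]) for s in ss.spawn(3)
    )
    tree_spec = SpeciesTreeSpec(
        n_species=spec.n_species,
        divergence_times=list(spec.divergence_times),
        tips_per_species=list(spec.tips_per_species),
        pop_sizes=list(spec.pop_sizes),
        seed=seed_tree,
    )
    gene_tree = simulate_gene_tree(tree_spec)
    subst_tree = scale_branch_lengths(gene_tree, seq_params.rate)
    alignment = simulate_alignment(
        subst_tree,
        length=seq_params.length,
        rate=1.0,
        kappa=seq_params.kappa,
        gamma_alpha=seq_params.gamma_alpha,
        p_invariant=seq_params.p_invariant,
        seed=seed_aln,
    )
    alignment = inject_missing(
        alignment, seq_params.missing_fraction, seed=seed_missing
    )
    assignment = assignment_from_labels(subst_tree.tip_labels)
    truth = {
        "seed": spec.seed,
        "n_species": spec.n_species,
        "divergence_times_coalescent": list(map(float, spec.divergence_times)),
        "tips_per_species": list(map(int, spec.tips_per_species)),
        "pop_sizes": list(map(float, spec.pop_sizes)),
        **{k: v for k, v in asdict(seq_params).items()},
        "tree_units": "substitutions/site",
    }
    dataset = SimulatedDataset(subst_tree, alignment, assignment, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(write_newick(subst_tree) + "\n")
        alignment.write_fasta(out / "alignment.fasta")
        with open(out / "assignments.tsv", "w") as fh:
            fh.write("tip\thaplogroup\n")
            for tip in subst_tree.tip_labels:
                fh.write(f"{tip}\t{assignment[tip]}\n")
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return dataset


def preset(name: str, seed: Optional[int] = 0) -> tuple[SpeciesTreeSpec, SeqParams]:
    """Named simulation presets.

    ``deer-like``: 17 species-level haplogroups with 1-20 tips each,
    transition-biased substitution, gamma + invariant-site rate
    heterogeneity and 11% missing data — the statistical silhouette of a
    multi-species mitochondrial barcoding matrix.  ``deep``: divergences
    >= 10x the within-species coalescent scale (clean monophyly).
    ``shallow``: divergences near 2N (incomplete lineage sorting).
    """
    rng = np.random.default_rng(seed)
    if name == "deer-like":
        k = 17
        tips = [int(rng.integers(1, 21)) for _ in range(k)]
        times = list(np.linspace(0.5, 6.0, k - 1))
        spec = SpeciesTreeSpec(k, times, tips, 1.0, seed=seed)
        params = SeqParams(
            length=1140, rate=0.008, kappa=8.0,
            gamma_alpha=0.3, p_invariant=0.4, missing_fraction=0.11,
        )
        return spec, params
    if name == "deep":
        k = 5
        times = list(np.linspace(10.0, 25.0, k - 1))
        spec = SpeciesTreeSpec(k, times, 6, 1.0, seed=seed)
        params = SeqParams(length=2000, rate=0.002, kappa=8.0)
        return spec, params
    if name == "shallow":
        k = 5
        times = list(np.linspace(1.0, 2.5, k - 1))
        spec = SpeciesTreeSpec(k, times, 6, 1.0, seed=seed)
        params = SeqParams(length=2000, rate=0.01, kappa=8.0)
        return spec, params
    raise ValueError(
        f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
    )


PRESETS = ("deer-like", "deep", "shallow")
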