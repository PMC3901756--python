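"""Synthetic data: ultrametric trees and partitioned alignments with
known per-site rates.

The generator exists so every analysis stage can be exercised against
ground truth. Its default dataset (:func:`aciliini_fixture`) emulates
the structure of a concatenated multi-marker matrix for diving beetles:
eight gene fragments totalling 6095 bp on a ~40-taxon chronogram with a
110 Ma root, codon substructure in the protein-coding fragments, strong
among-partition rate heterogeneity (mitochondrial third positions
saturating over the tree depth, first/second positions far from it),
and 11% fragment-level missing data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import SeqMatrix
from .partitions import PartitionScheme, resolve_partitions
from .rates import SiteRateTable
from .substmodel import hky_spectral, transition_matrices
from .tree import PhyloTree

__all__ = [
    "SimPartitionSpec",
    "SimBundle",
    "simulate_tree",
    "simulate_alignment",
    "inject_missing",
    "aciliini_fixture",
    "write_bundle",
    "FRAGMENTS",
    "RATE_CLASSES",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimPartitionSpec:
    """How to simulate one block of columns.

    mean_rate is in substitutions/site/Ma; gamma_shape controls
    among-site rate variation (None = all sites at the mean rate);
    model is "JC" or "HKY" (kappa, freqs used for HKY only).
    """

    name: str
    length: int
    mean_rate: float
    gamma_shape: float | None = None
    model: str = "JC"
    kappa: float = 2.0
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.mean_rate < 0:
            raise ValueError("mean rate must be >= 0")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if self.model not in ("JC", "HKY"):
            raise ValueError("model must be 'JC' or 'HKY'")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError("freqs must sum to 1")

    def effective(self):
        """(kappa, freqs) actually used: JC forces kappa=1, equal freqs."""
        if self.model == "JC":
            return 1.0, (0.25, 0.25, 0.25, 0.25)
        return self.kappa, self.freqs


@dataclass
class SimBundle:
    """A simulated dataset plus its ground truth."""

    tree: PhyloTree
    matrix: SeqMatrix
    rates: SiteRateTable  # true per-site rates
    scheme: PartitionScheme
    seed: int
    config: dict = field(default_factory=dict)


def simulate_tree(n_tips: int, root_age: float, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree rescaled to an exact root age (Ma).

    The birth-death sampler stops at the n-th birth event, which leaves a
    zero-length cherry; leaf edges are therefore extended by the correct
    exponential waiting time to the (n+1)-th event before rescaling.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if root_age <= 0:
        raise ValueError("root age must be > 0")
    from dendropy.simulate import treesim

    rng = random.Random(int(seed))
    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=int(n_tips), rng=rng
    )
    extra = rng.expovariate(float(n_tips))
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    dtree.seed_node.edge.length = None  # drop the stem edge
    tree = PhyloTree.from_dendropy(dtree)
    # deterministic tip labels in preorder
    width = len(str(n_tips))
    counter = 0
    for i in range(tree.n_nodes):
        if tree.labels[i] is not None:
            counter += 1
            tree.labels[i] = f"t{counter:0{width}d}"
    tree._tip_index = {
        lab: i for i, lab in enumerate(tree.labels) if lab is not None
    }
    scale = root_age / tree.root_age
    return tree.scaled(scale)


def _evolve_block(
    tree: PhyloTree, spec: SimPartitionSpec, rng: np.random.Generator
):
    """Simulate one block root-to-tips; returns (tip_codes, site_rates)."""
    L = spec.length
    if spec.gamma_shape is None or spec.mean_rate == 0:
        lam = np.full(L, spec.mean_rate)
    else:
        lam = rng.gamma(spec.gamma_shape, spec.mean_rate / spec.gamma_shape, L)
    kappa, freqs = spec.effective()
    spectral = hky_spectral(kappa, freqs)
    freqs = np.asarray(freqs)

    states = {0: rng.choice(4, size=L, p=freqs)}
    order = [0]
    stack = [0]
    while stack:  # preorder
        node = stack.pop()
        for child in tree.children[node]:
            order.append(child)
            stack.append(child)
    for node in order[1:]:
        parent = states[tree.parent[node]]
        d = lam * tree.blen[node]
        if np.all(d == 0):
            states[node] = parent.copy()
            continue
        P = transition_matrices(d, spectral)  # (L, 4, 4)
        rows = P[np.arange(L), parent, :]
        cdf = np.cumsum(rows, axis=1)
        u = rng.random(L)
        states[node] = np.minimum((cdf < u[:, None]).sum(axis=1), 3).astype(
            np.uint8
        )
    tip_codes = np.stack([states[i] for i in tree.tip_ids])
    return tip_codes, lam


def simulate_alignment(
    tree: PhyloTree, specs, seed: int
) -> SimBundle:
    """Evolve consecutive blocks (one per spec) along the tree.

    Root states are drawn from the model's stationary frequencies; each
    branch applies the transition matrix at distance lambda_i * length.
    True per-site rates are recorded in the bundle.
    """
    rng = np.random.default_rng(int(seed))
    blocks, lams, names = [], [], []
    for spec in specs:
        codes, lam = _evolve_block(tree, spec, rng)
        blocks.append(codes)
        lams.append(lam)
        names.extend([spec.name] * spec.length)
    codes = np.hstack(blocks)
    lam = np.concatenate(lams)
    chars = _BASES[codes]
    matrix = SeqMatrix(tree.tip_labels, chars)

    parts = {}
    start = 1
    for spec in specs:
        parts[spec.name] = np.arange(start, start + spec.length)
        start += spec.length
    scheme = PartitionScheme(parts, width=codes.shape[1])
    rates = _true_rate_table(lam, names)
    return SimBundle(tree, matrix, rates, scheme, int(seed))


def _true_rate_table(lam, partition_names) -> SiteRateTable:
    n = len(lam)
    return SiteRateTable(
        pd.DataFrame(
            {
                "site": np.arange(1, n + 1),
                "partition": partition_names,
                "lambda": lam,
                "loglik": np.nan,
                "boundary": False,
            }
        )
    )


def inject_missing(
    matrix: SeqMatrix,
    scheme: PartitionScheme,
    fragment_missing_rate: float,
    seed: int,
) -> SeqMatrix:
    """Fragment-level missingness: with the given probability, wipe a
    whole (taxon, partition) cell to '?', independently per cell."""
    if not 0 <= fragment_missing_rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(int(seed))
    chars = matrix.chars.copy()
    for name, cols0 in scheme.items0():
        hit = rng.random(matrix.n_taxa) < fragment_missing_rate
        for row in np.flatnonzero(hit):
            chars[row, cols0] = "?"
    return SeqMatrix(list(matrix.labels), chars)


# -- the study-structure fixture --------------------------------------------

#: fragment name -> (length bp, genome, coding?)
FRAGMENTS = {
    "CAD": (2008, "nuclear", True),
    "COI_3p": (821, "mito", True),
    "COII": (684, "mito", True),
    "COI_5p": (671, "mito", True),
    "28S": (670, "nuclear", False),
    "Wnt": (466, "nuclear", True),
    "16S": (447, "mito", False),
    "H3": (328, "nuclear", True),
}

#: mean rates (substitutions/site/Ma) per rate regime; chosen so that
#: mitochondrial third positions saturate over a 110 Ma tree
#: (expected root-to-tip divergence > 2 subs/site) while first/second
#: positions stay far below saturation (< 0.2), with nuclear third
#: positions peaking in informativeness between roughly 35 and 55 Ma.
RATE_CLASSES = {
    "mito_pos3": 0.050,
    "H3_pos3": 0.010,
    "CAD_pos3": 0.007,
    "Wnt_pos3": 0.0045,
    "16S": 0.0024,
    "mito_pos12": 0.0012,
    "nuclear_pos12": 0.0006,
    "28S": 0.0004,
}

GAMMA_SHAPE = 4.0  # among-site rate variation within a partition
MITO_FREQS = (0.30, 0.20, 0.20, 0.30)  # AT-rich
MITO_KAPPA = 4.0
NUC_KAPPA = 2.0
MISSING_RATE = 0.11
N_TIPS = 40
ROOT_AGE = 110.0


def _fixture_rate(fragment: str, pos: int | None) -> float:
    length, genome, coding = FRAGMENTS[fragment]
    if not coding:
        return RATE_CLASSES[fragment]
    if pos == 3:
        if genome == "mito":
            return RATE_CLASSES["mito_pos3"]
        return RATE_CLASSES[f"{fragment}_pos3"]
    return RATE_CLASSES[f"{genome}_pos12"]


def _fixture_model(fragment: str):
    length, genome, coding = FRAGMENTS[fragment]
    if fragment == "28S":
        return "JC", 1.0, (0.25, 0.25, 0.25, 0.25)
    if genome == "mito":
        return "HKY", MITO_KAPPA, MITO_FREQS
    return "HKY", NUC_KAPPA, (0.25, 0.25, 0.25, 0.25)


def aciliini_fixture(
    seed: int,
    missing_rate: float = MISSING_RATE,
    n_tips: int = N_TIPS,
    root_age: float = ROOT_AGE,
) -> SimBundle:
    """Simulated stand-in for an eight-fragment concatenated beetle
    matrix (synthetic; no real sequences involved).

    40 tips on a 110 Ma Yule chronogram; fragments laid out in the order
    and lengths of FRAGMENTS (total 6095 bp); protein-coding fragments
    carry codon substructure (positions 1/2/3 interleaved, frame starting
    at the fragment's first column); fragment-level missing data at the
    given rate. The returned scheme enumerates gene-by-codon-position
    partitions plus the two ribosomal fragments.
    """
    master = np.random.default_rng(int(seed))
    sub_seeds = master.integers(0, 2**31 - 1, size=4)
    tree = simulate_tree(n_tips, root_age, int(sub_seeds[0]))

    # per-partition specs, simulated as blocks then interleaved
    specs, targets = [], []
    charset_lines = []
    offset = 0  # 0-based global start of the fragment
    for frag, (length, genome, coding) in FRAGMENTS.items():
        model, kappa, freqs = _fixture_model(frag)
        if coding:
            for pos in (1, 2, 3):
                cols0 = np.arange(offset + pos - 1, offset + length, 3)
                name = f"{frag}_pos{pos}"
                specs.append(
                    SimPartitionSpec(
                        name=name,
                        length=cols0.size,
                        mean_rate=_fixture_rate(frag, pos),
                        gamma_shape=GAMMA_SHAPE,
                        model=model,
                        kappa=kappa,
                        freqs=freqs,
                    )
                )
                targets.append(cols0)
                charset_lines.append(
                    f"{name} = {offset + pos}-{offset + length}\\3"
                )
        else:
            cols0 = np.arange(offset, offset + length)
            specs.append(
                SimPartitionSpec(
                    name=frag,
                    length=length,
                    mean_rate=_fixture_rate(frag, None),
                    gamma_shape=GAMMA_SHAPE,
                    model=model,
                    kappa=kappa,
                    freqs=freqs,
                )
            )
            targets.append(cols0)
            charset_lines.append(f"{frag} = {offset + 1}-{offset + length}")
        offset += length
    width = offset

    rng = np.random.default_rng(int(sub_seeds[1]))
    chars = np.empty((tree.n_tips, width), dtype="U1")
    lam = np.empty(width)
    part_names = np.empty(width, dtype=object)
    for spec, cols0 in zip(specs, targets):
        codes, block_lam = _evolve_block(tree, spec, rng)
        chars[:, cols0] = _BASES[codes]
        lam[cols0] = block_lam
        part_names[cols0] = spec.name
    matrix = SeqMatrix(tree.tip_labels, chars)
    scheme = resolve_partitions("\n".join(charset_lines), width)

    # missingness acts on whole gene fragments, not codon sub-partitions
    frag_lines = []
    start = 1
    for frag, (length, _, _) in FRAGMENTS.items():
        frag_lines.append(f"{frag} = {start}-{start + length - 1}")
        start += length
    frag_scheme = resolve_partitions("\n".join(frag_lines), width)
    matrix = inject_missing(matrix, frag_scheme, missing_rate, int(sub_seeds[2]))

    rates = _true_rate_table(lam, list(part_names))
    config = {
        "seed": int(seed),
        "n_tips": n_tips,
        "root_age_ma": root_age,
        "total_bp": width,
        "missing_rate": missing_rate,
        "gamma_shape": GAMMA_SHAPE,
        "rate_classes": dict(RATE_CLASSES),
        "partition_mean_rate": {s.name: s.mean_rate for s in specs},
        "partition_model": {
            s.name: (s.model, s.kappa if s.model == "HKY" else 1.0)
            for s in specs
        },
    }
    return SimBundle(tree, matrix, rates, scheme, int(seed), config)


def write_bundle(bundle: SimBundle, outdir) -> dict:
    """Write alignment.fasta, tree.nwk, partitions.txt, true_rates.tsv
    and config.txt into *outdir*; returns the path map."""
    import os

    from .alignment import write_fasta

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "alignment": os.path.join(outdir, "alignment.fasta"),
        "tree": os.path.join(outdir, "tree.nwk"),
        "partitions": os.path.join(outdir, "partitions.txt"),
        "true_rates": os.path.join(outdir, "true_rates.tsv"),
        "config": os.path.join(outdir, "config.txt"),
    }
    write_fasta(bundle.matrix, paths["alignment"])
    bundle.tree.write(paths["tree"])
    bundle.scheme.write(paths["partitions"])
    bundle.rates.write_tsv(paths["true_rates"])
    config = dict(bundle.config)
    config.setdefault("seed", bundle.seed)
    with open(paths["config"], "w") as fh:
        for key, value in _flatten(config):
            fh.write(f"{key}: {value}\n")
    return paths


def _flatten(d, prefix=""):
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, key + ".")
        else:
            yield key, v
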