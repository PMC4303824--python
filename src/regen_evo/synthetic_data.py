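"""Simulation of three-clade codon families under ToL and non-ToL scenarios.

The species tree is ultrametric with the Tree-of-Life topology
((metazoa, fungi), plant): each clade is a random-shape crown of
``n_per_clade`` species hanging off its stem. In time units (leaf depth
1.0) the crowns are 0.5 deep, the metazoan and fungal stems 0.3, and
the plant lineage splits from the opisthokont stem at the root, so a
fungi-plant leaf path spans 2.0 units against 1.6 for metazoa-fungi —
the fungi-plant comparison is the deepest, as expected when the
plant split predates the Opisthokonta.

Sequences evolve by candidate point mutations drawn as a Poisson
process along each branch: synonymous changes are always accepted,
non-synonymous ones with probability omega (purifying selection), and
mutations creating stop codons are rejected. The *non-ToL scenario*
multiplies the metazoan stem and crown branch lengths by
``metazoan_multiplier`` (an accelerated clock) and optionally relaxes
omega on those branches by ``omega_multiplier``, emulating the loss of
functional constraint after pathway-partner loss. No indels are
simulated, so families come out pre-aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from regen_evo.seqio import (
    SENSE_CODONS,
    STOP_CODONS,
    CladeMap,
    ProteinAlignment,
    _CODON_TABLE,
    read_fasta,
    read_newick,
    translate,
    write_fasta,
    write_newick,
)

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "DEEP_OVERRIDES",
    "build_species_tree",
    "evolve_sequence",
    "simulate_family",
    "make_benchmark",
    "write_family",
    "load_family",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated gene family.

    Branch lengths are in arbitrary time units with leaf depth 1.0;
    ``base_mutation_rate`` converts them to candidate mutations per
    nucleotide site per unit time. ``metazoan_multiplier`` = 1 is the
    ToL scenario; > 1 accelerates the metazoan stem and crown.
    """

    n_per_clade: int = 10
    n_codons: int = 300
    base_mutation_rate: float = 0.3
    omega: float = 0.2
    metazoan_multiplier: float = 1.0
    omega_multiplier: float = 1.0
    seed: int = 0
    clade_order: tuple[str, str, str] = ("plant", "fungi", "metazoa")
    crown_depth: float = 0.5
    metazoan_stem: float = 0.3
    fungi_stem: float = 0.3
    plant_stem: float = 0.5
    opisthokont_stem: float = 0.2

    def __post_init__(self) -> None:
        if self.base_mutation_rate <= 0:
            raise ValueError("base_mutation_rate must be > 0")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0, 1]")
        if self.metazoan_multiplier < 1.0:
            raise ValueError("metazoan_multiplier must be >= 1")
        if self.n_per_clade < 1 or self.n_codons < 1:
            raise ValueError("n_per_clade and n_codons must be >= 1")

    @property
    def scenario(self) -> str:
        accelerated = self.metazoan_multiplier > 1.0 or self.omega_multiplier > 1.0
        return "non_tol" if accelerated else "tol"


#: Overrides for the canned "deep" configuration: strong purifying
#: selection at high mutational depth, the regime of ~1 Gya-old enzyme
#: orthologs — amino acids stay alignable while synonymous positions
#: randomize, so Ks (but not Ka) saturates past the Jukes-Cantor domain.
DEEP_OVERRIDES: dict[str, float] = {"base_mutation_rate": 2.0, "omega": 0.05}


@dataclass
class SimulatedFamily:
    """One simulated codon family with full ground truth attached."""

    gene: str
    cds: dict[str, str]
    protein_aln: ProteinAlignment
    clade_map: CladeMap
    true_tree: dendropy.Tree
    scenario: str
    config: SimulationConfig


def _random_crown(
    labels: list[str], depth: float, rng: np.random.Generator
) -> dendropy.Node:
    """Random-topology ultrametric crown: every leaf is ``depth`` below
    the returned crown ancestor."""
    tns_nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=dendropy.Taxon(label=lab))
        tns_nodes.append((node, 0.0))
    n_joins = len(labels) - 1
    for k in range(1, n_joins + 1):
        height = depth * k / n_joins
        i, j = sorted(rng.choice(len(tns_nodes), size=2, replace=False))
        (na, ha), (nb, hb) = tns_nodes[i], tns_nodes[j]
        parent = dendropy.Node()
        parent.add_child(na)
        na.edge.length = height - ha
        parent.add_child(nb)
        nb.edge.length = height - hb
        tns_nodes[i] = (parent, height)
        del tns_nodes[j]
    if len(tns_nodes) == 1 and n_joins == 0:
        # single-species clade: bare leaf, stem supplies all depth
        return tns_nodes[0][0]
    return tns_nodes[0][0]


def build_species_tree(
    config: SimulationConfig, rng: np.random.Generator
) -> dendropy.Tree:
    """Rooted ((metazoa, fungi), plant) species tree with random crowns.

    The metazoan stem and crown branch lengths carry the
    ``metazoan_multiplier``, so the tree is in expected-divergence (not
    time) units and is the ground truth for topology classification and
    the mf/fp ratio.
    """
    plant, fungi, metazoa = config.clade_order
    labels = {
        c: [f"{c}_{i+1}" for i in range(config.n_per_clade)]
        for c in config.clade_order
    }
    crowns = {c: _random_crown(labels[c], config.crown_depth, rng) for c in config.clade_order}

    mult = config.metazoan_multiplier
    for node in crowns[metazoa].preorder_iter():
        if node.edge.length is not None:
            node.edge.length *= mult

    opisthokonta = dendropy.Node()
    opisthokonta.add_child(crowns[metazoa])
    crowns[metazoa].edge.length = (
        config.metazoan_stem * mult
        if config.n_per_clade > 1
        else (config.metazoan_stem + config.crown_depth) * mult
    )
    opisthokonta.add_child(crowns[fungi])
    crowns[fungi].edge.length = (
        config.fungi_stem
        if config.n_per_clade > 1
        else config.fungi_stem + config.crown_depth
    )
    root = dendropy.Node()
    root.add_child(opisthokonta)
    opisthokonta.edge.length = config.opisthokont_stem
    root.add_child(crowns[plant])
    crowns[plant].edge.length = (
        config.plant_stem
        if config.n_per_clade > 1
        else config.plant_stem + config.crown_depth
    )

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        tns.add_taxon(leaf.taxon)
    return tree


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    picks = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in picks)


def evolve_sequence(
    parent_cds: str,
    branch_length: float,
    rate: float,
    omega: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a stop-free CDS along one branch.

    Poisson(rate * branch_length * length) candidate point mutations are
    applied sequentially at uniform random positions; synonymous
    candidates are always accepted, non-synonymous ones with probability
    omega, and candidates creating a stop codon are rejected.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    seq = list(parent_cds)
    n_mut = int(rng.poisson(rate * branch_length * len(seq)))
    for _ in range(n_mut):
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        new = _BASES[(_BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
        cstart = 3 * (pos // 3)
        codon = seq[cstart : cstart + 3]
        old_aa = _CODON_TABLE["".join(codon)]
        codon[pos - cstart] = new
        mutant = "".join(codon)
        if mutant in STOP_CODONS:
            continue
        if _CODON_TABLE[mutant] != old_aa and rng.random() >= omega:
            continue
        seq[pos] = new
    return "".join(seq)


def simulate_family(config: SimulationConfig, gene: str | None = None) -> SimulatedFamily:
    """Simulate one family down the species tree. Same config, same output."""
    rng = np.random.default_rng(config.seed)
    tree = build_species_tree(config, rng)
    root_cds = _random_cds(config.n_codons, rng)

    metazoa = config.clade_order[2]
    omega_meta = min(1.0, config.omega * config.omega_multiplier)

    # mark the metazoan stem + crown so relaxed omega can be applied there
    meta_nodes: set[int] = set()
    for node in tree.preorder_node_iter():
        leaves_below = {l.taxon.label for l in node.leaf_iter()}
        if leaves_below and all(l.startswith(f"{metazoa}_") for l in leaves_below):
            meta_nodes.add(id(node))

    cds: dict[str, str] = {}

    def descend(node: dendropy.Node, seq: str) -> None:
        for child in node.child_nodes():
            omega_here = omega_meta if id(child) in meta_nodes else config.omega
            child_seq = evolve_sequence(
                seq, child.edge.length or 0.0, config.base_mutation_rate, omega_here, rng
            )
            if child.is_leaf():
                cds[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    descend(tree.seed_node, root_cds)

    ordered = [
        f"{c}_{i+1}" for c in config.clade_order for i in range(config.n_per_clade)
    ]
    cds = {sid: cds[sid] for sid in ordered}
    protein_aln = ProteinAlignment({sid: translate(s) for sid, s in cds.items()})
    clade_map = CladeMap(
        entries={sid: sid.rsplit("_", 1)[0] for sid in ordered},
        clade_order=config.clade_order,
    )
    return SimulatedFamily(
        gene=gene or f"{config.scenario}_seed{config.seed}",
        cds=cds,
        protein_aln=protein_aln,
        clade_map=clade_map,
        true_tree=tree,
        scenario=config.scenario,
        config=config,
    )


def make_benchmark(
    n_families_per_scenario: int,
    config_overrides: Mapping[str, object] | None = None,
    seed: int = 0,
    non_tol_multiplier: float = 3.0,
) -> list[SimulatedFamily]:
    """Balanced labeled benchmark: half ToL, half metazoan-accelerated.

    Family seeds are derived from the master seed, so the benchmark is
    fully reproducible and families are mutually independent.
    """
    if n_families_per_scenario < 1:
        raise ValueError("need at least one family per scenario")
    overrides = dict(config_overrides or {})
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=2 * n_families_per_scenario)
    families = []
    for i in range(n_families_per_scenario):
        tol_cfg = SimulationConfig(
            **{**overrides, "metazoan_multiplier": 1.0, "seed": int(child_seeds[2 * i])}
        )
        non_cfg = SimulationConfig(
            **{
                **overrides,
                "metazoan_multiplier": non_tol_multiplier,
                "seed": int(child_seeds[2 * i + 1]),
            }
        )
        families.append(simulate_family(tol_cfg, gene=f"tol_{i:03d}"))
        families.append(simulate_family(non_cfg, gene=f"non_tol_{i:03d}"))
    return families


def write_family(family: SimulatedFamily, outdir: str | Path) -> None:
    """Write the standard per-family files consumed by the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(family.cds, outdir / "cds.fasta")
    write_fasta(family.protein_aln.rows, outdir / "protein_aln.fasta")
    with open(outdir / "clades.tsv", "w") as fh:
        for sid, clade in family.clade_map.entries.items():
            fh.write(f"{sid}\t{clade}\n")
    write_newick(family.true_tree, outdir / "true_tree.nwk")
    meta = {"gene": family.gene, "scenario": family.scenario}
    (outdir / "meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def load_family(indir: str | Path) -> SimulatedFamily:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    cds = read_fasta(indir / "cds.fasta")
    protein_aln = ProteinAlignment(read_fasta(indir / "protein_aln.fasta"))
    entries = {}
    for line in (indir / "clades.tsv").read_text().splitlines():
        sid, clade = line.split("\t")
        entries[sid] = clade
    clade_map = CladeMap(entries=entries)
    tree = read_newick(indir / "true_tree.nwk")
    return SimulatedFamily(
        gene=meta["gene"],
        cds=cds,
        protein_aln=protein_aln,
        clade_map=clade_map,
        true_tree=tree,
        scenario=meta["scenario"],
        config=SimulationConfig(),
    )
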