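"""End-to-end orchestration and the per-gene ToL / non-ToL verdict.

Three independent signals are computed per gene family — the tree
topology class, the conservation-profile contrast, and the clade-average
Ka contrast — and combined conjunctively:

* non-ToL : autotrophic paraphyly AND conservation non-ToL AND
            metazoan-elevated Ka;
* ToL     : ToL-like topology AND ToL-like conservation AND Ka not
            metazoan-elevated;
* mixed   : any other combination (disagreeing signals).

The conjunctive rule is deliberately conservative: a family is only
called non-ToL when all three lines of evidence agree.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

from regen_evo import conservation as _cons
from regen_evo import kaks as _kaks
from regen_evo import phylo as _phylo
from regen_evo.seqio import (
    CladeMap,
    ProteinAlignment,
    back_translate,
    write_fasta,
    write_newick,
)
from regen_evo.synthetic_data import SimulatedFamily, load_family

__all__ = ["PipelineConfig", "GeneVerdict", "combine_signals", "run_gene", "run_benchmark"]

log = logging.getLogger("regen_evo")


@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.05  # low-pass filter constant
    delta: float = 0.0  # conservation-contrast decision margin
    gap_policy: str = "any-gap"
    tree_bootstrap: int = 100  # 0 disables support values
    kaks_bootstrap: int = 200  # 0 disables the Ka-contrast CI
    distance_max: float = 10.0
    seed: int = 0


@dataclass
class GeneVerdict:
    gene: str
    topology: _phylo.TopologyCall
    conservation: _cons.ConservationCall
    kaks: _kaks.KaKsCall
    kaks_bootstrap: dict | None
    final_class: str  # "ToL" | "non-ToL" | "mixed"

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "final_class": self.final_class,
            "topology": {
                "category": self.topology.category,
                "mf_fp_ratio": self.topology.mf_fp_ratio,
                "monophyly": dict(self.topology.monophyly),
            },
            "conservation": dataclasses.asdict(self.conservation),
            "kaks": {
                "metazoan_elevated": self.kaks.metazoan_elevated,
                "ka_gt_one": self.kaks.ka_gt_one,
                "mean_ka": dict(self.kaks.mean_ka),
            },
            "kaks_bootstrap": self.kaks_bootstrap,
        }


def combine_signals(
    topology_category: str, conservation_verdict: str, metazoan_elevated: bool
) -> str:
    """Pure mapping from the three stage verdicts to the final class."""
    if (
        topology_category == "autotrophic_paraphyly"
        and conservation_verdict == "non-ToL"
        and metazoan_elevated
    ):
        return "non-ToL"
    if (
        topology_category == "tol_like"
        and conservation_verdict == "ToL-like"
        and not metazoan_elevated
    ):
        return "ToL"
    return "mixed"


def run_gene(
    gene: str,
    protein_aln: ProteinAlignment,
    cds: Mapping[str, str],
    clade_map: CladeMap,
    config: PipelineConfig | None = None,
    tree: dendropy.Tree | None = None,
    outdir: str | Path | None = None,
) -> GeneVerdict:
    """Run all stages on one gene family and emit the verdict.

    If ``tree`` is given (e.g. an externally computed ML tree) it is
    classified as-is after midpoint rooting; otherwise a neighbor-joining
    tree is built from Kimura-corrected protein distances. All artifacts
    are written under ``outdir`` when provided.
    """
    config = config or PipelineConfig()
    clade_map.require_three_clades(protein_aln.ids)

    profiles = _cons.bidirectional_profile(
        protein_aln, clade_map, alpha=config.alpha, gap_policy=config.gap_policy
    )
    cons_call = _cons.profile_contrast(profiles, delta=config.delta)

    codon_aln = back_translate(protein_aln, cds)
    table = _kaks.clade_average(codon_aln, clade_map)
    kaks_call = _kaks.kaks_contrast(table)
    boot = None
    if config.kaks_bootstrap > 0:
        boot = _kaks.bootstrap_ka_contrast(
            codon_aln, clade_map, n_reps=config.kaks_bootstrap, seed=config.seed
        )

    if tree is None:
        if config.tree_bootstrap > 0:
            tree = _phylo.bootstrap_support(
                protein_aln, n_reps=config.tree_bootstrap, seed=config.seed
            )
        else:
            ids, D, _ = _phylo.protein_distance_matrix(
                protein_aln, max_distance=config.distance_max
            )
            tree = _phylo.neighbor_joining(D, ids)
    rooted = _phylo.midpoint_root(tree)
    topo_call = _phylo.classify_topology(rooted, clade_map)

    verdict = GeneVerdict(
        gene=gene,
        topology=topo_call,
        conservation=cons_call,
        kaks=kaks_call,
        kaks_bootstrap=boot,
        final_class=combine_signals(
            topo_call.category, cons_call.verdict, kaks_call.metazoan_elevated
        ),
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _cons.profiles_to_frame(profiles).to_csv(
            outdir / "profile.tsv", sep="\t", index=False
        )
        write_fasta(codon_aln.rows, outdir / "codon_aln.fasta")
        write_newick(rooted, outdir / "tree.nwk")
        table.to_frame(gene).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
        (outdir / "verdict.json").write_text(
            json.dumps(verdict.to_dict(), sort_keys=True, indent=1) + "\n"
        )
    return verdict


#: Benchmark runs skip bootstrap resampling: neither support values nor
#: the Ka CI enter the final classification.
BENCHMARK_CONFIG = PipelineConfig(tree_bootstrap=0, kaks_bootstrap=0)

_EXPECTED = {"tol": "ToL", "non_tol": "non-ToL"}
_STAGE_EXPECTED = {
    "topology": {"tol": "tol_like", "non_tol": "autotrophic_paraphyly"},
    "conservation": {"tol": "ToL-like", "non_tol": "non-ToL"},
    "kaks": {"tol": False, "non_tol": True},
}


def run_benchmark(
    families: Iterable[SimulatedFamily] | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Score the pipeline against the ground truth of a labeled benchmark.

    ``families`` is either an iterable of :class:`SimulatedFamily` or a
    directory of per-family subdirectories written by ``write_family``.
    Returns a report with overall accuracy, the confusion matrix, and
    per-stage agreement with the scenario labels.
    """
    config = config or BENCHMARK_CONFIG
    if isinstance(families, (str, Path)):
        root = Path(families)
        loaded = []
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            try:
                loaded.append(load_family(sub))
            except Exception as exc:
                log.warning("skipping %s: %s", sub, exc)
        families = loaded

    rows = []
    confusion: dict[str, dict[str, int]] = {}
    stage_hits = {s: 0 for s in _STAGE_EXPECTED}
    n = 0
    for fam in families:
        verdict = run_gene(
            fam.gene,
            fam.protein_aln,
            fam.cds,
            fam.clade_map,
            config=config,
            outdir=None if outdir is None else Path(outdir) / fam.gene,
        )
        n += 1
        confusion.setdefault(fam.scenario, {}).setdefault(verdict.final_class, 0)
        confusion[fam.scenario][verdict.final_class] += 1
        observed = {
            "topology": verdict.topology.category,
            "conservation": verdict.conservation.verdict,
            "kaks": verdict.kaks.metazoan_elevated,
        }
        for stage, expect in _STAGE_EXPECTED.items():
            if observed[stage] == expect[fam.scenario]:
                stage_hits[stage] += 1
        rows.append(
            {
                "gene": fam.gene,
                "scenario": fam.scenario,
                "final_class": verdict.final_class,
                "correct": verdict.final_class == _EXPECTED[fam.scenario],
                **{f"{s}_call": observed[s] for s in _STAGE_EXPECTED},
                "mf_fp_ratio": verdict.topology.mf_fp_ratio,
            }
        )
    accuracy = float(np.mean([r["correct"] for r in rows])) if rows else float("nan")
    report = {
        "n_families": n,
        "accuracy": accuracy,
        "confusion": confusion,
        "stage_agreement": {s: stage_hits[s] / n if n else float("nan") for s in stage_hits},
        "families": rows,
    }
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        (Path(outdir) / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1) + "\n"
        )
    return report
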