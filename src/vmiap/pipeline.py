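"""Config-driven orchestration of the full inference chain.

simulate -> classify -> GBE -> map -> targets -> phylo -> profiles

Every stochastic stage draws from a child generator derived from the
single top-level seed, so a fixed configuration reproduces byte-identical
reports.  The report compares the mapped interval against the simulator's
ground-truth modifier locus when the manifest is present.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from .config import Thresholds
from .gbe import gbe_analysis
from .mapping import (
    GenotypeMatrix,
    assemble_interval,
    candidate_snps,
    interval_length_mb,
    pedigree_consistency,
    segregation_test,
)
from .methylation import MethylationTable, classify_variability, individual_means, threshold_classify
from .phylo import length_filter, neighbor_joining, p_distance_matrix, subtree_enrichment, tree_to_newick
from .profiles import CoverageTrack, anchored_matrix, group_compare
from .sim import (
    BedElement,
    EnrichmentSpec,
    MethylationModel,
    MotifSpec,
    Pedigree,
    assign_methylation,
    breed_backcross,
    breed_reciprocal_f1,
    default_genome,
    evolve_ltr_family,
    synth_coverage,
)
from .sim.io import (
    genotype_frame,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_genotype_csv,
    write_manifest,
    write_methylation_csv,
    write_pedigree_csv,
)
from .targets import (
    align_multiple,
    concordance,
    divergent_window_scan,
    percent_identity,
    reverse_complement,
    ttest_bky,
)

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "classify", "gbe", "map", "targets", "phylo", "profiles")

log = logging.getLogger("vmiap")


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    design: str = "backcross"
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: Sequence[str] = ALL_STAGES
    n_n3: int = 47
    n_per_f1_group: int = 40
    n_targets: int = 7
    n_nontargets: int = 2
    n_background: int = 24
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds.from_dict(raw["thresholds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {
            "seed": self.seed,
            "outdir": str(self.outdir),
            "design": self.design,
            "thresholds": self.thresholds.to_dict(),
            "stages": list(self.stages),
            "n_n3": self.n_n3,
            "n_per_f1_group": self.n_per_f1_group,
            "n_targets": self.n_targets,
            "n_nontargets": self.n_nontargets,
            "n_background": self.n_background,
            "n_permutations": self.n_permutations,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


_GBE_LOCI = {
    "locus_maternal": "maternal",
    "locus_zygotic": "zygotic",
    "locus_both": "maternal+zygotic",
    "locus_none": "none",
}


def _rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate(cfg: RunConfig, report: dict) -> dict:
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    rng_ped, rng_meth, rng_f1meth, rng_ltr, rng_cov, rng_n2 = _rngs(cfg.seed, 6)
    genome = default_genome()
    state: dict = {"genome": genome}

    # reciprocal F1 design for the GBE stage: four loci, one per effect mode
    f1_ped, groups = breed_reciprocal_f1(
        genome, rng_ped, n_b6=cfg.n_per_f1_group, n_bc=cfg.n_per_f1_group, n_cb=cfg.n_per_f1_group
    )
    meth_records = []
    for locus, mode in _GBE_LOCI.items():
        model = MethylationModel(effect_mode=mode)
        for gname, ids in groups.items():
            for ind_id in ids:
                vals = assign_methylation(f1_ped[ind_id], model, rng_f1meth)
                for j, v in enumerate(vals):
                    meth_records.append(
                        {"locus": locus, "individual": ind_id, "cpg_index": j, "percent": float(v)}
                    )
    state["f1_groups"] = groups
    state["f1_methylation"] = meth_records

    # backcross design for mapping; index-locus methylation is zygotic.
    # The index locus is chosen for mapping precisely because its baseline
    # and high-state distributions do not overlap the 60% cutoff, so its
    # baseline is tighter (same 45% mean) than the generic default.
    bc_ped = breed_backcross(genome, rng_ped, n_n3=cfg.n_n3)
    index_model = MethylationModel(baseline=(54.0, 66.0), high_state=(96.0, 24.0), effect_mode="zygotic")
    n3 = bc_ped.by_generation("N3")
    bc_records = []
    for ind in bc_ped:
        if ind.generation in ("N1", "N2", "N3"):
            vals = assign_methylation(ind, index_model, rng_meth)
            for j, v in enumerate(vals):
                bc_records.append(
                    {"locus": "IAP-index", "individual": ind.id, "cpg_index": j, "percent": float(v)}
                )
    state["backcross"] = bc_ped
    state["n3_ids"] = [i.id for i in n3]
    state["bc_methylation"] = bc_records

    # LTR family + candidate-locus methylation in N2 carriers/noncarriers
    family = evolve_ltr_family(
        cfg.n_targets, cfg.n_nontargets, cfg.n_background, MotifSpec(), rng_ltr
    )
    state["family"] = family
    n2 = bc_ped.by_generation("N2")
    cand_records = []
    intact = [r.id for r in family if r.label == "VM"]
    disrupted = [r.id for r in family if r.label == "nontarget"]
    for locus in intact:
        model = MethylationModel(baseline=(54.0, 66.0), high_state=(96.0, 24.0), effect_mode="zygotic")
        for ind in n2:
            vals = assign_methylation(ind, model, rng_n2)
            for j, v in enumerate(vals):
                cand_records.append(
                    {"locus": locus, "individual": ind.id, "cpg_index": j, "percent": float(v)}
                )
    for locus in disrupted:
        model = MethylationModel(effect_mode="none")
        for ind in n2:
            vals = assign_methylation(ind, model, rng_n2)
            for j, v in enumerate(vals):
                cand_records.append(
                    {"locus": locus, "individual": ind.id, "cpg_index": j, "percent": float(v)}
                )
    state["n2_ids"] = [i.id for i in n2]
    state["candidate_methylation"] = cand_records

    # elements along a synthetic contig + coverage with 3' enrichment on the VM clade
    gap = 2000
    elements = []
    pos = 1000
    strands = {"+": "+", "-": "-"}
    for rec in family:
        elements.append(
            BedElement("chrLTR", pos, pos + len(rec.seq), rec.id, 0.0, strands[rec.orientation])
        )
        pos += len(rec.seq) + gap
    chrom_sizes = {"chrLTR": pos + 1000}
    enriched = [r.id for r in family if r.label in ("VM", "nontarget")]
    track = synth_coverage(elements, chrom_sizes, EnrichmentSpec(), rng_cov, enriched=enriched)
    state["elements"] = elements
    state["track_dense"] = track

    # persist all artefacts
    write_pedigree_csv(bc_ped, out / "pedigree.csv")
    write_genotype_csv(n3, genome, out / "genotypes_n3.csv")
    write_methylation_csv(bc_records, out / "methylation_backcross.csv")
    write_methylation_csv(meth_records, out / "methylation_f1.csv")
    write_methylation_csv(cand_records, out / "methylation_candidates.csv")
    write_fasta(family, out / "ltr_family.fasta")
    write_bed(elements, out / "elements.bed")
    write_bedgraph(track, out / "coverage.bedgraph")
    manifest = {
        "seed": cfg.seed,
        "modifier_locus": {"chrom": genome.modifier_locus[0], "pos": genome.modifier_locus[1]},
        "modifier_strain": genome.modifier_strain,
        "effect_modes": _GBE_LOCI,
        "index_locus": "IAP-index",
        "intact_motif_loci": intact,
        "disrupted_motif_loci": disrupted,
    }
    write_manifest(manifest, out / "manifest.json")
    state["manifest"] = manifest
    report["simulate"] = {
        "n_individuals_backcross": len(bc_ped),
        "n_n3": len(n3),
        "n_family_sequences": len(family),
        "outdir": str(out),
    }
    return state


def _classify(cfg: RunConfig, state: dict, report: dict) -> None:
    table = MethylationTable.from_records(state["bc_methylation"])
    th = cfg.thresholds
    means = individual_means(table, "IAP-index")
    classes = {ind: threshold_classify(float(m), th) for ind, m in means.items()}
    state["index_classes"] = classes
    report["classify"] = {
        "locus": "IAP-index",
        "variability": classify_variability(means.to_numpy(), th),
        "n_high": sum(1 for c in classes.values() if c == "high"),
        "n_low": sum(1 for c in classes.values() if c == "low"),
    }


def _gbe(cfg: RunConfig, state: dict, report: dict) -> None:
    table = MethylationTable.from_records(state["f1_methylation"])
    assignment = {
        ind: gname for gname, ids in state["f1_groups"].items() for ind in ids
    }
    results = gbe_analysis(table, assignment, alpha=cfg.thresholds.alpha)
    truth = state["manifest"]["effect_modes"]
    report["gbe"] = {
        r.locus: {
            "H": r.h_statistic,
            "p": r.kw_p,
            "category": r.category,
            "direction": r.direction,
            "true_mode": truth.get(r.locus),
            "recovered": r.category == truth.get(r.locus),
        }
        for r in results
    }


def _map(cfg: RunConfig, state: dict, report: dict) -> None:
    genome = state["genome"]
    n3_ids = state["n3_ids"]
    matrix = GenotypeMatrix.from_frame(genotype_frame(
        [state["backcross"][i] for i in n3_ids], genome
    ))
    labels = {i: state["index_classes"][i] for i in n3_ids}
    cands, marker_report = candidate_snps(matrix, labels)
    intervals = assemble_interval(cands, marker_report)
    truth = state["manifest"]["modifier_locus"]
    per_chrom = {}
    contained = False
    for chrom, iv in intervals.items():
        per_chrom[chrom] = {
            "inner": iv["inner"].to_printed(),
            "outer": iv["outer"].to_printed(),
            "inner_mb": interval_length_mb(iv["inner"]),
            "outer_mb": interval_length_mb(iv["outer"]),
        }
        if iv["outer"].contains(truth["chrom"], truth["pos"]):
            contained = True
    n_high = sum(1 for c in labels.values() if c == "high")
    n_low = len(labels) - n_high
    seg = segregation_test(n_high, n_low, cfg.thresholds.alpha)
    ped_check = pedigree_consistency(state["backcross"], state["index_classes"], cfg.thresholds.alpha)
    report["map"] = {
        "n_candidate_snps": int(len(cands)),
        "intervals": per_chrom,
        "multi_locus": len(intervals) > 1,
        "true_locus_in_outer_interval": contained,
        "segregation": {"n_high": seg.n_high, "n_low": seg.n_low,
                        "p": seg.p_value, "consistent": seg.consistent},
        "pedigree_consistent": ped_check.consistent,
    }


def _targets(cfg: RunConfig, state: dict, report: dict) -> None:
    family = state["family"]
    th = cfg.thresholds
    oriented = {
        r.id: (reverse_complement(r.seq) if r.orientation == "-" else r.seq) for r in family
    }
    labels = {r.id: r.label for r in family}
    index_id = next(r.id for r in family if r.label == "VM")
    vm_clade = {r.id for r in family if r.label in ("VM", "nontarget")}
    identity = {
        i: percent_identity(oriented[index_id], s)
        for i, s in oriented.items()
        if i != index_id
    }
    candidates = sorted(i for i, v in identity.items() if v >= th.identity_min)
    aln = align_multiple(
        {i: oriented[i] for i in sorted(vm_clade)},
        labels={i: labels[i] for i in vm_clade},
    )
    windows = divergent_window_scan(aln)
    # concordance of candidate-locus phenotypes with the index phenotype
    cand_table = MethylationTable.from_records(state["candidate_methylation"])
    bc_table = MethylationTable.from_records(state["bc_methylation"])
    index_means = individual_means(bc_table, "IAP-index")
    n2 = set(state["n2_ids"])
    index_classes = {
        i: threshold_classify(float(m), th) for i, m in index_means.items() if i in n2
    }
    cand_classes = {}
    cand_groups = {}
    for locus in cand_table.loci:
        m = individual_means(cand_table, locus)
        cand_classes[locus] = {i: threshold_classify(float(v), th) for i, v in m.items()}
        highs = [float(v) for i, v in m.items() if index_classes.get(i) == "high"]
        lows = [float(v) for i, v in m.items() if index_classes.get(i) == "low"]
        cand_groups[locus] = (highs, lows)
    conc = concordance(index_classes, cand_classes, th.concordance_min)
    tt = ttest_bky(cand_groups, q=th.fdr_q)
    report["targets"] = {
        "index": index_id,
        "identity_to_index": identity,
        "identity_candidates": candidates,
        "top_window": (
            {"start": windows[0].start, "end": windows[0].end,
             "length_bp": windows[0].length_bp, "score": windows[0].score}
            if windows else None
        ),
        "concordance": {c.locus: {"fraction": c.fraction, "verdict": c.verdict} for c in conc},
        "ttest_bky": {t.locus: {"t": t.t, "p": t.p, "discovery": t.discovery} for t in tt},
    }


def _phylo(cfg: RunConfig, state: dict, report: dict) -> None:
    family = state["family"]
    rng = _rngs(cfg.seed + 1, 1)[0]
    oriented = {
        r.id: (reverse_complement(r.seq) if r.orientation == "-" else r.seq) for r in family
    }
    th = cfg.thresholds
    kept = length_filter(oriented, th.nj_len_min, th.nj_len_max)
    aln = align_multiple(kept)
    dm = p_distance_matrix({i: aln.row(i) for i in aln.ids})
    tree = neighbor_joining(dm)
    vm = {r.id for r in family if r.label in ("VM", "nontarget") and r.id in kept}
    enr = subtree_enrichment(tree, vm, n_permutations=cfg.n_permutations, rng=rng)
    newick = tree_to_newick(tree)
    (cfg.outdir / "tree.nwk").write_text(newick)
    report["phylo"] = {
        "n_sequences": len(kept),
        "vm_clade_size": enr.clade_size,
        "n_vm_in_clade": enr.n_vm_in_clade,
        "n_vm_total": len(vm),
        "hypergeom_p": enr.hypergeom_p,
        "permutation_p": enr.permutation_p,
        "newick_file": str(cfg.outdir / "tree.nwk"),
    }


def _profiles(cfg: RunConfig, state: dict, report: dict) -> None:
    track = CoverageTrack.from_dense(state["track_dense"])
    elements = state["elements"]
    matrix = anchored_matrix(track, elements, cfg.thresholds)
    family = state["family"]
    groups = {
        "vm_clade": [r.id for r in family if r.label in ("VM", "nontarget")],
        "background": [r.id for r in family if r.label == "background"],
    }
    res = group_compare(matrix, groups, difference=("vm_clade", "background"))
    diff = res["difference"]
    body = diff[cfg.thresholds.flank : cfg.thresholds.flank + cfg.thresholds.pseudolength]
    q = cfg.thresholds.pseudolength // 4
    report["profiles"] = {
        "n_elements": len(elements),
        "mean_vm_clade": float(res["vm_clade"].mean.mean()),
        "mean_background": float(res["background"].mean.mean()),
        "difference_3prime_quarter_mean": float(body[-q:].mean()),
        "difference_5prime_quarter_mean": float(body[:q].mean()),
        "three_prime_biased": bool(body[-q:].mean() > body[:q].mean()),
    }


_STAGE_FUNCS = {
    "classify": _classify,
    "gbe": _gbe,
    "map": _map,
    "targets": _targets,
    "phylo": _phylo,
    "profiles": _profiles,
}

_STAGE_DEPS = {
    "classify": ("simulate",),
    "gbe": ("simulate",),
    "map": ("simulate", "classify"),
    "targets": ("simulate", "classify"),
    "phylo": ("simulate",),
    "profiles": ("simulate",),
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write
    ``report.json`` to the configured output directory."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="[vmiap %(levelname)s] %(message)s")
    from . import __version__

    report: dict = {"seed": config.seed, "version": __version__,
                    "stages": list(config.stages)}
    stages = list(config.stages)
    if not stages:
        config.outdir.mkdir(parents=True, exist_ok=True)
        _write_report(report, config.outdir)
        return report
    state: dict = {}
    for st in stages:
        for dep in _STAGE_DEPS.get(st, ()):
            if dep not in stages:
                raise ValueError(f"stage {st!r} requires {dep!r} to be enabled")
    if "simulate" in stages:
        log.info("stage simulate")
        state = _simulate(config, report)
    for st in ALL_STAGES[1:]:
        if st in stages:
            log.info("stage %s", st)
            _STAGE_FUNCS[st](config, state, report)
    _write_report(report, config.outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
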