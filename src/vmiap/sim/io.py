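"""Plain-text writers/readers for every simulator artefact.

Formats:
  pedigree CSV      id,sex,generation,dam,sire,dam_strain,modifier_alleles
  genotype CSV      chrom,pos,marker,<ind1>,<ind2>,... with calls BB/BC/CC/NA
  methylation CSV   locus,individual,cpg_index,percent
  FASTA             description carries "label=... orientation=..."
  BED6              elements
  bedGraph          run-length merged coverage
  manifest JSON     ground truth (modifier locus, effect modes, seed)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import BedElement
from .genome import GenomeSpec
from .ltr import LtrRecord
from .pedigree import Individual, Pedigree, genotype_individual

__all__ = [
    "write_pedigree_csv",
    "write_genotype_csv",
    "read_genotype_csv",
    "write_methylation_csv",
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_manifest",
    "read_manifest",
]

_CALL_NAMES = {0: "BB", 1: "BC", 2: "CC", -1: "NA"}
_CALL_CODES = {v: k for k, v in _CALL_NAMES.items()}


def write_pedigree_csv(ped: Pedigree, path) -> None:
    rows = [
        {
            "id": i.id,
            "sex": i.sex,
            "generation": i.generation,
            "dam": i.dam_id or "",
            "sire": i.sire_id or "",
            "dam_strain": i.dam_strain or "",
            "modifier_alleles": i.modifier_alleles,
        }
        for i in ped
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def genotype_frame(ped_or_inds, genome: GenomeSpec) -> pd.DataFrame:
    """Genotype calls (BB/BC/CC) for a set of individuals over the marker map."""
    inds: List[Individual] = list(ped_or_inds)
    marker_rows = genome.marker_table()
    data = {"chrom": [r[0] for r in marker_rows], "pos": [r[1] for r in marker_rows],
            "marker": [r[2] for r in marker_rows]}
    df = pd.DataFrame(data)
    for ind in inds:
        calls = genotype_individual(ind, genome)
        flat = np.concatenate([calls[c.name] for c in genome.chromosomes])
        df[ind.id] = [_CALL_NAMES[int(v)] for v in flat]
    return df


def write_genotype_csv(ped_or_inds, genome: GenomeSpec, path) -> None:
    genotype_frame(ped_or_inds, genome).to_csv(path, index=False)


def read_genotype_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"chrom": str, "marker": str}, keep_default_na=False)
    return df


def write_methylation_csv(records: Iterable[dict], path) -> None:
    """``records``: dicts with locus, individual, cpg_index, percent."""
    pd.DataFrame(list(records)).to_csv(path, index=False)


def write_fasta(records: Sequence[LtrRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=f"label={r.label} orientation={r.orientation}")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> List[LtrRecord]:
    out: List[LtrRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label, orientation = "", "+"
        for token in rec.description.split():
            if token.startswith("label="):
                label = token.split("=", 1)[1]
            elif token.startswith("orientation="):
                orientation = token.split("=", 1)[1]
        out.append(LtrRecord(rec.id, str(rec.seq), label, orientation))
    return out


def write_bed(elements: Sequence[BedElement], path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.name}\t{e.score:g}\t{e.strand}\n")


def read_bed(path) -> List[BedElement]:
    out: List[BedElement] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append(BedElement(f[0], int(f[1]), int(f[2]), f[3],
                                  float(f[4]) if len(f) > 4 else 0.0,
                                  f[5] if len(f) > 5 else "+"))
    return out


def write_bedgraph(track: Dict[str, np.ndarray], path) -> None:
    """Run-length merge per-bp values into bedGraph lines."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            v = np.asarray(track[chrom], dtype=float)
            if v.size == 0:
                continue
            change = np.nonzero(np.diff(v))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        comment="#",
    )


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
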