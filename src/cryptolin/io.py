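"""Readers and writers for the file formats the pipeline exchanges.

GenePop for codominant genotypes (3-digit allele codes), aligned FASTA for
haplotype sequences, CSV for flowering schedules and trait tables, and JSON
for simulation truth/configuration echoes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import MISSING, FloweringSchedule, GenotypeMatrix, TraitTable

# ---------------------------------------------------------------- GenePop

_ALLELE_WIDTH = 3


def write_genepop(
    g: GenotypeMatrix,
    groups: Iterable[str],
    path: str | Path,
    title: str = "cryptolin export",
) -> None:
    """Write genotypes in GenePop format, one ``Pop`` block per group.

    Allele labels are encoded as 3-digit codes; missing genotypes as
    ``000000``.  Group blocks follow the order of first appearance.
    """
    groups = list(groups)
    if len(groups) != g.n_individuals:
        raise ValueError("one group label per individual required")
    order: list[str] = []
    for lab in groups:
        if lab not in order:
            order.append(lab)
    if np.any(g.alleles >= 10**_ALLELE_WIDTH):
        raise ValueError("allele label too large for 3-digit GenePop code")
    lines = [title]
    lines.extend(g.loci)
    for lab in order:
        lines.append("Pop")
        for i, ind in enumerate(g.individuals):
            if groups[i] != lab:
                continue
            cells = [
                f"{g.alleles[i, l, 0]:0{_ALLELE_WIDTH}d}{g.alleles[i, l, 1]:0{_ALLELE_WIDTH}d}"
                for l in range(g.n_loci)
            ]
            lines.append(f"{ind} , " + " ".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read a GenePop file; returns (genotypes, per-individual pop labels).

    Populations are labelled ``pop1``, ``pop2``, ... in file order; use a
    separate label file to attach meaningful group names.
    """
    raw = [ln.rstrip() for ln in Path(path).read_text().splitlines()]
    if not raw:
        raise ValueError(f"empty GenePop file: {path}")
    body = raw[1:]  # first line is the title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # loci may be one per line or comma-separated on one line
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    if i == len(body):
        raise ValueError("no 'Pop' line found")
    inds: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    for ln in body[i:]:
        if not ln.strip():
            continue
        if ln.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in ln:
            raise ValueError(f"malformed GenePop line: {ln!r}")
        name, geno = ln.split(",", 1)
        cells = geno.split()
        if len(cells) != len(loci):
            raise ValueError(
                f"individual {name.strip()!r} has {len(cells)} genotypes, expected {len(loci)}"
            )
        row = []
        for cell in cells:
            w = len(cell) // 2
            a, b = int(cell[:w]), int(cell[w:])
            if (a == 0) != (b == 0):
                a = b = MISSING
            row.append((a, b))
        inds.append(name.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(row)
    alleles = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(alleles, inds, loci), np.array(pops)


# ----------------------------------------------------------------- FASTA


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA; raises on unequal sequence lengths."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    if len({len(s) for s in seqs.values()}) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return seqs


# ------------------------------------------------------------------- CSV


def write_schedule_csv(s: FloweringSchedule, path: str | Path) -> None:
    """Rows = individuals; first column = lineage; remaining columns = dates."""
    out = s.values.copy()
    out.insert(0, "lineage", s.lineage)
    out.to_csv(path, index_label="individual")


def read_schedule_csv(path: str | Path) -> FloweringSchedule:
    df = pd.read_csv(path, index_col="individual")
    lineage = df.pop("lineage")
    df.columns = [float(c) for c in df.columns]
    return FloweringSchedule(df, lineage)


def write_traits_csv(t: TraitTable, path: str | Path) -> None:
    t.data.to_csv(path, index_label="individual")


def read_traits_csv(path: str | Path, group_col: str = "lineage") -> TraitTable:
    df = pd.read_csv(path, index_col="individual")
    return TraitTable(df, group_col=group_col)


# ------------------------------------------------------------------ JSON


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
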