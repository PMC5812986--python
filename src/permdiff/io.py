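"""Plain-text readers and writers: methylation count TSV (bedGraph-like),
sample sheets, BED annotation, expression TSV and truth tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .methylation import MethylationTable
from .expression import ExpressionTable
from .simulate import GenomeModel, TruthSet


def write_methylation_tsv(table: MethylationTable, path) -> None:
    """chrom, pos0, pos0+1 then m_<sample>, t_<sample> column pairs."""
    df = pd.DataFrame({"chrom": table.chrom, "pos0": table.pos,
                       "pos1": table.pos + 1})
    for i, s in enumerate(table.samples):
        df[f"m_{s}"] = table.m[i]
        df[f"t_{s}"] = table.t[i]
    df.to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path, groups: Dict[str, str]) -> MethylationTable:
    df = pd.read_csv(path, sep="\t")
    samples = [c[2:] for c in df.columns if c.startswith("m_")]
    return MethylationTable(
        chrom=df["chrom"].to_numpy(),
        pos=df["pos0"].to_numpy(),
        m=np.vstack([df[f"m_{s}"].to_numpy() for s in samples]),
        t=np.vstack([df[f"t_{s}"].to_numpy() for s in samples]),
        samples=samples,
        groups=groups,
    )


def write_sample_sheet(groups: Dict[str, str], path) -> None:
    pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"], df["group"]))


def write_annotation_beds(model: GenomeModel, outdir) -> None:
    """transcripts.bed / exons.bed (BED6), islands.bed (BED3), tss.bed (BED6)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tx, ex, tss = [], [], []
    for t in model.transcripts:
        tx.append((t.chrom, t.start, t.end, t.transcript_id, 0, t.strand))
        for es, ee in t.exons:
            ex.append((t.chrom, es, ee, t.transcript_id, 0, t.strand))
        tss.append((t.chrom, t.tss, t.tss + 1, t.transcript_id, 0, t.strand))
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    pd.DataFrame(tx, columns=cols).to_csv(outdir / "transcripts.bed", sep="\t",
                                          index=False, header=False)
    pd.DataFrame(ex, columns=cols).to_csv(outdir / "exons.bed", sep="\t",
                                          index=False, header=False)
    pd.DataFrame(tss, columns=cols).to_csv(outdir / "tss.bed", sep="\t",
                                           index=False, header=False)
    pd.DataFrame(model.cpg_islands, columns=["chrom", "start", "end"]).to_csv(
        outdir / "islands.bed", sep="\t", index=False, header=False)
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for c, L in model.chrom_sizes.items():
            fh.write(f"{c}\t{L}\n")


def write_expression_tsv(table: ExpressionTable, path) -> None:
    table.abundance.to_csv(path, sep="\t")


def read_expression_tsv(path, groups: Dict[str, str]) -> ExpressionTable:
    return ExpressionTable(pd.read_csv(path, sep="\t", index_col=0), groups)


def write_truth(truth: TruthSet, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.dml.to_csv(outdir / "truth_dml.tsv", sep="\t", index=False)
    truth.deg.to_csv(outdir / "truth_deg.tsv", sep="\t", index=False)


def write_dmrs_bed(dmrs, path) -> None:
    """BED6: chrom, start, peak+1, name, score, '.'"""
    rows = [(r.chrom, r.start_pos, r.peak_pos + 1, f"dmr{i + 1}",
             round(r.score, 4), ".") for i, r in enumerate(dmrs)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
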