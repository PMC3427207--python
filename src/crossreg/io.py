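"""Readers and writers for the pipeline's plain-text formats.

Expression/metadata/regulon/conservation/annotation tables are TSV with
headers; promoters are FASTA with ``gene|tss_offset`` headers; open-
chromatin intervals are BED3 with the gene id in the chrom column; PWMs
use the TRANSFAC matrix dialect (P0 header, one row per position).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import PWM, GenomicInterval, PromoterRecord
from .preprocessing import ExpressionStudy
from .specificity import TissueAtlas
from .tfreg import TFRegulon

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_study",
    "write_study",
    "read_regulons",
    "write_regulons",
    "read_promoters",
    "write_promoters",
    "read_conservation",
    "write_conservation",
    "read_bed",
    "write_bed",
    "read_transfac",
    "write_transfac",
    "read_atlas",
    "write_atlas",
    "read_annotation",
]


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group"}
    if missing := required - set(meta.columns):
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta.set_index("sample")


def write_metadata(study: ExpressionStudy, path) -> None:
    meta = pd.DataFrame(
        {
            "sample": study.samples,
            "group": study.group.values,
            "batch": "" if study.batch is None else study.batch.values,
            "dataset": study.dataset,
        }
    )
    meta.to_csv(path, sep="\t", index=False)


def read_study(expr_path, meta_path, dataset: str | None = None) -> ExpressionStudy:
    values = read_expression(expr_path)
    meta = read_metadata(meta_path).reindex(values.columns)
    if meta["group"].isna().any():
        raise ValueError("metadata does not cover all matrix samples")
    batch = None
    if "batch" in meta.columns and meta["batch"].fillna("").ne("").all():
        batch = meta["batch"]
    ds = dataset
    if ds is None:
        ds = meta["dataset"].iloc[0] if "dataset" in meta.columns else ""
    return ExpressionStudy(values=values, group=meta["group"], batch=batch, dataset=str(ds))


def write_study(study: ExpressionStudy, expr_path, meta_path) -> None:
    write_expression(study.values, expr_path)
    write_metadata(study, meta_path)


_REGULON_COLS = [
    "tf",
    "motif",
    "target",
    "site_start",
    "site_strand",
    "site_score",
    "site_mean_conservation",
]


def write_regulons(regulons: list[TFRegulon], path) -> None:
    rows = []
    for reg in regulons:
        for target in sorted(reg.targets):
            sites = reg.sites.get(target, [None])
            for s in sites:
                rows.append(
                    {
                        "tf": reg.tf,
                        "motif": reg.motif,
                        "target": target,
                        "site_start": "" if s is None else s.start,
                        "site_strand": "" if s is None else s.strand,
                        "site_score": "" if s is None else f"{s.score:.4f}",
                        "site_mean_conservation": ""
                        if s is None or not np.isfinite(s.mean_conservation)
                        else f"{s.mean_conservation:.4f}",
                    }
                )
    pd.DataFrame(rows, columns=_REGULON_COLS).to_csv(path, sep="\t", index=False)


def read_regulons(path) -> list[TFRegulon]:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "motif": str, "target": str})
    regulons = []
    for (tf, motif), sub in df.groupby(["tf", "motif"], sort=True):
        regulons.append(
            TFRegulon(tf=tf, motif=motif, targets=frozenset(sub["target"]))
        )
    return regulons


def write_promoters(promoters: list[PromoterRecord], fasta_path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=f"{p.gene}|{p.tss_offset}", description="")
        for p in promoters
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def read_promoters(fasta_path, conservation_path=None) -> list[PromoterRecord]:
    cons = read_conservation(conservation_path) if conservation_path else {}
    promoters = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene, _, tss = rec.id.partition("|")
        if not tss:
            raise ValueError(f"FASTA header {rec.id!r} lacks '|tss_offset'")
        seq = str(rec.seq).upper()
        track = cons.get(gene)
        if track is not None and len(track) != len(seq):
            raise ValueError(f"{gene}: conservation length != sequence length")
        promoters.append(
            PromoterRecord(
                gene=gene, tss_offset=int(tss), sequence=seq, conservation=track
            )
        )
    return promoters


def write_conservation(promoters: list[PromoterRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tpos\tscore\n")
        for p in promoters:
            if p.conservation is None:
                continue
            for i, s in enumerate(p.conservation):
                if np.isfinite(s):
                    fh.write(f"{p.gene}\t{i}\t{s:.4f}\n")


def read_conservation(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    tracks: dict[str, np.ndarray] = {}
    for gene, sub in df.groupby("gene"):
        n = int(sub["pos"].max()) + 1
        arr = np.full(n, np.nan)
        arr[sub["pos"].to_numpy(dtype=int)] = sub["score"].to_numpy(dtype=float)
        tracks[gene] = arr
    return tracks


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def write_transfac(pwm: PWM, path_or_handle) -> None:
    own = isinstance(path_or_handle, (str, Path))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write(f"ID {pwm.id}\n")
        cs, ce = pwm.core
        fh.write(f"CC core={cs}..{ce}\n")
        fh.write("P0\tA\tC\tG\tT\n")
        for i, row in enumerate(pwm.counts, start=1):
            vals = "\t".join(f"{v:g}" for v in row)
            fh.write(f"{i:02d}\t{vals}\n")
        fh.write("//\n")
    finally:
        if own:
            fh.close()


def read_transfac(path) -> list[PWM]:
    pwms = []
    pid, core, rows = None, None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("ID"):
                pid = line.split(None, 1)[1].strip()
            elif line.startswith("CC") and "core=" in line:
                frag = line.split("core=", 1)[1]
                a, _, b = frag.partition("..")
                core = (int(a), int(b))
            elif line.startswith("//"):
                if pid is not None and rows:
                    pwms.append(PWM(pid, np.array(rows), core))
                pid, core, rows = None, None, []
            elif line[:2].isdigit() or (line[:1].isdigit() and line[1:2] in ("\t", " ")):
                parts = line.split()
                rows.append([float(v) for v in parts[1:5]])
    if pid is not None and rows:
        pwms.append(PWM(pid, np.array(rows), core))
    return pwms


def write_atlas(atlas: TissueAtlas, path) -> None:
    atlas.values.to_csv(path, sep="\t", index_label="gene")


def read_atlas(path, species: str, focal_tissue: str) -> TissueAtlas:
    vals = pd.read_csv(path, sep="\t", index_col=0)
    vals.index = vals.index.astype(str)
    return TissueAtlas(values=vals, species=species, focal_tissue=focal_tissue)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "category"} <= set(df.columns):
        raise ValueError("annotation TSV needs 'gene' and 'category' columns")
    return df
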