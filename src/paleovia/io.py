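"""File formats: TIFF stacks with a channel-map sidecar, SAM and a documented
TSV dialect for aligned reads, FASTA references, and the CSV schemas for PSM
tables and XIC traces.

TSV read dialect (tab-separated, header row):
    id  reference  start  strand  sequence  qualities
with 0-based start, strand '+'/'-', sequence in forward-reference
orientation and qualities as a Phred+33 string (SAM convention).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .adna import AlignedRead
from .imaging import ImageStack
from .proteomics import XICTrace

logger = logging.getLogger(__name__)

__all__ = [
    "write_stack", "read_stack",
    "write_fasta", "read_fasta",
    "write_reads_tsv", "read_reads_tsv",
    "write_reads_sam", "read_reads_sam",
    "write_xic_csv", "read_xic_csv",
    "read_psm_table",
    "write_vcf",
]


# --- image stacks -----------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Multi-page TIFF (axes TCZYX) plus a JSON sidecar with the channel map."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels.astype(np.float32), metadata={"axes": "TCZYX"})
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"channel_map": stack.channel_map, "voxel_size_um": list(stack.voxel_size)}, indent=2
    ))


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 4:  # single time point stored without the T axis
        voxels = voxels[None]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ImageStack(
        voxels=np.asarray(voxels, dtype=float),
        channel_map={k: int(v) for k, v in meta["channel_map"].items()},
        voxel_size=tuple(meta["voxel_size_um"]),
    )


# --- FASTA ------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --- aligned reads ----------------------------------------------------------

def _quals_to_str(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def _quals_from_str(s: str) -> np.ndarray:
    return np.array([ord(c) - 33 for c in s], dtype=int)


def write_reads_tsv(reads: list[AlignedRead], path: str | Path) -> None:
    rows = [
        {"id": r.id, "reference": r.reference, "start": r.start, "strand": r.strand,
         "sequence": r.sequence, "qualities": _quals_to_str(r.qualities)}
        for r in reads
    ]
    pd.DataFrame(rows, columns=["id", "reference", "start", "strand", "sequence", "qualities"]).to_csv(
        path, sep="\t", index=False
    )


def read_reads_tsv(path: str | Path) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "reference": str, "strand": str})
    return [
        AlignedRead(id=row.id, reference=row.reference, start=int(row.start),
                    strand=row.strand, sequence=row.sequence,
                    qualities=_quals_from_str(row.qualities))
        for row in df.itertuples(index=False)
    ]


def write_reads_sam(
    reads: list[AlignedRead], path: str | Path, reference_lengths: dict[str, int]
) -> None:
    """Minimal SAM: @HD/@SQ header plus the 11 mandatory columns per read."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in reads:
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"{r.id}\t{flag}\t{r.reference}\t{r.start + 1}\t60\t{r.length}M\t*\t0\t0\t"
                f"{r.sequence}\t{_quals_to_str(r.qualities)}\n"
            )


def read_reads_sam(path: str | Path) -> list[AlignedRead]:
    """Read gapless alignments from SAM/BAM; records with indels or clipping
    in the CIGAR are skipped with a logged count (gapless-alignment proxy)."""
    reads = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                skipped += 1
                continue
            if any(op != 0 for op, _ in (aln.cigartuples or [])):
                skipped += 1
                continue
            quals = aln.query_qualities
            reads.append(
                AlignedRead(
                    id=aln.query_name, reference=aln.reference_name,
                    start=aln.reference_start, strand="-" if aln.is_reverse else "+",
                    sequence=aln.query_sequence,
                    qualities=np.array(quals, dtype=int) if quals is not None
                    else np.full(len(aln.query_sequence), 30, dtype=int),
                )
            )
    if skipped:
        logger.info("read_reads_sam: skipped %d unmapped/gapped records", skipped)
    return reads


# --- XIC and PSM tables -----------------------------------------------------

def write_xic_csv(trace: XICTrace, path: str | Path) -> None:
    df = pd.DataFrame({"retention_time_min": trace.time, **trace.channels})
    df.to_csv(path, index=False)
    if trace.peptide:
        Path(str(path) + ".json").write_text(json.dumps({"peptide": trace.peptide}))


def read_xic_csv(path: str | Path) -> XICTrace:
    df = pd.read_csv(path)
    time = df["retention_time_min"].to_numpy(float)
    channels = {c: df[c].to_numpy(float) for c in df.columns if c != "retention_time_min"}
    peptide = None
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        peptide = json.loads(sidecar.read_text()).get("peptide")
    return XICTrace(time=time, channels=channels, peptide=peptide)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """PSM table from CSV or TSV with columns sample, peptide, modifications,
    confidence (percent); modifications as 'Name@idx;...' with 0-based index."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"sample", "peptide", "modifications", "confidence"} - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    df["modifications"] = df["modifications"].fillna("")
    return df


# --- VCF --------------------------------------------------------------------

def write_vcf(calls: pd.DataFrame, path: str | Path, contig: str, contig_length: int) -> None:
    """Minimal VCF 4.2 with DP/AD info; POS is 1-based on output."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternate-supporting reads">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in calls.itertuples(index=False):
            fh.write(
                f"{contig}\t{rec.site + 1}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
                f"DP={rec.depth};AD={rec.alt_count}\n"
            )
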