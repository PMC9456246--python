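"""File round-trips: TIFF stacks, FASTA/FASTQ, BED/bedGraph, truth sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .stack import VoxelStack
from .synth.fish import FishTruth, LocusTruth, NucleusTruth, TerritoryTruth

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_truth_json",
    "read_truth_json",
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "read_bed",
    "write_bed_fragments",
    "write_bedgraph",
]


def write_stack_tiff(channels: dict[str, VoxelStack], prefix: str | Path) -> list[Path]:
    """Write one 16-bit multi-page (z-plane per page) TIFF per channel."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, stack in channels.items():
        path = prefix.parent / f"{prefix.name}_{name}.tif"
        data = np.clip(np.round(stack.values), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data)
        paths.append(path)
    return paths


def read_stack_tiff(
    path: str | Path, spacing: tuple[float, float, float], channel: str = ""
) -> VoxelStack:
    """Read a multi-page TIFF z-stack as one channel."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return VoxelStack(data.astype(np.float64), spacing, channel)


def write_truth_json(truth: FishTruth, path: str | Path) -> None:
    payload = {
        "nuclei": [dataclasses.asdict(n) for n in truth.nuclei],
        "loci": [dataclasses.asdict(l) for l in truth.loci],
        "territories": [dataclasses.asdict(t) for t in truth.territories],
        "planted_broken": {str(k): v for k, v in truth.planted_broken.items()},
        "planted_outside": {str(k): v for k, v in truth.planted_outside.items()},
        "pair_separation_nm": {str(k): v for k, v in truth.pair_separation_nm.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> FishTruth:
    payload = json.loads(Path(path).read_text())
    return FishTruth(
        nuclei=[NucleusTruth(**{**n, "center_nm": tuple(n["center_nm"])}) for n in payload["nuclei"]],
        loci=[LocusTruth(**{**l, "position_nm": tuple(l["position_nm"])}) for l in payload["loci"]],
        territories=[
            TerritoryTruth(**{**t, "center_nm": tuple(t["center_nm"])})
            for t in payload["territories"]
        ],
        planted_broken={int(k): v for k, v in payload["planted_broken"].items()},
        planted_outside={int(k): v for k, v in payload["planted_outside"].items()},
        pair_separation_nm={
            int(k): v for k, v in payload.get("pair_separation_nm", {}).items()
        },
    )


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs with dummy Sanger qualities (Q40)."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED file into (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols) :])
    return df


def write_bed_fragments(fragments, path: str | Path) -> None:
    rows = [(f.chrom, f.start, f.end, f"frag_{f.chrom}_{f.index}") for f in fragments]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(profile, path: str | Path, track_name: str = "4C") -> None:
    """Write a window profile as bedGraph."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for _, row in profile.to_frame().iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{row['value']}\n")
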