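"""Readers and writers for the toolkit's plain-text interchange formats.

Contacts, localizations, interactome tables and junction counts travel as
TSV; masks as plain (ASCII, P1) PBM rasters with a JSON sidecar carrying
the pixel size; proteomes as FASTA (via Biopython); signal tracks as
4-column bedGraph (0-based, half-open); intervals as BED3. Ground-truth
ledgers and provenance records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .storm import MaskRaster
from .tracks import GenomicInterval, SignalTrack

# -- contacts ---------------------------------------------------------------


def write_contacts(contacts: pd.DataFrame, path) -> None:
    contacts.to_csv(path, sep="\t", index=False)


def read_contacts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos1", "pos2", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"contact table missing columns: {sorted(missing)}")
    if (df["pos1"] > df["pos2"]).any() or (df["pos1"] < 0).any():
        raise ValueError("contacts must satisfy 0 <= pos1 <= pos2")
    return df


# -- localizations ----------------------------------------------------------


def write_localizations(patterns, path) -> None:
    rows = [
        {"nucleus_id": p.nucleus_id, "channel": p.channel, "x_nm": x, "y_nm": y}
        for p in patterns
        for x, y in p.points
    ]
    pd.DataFrame(rows, columns=["nucleus_id", "channel", "x_nm", "y_nm"]).to_csv(
        path, sep="\t", index=False
    )


def read_localizations(path):
    from .storm import PointPattern

    df = pd.read_csv(path, sep="\t")
    return [
        PointPattern(str(nid), str(ch), grp[["x_nm", "y_nm"]].to_numpy())
        for (nid, ch), grp in df.groupby(["nucleus_id", "channel"], sort=True)
    ]


# -- masks (plain PBM + JSON sidecar) ---------------------------------------


def write_mask(mask: MaskRaster, path) -> None:
    path = Path(path)
    h, w = mask.grid.shape
    with open(path, "w") as fh:
        fh.write(f"P1\n{w} {h}\n")
        for row in mask.grid.astype(int):
            fh.write(" ".join(map(str, row)) + "\n")
    sidecar = {"pixel_size_nm": mask.pixel_size, "role": mask.role}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_mask(path) -> MaskRaster:
    path = Path(path)
    tokens = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if tokens[0] != "P1":
        raise ValueError(f"expected plain PBM (P1), got {tokens[0]!r}")
    w, h = int(tokens[1]), int(tokens[2])
    grid = np.array(tokens[3 : 3 + w * h], dtype=int).reshape(h, w).astype(bool)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return MaskRaster(grid, sidecar["pixel_size_nm"], role=sidecar.get("role", "nuclear"))


# -- proteome ---------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# -- tracks and intervals ---------------------------------------------------


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            fh.write(
                f"{track.chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:g}\n"
            )


def read_bedgraph(path, bin_size: int | None = None) -> SignalTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    df = df[df["chrom"].astype(str).str.lower() != "track"]
    if df["chrom"].nunique() != 1:
        raise ValueError("expected a single-chromosome bedGraph")
    inferred = int(df["end"].iloc[0] - df["start"].iloc[0])
    bin_size = bin_size or inferred
    n_bins = int(df["end"].max() // bin_size)
    values = np.zeros(n_bins)
    idx = (df["start"] // bin_size).astype(int)
    values[idx] = df["value"].to_numpy()
    return SignalTrack(str(df["chrom"].iloc[0]), bin_size, values)


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, *_ = line.split("\t")
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


# -- ledgers ----------------------------------------------------------------


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
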