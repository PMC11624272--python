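"""Plain-text readers and writers for every format the pipeline exchanges.

All genomic intervals are 0-based half-open (BED convention). Tables are
tab-separated with a header line; the bin table and bin-pair pixel table
together serialize a :class:`~stag2loop.contacts.ContactMatrix`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import BinTable, ContactMatrix

_FASTA_WIDTH = 60


def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(df: pd.DataFrame, path) -> None:
    """BED with a header line (kept: downstream columns such as q/best_n vary)."""
    write_tsv(df, path)


read_bed = read_tsv


def write_bin_table(bt: BinTable, path) -> None:
    write_tsv(bt.bins.assign(is_bait=bt.bins["is_bait"].astype(int)), path)


def read_bin_table(path) -> BinTable:
    bins = read_tsv(path)
    bins["is_bait"] = bins["is_bait"].astype(bool)
    sizes = (bins["end"] - bins["start"]).to_numpy()
    bin_size = int(np.bincount(sizes).argmax()) if len(sizes) else 0
    return BinTable(bins=bins, bin_size=bin_size)


def write_pixels(m: ContactMatrix, path) -> None:
    write_tsv(m.pixels, path)


def read_contact_matrix(bins_path, pixels_path, condition: str = "",
                        normalized: str = "raw") -> ContactMatrix:
    bt = read_bin_table(bins_path)
    px = read_tsv(pixels_path)
    return ContactMatrix(bt, px, condition=condition, normalized=normalized)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_jsonable)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    raise TypeError(f"cannot serialize {type(obj)}")
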