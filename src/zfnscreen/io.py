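"""File-format boundaries: FASTA, BED6, peak-table CSV, plate-layout YAML."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from zfnscreen.founders import Peak, PeakTable
from zfnscreen.sites import GenomeMatch


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA as an ordered {id: uppercase sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: dict[str, str] | list[tuple[str, str]],
                path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seqs, str(path), "fasta")


def write_bed(matches: list[GenomeMatch], query_id: str, k: int,
              path: str | Path) -> None:
    """Off-target matches as BED6: name=<query_id>;mm=<k>, score=mismatches."""
    with open(path, "w") as fh:
        for m in matches:
            fh.write(f"{m.contig}\t{m.start}\t{m.end}\t"
                     f"{query_id};mm={k}\t{m.mismatches}\t{m.strand}\n")


def mismatch_summary(matches: list[GenomeMatch], k: int) -> pd.DataFrame:
    """Hit counts per mismatch level 0..k (both strands pooled)."""
    counts = {mm: 0 for mm in range(k + 1)}
    for m in matches:
        counts[m.mismatches] += 1
    return pd.DataFrame({"mismatches": list(counts),
                         "n_hits": list(counts.values())})


def read_peak_tables(path: str | Path) -> list[PeakTable]:
    """GeneMapper-export-like CSV: well_id, [dye,] size_bp, height."""
    df = pd.read_csv(path)
    required = {"well_id", "size_bp", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak CSV missing columns: {sorted(missing)}")
    tables = []
    for well_id, grp in df.groupby("well_id", sort=False):
        peaks = tuple(Peak(size=float(r.size_bp), height=float(r.height))
                      for r in grp.itertuples())
        tables.append(PeakTable(well_id=str(well_id), peaks=peaks))
    return tables


def write_peak_tables(tables: list[PeakTable], path: str | Path) -> None:
    rows = [{"well_id": t.well_id, "dye": "FAM",
             "size_bp": p.size, "height": p.height}
            for t in tables for p in t.peaks]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_layout(path: str | Path) -> dict[str, list[str]]:
    """YAML mapping founder id -> list of well ids."""
    with open(path) as fh:
        layout = yaml.safe_load(fh)
    if not isinstance(layout, dict):
        raise ValueError("plate layout must be a mapping founder -> wells")
    return {str(k): [str(w) for w in v] for k, v in layout.items()}
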