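"""Readers and writers for the pipeline's on-disk formats.

TSV matrices (header: window_id, chrom, start, end, then sample columns) for
depth/timing; BED (0-based half-open) for intervals, peaks and regions; a
minimal GT-only VCF plus a dosage TSV for genotypes; JSON for the truth
table, per-signal records and run manifests. Floating point is written at
six significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .grid import GenomeGrid, Intervals
from .rtmatrix import RTMatrix

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# timing / depth matrices


def write_matrix_tsv(matrix: RTMatrix, path: str | Path) -> None:
    grid = matrix.grid
    df = pd.DataFrame(
        {
            "window_id": np.arange(grid.n_windows),
            "chrom": grid.chrom,
            "start": grid.start,
            "end": grid.end,
        }
    )
    for i, s in enumerate(matrix.samples):
        df[s] = matrix.values[i]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_matrix_tsv(path: str | Path, state: str = "raw") -> RTMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["window_id", "chrom", "start", "end"]
    samples = [c for c in df.columns if c not in meta]
    grid = GenomeGrid(df[["chrom", "start", "end"]])
    values = df[samples].to_numpy().T
    return RTMatrix(grid, values, state=state, samples=samples)


# ---------------------------------------------------------------------------
# genotypes


def write_dosage_tsv(genotypes: GenotypeTable, path: str | Path) -> None:
    df = genotypes.variants.copy()
    for i, s in enumerate(genotypes.samples):
        df[s] = genotypes.dosages[i].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t")
    meta = ["chrom", "pos", "id", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta]
    return GenotypeTable(df[meta], df[samples].to_numpy(dtype=float).T, samples=samples)


_VCF_HEADER = """##fileformat=VCFv4.2
##source=replitime
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(genotypes: GenotypeTable, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Minimal biallelic GT-only VCF."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.samples) + "\n")
        for j, row in enumerate(genotypes.variants.itertuples(index=False)):
            gts = "\t".join(gt_code[int(d)] for d in genotypes.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a minimal GT-only VCF (1-based positions converted to 0-based)."""
    rows = []
    dosages = []
    samples: list[str] = []
    code = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], int(fields[1]) - 1, fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            gi = fmt.index("GT")
            rows.append((chrom, pos, vid, ref, alt))
            dosages.append([code[f.split(":")[gi]] for f in fields[9:]])
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeTable(variants, np.array(dosages, dtype=float).T, samples=samples)


# ---------------------------------------------------------------------------
# intervals / BED


def write_bed(intervals_or_df, path: str | Path, extra_cols: list[str] | None = None) -> None:
    df = intervals_or_df.df if isinstance(intervals_or_df, Intervals) else intervals_or_df
    cols = ["chrom", "start", "end"] + (extra_cols or [c for c in df.columns if c not in ("chrom", "start", "end")])
    df[cols].to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FMT)


def read_bed(path: str | Path, names: list[str] | None = None) -> Intervals:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "start", "end"]
    extra = names or [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = base + extra[: df.shape[1] - 3]
    return Intervals(df)


# ---------------------------------------------------------------------------
# JSON records


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_Encoder, indent=1)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def signals_to_records(signals, genotypes: GenotypeTable) -> list[dict]:
    recs = []
    for s in signals:
        recs.append(
            dict(
                tag_id=s.tag_id,
                chrom=s.chrom,
                tag_pos=int(genotypes.pos[s.tag]),
                top_p=float(s.top_p),
                threshold_pt=float(s.threshold_pt),
                n_members=int(s.n_members),
                member_ids=[str(genotypes.ids[int(v)]) for v in s.members],
                member_p={str(genotypes.ids[int(v)]): float(p) for v, p in s.member_p.items()},
                beta_tag=float(s.member_beta.get(s.tag, float("nan"))),
                associated_region=list(s.associated_region) if s.associated_region else None,
                filter_verdicts=s.filter_verdicts,
                provenance=s.provenance,
                passes_filters=s.passes_filters,
            )
        )
    return recs
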