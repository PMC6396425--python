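"""Readers and writers for the pipeline's plain-text formats.

Conventions: VCF positions are 1-based (kept as the internal SNP
coordinate); BED/BEDPE intervals are 0-based half-open (the internal
anchor/domain coordinate); LD blocks are 1-based inclusive internally and
converted to BED on output. The contact-matrix triplet format is
``bin_i<TAB>bin_j<TAB>count`` after a header line carrying chrom, bin_size
and n_bins.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .hic import ContactMatrix
from .interactions import InteractionSet
from .ld import HaplotypePanel, LDBlock, LDPairTable

__all__ = [
    "write_vcf_panel", "read_vcf_panel",
    "write_triplet_matrix", "read_triplet_matrix",
    "write_bed_blocks", "read_bed_blocks", "write_bed", "read_bed",
    "write_bedpe", "read_bedpe",
    "write_ld_pairs", "read_ld_pairs",
    "write_truth", "read_truth",
]

log = logging.getLogger(__name__)


# --- VCF + panel -----------------------------------------------------------

def write_vcf_panel(panel: HaplotypePanel, vcf_path, panel_path) -> None:
    """Write a phased single-chromosome VCF plus the sample->population
    panel TSV."""
    n = panel.n_samples
    samples = [f"S{k:05d}" for k in range(n)]
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={int(panel.positions[-1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for k in range(panel.n_snps):
            gts = "\t".join(
                f"{panel.alleles[2 * s, k]}|{panel.alleles[2 * s + 1, k]}"
                for s in range(n)
            )
            fh.write(f"{panel.chrom}\t{panel.positions[k]}\trs{k}\tA\tG\t.\t.\t.\tGT\t{gts}\n")
    pd.DataFrame({"sample": samples,
                  "super_population": panel.sample_population}).to_csv(
        panel_path, sep="\t", index=False)


def read_vcf_panel(vcf_path, panel_path, strict: bool = True) -> HaplotypePanel:
    """Read a phased single-chromosome VCF (bi-allelic records only;
    others skipped with a logged count) joined with the panel TSV."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    panel_df = pd.read_csv(panel_path, sep="\t")
    pop = dict(zip(panel_df["sample"], panel_df["super_population"]))
    missing = [s for s in samples if s not in pop]
    if missing:
        raise ValueError(f"samples missing from panel file: {missing[:5]}")
    positions, rows, chrom = [], [], None
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        gt = np.asarray(var.genotype.array())
        if strict and not np.all(gt[:, 2] == 1):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        positions.append(var.POS)
        rows.append(gt[:, :2].reshape(-1))
        chrom = var.CHROM
    if skipped:
        log.info("read_vcf_panel: skipped %d non-bi-allelic records", skipped)
    alleles = np.array(rows, dtype=np.uint8).T
    return HaplotypePanel(
        alleles,
        np.array(positions, dtype=np.int64),
        chrom=chrom or "chr1",
        sample_population=np.array([pop[s] for s in samples], dtype=object),
    )


# --- contact matrices ------------------------------------------------------

def write_triplet_matrix(matrix: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chrom={matrix.chrom}\tbin_size={matrix.bin_size}\t"
                 f"n_bins={matrix.n_bins}\n")
        for i, j, v in zip(matrix.bins_i, matrix.bins_j, matrix.values):
            fh.write(f"{i}\t{j}\t{v:.6g}\n")


def read_triplet_matrix(path) -> ContactMatrix:
    """Read a triplet matrix; tolerates full symmetric input, which is
    folded onto the upper triangle by max."""
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError("triplet file must start with a header line")
    meta = dict(kv.split("=") for kv in header.lstrip("#").split("\t"))
    df = pd.read_csv(path, sep="\t", skiprows=1,
                     names=["bin_i", "bin_j", "count"])
    for ln, (i, j) in enumerate(zip(df["bin_i"], df["bin_j"]), start=2):
        if i < 0 or j < 0:
            raise ValueError(f"negative bin index at line {ln}")
    i = np.minimum(df["bin_i"], df["bin_j"]).to_numpy()
    j = np.maximum(df["bin_i"], df["bin_j"]).to_numpy()
    folded = pd.DataFrame({"i": i, "j": j, "v": df["count"].to_numpy()})
    folded = folded.groupby(["i", "j"], as_index=False)["v"].max()
    return ContactMatrix(
        bin_size=int(meta["bin_size"]),
        n_bins=int(meta["n_bins"]),
        chrom=meta["chrom"],
        bins_i=folded["i"].to_numpy(),
        bins_j=folded["j"].to_numpy(),
        values=folded["v"].to_numpy(),
    )


# --- BED -------------------------------------------------------------------

def write_bed(intervals, path, chrom: str = "chr1") -> None:
    """Write (start, end) 0-based half-open intervals as BED3."""
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")


def read_bed(path) -> tuple[str, list[tuple[int, int]]]:
    out, chrom = [], "chr1"
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln}")
            chrom = parts[0]
            out.append((int(parts[1]), int(parts[2])))
    return chrom, out


def write_bed_blocks(blocks: list[LDBlock], path) -> None:
    """LD blocks as BED: 1-based inclusive [start, end] -> [start-1, end)."""
    with open(path, "w") as fh:
        for b in blocks:
            name = b.population or "."
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{name}\t{b.snp_count}\n")


def read_bed_blocks(path) -> list[LDBlock]:
    blocks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed block BED line {ln}")
            pop = parts[3] if len(parts) > 3 and parts[3] != "." else None
            snp_count = int(parts[4]) if len(parts) > 4 else 2
            blocks.append(LDBlock(
                chrom=parts[0], start=int(parts[1]) + 1, end=int(parts[2]),
                snp_count=snp_count, population=pop,
            ))
    return blocks


# --- BEDPE -----------------------------------------------------------------

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "significant", "distance", "kind"]


def write_bedpe(interactions: InteractionSet, path) -> None:
    df = interactions.df
    with open(path, "w") as fh:
        for k, r in df.iterrows():
            fh.write("\t".join(str(x) for x in (
                r["chrom"], int(r["start1"]), int(r["end1"]),
                r["chrom"], int(r["start2"]), int(r["end2"]),
                f"I{k}", f"{r['score']:.6g}",
                int(bool(r["significant"])), int(r["distance"]), r["kind"],
            )) + "\n")


def read_bedpe(path) -> InteractionSet:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 8:
                raise ValueError(f"malformed BEDPE line {ln}")
            rows.append({
                "chrom": p[0],
                "start1": int(p[1]), "end1": int(p[2]),
                "start2": int(p[4]), "end2": int(p[5]),
                "score": float(p[7]),
                "significant": bool(int(p[8])) if len(p) > 8 else None,
                "distance": int(p[9]) if len(p) > 9 else None,
                "kind": p[10] if len(p) > 10 else "hic",
            })
    df = pd.DataFrame(rows)
    if df["significant"].isna().any():
        df = df.drop(columns=["significant"])
    if df["distance"].isna().any():
        df = df.drop(columns=["distance"])
    return InteractionSet(df)


# --- LD pair tables --------------------------------------------------------

def write_ld_pairs(pairs: LDPairTable, path) -> None:
    out = pairs.df.rename(columns={"pos_i": "BP_A", "pos_j": "BP_B",
                                   "r2": "R2", "dprime": "DP"})
    out.insert(0, "CHR_A", "chr1")
    out.to_csv(path, sep="\t", index=False,
               float_format="%.6g")


def read_ld_pairs(path, population: str | None = None) -> LDPairTable:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"BP_A": "pos_i", "BP_B": "pos_j",
                            "R2": "r2", "DP": "dprime"})
    if "distance" not in df.columns:
        df["distance"] = df["pos_j"] - df["pos_i"]
    return LDPairTable(df[["pos_i", "pos_j", "r2", "dprime", "distance"]],
                       population=population)


# --- truth -----------------------------------------------------------------

def write_truth(truth, path) -> None:
    payload = dataclasses.asdict(truth)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=lambda o: list(o)
                  if isinstance(o, (tuple, set, np.ndarray)) else o)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
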