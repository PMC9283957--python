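"""Readers and writers for the package's on-disk formats.

SNP calls travel either as VCF 4.2 (GT fields ``0/0``, ``0/1``, ``1/1``,
``./.``; the parent-1 allele is REF) or as a coded TSV (one marker per row:
chrom, pos, then one AA/AB/BB/NA column per individual).  Phenotypes are tidy
TSV (individual, environment, replicate, value); simulation truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AA, AB, BB, MISSING, CODE_TO_LABEL, LABEL_TO_CODE, SnpCallMatrix

_GT = {AA: "0/0", AB: "0/1", BB: "1/1", MISSING: "./."}
_GT_INV = {v: k for k, v in _GT.items()}


def write_vcf(calls: SnpCallMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=binqtl\n")
        for c in calls.chromosomes:
            p = calls.pos[calls.chrom == c]
            fh.write(f"##contig=<ID={c},length={int(p[-1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(calls.samples) + "\n")
        for i in range(calls.n_markers):
            gts = "\t".join(_GT[int(g)] for g in calls.calls[i])
            fh.write(
                f"{calls.chrom[i]}\t{int(calls.pos[i])}\t"
                f"{calls.chrom[i]}_{int(calls.pos[i])}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path, population: str = "ril") -> SnpCallMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, pos, rows = [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        pos.append(var.POS)
        gt = var.genotype.array()[:, :2]  # n x 2 allele indices, -1 missing
        row = np.where(
            (gt < 0).any(axis=1), MISSING, gt.sum(axis=1).clip(0, 2)
        ).astype(np.int8)
        rows.append(row)
    vcf.close()
    return SnpCallMatrix(
        np.asarray(chroms, dtype=object),
        np.asarray(pos, dtype=np.int64),
        np.vstack(rows),
        samples,
        population,
    )


def write_calls_tsv(calls: SnpCallMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        np.vectorize(CODE_TO_LABEL.get)(calls.calls), columns=calls.samples
    )
    df.insert(0, "pos", calls.pos)
    df.insert(0, "chrom", calls.chrom)
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path, population: str = "ril") -> SnpCallMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    codes = np.vectorize(LABEL_TO_CODE.get)(df[samples].to_numpy()).astype(np.int8)
    return SnpCallMatrix(
        df["chrom"].to_numpy(dtype=object),
        df["pos"].to_numpy(dtype=np.int64),
        codes,
        samples,
        population,
    )


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth, path: str | Path) -> None:
    """Serialize a TruthRecord's mosaics, QTLs and realized heritabilities."""
    payload = {
        "qtl": [
            {"chrom": q.chrom, "pos": q.pos, "a": q.a, "env_dev": q.env_dev}
            for q in truth.qtl
        ],
        "realized_h2_per_env": truth.realized_h2_per_env,
        "mosaics": [
            {
                chrom: {
                    "breakpoints": [float(b) for b in breaks],
                    "states": [CODE_TO_LABEL[int(s)] for s in states],
                }
                for chrom, (breaks, states) in per_ind.items()
            }
            for per_ind in truth.mosaics
        ],
    }
    Path(path).write_text(json.dumps(payload))
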