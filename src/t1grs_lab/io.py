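"""Cohort serialization: VCF v4.2 genotypes, TSV sample table, JSON truth.

A cohort directory holds ``genotypes.vcf`` (one sample column per
individual, GT field only), ``samples.tsv`` and ``truth.json``; the
round-trip is exact on dosages, sample fields and the truth record.
Reading goes through :mod:`cyvcf2`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cohort import CohortData, TruthRecord

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_cohort(cohort: CohortData, out_dir: str | Path) -> Path:
    """Write a cohort directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample_ids = cohort.samples["sample_id"].tolist()

    with open(out / "genotypes.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in cohort.truth.panel):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j, v in enumerate(cohort.truth.panel):
            gts = "\t".join(_GT[int(d)] for d in cohort.dosage[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")

    cohort.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_jsonable(), fh, indent=1)
    return out


def read_cohort(in_dir: str | Path) -> CohortData:
    """Read a cohort directory written by :func:`write_cohort`.

    Raises ``ValueError`` naming the offending record on malformed input.
    """
    d = Path(in_dir)
    for required in ("genotypes.vcf", "samples.tsv", "truth.json"):
        if not (d / required).exists():
            raise FileNotFoundError(f"missing {required} in {d}")
    with open(d / "truth.json") as fh:
        truth = TruthRecord.from_jsonable(json.load(fh))

    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    if len(samples) == 0:
        raise ValueError("samples.tsv has no rows")

    vcf = VCF(str(d / "genotypes.vcf"))
    n = len(vcf.samples)
    if n != len(samples):
        raise ValueError(
            f"sample count mismatch: VCF has {n}, samples.tsv has {len(samples)}"
        )
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for k, rec in enumerate(vcf):
        gt = np.asarray(rec.gt_types)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        if np.any(gt == 2):
            raise ValueError(f"missing genotype at record {k + 1} ({rec.ID})")
        dos = np.where(gt == 3, 2, gt).astype(np.int8)
        rows.append(dos)
        ids.append(rec.ID)
    if not rows:
        raise ValueError("genotypes.vcf contains no variant records")
    expected = [v.id for v in truth.panel]
    if ids != expected:
        raise ValueError("VCF variant records do not match the truth panel "
                         f"(first mismatch near record {_first_mismatch(ids, expected) + 1})")
    dosage = np.vstack(rows).T
    return CohortData(dosage=dosage, variant_ids=ids, samples=samples, truth=truth)


def _first_mismatch(a: list[str], b: list[str]) -> int:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    return min(len(a), len(b))


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    """Write an association summary-statistics TSV
    (variant_id, chrom, pos, ref, alt, af, beta, se, z, p, n)."""
    cols = ["variant_id", "chrom", "pos", "ref", "alt", "af", "beta", "se", "z", "p", "n"]
    present = [c for c in cols if c in df.columns]
    df[present].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "variant_id" not in df.columns:
        raise ValueError(f"{path}: not a summary-statistics TSV (no variant_id column)")
    return df
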