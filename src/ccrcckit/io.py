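"""Readers and writers for the pipeline's on-disk formats.

Expression matrices, metadata and gene lists travel as TSV; variants as
VCF 4.x (read through cyvcf2, with a configurable mapping from INFO/FORMAT
keys to the attributes the filter cascade consumes); models and manifests as
JSON.  Coordinates are 1-based inclusive throughout, as in VCF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .variants import VariantRecord

__all__ = [
    "VcfFieldMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "read_gene_list",
    "read_variants_vcf",
    "write_variants_vcf",
    "write_manifest",
]


def read_expression_matrix(path: str | Path, scale: str = "raw") -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene id, header sample ids).

    Ragged rows, duplicate gene ids, non-numeric bodies and (for raw scale)
    negative values produce errors naming the offending line or gene.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            n = len(line.rstrip("\n").split("\t"))
            if n != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({n} fields, expected {width})"
                )
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    if scale == "raw" and (df.to_numpy() < 0).any():
        genes = df.index[(df < 0).any(axis=1)].tolist()
        raise ValueError(f"{path}: negative values for raw-scale genes {genes[:5]}")
    return ExpressionMatrix(df, scale=scale)


def write_expression_matrix(X: ExpressionMatrix, path: str | Path) -> None:
    X.data.to_csv(path, sep="\t", index_label="gene")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    genes = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes


@dataclass
class VcfFieldMap:
    """Which VCF INFO keys hold the annotation the cascade needs."""

    gene: str = "GENE"
    consequence: str = "CSQ"
    region: str = "REGION"
    pop_freq_1kg: str = "AF_1KG"
    pop_freq_esp: str = "AF_ESP"
    polyn: str = "POLYN"


def read_variants_vcf(
    path: str | Path, field_map: VcfFieldMap | None = None
) -> list[VariantRecord]:
    """Read per-sample variant records from a multi-sample VCF.

    One record is emitted per (variant, sample) pair where the sample carries
    the alternate allele (non-ref genotype).  Multi-allelic sites produce one
    record per alternate allele.  Missing mapped annotation becomes
    ``"missing"`` (later removed by the functional filter), except population
    frequencies, which stay ``None`` ("not observed").  Allele depth/rate come
    from the AD FORMAT field.
    """
    from cyvcf2 import VCF

    fm = field_map or VcfFieldMap()
    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for var in vcf:
        filt = var.FILTER or "PASS"  # cyvcf2 reports PASS as None
        gene = var.INFO.get(fm.gene)
        csq = var.INFO.get(fm.consequence)
        region = var.INFO.get(fm.region)
        polyn = bool(var.INFO.get(fm.polyn, 0))
        f1kg = var.INFO.get(fm.pop_freq_1kg)
        fesp = var.INFO.get(fm.pop_freq_esp)
        ad = var.format("AD")
        gts = var.genotypes  # [allele1, allele2, phased]
        for alt_index, alt in enumerate(var.ALT, start=1):
            is_indel = len(var.REF) != len(alt)
            for si, sample in enumerate(samples):
                alleles = gts[si][:-1]
                if alt_index not in alleles:
                    continue
                alt_depth, alt_rate = 0, 0.0
                if ad is not None and ad.shape[1] > alt_index:
                    ref_d = max(int(ad[si][0]), 0)
                    alt_d = max(int(ad[si][alt_index]), 0)
                    alt_depth = alt_d
                    total = ref_d + alt_d
                    alt_rate = alt_d / total if total else 0.0
                records.append(
                    VariantRecord(
                        sample_id=sample,
                        chrom=var.CHROM,
                        pos=int(var.POS),
                        ref=var.REF,
                        alt=alt,
                        filter_status=filt,
                        alt_depth=alt_depth,
                        alt_rate=alt_rate,
                        is_indel=is_indel,
                        in_polyN_region=polyn,
                        pop_freq_1kg=float(f1kg) if f1kg is not None else None,
                        pop_freq_esp=float(fesp) if fesp is not None else None,
                        region_class=region if region is not None else "missing",
                        consequence=csq if csq is not None else "missing",
                        gene_symbol=gene if gene is not None else "missing",
                    )
                )
    return records


def write_variants_vcf(
    records: list[VariantRecord],
    path: str | Path,
    field_map: VcfFieldMap | None = None,
) -> None:
    """Write records as a multi-sample VCF 4.2 file.

    Each record becomes one VCF line genotyped 0/1 in its carrying sample
    (0/0 with missing depth elsewhere).  Approximate read depths are
    reconstructed from ``alt_depth`` and ``alt_rate``.
    """
    fm = field_map or VcfFieldMap()
    samples = sorted({r.sample_id for r in records})
    sample_pos = {s: i for i, s in enumerate(samples)}
    contigs = sorted({r.chrom for r in records})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        f'##INFO=<ID={fm.gene},Number=1,Type=String,Description="Gene symbol">',
        f'##INFO=<ID={fm.consequence},Number=1,Type=String,Description="Consequence">',
        f'##INFO=<ID={fm.region},Number=1,Type=String,Description="Region class">',
        f'##INFO=<ID={fm.pop_freq_1kg},Number=1,Type=Float,Description="1000 Genomes AF">',
        f'##INFO=<ID={fm.pop_freq_esp},Number=1,Type=Float,Description="6500 Exomes AF">',
        f'##INFO=<ID={fm.polyn},Number=0,Type=Flag,Description="Poly-N region">',
        '##FILTER=<ID=LowQual,Description="Low quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    def _chrom_key(r: VariantRecord):
        return (r.chrom, r.pos, r.ref, r.alt, r.sample_id)

    for r in sorted(records, key=_chrom_key):
        info = [
            f"{fm.gene}={r.gene_symbol or 'missing'}",
            f"{fm.consequence}={r.consequence}",
            f"{fm.region}={r.region_class}",
        ]
        if r.pop_freq_1kg is not None:
            info.append(f"{fm.pop_freq_1kg}={r.pop_freq_1kg:.6g}")
        if r.pop_freq_esp is not None:
            info.append(f"{fm.pop_freq_esp}={r.pop_freq_esp:.6g}")
        if r.in_polyN_region:
            info.append(fm.polyn)
        if r.alt_rate > 0:
            ref_depth = int(round(r.alt_depth * (1.0 - r.alt_rate) / r.alt_rate))
        else:
            ref_depth = 0
        gts = ["0/0:.,."] * len(samples)
        gts[sample_pos[r.sample_id]] = f"0/1:{ref_depth},{r.alt_depth}"
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.pos),
                    ".",
                    r.ref,
                    r.alt,
                    ".",
                    r.filter_status,
                    ";".join(info),
                    "GT:AD",
                ]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path: str | Path, config: dict, stage_counts: dict | None = None) -> None:
    """Run manifest: config, seed and stage record counts, for re-running."""
    import ccrcckit

    manifest = {
        "package_version": getattr(ccrcckit, "__version__", "unknown"),
        "config": config,
        "stage_counts": stage_counts or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
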