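"""File interchange: minimal VCF per MA line (pysam), metadata and trait TSVs.

The VCF carries one sample per line-VCF with GT, and INFO keys
DP (line depth), DPA (ancestor depth), ADF/ADR (forward/reverse support),
HRUN (homonucleotide-run flag), GENIC (genic flag), EFFECT (coding effect).
Key names are configurable on read; these are the documented defaults.
"""

from __future__ import annotations

import os

import pandas as pd
import pysam

from .variant_filtering import MALine, VariantRecord

__all__ = [
    "write_line_vcf",
    "read_line_vcf",
    "write_ma_metadata",
    "read_ma_metadata",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_trait_tsv",
    "read_trait_tsv",
]

_INFO_DEFAULTS = {"dp": "DP", "dpa": "DPA", "adf": "ADF", "adr": "ADR"}


def _vcf_header(sample: str, contigs: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.info.add("DP", 1, "Integer", "Read depth in the MA line")
    header.info.add("DPA", 1, "Integer", "Read depth in the ancestor")
    header.info.add("ADF", 1, "Integer", "Forward reads supporting the variant")
    header.info.add("ADR", 1, "Integer", "Reverse reads supporting the variant")
    header.info.add("HRUN", 0, "Flag", "Variant lies in a homonucleotide run")
    header.info.add("GENIC", 0, "Flag", "Variant lies in a genic region")
    header.info.add("EFFECT", 1, "String", "Coding effect: none/synonymous/nonsynonymous")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    return header


def write_line_vcf(line: MALine, path: str | os.PathLike) -> None:
    """Write one MA line's variants as an uncompressed single-sample VCF."""
    contigs = sorted({rec.chrom for rec in line.variants}) or ["chrI"]
    header = _vcf_header(line.line_id, contigs)
    records = sorted(line.variants, key=lambda r: (r.chrom, r.pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
                qual=rec.quality,
            )
            row.info["DP"] = rec.depth_sample
            row.info["DPA"] = rec.depth_ancestor
            row.info["ADF"] = rec.forward_support
            row.info["ADR"] = rec.reverse_support
            if rec.in_homonucleotide_run:
                row.info["HRUN"] = True
            if rec.genic:
                row.info["GENIC"] = True
            row.info["EFFECT"] = rec.coding_effect
            if rec.genotype_homogeneous:
                gt = (1,) if line.ploidy == "haploid" else (1, 1)
            else:
                gt = (0, 1)
            row.samples[line.line_id]["GT"] = gt
            out.write(row)


def read_line_vcf(
    path: str | os.PathLike,
    info_keys: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Read VariantRecords from a VCF; ``info_keys`` remaps depth/strand keys."""
    keys = dict(_INFO_DEFAULTS)
    if info_keys:
        keys.update(info_keys)
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            sample = next(iter(row.samples.values())) if row.samples else None
            gt = sample["GT"] if sample else (1,)
            alleles = set(a for a in gt if a is not None)
            homogeneous = len(alleles) <= 1
            out.append(
                VariantRecord(
                    chrom=row.chrom,
                    pos=row.pos,
                    ref=row.ref,
                    alt=row.alts[0],
                    depth_sample=int(row.info.get(keys["dp"], 0)),
                    depth_ancestor=int(row.info.get(keys["dpa"], 0)),
                    forward_support=int(row.info.get(keys["adf"], 0)),
                    reverse_support=int(row.info.get(keys["adr"], 0)),
                    quality=float(row.qual if row.qual is not None else 0.0),
                    genotype_homogeneous=homogeneous,
                    in_homonucleotide_run=bool(row.info.get("HRUN", False)),
                    genic=bool(row.info.get("GENIC", False)),
                    coding_effect=str(row.info.get("EFFECT", "none")),
                )
            )
    return out


def write_ma_metadata(lines: list[MALine], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "line_id": [l.line_id for l in lines],
            "generations": [l.generations for l in lines],
            "callable_sites": [l.callable_sites for l in lines],
            "ploidy": [l.ploidy for l in lines],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ma_metadata(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts_tsv(counts, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"culture_id": [f"c{i + 1}" for i in range(len(counts))], "mutant_count": counts}
    ).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | os.PathLike) -> list[int]:
    return pd.read_csv(path, sep="\t")["mutant_count"].astype(int).tolist()


def write_trait_tsv(strain_ids, values, path: str | os.PathLike,
                    trait: str = "mutation_rate") -> None:
    pd.DataFrame({"strain_id": strain_ids, "trait": trait, "value": values}).to_csv(
        path, sep="\t", index=False
    )


def read_trait_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
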