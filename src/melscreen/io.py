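"""Shared table, VCF and configuration I/O.

All tabular interchange uses tab-separated text with a header row and floats
written at 12 significant digits, so every writer's output round-trips through
the matching reader. Genomic coordinates are 1-based and inclusive throughout
(VCF convention); BED-derived inputs must be converted before loading.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

log = logging.getLogger("melscreen")

FLOAT_FORMAT = "%.12g"

POPULATIONS = ("A", "B", "C")


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as TSV with 12-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a header-bearing TSV (transparently gzip-compressed if .gz)."""
    return pd.read_csv(path, sep="\t")


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a sample -> population map (TSV: sample, population).

    Every population must have at least one sample.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     comment="#", dtype=str)
    popmap = dict(zip(df["sample"], df["population"]))
    if not popmap:
        raise ValueError("population map is empty")
    return popmap


def read_vcf_frequencies(vcf_path: str | Path, popmap: Mapping[str, str]) -> pd.DataFrame:
    """Compute per-population alternate-allele frequencies from VCF genotypes.

    Only biallelic SNP records are used; multiallelic or non-SNP records are
    skipped and counted. Missing genotypes are excluded from the chromosome
    denominator. A site where any population has zero called chromosomes is
    skipped.

    Parameters
    ----------
    vcf_path:
        VCF 4.2 file with GT fields (plain or bgzipped).
    popmap:
        Mapping of sample name to population label; every sample in the VCF
        must be mapped.

    Returns
    -------
    DataFrame with columns chrom, pos, ref, alt and, for each population
    label k, ``p_k`` (alt frequency) and ``n_k`` (called chromosomes).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    unmapped = [s for s in vcf.samples if s not in popmap]
    if unmapped:
        raise ValueError(f"samples missing from population map: {unmapped}")
    pops = sorted(set(popmap.values()))
    pop_cols = {p: [i for i, s in enumerate(vcf.samples) if popmap[s] == p] for p in pops}
    for p, cols in pop_cols.items():
        if not cols:
            raise ValueError(f"population {p!r} has no samples in the VCF")

    rows = []
    n_skipped_multi = n_skipped_nonsnp = n_skipped_uncalled = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped_nonsnp += 1
            continue
        row = {"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]}
        ok = True
        for p in pops:
            alt = n_called = 0
            for i in pop_cols[p]:
                for a in v.genotypes[i][:-1]:  # last entry is the phasing flag
                    if a < 0:
                        continue
                    n_called += 1
                    if a > 0:
                        alt += 1
            if n_called == 0:
                ok = False
                break
            row[f"p_{p}"] = alt / n_called
            row[f"n_{p}"] = n_called
        if ok:
            rows.append(row)
        else:
            n_skipped_uncalled += 1
    if n_skipped_multi or n_skipped_nonsnp or n_skipped_uncalled:
        log.info("read_vcf_frequencies: skipped %d multiallelic, %d non-SNP, "
                 "%d with an uncalled population",
                 n_skipped_multi, n_skipped_nonsnp, n_skipped_uncalled)
    return pd.DataFrame(rows)


def write_frequency_vcf(freqs: pd.DataFrame, path: str | Path,
                        pops: tuple[str, ...] = POPULATIONS) -> Path:
    """Write a sites-only VCF 4.2 carrying per-population frequencies in INFO.

    INFO fields ``AF_<pop>`` (alt frequency) and ``AN_<pop>`` (chromosome
    count) are emitted for each population label.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=melscreen\n")
        for p in pops:
            fh.write(f'##INFO=<ID=AF_{p},Number=1,Type=Float,'
                     f'Description="Alt allele frequency in population {p}">\n')
            fh.write(f'##INFO=<ID=AN_{p},Number=1,Type=Integer,'
                     f'Description="Called chromosomes in population {p}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in freqs.iterrows():
            info = ";".join(
                f"AF_{p}={r[f'p_{p}']:.12g};AN_{p}={int(r[f'n_{p}'])}" for p in pops
            )
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}"
                     f"\t.\tPASS\t{info}\n")
    return path


def read_frequency_vcf(path: str | Path,
                       pops: tuple[str, ...] = POPULATIONS) -> pd.DataFrame:
    """Read a sites-only frequency VCF written by :func:`write_frequency_vcf`."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        row = {"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]}
        for p in pops:
            row[f"p_{p}"] = float(v.INFO[f"AF_{p}"])
            row[f"n_{p}"] = int(v.INFO[f"AN_{p}"])
        rows.append(row)
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
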