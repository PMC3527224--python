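"""Minimal VCF 4.2 export/import for tetraploid genotype calls.

Genotypes are written as unphased tetraploid GT fields (e.g. ``0/0/0/1``)
with per-genotype log10 likelihoods in a GL-like ``TL`` field ordered by ALT
dosage 0..4.  Uncalled individuals are written as ``./././.``; the FILTER
column carries site-level drop reasons from the coverage/variant filters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_vcf", "read_vcf"]

_HEADER = """##fileformat=VCFv4.2
##source=tetrapop
##FILTER=<ID=low_coverage,Description="Some individual at coverage <= 4x">
##FILTER=<ID=too_many_variants,Description="More than two variant bases across individuals">
##INFO=<ID=AC,Number=A,Type=Integer,Description="ALT allele count in called genotypes">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Tetraploid genotype">
##FORMAT=<ID=TL,Number=5,Type=Float,Description="log10 genotype likelihoods for ALT dosage 0..4">
"""


def write_vcf(path: Path | str, sites: pd.DataFrame, n_individuals: int = 12) -> None:
    """Write one row per site.

    ``sites`` columns: chrom, pos (0-based), ref, alt, filter, plus per
    individual ``dosage_i`` (ALT dosage, -1 = uncalled) and optional ``tl_i``
    (comma-joined 5 log10 likelihoods).
    """
    names = [f"ind{i:02d}" for i in range(n_individuals)]
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for row in sites.itertuples(index=False):
            dosages = [getattr(row, f"dosage_{i}") for i in range(n_individuals)]
            an = sum(4 for d in dosages if d >= 0)
            ac = sum(d for d in dosages if d >= 0)
            has_tl = hasattr(row, "tl_0")
            fmt = "GT:TL" if has_tl else "GT"
            samples = []
            for i, d in enumerate(dosages):
                if d < 0:
                    gt = "./././."
                else:
                    gt = "/".join(["0"] * (4 - d) + ["1"] * d)
                if has_tl:
                    gt += ":" + getattr(row, f"tl_{i}")
                samples.append(gt)
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\t{row.filter}"
                f"\tAC={ac};AN={an}\t{fmt}\t" + "\t".join(samples) + "\n"
            )


def read_vcf(path: Path | str) -> pd.DataFrame:
    """Read a tetrapop VCF back into the frame layout accepted by write_vcf."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                n_ind = len(line.rstrip("\n").split("\t")) - 9
                continue
            f = line.rstrip("\n").split("\t")
            rec = {
                "chrom": f[0],
                "pos": int(f[1]) - 1,
                "ref": f[3],
                "alt": f[4],
                "filter": f[6],
            }
            for i in range(n_ind):
                fields = f[9 + i].split(":")
                gt = fields[0]
                rec[f"dosage_{i}"] = -1 if "." in gt else gt.count("1")
                if len(fields) > 1:
                    rec[f"tl_{i}"] = fields[1]
            rows.append(rec)
    return pd.DataFrame(rows)
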