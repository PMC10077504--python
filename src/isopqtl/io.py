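"""Plain-text readers and writers for every pipeline artefact.

Genotypes travel as GT-only VCF (1-based positions); everything else is
TSV or JSON so each stage is independently inspectable and replaceable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypePanel, ProteinMatrix

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as an uncompressed GT-only VCF."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = panel.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        D = panel.dosages
        for j in range(panel.n_variants):
            v = panel.variants.iloc[j]
            gts = [
                "./." if np.isnan(d) else _GT[int(round(d))] for d in D[:, j]
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['rsid']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a GT VCF into a dosage panel (cyvcf2-backed)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dos = [], []
    for var in vcf:
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "rsid": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        d = np.where(gt == 3, 2.0, gt)
        d[gt == 2] = np.nan
        dos.append(d)
    vcf.close()
    return GenotypePanel(
        np.array(dos).T if dos else np.empty((len(samples), 0)),
        pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "ref", "alt"]),
        samples,
    )


def write_protein_matrix(matrix: ProteinMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    matrix.values.to_csv(f"{prefix}_npx.tsv", sep="\t", index_label="sample")
    matrix.lod.rename("lod").to_csv(f"{prefix}_lod.tsv", sep="\t", index_label="protein")
    matrix.covariates.to_csv(f"{prefix}_samples.tsv", sep="\t", index_label="sample")


def read_protein_matrix(prefix: str | Path) -> ProteinMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(f"{prefix}_npx.tsv", sep="\t", index_col="sample")
    lod = pd.read_csv(f"{prefix}_lod.tsv", sep="\t", index_col="protein")["lod"]
    covs = pd.read_csv(f"{prefix}_samples.tsv", sep="\t", index_col="sample")
    return ProteinMatrix(values, lod, covs)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
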