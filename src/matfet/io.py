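"""Readers and writers for the pipeline's on-disk formats.

Trio genotypes and variant records travel as VCF v4.2 (written as plain text,
read back through pysam); per-cell observations as a TSV sidecar (cell,
chrom, pos, allele, depth); expression matrices as Matrix Market triplets
with barcode/feature TSVs (the feature file carries a ``mito`` flag column);
labels, reference panels and ligand-receptor pair lists as simple TSVs.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .filters import FilterVerdict
from .simulate import AnnotatedVariantRecord, CellAlleleObservations, GenotypeTable

_VCF_HEADER = """##fileformat=VCFv4.2
##source=matfet
{extra}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO{samples}
"""

_ANN_KEYS = ("DP", "QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


def _info_header_lines() -> str:
    types = {"DP": "Integer"}
    lines = []
    for k in _ANN_KEYS:
        t = types.get(k, "Float")
        lines.append(f'##INFO=<ID={k},Number=1,Type={t},Description="{k}">')
    return "\n".join(lines) + "\n"


def write_trio_vcf(genotypes: GenotypeTable, path: str) -> None:
    """Write the trio as a three-sample VCF v4.2 (GT only, unphased)."""
    individuals = list(genotypes.genotypes)
    samples = "\tFORMAT\t" + "\t".join(individuals)
    extra = '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(extra=extra, samples=samples))
        for i, row in genotypes.sites.iterrows():
            gts = "\t".join(
                f"{genotypes.genotypes[ind][i, 0]}/{genotypes.genotypes[ind][i, 1]}"
                for ind in individuals
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t."
                f"\tGT\t{gts}\n"
            )


def read_trio_vcf(path: str) -> GenotypeTable:
    """Read a multi-sample VCF back into a GenotypeTable (biallelic sites)."""
    import pysam

    with pysam.VariantFile(path) as vf:
        individuals = list(vf.header.samples)
        rows, gts = [], {ind: [] for ind in individuals}
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "maf": np.nan,
                    "informative": False,
                }
            )
            for ind in individuals:
                alleles = rec.samples[ind]["GT"]
                gts[ind].append([a if a is not None else 0 for a in alleles])
    sites = pd.DataFrame(rows)
    genotypes = {ind: np.asarray(g, dtype=np.int8) for ind, g in gts.items()}
    return GenotypeTable(sites=sites, genotypes=genotypes)


def write_variant_vcf(
    records: list[AnnotatedVariantRecord],
    path: str,
    verdicts: Optional[list[FilterVerdict]] = None,
    filter_name: str = "Filter",
    drop_failing: bool = False,
) -> None:
    """Write annotated records as a sites-only VCF.

    With verdicts, failing records keep their line but get the profile's
    filter tag in FILTER (mirroring tag-don't-delete filtration); pass
    ``drop_failing`` to omit them entirely.
    """
    extra = _info_header_lines()
    extra += f'##FILTER=<ID={filter_name},Description="hard filter">\n'
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(extra=extra, samples=""))
        for i, rec in enumerate(records):
            status = "PASS"
            if verdicts is not None and verdicts[i].status == "fail":
                if drop_failing:
                    continue
                status = filter_name
            info = ";".join(
                f"{k}={rec.annotations[k]:g}"
                for k in _ANN_KEYS
                if rec.annotations.get(k) is not None
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t{status}"
                f"\t{info or '.'}\n"
            )


def read_variant_vcf(path: str) -> list[AnnotatedVariantRecord]:
    """Read a VCF into AnnotatedVariantRecords (INFO annotations only)."""
    import pysam

    records = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            ann = {}
            for k in _ANN_KEYS:
                if k in rec.info:
                    v = rec.info[k]
                    ann[k] = float(v[0] if isinstance(v, tuple) else v)
            records.append(
                AnnotatedVariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    annotations=ann,
                )
            )
    return records


def write_observations_tsv(
    obs: CellAlleleObservations, genotypes: GenotypeTable, path: str
) -> None:
    """Per-cell observations as TSV: cell, chrom, pos, allele, depth."""
    sites = genotypes.sites
    rec = obs.records
    out = pd.DataFrame(
        {
            "cell": rec["cell"],
            "chrom": sites["chrom"].to_numpy()[rec["site_idx"]],
            "pos": sites["pos"].to_numpy()[rec["site_idx"]],
            "allele": rec["allele"],
            "depth": rec["depth"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str, genotypes: GenotypeTable) -> pd.DataFrame:
    """Read an observations TSV and map (chrom, pos) back to site indices."""
    df = pd.read_csv(path, sep="\t")
    key = pd.MultiIndex.from_frame(genotypes.sites[["chrom", "pos"]])
    lookup = pd.Series(np.arange(len(key)), index=key)
    df["site_idx"] = lookup.loc[
        pd.MultiIndex.from_frame(df[["chrom", "pos"]])
    ].to_numpy()
    return df


def write_labels_tsv(truth: pd.Series, path: str) -> None:
    truth.rename("label").rename_axis("cell").to_csv(path, sep="\t")


def read_labels_tsv(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["label"].to_numpy(), index=df["cell"].to_numpy())


def write_expression_mtx(adata, out_dir: str) -> None:
    """Matrix Market triplet + barcodes.tsv + features.tsv (genes x cells)."""
    from scipy import io as sio
    from scipy import sparse

    os.makedirs(out_dir, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    sio.mmwrite(os.path.join(out_dir, "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.obs_names).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    feats = pd.DataFrame(
        {
            "gene": adata.var_names,
            "mito": adata.var["mito"].astype(int)
            if "mito" in adata.var
            else 0,
        }
    )
    feats.to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", index=False, header=False
    )


def read_expression_mtx(in_dir: str):
    """Read a Matrix Market directory back into AnnData (cells x genes)."""
    import anndata as ad
    from scipy import io as sio

    X = sio.mmread(os.path.join(in_dir, "matrix.mtx")).T.tocsr()
    barcodes = pd.read_csv(
        os.path.join(in_dir, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    feats = pd.read_csv(os.path.join(in_dir, "features.tsv"), sep="\t", header=None)
    var = pd.DataFrame(index=pd.Index(feats[0].astype(str), name="gene"))
    var["mito"] = feats[1].astype(bool).to_numpy() if feats.shape[1] > 1 else False
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell"))
    return ad.AnnData(X=X, obs=obs, var=var)


def write_reference_tsv(reference, out_dir: str) -> None:
    """One 3-column TSV per panel: site_idx, allele0, allele1."""
    os.makedirs(out_dir, exist_ok=True)
    for label, panel in reference.panels.items():
        rows = [(s, g[0], g[1]) for s, g in sorted(panel.items())]
        pd.DataFrame(rows, columns=["site_idx", "a0", "a1"]).to_csv(
            os.path.join(out_dir, f"{label}.tsv"), sep="\t", index=False
        )


def read_pairs_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"}.issubset(df.columns):
        raise ValueError("pair list must have 'ligand' and 'receptor' columns")
    return df
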