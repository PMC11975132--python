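"""File readers and writers for the standard interchange formats.

BED peaks, GTF gene models, expression TSVs, TF annotation tables, the
binding-profile CSVs exchanged between the motif stage and the network
model, and the YAML run configuration.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
import yaml

from .regions import GeneModel, GenomicInterval, OpenRegion, RegionAnnotation

PROFILE_COLUMNS = [
    "gene_id",
    "tf_id",
    "site_rank",
    "offset",
    "strand",
    "sp",
    "repressor_id",
    "sq",
]


def read_bed_peaks(path: str, assay: Optional[str] = None) -> list[GenomicInterval]:
    """Read a BED3(+1) peak file.

    With ``assay`` given, every interval gets that label; otherwise a fourth
    column holding the assay name is required.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if assay is None:
        if df.shape[1] < 4:
            raise ValueError(f"{path}: no assay given and no 4th BED column")
        labels = df.iloc[:, 3].astype(str)
    else:
        labels = pd.Series([assay] * len(df))
    peaks = []
    for i, row in df.iterrows():
        try:
            peaks.append(
                GenomicInterval(str(row[0]), int(row[1]), int(row[2]), labels[i])
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i + 1}: {exc}") from exc
    return peaks


def write_bed(regions: Iterable[OpenRegion], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_bed_regions(path: str) -> list[OpenRegion]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [OpenRegion(str(c), int(s), int(e)) for c, s, e in df.iloc[:, :3].itertuples(index=False)]


def read_gene_models(path: str, feature: str = "gene") -> list[GeneModel]:
    """Read gene models from GTF/GFF3 via gffutils.

    GTF coordinates are 1-based closed; they are converted to 0-based
    half-open.  TSS is the 5' end of the feature on its strand, TES the 3'
    end, so on the minus strand tss > tes.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for f in db.features_of_type(feature):
        gene_id = f.attributes.get("gene_id", [f.id])[0]
        start0, end0 = f.start - 1, f.end  # 0-based half-open
        if f.strand == "-":
            tss, tes = end0 - 1, start0
        else:
            tss, tes = start0, end0 - 1
        genes.append(GeneModel(gene_id, f.seqid, f.strand, tss, tes))
    return genes


def write_region_annotation(annotations: Sequence[RegionAnnotation], path: str) -> None:
    """TSV: gene_id, promoter as chrom:start-end (or '.'), ;-joined bodies."""
    rows = []
    for a in annotations:
        prom = f"{a.promoter.chrom}:{a.promoter.start}-{a.promoter.end}" if a.promoter else "."
        bodies = ";".join(f"{r.chrom}:{r.start}-{r.end}" for r in a.gene_body_regions) or "."
        rows.append((a.gene_id, prom, bodies))
    pd.DataFrame(rows, columns=["gene_id", "promoter", "gene_body_regions"]).to_csv(
        path, sep="\t", index=False
    )


def _parse_region(token: str) -> Optional[OpenRegion]:
    if token == ".":
        return None
    chrom, span = token.rsplit(":", 1)
    s, e = span.split("-")
    return OpenRegion(chrom, int(s), int(e))


def read_region_annotation(path: str) -> list[RegionAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for gene_id, prom, bodies in df.itertuples(index=False):
        promoter = _parse_region(prom)
        body = [] if bodies == "." else [_parse_region(t) for t in bodies.split(";")]
        out.append(RegionAnnotation(gene_id, promoter, body))
    return out


def read_expression(path: str) -> pd.Series:
    """Two-column TSV gene_id -> expression level (no internal renormalization)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id, expression")
    s = pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))
    if (s < 0).any():
        bad = s.index[s < 0][0]
        raise ValueError(f"{path}: negative expression for {bad}")
    return s


def write_expression(series: pd.Series, path: str) -> None:
    df = pd.DataFrame({"gene_id": series.index, "expression": series.values})
    df.to_csv(path, sep="\t", index=False)


def read_tf_table(path: str) -> pd.DataFrame:
    """TF annotation: tf_id, gene_id (encoding gene), is_repressor_only flag."""
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "gene_id": str})
    required = {"tf_id", "gene_id", "is_repressor_only"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["is_repressor_only"] = df["is_repressor_only"].astype(bool)
    return df.set_index("tf_id", drop=False)


def write_profiles(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, columns=PROFILE_COLUMNS, float_format="%.10g")


def read_profiles(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gene_id": str, "tf_id": str, "repressor_id": str})
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["repressor_id"] = df["repressor_id"].fillna("")
    return df


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
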