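"""Readers, writers, marker filtering and marker-to-gene assignment.

Coordinate conventions: VCF and GFF3 input are 1-based; BED input is
0-based half-open; everything internal is 0-based half-open.  Gene
windows extend the half-open gene interval by ``window_bp`` on each
side, so a marker at 0-based position p maps to gene [s, e) iff
s - w <= p < e + w.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .models import DIETS, PHENOTYPE_COLUMNS, GeneModel, GenotypePanel, Marker, PhenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | os.PathLike, format: str | None = None) -> GenotypePanel:
    """Read a genotype panel from VCF 4.x or the TSV dialect.

    Heterozygous VCF calls are mapped to missing (the panel is inbred;
    the diallelic-homozygous model has no het state); the count is
    logged.  Multi-allelic records are rejected with a warning.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypePanel:
    # check the sample columns ourselves: htslib rejects sample-less VCFs
    # with an opaque parse error
    with open(path) as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                if len(line.rstrip("\n").split("\t")) <= 9:
                    raise ValueError(f"{path}: VCF has zero samples")
                break
    vcf = VCF(str(path), gts012=True)
    lines = list(vcf.samples)
    if not lines:
        raise ValueError(f"{path}: VCF has zero samples")
    markers: list[Marker] = []
    columns: list[np.ndarray] = []
    n_het = 0
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            logger.warning("%s: skipping multi-allelic record at %s:%d", path, rec.CHROM, rec.POS)
            continue
        # with gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = rec.gt_types
        col = np.full(len(lines), np.nan)
        col[gt == 0] = 0.0
        col[gt == 2] = 1.0
        het = gt == 1
        n_het += int(het.sum())
        if np.isnan(col).all():
            logger.warning("%s: all-missing record at %s:%d skipped", path, rec.CHROM, rec.POS)
            continue
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        markers.append(Marker(mid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        columns.append(col)
    if n_het:
        logger.info("%s: %d heterozygous calls treated as missing", path, n_het)
    calls = np.column_stack(columns) if columns else np.empty((len(lines), 0))
    return GenotypePanel(lines, markers, calls)


def _read_genotype_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=["NA"])
    if df.shape[0] == 0:
        raise ValueError(f"{path}: genotype TSV has zero lines")
    calls = df.to_numpy(dtype=float)
    markers = []
    for j, mid in enumerate(df.columns):
        chrom, pos = _marker_locus(str(mid), default_pos=j + 1)
        markers.append(Marker(str(mid), chrom, pos))
    return GenotypePanel([str(x) for x in df.index], markers, calls)


def _marker_locus(marker_id: str, default_pos: int) -> tuple[str, int]:
    """Best-effort chrom:pos from a "chrom:pos"-style marker id."""
    if ":" in marker_id:
        chrom, _, rest = marker_id.partition(":")
        pos = rest.split("_")[0]
        if pos.isdigit():
            return chrom, int(pos)
    return "un", default_pos


def write_genotypes(panel: GenotypePanel, path: str | os.PathLike, format: str = "vcf") -> None:
    """Write a panel as minimal VCF 4.2 or as the TSV dialect."""
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(panel.calls, index=panel.lines, columns=panel.marker_ids())
        out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        out.index.name = "line"
        out.to_csv(path, sep="\t")
        return
    if format != "vcf":
        raise ValueError(f"unknown genotype format: {format!r}")
    order = sorted(range(panel.n_markers), key=lambda i: (panel.markers[i].chrom, panel.markers[i].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({m.chrom for m in panel.markers}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.lines) + "\n")
        gt_map = {0.0: "0/0", 1.0: "1/1"}
        for j in order:
            m = panel.markers[j]
            gts = "\t".join(gt_map.get(v, "./.") for v in panel.calls[:, j])
            fh.write(f"{m.chrom}\t{m.pos}\t{m.id}\t{m.ref_allele}\t{m.alt_allele}\t.\t.\t.\tGT\t{gts}\n")


def filter_by_maf(panel: GenotypePanel, min_maf: float) -> GenotypePanel:
    """Retain exactly the markers with minor allele frequency >= min_maf."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    keep = np.flatnonzero(panel.maf() >= min_maf) if panel.n_markers else np.array([], dtype=int)
    if panel.n_markers and keep.size == 0:
        logger.warning("MAF filter at %.3f removed all %d markers", min_maf, panel.n_markers)
    return panel.subset_markers(keep)


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "diet": str, "trait": str})
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | os.PathLike) -> None:
    table.df[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models and annotations


def read_gene_models(
    path: str | os.PathLike,
    format: str | None = None,
    homolog_flags: str | os.PathLike | None = None,
) -> list[GeneModel]:
    """Read gene intervals from GFF3 (``gene`` features) or BED6.

    The disease-homolog flag comes from a GFF3 ``disease_homolog=1``
    attribute, or from a supplementary 2-column TSV (gene_id, 0/1)
    which overrides anything in the GFF3.
    """
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix == ".bed" else "gff3"
    if format == "gff3":
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            flag = feat.attributes.get("disease_homolog", ["0"])[0] == "1"
            genes.append(GeneModel(feat.id, feat.seqid, feat.start - 1, feat.end, flag))
    elif format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
        genes = [
            GeneModel(str(r.name), str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)
        ]
    else:
        raise ValueError(f"unknown gene-model format: {format!r}")
    if homolog_flags is not None:
        flags = pd.read_csv(homolog_flags, sep="\t", header=None, names=["gene", "flag"])
        flag_map = dict(zip(flags["gene"].astype(str), flags["flag"].astype(int)))
        for g in genes:
            if g.id in flag_map:
                g.is_disease_homolog = bool(flag_map[g.id])
    return genes


def write_gene_models(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Write genes as GFF3 with the disease_homolog attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.id)):
            attrs = f"ID={g.id};disease_homolog={int(g.is_disease_homolog)}"
            fh.write(f"{g.chrom}\tcrossphen\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t{attrs}\n")


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    """Gene-to-term annotation pairs: 2-column TSV (gene_id, term_id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    return df.drop_duplicates().reset_index(drop=True)


def write_annotations(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["gene", "term"]].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# marker -> gene assignment


def assign_markers_to_genes(
    panel: GenotypePanel, genes: list[GeneModel], window_bp: int = 1000
) -> dict[str, set[str]]:
    """Map each marker to the genes whose windowed interval contains it.

    A marker at 1-based position p (0-based p-1) is assigned to every
    gene on the same chromosome with start - window_bp <= p-1 <
    end + window_bp.  Markers may map to several genes or to none;
    unmapped markers are simply absent from the result.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.start, g.end, g.id))
        starts[chrom] = np.array([g.start - window_bp for g in gs])
        ends[chrom] = np.array([g.end + window_bp for g in gs])
    out: dict[str, set[str]] = {}
    for m in panel.markers:
        gs = by_chrom.get(m.chrom)
        if gs is None:
            continue
        p = m.pos - 1
        hit = (starts[m.chrom] <= p) & (p < ends[m.chrom])
        if hit.any():
            out[m.id] = {gs[i].id for i in np.flatnonzero(hit)}
    return out


def homolog_marker_subset(
    panel: GenotypePanel, genes: list[GeneModel], window_bp: int = 1000
) -> GenotypePanel:
    """Restrict the panel to markers within window_bp of a flagged gene."""
    flagged = [g for g in genes if g.is_disease_homolog]
    assignment = assign_markers_to_genes(panel, flagged, window_bp)
    keep = [j for j, m in enumerate(panel.markers) if m.id in assignment]
    return panel.subset_markers(np.array(keep, dtype=int))
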