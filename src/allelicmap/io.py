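"""Readers and writers for the pipeline's standard formats.

FASTA through Biopython, VCF 4.2 through pysam (site-only records carrying
total depth in INFO/DP and alternate-supporting reads in INFO/AO), GFF3
parsing through gffutils, and plain TSV for the allele-frequency panel and
truth tables. All genomic coordinates on disk are 1-based per the formats.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .filtering import BackgroundPanel, VariantCall
from .genome import GeneModel, ToyGenome

logger = logging.getLogger(__name__)


class VcfFormatError(ValueError):
    """Malformed or incomplete VCF input."""


class GffValidationError(ValueError):
    """GFF3 gene model violates the single-transcript model contract."""


class PanelFormatError(ValueError):
    """Malformed allele-frequency panel row."""


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: ToyGenome, path) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=c.name, description="") for c in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3


def _cds_phases(gene: GeneModel) -> dict[tuple[int, int], int]:
    """GFF3 phase per CDS interval, accumulated in transcript order."""
    order = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    phases = {}
    cum = 0
    for a, b in order:
        phases[(a, b)] = (3 - cum % 3) % 3
        cum += b - a + 1
    return phases


def write_gff3(genes: list[GeneModel], path, source: str = "allelicmap") -> None:
    """Emit gene / mRNA / exon / CDS features, one transcript per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            rna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={rna_id};Parent={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={rna_id}.exon{i};Parent={rna_id}\n"
                )
            phases = _cds_phases(g)
            for i, (a, b) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{a}\t{b}\t.\t{g.strand}\t{phases[(a, b)]}\t"
                    f"ID={rna_id}.cds{i};Parent={rna_id}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Parse single-transcript gene models and validate the model contract."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        if len(mrnas) > 1:
            raise GffValidationError(f"{gene.id}: multiple transcripts not supported")
        exons = sorted((f.start, f.end) for f in db.children(parent, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(parent, featuretype="CDS"))
        model = GeneModel(gene.id, gene.seqid, gene.strand, exons, cds)
        try:
            model.validate()
        except ValueError as exc:
            raise GffValidationError(str(exc)) from exc
        genes.append(model)
    return genes


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_meta(
        "INFO", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                       ("Description", "Total read depth at the locus")],
    )
    header.add_meta(
        "INFO", items=[("ID", "AO"), ("Number", "1"), ("Type", "Integer"),
                       ("Description", "Reads supporting the alternate allele")],
    )
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    return header


def write_vcf(variants, path, contigs: dict[str, int]) -> None:
    """Write site-only VCF 4.2 records with INFO DP/AO.

    ``variants`` is a DataFrame with chrom/pos/ref/alt/total_depth/alt_depth
    columns or an iterable of VariantCall.
    """
    if isinstance(variants, pd.DataFrame):
        rows = [
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
             int(r.total_depth), int(r.alt_depth))
            for r in variants.itertuples(index=False)
        ]
    else:
        rows = [(v.chrom, v.pos, v.ref, v.alt, v.total_depth, v.alt_depth) for v in variants]
    order = {name: i for i, name in enumerate(contigs)}
    rows.sort(key=lambda r: (order[r[0]], r[1]))
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for chrom, pos, ref, alt, dp, ao in rows:
            rec = vf.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            rec.info["DP"] = dp
            rec.info["AO"] = ao
            vf.write(rec)


def _prescan_vcf(path) -> None:
    """Cheap structural check so truncated files fail with a line number."""
    with open(path) as fh:
        last = None
        for lineno, line in enumerate(fh, 1):
            last = (lineno, line)
            if line.startswith("#"):
                continue
            if line.endswith("\n") and len(line.rstrip("\n").split("\t")) < 8:
                raise VcfFormatError(f"{path}: line {lineno}: fewer than 8 VCF columns")
        if last is not None and not last[1].endswith("\n"):
            raise VcfFormatError(f"{path}: line {last[0]}: truncated record (no newline)")


def read_vcf(path) -> list[VariantCall]:
    """Read pooled variant calls; every record must carry INFO DP and AO.

    Multi-allelic records are skipped with a warning; records lacking depth
    information are rejected with their locus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_vcf(path)
    calls: list[VariantCall] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vf:
        for i, rec in enumerate(vf, 1):
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning("%s: record %d (%s:%d) is not biallelic; skipped",
                               path.name, i, rec.chrom, rec.pos)
                continue
            dp = rec.info.get("DP")
            ao = rec.info.get("AO")
            if dp is None or ao is None:
                raise VcfFormatError(
                    f"{path}: record {i} at {rec.chrom}:{rec.pos} lacks INFO DP/AO"
                )
            calls.append(
                VariantCall(rec.chrom, rec.pos, rec.ref, rec.alts[0], int(dp), int(ao))
            )
    return calls


# ---------------------------------------------------------------------------
# allele-frequency panel & tables

_PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "af"]


def write_af_panel(panel: pd.DataFrame, path) -> None:
    panel.loc[:, _PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_af_panel(path) -> dict[tuple[str, int, str, str], float]:
    """Keyed allele-frequency map; duplicate keys or out-of-range af are errors."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    if list(df.columns) != _PANEL_COLUMNS:
        raise PanelFormatError(
            f"{path}: expected columns {_PANEL_COLUMNS}, found {list(df.columns)}"
        )
    out: dict[tuple[str, int, str, str], float] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # 1-based, after the header line
        try:
            key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
            af = float(row.af)
        except (TypeError, ValueError) as exc:
            raise PanelFormatError(f"{path}: line {lineno}: malformed row: {exc}") from exc
        if not 0.0 <= af <= 1.0:
            raise PanelFormatError(f"{path}: line {lineno}: af {af} outside [0, 1]")
        if key in out:
            raise PanelFormatError(f"{path}: line {lineno}: duplicate key {key}")
        out[key] = af
    return out


def load_background_panel(parent_vcf, panel_tsv) -> BackgroundPanel:
    parental = frozenset(v.key for v in read_vcf(parent_vcf)) if parent_vcf else frozenset()
    population_af = read_af_panel(panel_tsv) if panel_tsv else {}
    return BackgroundPanel(parental, population_af)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
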