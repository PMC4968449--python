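"""Domain types and readers/writers for the external formats consumed by the
pipeline: multi-sample VCF with CSQ consequence annotations, GFF3/GTF/BED gene
models, GMT pathway gene sets and tabular genotype panels.

Coordinates are 1-based inclusive internally (VCF convention); BED inputs are
converted on read. Multi-allelic VCF rows are decomposed into one
:class:`SiteRecord` per alternate allele, with genotype semantics preserved
per allele.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

SiteKey = tuple  # (chrom, pos, ref, alt)


class GTClass(enum.Enum):
    """Per-strain genotype classification at a decomposed site."""

    HOM_REF_HQ = "HOM_REF_HQ"
    HOM_ALT_HQ = "HOM_ALT_HQ"
    HET_HQ = "HET_HQ"
    LOW_QUALITY = "LOW_QUALITY"
    MISSING = "MISSING"


class VariantClass(enum.Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class QualityConfig:
    """Thresholds operationalising a "high quality" genotype call.

    A call is high quality when the site passed all soft filters and the
    per-sample genotype quality is at least ``min_gq``. Records with no GQ
    field fall back to the filter status alone.
    """

    min_gq: float = 20.0
    require_pass: bool = True


@dataclass(frozen=True)
class GenotypeCall:
    """One strain's classified genotype at one decomposed site."""

    strain: str
    gt_class: GTClass
    raw_gt: Optional[tuple] = None  # allele-index pair, None when missing
    gq: Optional[float] = None
    passed_filters: bool = True

    def __post_init__(self):
        if self.gt_class is GTClass.MISSING and self.raw_gt is not None:
            raise ValueError("MISSING call must have unset raw_gt")
        if self.gt_class is not GTClass.MISSING and self.raw_gt is None:
            raise ValueError(f"{self.gt_class} call requires raw_gt")
        if self.gt_class in (GTClass.HOM_REF_HQ, GTClass.HOM_ALT_HQ):
            a, b = self.raw_gt
            if a != b:
                raise ValueError("homozygous class requires equal allele indices")


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """A VEP-style consequence of one variant on one transcript."""

    gene_id: str
    transcript_id: str
    terms: frozenset
    aa_ref: str = ""
    aa_pos: Optional[int] = None
    aa_alt: str = ""
    sift_score: Optional[float] = None
    sift_call: Optional[str] = None  # "tolerated" | "deleterious"

    def __post_init__(self):
        if "missense_variant" in self.terms and not (self.aa_ref and self.aa_alt):
            raise ValueError("missense annotation requires aa_ref and aa_alt")
        if self.sift_score is not None and not (0.0 <= self.sift_score <= 1.0):
            raise ValueError(f"SIFT score {self.sift_score} outside [0,1]")
        if self.sift_call is not None and self.sift_call not in ("tolerated", "deleterious"):
            raise ValueError(f"bad sift_call {self.sift_call!r}")


@dataclass
class SiteRecord:
    """One (chrom, pos, ref, alt) site with one call per panel strain."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: VariantClass
    calls: dict  # strain -> GenotypeCall
    annotations: list = field(default_factory=list)

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def call_for(self, strain: str) -> GenotypeCall:
        return self.calls[strain]


@dataclass
class GeneModel:
    """A gene with its normalised (merged, sorted) CDS intervals."""

    gene_id: str
    chrom: str
    cds_intervals: list  # list of (start, end), 1-based inclusive

    def __post_init__(self):
        self.cds_intervals = normalize_intervals(self.cds_intervals)


@dataclass(frozen=True)
class PathwaySet:
    pathway_id: str
    name: str
    database: str  # "KEGG" | "REACTOME" | "other"
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id}: empty gene set")


def classify_variant(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNP
    if len(ref) > len(alt):
        return VariantClass.DEL
    if len(ref) < len(alt):
        return VariantClass.INS
    raise ValueError(f"unsupported allele pair {ref}>{alt} (MNP?)")


def normalize_intervals(intervals: Iterable[tuple]) -> list:
    """Sort 1-based inclusive intervals and merge overlapping/abutting ones."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"interval start {s} > end {e}")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def classify_genotype(
    raw_gt: Optional[tuple],
    alt_index: int,
    gq: Optional[float],
    passed_filters: bool,
    quality: QualityConfig,
) -> GTClass:
    """Classify one sample's genotype relative to one decomposed ALT allele.

    ``raw_gt`` is the allele-index pair from the original (undecomposed) row;
    ``alt_index`` is the 1-based ALT index this SiteRecord represents. A
    homozygote for a *different* ALT of the same row is classed HET_HQ: the
    site segregates another allele, so it is neither reference evidence nor
    alt-homozygous for this record.
    """
    if raw_gt is None or raw_gt[0] < 0 or raw_gt[1] < 0:
        return GTClass.MISSING
    if quality.require_pass and not passed_filters:
        return GTClass.LOW_QUALITY
    if gq is not None and gq < quality.min_gq:
        return GTClass.LOW_QUALITY
    a, b = raw_gt
    if a == b == alt_index:
        return GTClass.HOM_ALT_HQ
    if a == b == 0:
        return GTClass.HOM_REF_HQ
    return GTClass.HET_HQ


# ---------------------------------------------------------------------------
# CSQ annotation parsing
# ---------------------------------------------------------------------------

CSQ_FIELDS = ("Gene", "Feature", "Consequence", "Amino_acids", "Protein_position", "SIFT")


def parse_csq_entry(entry: str) -> Optional[ConsequenceAnnotation]:
    """Parse one pipe-delimited CSQ entry (Gene|Feature|Consequence|Amino_acids|Protein_position|SIFT)."""
    parts = entry.split("|")
    if len(parts) < 3:
        return None
    gene, feature, cons = parts[0], parts[1], parts[2]
    aa = parts[3] if len(parts) > 3 else ""
    aa_pos_s = parts[4] if len(parts) > 4 else ""
    sift = parts[5] if len(parts) > 5 else ""
    terms = frozenset(t for t in cons.split("&") if t)
    aa_ref = aa_alt = ""
    if aa and "/" in aa:
        aa_ref, aa_alt = aa.split("/", 1)
    elif aa:
        aa_ref = aa_alt = aa
    aa_pos = int(aa_pos_s) if aa_pos_s.isdigit() else None
    sift_call = sift_score = None
    if sift:
        if "(" in sift:
            call, score_s = sift.rstrip(")").split("(", 1)
            sift_call = call or None
            try:
                sift_score = float(score_s)
            except ValueError:
                sift_score = None
        else:
            try:
                sift_score = float(sift)
            except ValueError:
                sift_call = sift
    return ConsequenceAnnotation(
        gene_id=gene,
        transcript_id=feature,
        terms=terms,
        aa_ref=aa_ref,
        aa_pos=aa_pos,
        aa_alt=aa_alt,
        sift_score=sift_score,
        sift_call=sift_call,
    )


def format_csq_entry(ann: ConsequenceAnnotation) -> str:
    aa = f"{ann.aa_ref}/{ann.aa_alt}" if ann.aa_ref or ann.aa_alt else ""
    pos = str(ann.aa_pos) if ann.aa_pos is not None else ""
    sift = ""
    if ann.sift_call is not None and ann.sift_score is not None:
        sift = f"{ann.sift_call}({ann.sift_score:g})"
    elif ann.sift_call is not None:
        sift = ann.sift_call
    elif ann.sift_score is not None:
        sift = f"({ann.sift_score:g})"
    return "|".join([ann.gene_id, ann.transcript_id, "&".join(sorted(ann.terms)), aa, pos, sift])


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_multistrain_vcf(
    path,
    panel: Sequence[str],
    quality_config: QualityConfig = QualityConfig(),
) -> Iterator[SiteRecord]:
    """Stream decomposed SiteRecords from a multi-sample VCF.

    Every panel strain must be a sample column; a missing strain is a fatal
    configuration error. Multi-allelic rows yield one record per ALT allele,
    in ALT order, so record count equals the total ALT allele count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing = [s for s in panel if s not in samples]
    if missing:
        raise ValueError(f"panel strain(s) absent from VCF: {', '.join(missing)}")
    idx = [samples.index(s) for s in panel]

    for var in vcf:
        passed = var.FILTER is None or var.FILTER == "PASS"
        gts = var.genotypes  # [a, b, phased] per sample
        try:
            gqs = var.format("GQ")
        except KeyError:
            gqs = None
        anns = []
        csq = var.INFO.get("CSQ")
        if csq:
            for entry in str(csq).split(","):
                ann = parse_csq_entry(entry)
                if ann is not None:
                    anns.append(ann)
        for ai, alt in enumerate(var.ALT, start=1):
            try:
                vclass = classify_variant(var.REF, alt)
            except ValueError as exc:
                raise ValueError(f"{path}: bad row at {var.CHROM}:{var.POS}: {exc}") from exc
            calls = {}
            for strain, si in zip(panel, idx):
                g = gts[si]
                raw = (g[0], g[1])
                gq = None
                if gqs is not None:
                    val = float(gqs[si][0] if hasattr(gqs[si], "__len__") else gqs[si])
                    if val >= 0:  # cyvcf2 encodes missing GQ as negative sentinel
                        gq = val
                cls = classify_genotype(raw, ai, gq, passed, quality_config)
                calls[strain] = GenotypeCall(
                    strain=strain,
                    gt_class=cls,
                    raw_gt=None if cls is GTClass.MISSING else raw,
                    gq=gq,
                    passed_filters=passed,
                )
            yield SiteRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alt,
                vclass=vclass,
                calls=calls,
                annotations=anns,
            )


VCF_HEADER_TEMPLATE = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=LowQual,Description="Failed soft filters">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations: {fields}">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
"""


def write_multistrain_vcf(path, records: Iterable[SiteRecord], panel: Sequence[str], contigs=None):
    """Write SiteRecords as a plain-text biallelic multi-sample VCF.

    Output is deterministic: no timestamps, fixed field order. Round-tripping
    through :func:`read_multistrain_vcf` reproduces genotype classifications.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER_TEMPLATE.format(fields="|".join(CSQ_FIELDS)))
        for name, length in contigs or []:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel) + "\n")
        for rec in records:
            info = "."
            if rec.annotations:
                info = "CSQ=" + ",".join(format_csq_entry(a) for a in rec.annotations)
            passed = all(c.passed_filters for c in rec.calls.values())
            fields = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                rec.alt,
                ".",
                "PASS" if passed else "LowQual",
                info,
                "GT:GQ",
            ]
            for strain in panel:
                call = rec.calls[strain]
                if call.gt_class is GTClass.MISSING:
                    fields.append("./.:.")
                else:
                    a, b = call.raw_gt
                    gq = "." if call.gq is None else str(int(call.gq))
                    fields.append(f"{a}/{b}:{gq}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def read_gene_models(path) -> list:
    """Read gene models with CDS intervals from GFF3/GTF or 6-column BED.

    BED rows carry gene_id in the name column and are converted from 0-based
    half-open to 1-based inclusive. CDS features without gene attribution are
    skipped with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return _read_gene_models_bed(path)
    return _read_gene_models_gff(path)


def _read_gene_models_bed(path) -> list:
    per_gene: dict = {}
    n = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                warnings.warn(f"{path}:{ln}: BED row lacks a name (gene_id) field; skipped")
                continue
            chrom, start0, end0, gene_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            per_gene.setdefault((gene_id, chrom), []).append((start0 + 1, end0))
            n += 1
    if n == 0:
        warnings.warn(f"{path}: no gene model intervals found")
    return [
        GeneModel(gene_id=g, chrom=c, cds_intervals=ivs)
        for (g, c), ivs in sorted(per_gene.items())
    ]


def _read_gene_models_gff(path) -> list:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    per_gene: dict = {}
    n = 0
    for cds in db.features_of_type("CDS"):
        gene_id = None
        if "gene_id" in cds.attributes:
            gene_id = cds.attributes["gene_id"][0]
        else:
            for parent in db.parents(cds, featuretype="gene"):
                gene_id = parent.id
                break
            if gene_id is None and "Parent" in cds.attributes:
                p = cds.attributes["Parent"][0]
                if p.startswith("gene:"):
                    gene_id = p.split(":", 1)[1]
        if gene_id is None:
            warnings.warn(f"{path}: CDS at {cds.seqid}:{cds.start} without gene attribution; skipped")
            continue
        per_gene.setdefault((gene_id, cds.seqid), []).append((cds.start, cds.end))
        n += 1
    if n == 0:
        warnings.warn(f"{path}: no CDS features found")
    return [
        GeneModel(gene_id=g, chrom=c, cds_intervals=ivs)
        for (g, c), ivs in sorted(per_gene.items())
    ]


# ---------------------------------------------------------------------------
# GMT pathway sets
# ---------------------------------------------------------------------------


def read_gmt(path, database: str = "other") -> list:
    """Read a GMT file: one pathway per line, name<TAB>description<TAB>genes..."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            name, _desc = parts[0], parts[1]
            genes = []
            seen = set()
            for g in parts[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise ValueError(f"{path}:{ln}: GMT line has an empty gene list")
            db = database
            for known in ("KEGG", "REACTOME"):
                if name.upper().startswith(known):
                    db = known
            out.append(PathwaySet(pathway_id=name, name=name, database=db, genes=frozenset(genes)))
    return out


def write_gmt(path, pathways: Iterable[PathwaySet]):
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name] + sorted(pw.genes)) + "\n")


# ---------------------------------------------------------------------------
# Genotype panel TSV (chrom, pos, strain, genotype)
# ---------------------------------------------------------------------------


def read_genotype_panel_tsv(path) -> list:
    """Read panel entries (chrom, pos, strain, allele-pair); rows with a
    missing genotype ('.', './.', 'NA' or empty) are dropped on load."""
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.lower() for h in header[:4]] != ["chrom", "pos", "strain", "genotype"]:
            raise ValueError(f"{path}: expected header chrom<TAB>pos<TAB>strain<TAB>genotype")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, pos, strain, gt = line.split("\t")[:4]
            if gt in (".", "./.", "NA", ""):
                continue
            alleles = tuple(gt.split("/")) if "/" in gt else (gt, gt)
            entries.append((chrom, int(pos), strain, alleles))
    return entries


def write_genotype_panel_tsv(path, entries):
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrain\tgenotype\n")
        for chrom, pos, strain, alleles in entries:
            fh.write(f"{chrom}\t{pos}\t{strain}\t{alleles[0]}/{alleles[1]}\n")
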