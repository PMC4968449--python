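"""Candidate-gene discovery pipelines.

Two routes, matching the two study designs supported here:

* private-missense: all genes carrying a missense variant private to a
  focal strain;
* strain subtraction: a target strain's hom-alt SNPs minus those shared with
  any exclude strain, optionally restricted to SIFT-deleterious missense
  variants, mapped to genes.

"Shared" means the exclude strain is HOM_ALT_HQ for the identical
(chrom, pos, ref, alt); a missing or low-quality exclude-strain genotype
does not remove a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .consequence_scoring import SiftClass, classify_sift, try_grantham_score
from .genotype_catalog import PrivacyRule, StrainGenotypeMatrix, identify_private_variants
from .variant_model import GTClass, VariantClass


@dataclass
class CandidateGeneSet:
    focal_strain: str
    comparator_strains: list
    snp_keys: list
    genes: set
    filter_spec: dict = field(default_factory=dict)


def private_missense_gene_set(
    matrix: StrainGenotypeMatrix,
    strain: str,
    rule: PrivacyRule = PrivacyRule(),
) -> CandidateGeneSet:
    """Genes containing a missense variant private to ``strain``."""
    if strain not in matrix.strains:
        raise ValueError(f"strain {strain!r} absent from panel")
    private = identify_private_variants(matrix, rule, VariantClass.SNP)[strain]
    keys, genes = [], set()
    for key in private:
        rec = matrix.get(key)
        hit = [a for a in rec.annotations if "missense_variant" in a.terms]
        if hit:
            keys.append(key)
            genes.update(a.gene_id for a in hit)
    return CandidateGeneSet(
        focal_strain=strain,
        comparator_strains=[s for s in matrix.strains if s != strain],
        snp_keys=keys,
        genes=genes,
        filter_spec={
            "pipeline": "private_missense",
            "rule": {"min_homref_others": rule.min_homref_others,
                     "max_missing_lq": rule.max_missing_lq},
            "terms": ["missense_variant"],
        },
    )


def subtraction_candidate_set(
    matrix: StrainGenotypeMatrix,
    target: str,
    exclude_strains: list,
    require_deleterious: bool = True,
) -> CandidateGeneSet:
    """Target-specific SNP set by subtraction of shared variation.

    Starts from the target's HOM_ALT_HQ SNPs, removes any site where any
    exclude strain is HOM_ALT_HQ for the same alternate allele, then (when
    ``require_deleterious``) keeps only sites with at least one missense
    annotation classified SIFT-deleterious.
    """
    if target in exclude_strains:
        raise ValueError(f"target {target!r} listed among exclude strains")
    for s in [target, *exclude_strains]:
        if s not in matrix.strains:
            raise ValueError(f"strain {s!r} absent from panel")

    keys, genes = [], set()
    for rec in matrix.sites:
        if rec.vclass is not VariantClass.SNP:
            continue
        if rec.calls[target].gt_class is not GTClass.HOM_ALT_HQ:
            continue
        if any(rec.calls[s].gt_class is GTClass.HOM_ALT_HQ for s in exclude_strains):
            continue
        missense = [a for a in rec.annotations if "missense_variant" in a.terms]
        if require_deleterious:
            missense = [a for a in missense if classify_sift(a) is SiftClass.DELETERIOUS]
            if not missense:
                continue
        keys.append(rec.key)
        genes.update(a.gene_id for a in missense)
    keys.sort(key=lambda k: (k[0], k[1], k[2], k[3]))
    return CandidateGeneSet(
        focal_strain=target,
        comparator_strains=list(exclude_strains),
        snp_keys=keys,
        genes=genes,
        filter_spec={
            "pipeline": "subtraction",
            "exclude_strains": list(exclude_strains),
            "require_deleterious": require_deleterious,
        },
    )


def candidate_table(matrix: StrainGenotypeMatrix, cand: CandidateGeneSet) -> pd.DataFrame:
    """Per-annotation TSV rows for a candidate set (site key, gene,
    transcript, consequence, SIFT, substitution score)."""
    rows = []
    for key in cand.snp_keys:
        rec = matrix.get(key)
        for ann in rec.annotations:
            if "missense_variant" not in ann.terms:
                continue
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "gene": ann.gene_id,
                    "transcript": ann.transcript_id,
                    "consequence": "&".join(sorted(ann.terms)),
                    "sift_score": ann.sift_score,
                    "sift_class": classify_sift(ann).value,
                    "gms": try_grantham_score(ann.aa_ref, ann.aa_alt),
                }
            )
    return pd.DataFrame(rows)


def write_gene_list(path, cand: CandidateGeneSet):
    """Plain gene-list text file consumable by the ORA stage."""
    with open(path, "w") as fh:
        for gene in sorted(cand.genes):
            fh.write(gene + "\n")


def read_gene_list(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
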