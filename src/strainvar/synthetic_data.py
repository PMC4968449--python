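"""Seeded generators for every pipeline input, with planted ground truth.

Each generator draws from an independent substream derived from one global
seed, so datasets can be regenerated in isolation. All outputs are
deterministic: the same seed yields byte-identical files.

The synthetic genome is two 10-Mb chromosomes with declared assembly-gap and
telomere/centromere tracks so that SV proximity filters are exercisable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotype_catalog import PrivacyRule
from .sv_toolkit import StructuralVariant
from .variant_model import (
    ConsequenceAnnotation,
    GenotypeCall,
    GTClass,
    SiteRecord,
    VariantClass,
)

CHROMS = (("chr1", 10_000_000), ("chr2", 10_000_000))
# declared genome tracks (1-based inclusive)
ASSEMBLY_GAPS = (("chr1", 4_000_001, 4_010_000), ("chr2", 6_500_001, 6_505_000))
TELOMERE_CENTROMERE = tuple(
    (name, s, e)
    for name, length in CHROMS
    for s, e in ((1, 10_000), (length - 9_999, length))
)

_BASES = ("A", "C", "G", "T")

# substream indices per generator
_STREAM_PANEL = 0
_STREAM_ANNOT = 1
_STREAM_SV = 2
_STREAM_PATHWAY = 3
_STREAM_CONCORD = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def default_strain_names(n: int) -> list:
    return [f"STR{i:02d}" for i in range(1, n + 1)]


def _clades_from_tree(tree) -> list:
    """All internal-node leaf sets with >= 2 leaves from a nested grouping."""
    clades = []

    def walk(node):
        if isinstance(node, str):
            return [node]
        leaves = []
        for child in node:
            leaves.extend(walk(child))
        if len(leaves) >= 2:
            clades.append(tuple(leaves))
        return leaves

    walk(tree)
    return clades


def _balanced_tree(strains: Sequence[str]):
    if len(strains) <= 2:
        return list(strains)
    mid = len(strains) // 2
    return [_balanced_tree(strains[:mid]), _balanced_tree(strains[mid:])]


def _hq(strain: str, gt, gq: float = 60.0) -> GenotypeCall:
    cls = {(0, 0): GTClass.HOM_REF_HQ, (1, 1): GTClass.HOM_ALT_HQ}.get(gt, GTClass.HET_HQ)
    return GenotypeCall(strain=strain, gt_class=cls, raw_gt=gt, gq=gq, passed_filters=True)


def _lq(strain: str, gt) -> GenotypeCall:
    return GenotypeCall(strain=strain, gt_class=GTClass.LOW_QUALITY, raw_gt=gt, gq=5.0,
                        passed_filters=True)


def _missing(strain: str) -> GenotypeCall:
    return GenotypeCall(strain=strain, gt_class=GTClass.MISSING, raw_gt=None, gq=None,
                        passed_filters=True)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset."""

    seed: int
    params: dict
    data: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "params": self.params, "data": self.data},
                      fh, indent=1, sort_keys=True, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(seed=obj["seed"], params=obj["params"], data=obj["data"])


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Strain panel
# ---------------------------------------------------------------------------


def simulate_strain_panel(
    n_strains: int,
    n_sites: int,
    n_private_per_strain: int,
    sharing_tree=None,
    missing_rate: float = 0.0,
    lowqual_rate: float = 0.0,
    het_rate: float = 0.0,
    indel_fraction: float = 0.0,
    rule: Optional[PrivacyRule] = None,
    seed: int = 0,
):
    """Generate a multi-strain genotype panel with planted private variants.

    Shared variants are assigned to clades of the sharing tree (shared
    homozygous blocks of common ancestry); private variants are HOM_ALT_HQ in
    exactly one strain. Missing/low-quality/het noise is injected at the
    stated per-call rates on non-carrier strains, but never on the focal
    strain of a planted private site. The truth records, per site, the
    privacy verdict under ``rule`` evaluated from the final injected calls.

    Returns (records, strains, truth).
    """
    if n_private_per_strain * n_strains > n_sites:
        raise ValueError("n_private_per_strain * n_strains exceeds n_sites")
    combined = missing_rate + lowqual_rate + het_rate
    if combined > 1.0 or min(missing_rate, lowqual_rate, het_rate) < 0:
        raise ValueError("noise rates must be non-negative and sum to <= 1")
    strains = default_strain_names(n_strains)
    if rule is None:
        rule = PrivacyRule.for_panel(n_strains)
    rule.validate_for_panel(n_strains)
    clades = _clades_from_tree(sharing_tree if sharing_tree is not None
                               else _balanced_tree(strains))
    rng = _rng(seed, _STREAM_PANEL)

    # distinct positions across the genome, in coordinate order
    per_chrom = np.array_split(np.arange(n_sites), len(CHROMS))
    positions = []
    for (chrom, length), idx in zip(CHROMS, per_chrom):
        pos = np.sort(rng.choice(np.arange(50_000, length - 50_000), size=len(idx),
                                 replace=False))
        positions.extend((chrom, int(p)) for p in pos)

    # which sites are private, and to whom (spread deterministically)
    site_order = rng.permutation(n_sites)
    private_owner = {}
    i = 0
    for strain in strains:
        for _ in range(n_private_per_strain):
            private_owner[int(site_order[i])] = strain
            i += 1

    records = []
    truth_private: dict = {s: [] for s in strains}
    expected_private: dict = {s: [] for s in strains}
    for si, (chrom, pos) in enumerate(positions):
        ref_i = int(rng.integers(4))
        alt_i = int((ref_i + 1 + rng.integers(3)) % 4)
        ref, alt = _BASES[ref_i], _BASES[alt_i]
        if indel_fraction > 0 and rng.random() < indel_fraction:
            if rng.random() < 0.5:
                ref = ref + _BASES[int(rng.integers(4))]  # DEL
            else:
                alt = alt + _BASES[int(rng.integers(4))]  # INS
        vclass = (VariantClass.SNP if len(ref) == len(alt) == 1
                  else VariantClass.DEL if len(ref) > len(alt) else VariantClass.INS)

        owner = private_owner.get(si)
        if owner is not None:
            carriers = {owner}
        else:
            carriers = set(clades[int(rng.integers(len(clades)))])

        calls = {}
        for strain in strains:
            carrier = strain in carriers
            protected = owner is not None and strain == owner
            u = rng.random()  # always consumed: keeps the stream aligned
            if not protected and u < missing_rate:
                calls[strain] = _missing(strain)
            elif not protected and u < missing_rate + lowqual_rate:
                calls[strain] = _lq(strain, (1, 1) if carrier else (0, 0))
            elif not protected and u < combined:
                calls[strain] = _hq(strain, (0, 1))
            else:
                calls[strain] = _hq(strain, (1, 1) if carrier else (0, 0))
        rec = SiteRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, vclass=vclass, calls=calls)
        records.append(rec)
        if owner is not None:
            truth_private[owner].append(list(rec.key))
        # brute-force verdict under the rule, from the injected calls
        verdict = _privacy_verdict(rec, strains, rule)
        if verdict is not None:
            expected_private[verdict].append(list(rec.key))

    for d in (truth_private, expected_private):
        for s in d:
            d[s].sort(key=lambda k: (k[0], k[1], k[2], k[3]))

    truth = SyntheticTruth(
        seed=seed,
        params={
            "generator": "simulate_strain_panel",
            "n_strains": n_strains,
            "n_sites": n_sites,
            "n_private_per_strain": n_private_per_strain,
            "missing_rate": missing_rate,
            "lowqual_rate": lowqual_rate,
            "het_rate": het_rate,
            "indel_fraction": indel_fraction,
            "rule": {"min_homref_others": rule.min_homref_others,
                     "max_missing_lq": rule.max_missing_lq},
        },
        data={
            "strains": strains,
            "planted_private": truth_private,
            "expected_private": expected_private,
        },
    )
    return records, strains, truth


def _privacy_verdict(rec: SiteRecord, strains, rule: PrivacyRule):
    """Direct per-site transcription of the privacy rule; independent of the
    vectorised catalog implementation."""
    alt_strains = [s for s in strains if rec.calls[s].gt_class is GTClass.HOM_ALT_HQ]
    if len(alt_strains) != 1:
        return None
    focal = alt_strains[0]
    others = [rec.calls[s].gt_class for s in strains if s != focal]
    if any(c is GTClass.HET_HQ for c in others):
        return None
    n_mlq = sum(c in (GTClass.MISSING, GTClass.LOW_QUALITY) for c in others)
    n_ref = sum(c is GTClass.HOM_REF_HQ for c in others)
    if n_mlq > rule.max_missing_lq or n_ref < rule.min_homref_others:
        return None
    return focal


# ---------------------------------------------------------------------------
# Consequence annotations
# ---------------------------------------------------------------------------

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def simulate_annotations(
    records: Sequence[SiteRecord],
    gene_catalog_size: int = 50,
    missense_fraction: float = 0.3,
    deleterious_fraction: float = 0.3,
    seed: int = 0,
):
    """Attach CSQ-style annotations to SNP records.

    Each SNP gets one transcript annotation: with probability
    ``missense_fraction`` a missense with a random residue pair and a SIFT
    score drawn so that exactly the deleterious fraction falls <= 0.05;
    otherwise a synonymous or intron consequence. Indel records get a
    frameshift annotation. Returns (records, truth); records are annotated
    in place.
    """
    for frac in (missense_fraction, deleterious_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction {frac} outside [0,1]")
    rng = _rng(seed, _STREAM_ANNOT)
    genes = [f"GENE{i:04d}" for i in range(1, gene_catalog_size + 1)]
    missense_keys, deleterious_keys = [], []
    gene_of_key: dict = {}
    for rec in records:
        gene = genes[int(rng.integers(len(genes)))]
        transcript = f"{gene}.t1"
        gene_of_key["|".join(map(str, rec.key))] = gene
        if rec.vclass is not VariantClass.SNP:
            ann = ConsequenceAnnotation(gene_id=gene, transcript_id=transcript,
                                        terms=frozenset({"frameshift_variant"}))
        elif rng.random() < missense_fraction:
            i, j = rng.choice(len(_RESIDUES), size=2, replace=False)
            deleterious = rng.random() < deleterious_fraction
            score = (round(float(rng.uniform(0.0, 0.05)), 3) if deleterious
                     else round(float(rng.uniform(0.051, 1.0)), 3))
            ann = ConsequenceAnnotation(
                gene_id=gene,
                transcript_id=transcript,
                terms=frozenset({"missense_variant"}),
                aa_ref=_RESIDUES[int(i)],
                aa_alt=_RESIDUES[int(j)],
                aa_pos=int(rng.integers(1, 500)),
                sift_score=score,
                sift_call="deleterious" if score <= 0.05 else "tolerated",
            )
            missense_keys.append(list(rec.key))
            if score <= 0.05:
                deleterious_keys.append(list(rec.key))
        else:
            term = "synonymous_variant" if rng.random() < 0.5 else "intron_variant"
            ann = ConsequenceAnnotation(gene_id=gene, transcript_id=transcript,
                                        terms=frozenset({term}))
        rec.annotations = [ann]
    truth = SyntheticTruth(
        seed=seed,
        params={
            "generator": "simulate_annotations",
            "gene_catalog_size": gene_catalog_size,
            "missense_fraction": missense_fraction,
            "deleterious_fraction": deleterious_fraction,
        },
        data={
            "missense_keys": missense_keys,
            "deleterious_keys": deleterious_keys,
            "gene_of_key": gene_of_key,
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# SV call sets
# ---------------------------------------------------------------------------


def simulate_sv_callsets(
    n_true_deletions: int,
    n_strains: int,
    callers: Sequence[str] = ("breakdancer", "cnd", "lumpy"),
    jitter_sd_bp: float = 20.0,
    shared_across_strains: float = 0.3,
    n_true_insertions: int = 0,
    ins_window: int = 100,
    min_length: int = 2_000,
    max_length: int = 20_000,
    seed: int = 0,
):
    """Plant true deletions (and optionally insertions) and emit one jittered
    call per carrier strain per caller.

    Deletion jitter is clipped so that every intra-cluster pair keeps a
    reciprocal overlap > 0.9 by construction; planting fails loudly when the
    nominal jitter is incompatible with that guarantee. True events are
    spaced far apart so distinct clusters never satisfy the merge relation.

    Returns (calls, truth).
    """
    if jitter_sd_bp > 0.012 * min_length:
        raise ValueError(
            f"jitter_sd_bp={jitter_sd_bp} incompatible with RO>0.9 guarantee at "
            f"min_length={min_length} (need <= {0.012 * min_length:.0f})"
        )
    strains = default_strain_names(n_strains)
    rng = _rng(seed, _STREAM_SV)
    spacing = 2 * max_length + 100_000

    def place_events(n: int, offset: int):
        events = []
        per_chrom = int(np.ceil(n / len(CHROMS)))
        i = 0
        for chrom, length in CHROMS:
            pos = 100_000 + offset
            for _ in range(per_chrom):
                if i >= n:
                    break
                ev_len = int(rng.integers(min_length, max_length + 1))
                if pos + ev_len > length - 100_000:
                    break
                events.append((chrom, pos, pos + ev_len - 1))
                pos += ev_len + spacing
                i += 1
        if len(events) < n:
            raise ValueError(f"genome too small for {n} events at this spacing")
        return events

    def carriers_for():
        if n_strains > 1 and rng.random() < shared_across_strains:
            size = int(rng.integers(2, n_strains + 1))
            return sorted(rng.choice(strains, size=size, replace=False).tolist())
        return [strains[int(rng.integers(n_strains))]]

    calls, truth_dels, truth_inss = [], [], []
    for ei, (chrom, start, end) in enumerate(place_events(n_true_deletions, 0)):
        length = end - start + 1
        jmax = int(0.012 * length)
        carriers = carriers_for()
        member_ids = []
        for strain in carriers:
            for caller in callers:
                js = int(np.clip(rng.normal(0, jitter_sd_bp), -jmax, jmax))
                je = int(np.clip(rng.normal(0, jitter_sd_bp), -jmax, jmax))
                calls.append(StructuralVariant(chrom=chrom, start=start + js, end=end + je,
                                               svtype="DEL", strain=strain, caller=caller))
                member_ids.append(len(calls) - 1)
        truth_dels.append({
            "id": f"DEL{ei:04d}", "chrom": chrom, "start": start, "end": end,
            "strains": carriers, "private": len(carriers) == 1,
            "member_indices": member_ids,
        })
    for ei, (chrom, start, end) in enumerate(place_events(n_true_insertions, 37_000)):
        jmax = max(ins_window // 2 - 1, 0)
        carriers = carriers_for()
        member_ids = []
        for strain in carriers:
            for caller in callers:
                j = int(np.clip(rng.normal(0, min(jitter_sd_bp, jmax / 3 or 1)), -jmax, jmax))
                calls.append(StructuralVariant(chrom=chrom, start=start + j, end=start + j,
                                               svtype="INS", strain=strain, caller=caller,
                                               ins_length=int(rng.integers(100, 5_000))))
                member_ids.append(len(calls) - 1)
        truth_inss.append({
            "id": f"INS{ei:04d}", "chrom": chrom, "pos": start,
            "strains": carriers, "private": len(carriers) == 1,
            "member_indices": member_ids,
        })
    truth = SyntheticTruth(
        seed=seed,
        params={
            "generator": "simulate_sv_callsets",
            "n_true_deletions": n_true_deletions,
            "n_true_insertions": n_true_insertions,
            "n_strains": n_strains,
            "callers": list(callers),
            "jitter_sd_bp": jitter_sd_bp,
            "shared_across_strains": shared_across_strains,
            "ins_window": ins_window,
        },
        data={"deletions": truth_dels, "insertions": truth_inss, "strains": strains},
    )
    return calls, truth


# ---------------------------------------------------------------------------
# Pathway database
# ---------------------------------------------------------------------------


def simulate_pathway_db(
    n_pathways: int = 20,
    genes_per_pathway: int = 50,
    universe_size: int = 1_000,
    enriched_pathway_draw_weight: float = 10.0,
    candidate_set_size: int = 40,
    seed: int = 0,
):
    """A pathway database with one planted enriched pathway.

    Candidates are drawn without replacement with elevated weight on the
    designated pathway's genes (weighted reservoir via Gumbel top-k).
    Returns (pathways, candidates, truth).
    """
    from .variant_model import PathwaySet

    if enriched_pathway_draw_weight < 1:
        raise ValueError("enriched_pathway_draw_weight must be >= 1")
    if candidate_set_size > universe_size:
        raise ValueError("candidate_set_size exceeds universe_size")
    rng = _rng(seed, _STREAM_PATHWAY)
    universe = [f"G{i:05d}" for i in range(1, universe_size + 1)]
    pathways = []
    for pi in range(n_pathways):
        genes = rng.choice(universe, size=genes_per_pathway, replace=False)
        db = "KEGG" if pi % 2 == 0 else "REACTOME"
        pathways.append(PathwaySet(pathway_id=f"PW{pi:03d}", name=f"PW{pi:03d}",
                                   database=db, genes=frozenset(genes.tolist())))
    enriched = pathways[0]
    weights = np.ones(universe_size)
    enriched_idx = [i for i, g in enumerate(universe) if g in enriched.genes]
    weights[enriched_idx] = enriched_pathway_draw_weight
    gumbel = rng.gumbel(size=universe_size)
    keys = np.log(weights) + gumbel
    chosen = np.argsort(-keys, kind="stable")[:candidate_set_size]
    candidates = {universe[int(i)] for i in chosen}
    truth = SyntheticTruth(
        seed=seed,
        params={
            "generator": "simulate_pathway_db",
            "n_pathways": n_pathways,
            "genes_per_pathway": genes_per_pathway,
            "universe_size": universe_size,
            "enriched_pathway_draw_weight": enriched_pathway_draw_weight,
            "candidate_set_size": candidate_set_size,
        },
        data={
            "enriched_pathway": enriched.pathway_id,
            "candidates": sorted(candidates),
            "universe": universe,
        },
    )
    return pathways, candidates, truth


# ---------------------------------------------------------------------------
# Concordance panel
# ---------------------------------------------------------------------------


def simulate_panel_from_truth(
    records: Sequence[SiteRecord],
    strains: Sequence[str],
    discordance_count: int = 0,
    seed: int = 0,
):
    """Build a genotype panel from the true high-quality homozygous calls and
    flip exactly ``discordance_count`` entries to a wrong genotype.

    Returns (entries, truth); entries are (chrom, pos, strain, allele-pair).
    """
    entries = []
    for rec in records:
        for strain in strains:
            cls = rec.calls[strain].gt_class
            if cls is GTClass.HOM_REF_HQ:
                entries.append((rec.chrom, rec.pos, strain, (rec.ref, rec.ref)))
            elif cls is GTClass.HOM_ALT_HQ:
                entries.append((rec.chrom, rec.pos, strain, (rec.alt, rec.alt)))
    if discordance_count > len(entries):
        raise ValueError("discordance_count exceeds panel size")
    rng = _rng(seed, _STREAM_CONCORD)
    flip_idx = sorted(rng.choice(len(entries), size=discordance_count, replace=False).tolist()) \
        if discordance_count else []
    for i in flip_idx:
        chrom, pos, strain, alleles = entries[i]
        wrong = next(b for b in _BASES if b != alleles[0])
        entries[i] = (chrom, pos, strain, (wrong, wrong))
    truth = SyntheticTruth(
        seed=seed,
        params={"generator": "simulate_panel_from_truth",
                "discordance_count": discordance_count},
        data={"n_entries": len(entries), "flipped_indices": flip_idx},
    )
    return entries, truth
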