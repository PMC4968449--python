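import numpy as np
import pytest
from hypothesis import settings

# keep example-database files out of the repo
settings.register_profile("no_db", database=None)
settings.load_profile("no_db")

from strainvar.genotype_catalog import StrainGenotypeMatrix
from strainvar.variant_model import GenotypeCall, GTClass, SiteRecord, VariantClass

# class codes used by the random-matrix helpers (match genotype_catalog._CODE)
CODE_TO_CLASS = {
    0: GTClass.HOM_REF_HQ,
    1: GTClass.HOM_ALT_HQ,
    2: GTClass.HET_HQ,
    3: GTClass.LOW_QUALITY,
    4: GTClass.MISSING,
}

_CALL_CACHE = {}


def _call(strain: str, cls: GTClass) -> GenotypeCall:
    """GenotypeCall instances are immutable; cache per (strain, class) so huge
    random matrices build quickly."""
    key = (strain, cls)
    if key not in _CALL_CACHE:
        raw = {
            GTClass.HOM_REF_HQ: (0, 0),
            GTClass.HOM_ALT_HQ: (1, 1),
            GTClass.HET_HQ: (0, 1),
            GTClass.LOW_QUALITY: (0, 0),
            GTClass.MISSING: None,
        }[cls]
        gq = {GTClass.LOW_QUALITY: 5.0, GTClass.MISSING: None}.get(cls, 60.0)
        _CALL_CACHE[key] = GenotypeCall(strain=strain, gt_class=cls, raw_gt=raw, gq=gq)
    return _CALL_CACHE[key]


def matrix_from_codes(codes, strains=None) -> StrainGenotypeMatrix:
    """Build a genotype matrix from an (n_sites x S) array of class codes."""
    codes = np.asarray(codes)
    n_sites, S = codes.shape
    if strains is None:
        strains = [f"STR{i:02d}" for i in range(1, S + 1)]
    sites = [
        SiteRecord(
            chrom="chr1",
            pos=i + 1,
            ref="A",
            alt="G",
            vclass=VariantClass.SNP,
            calls={s: _call(s, CODE_TO_CLASS[int(codes[i, j])]) for j, s in enumerate(strains)},
        )
        for i in range(n_sites)
    ]
    return StrainGenotypeMatrix(strains=list(strains), sites=sites)


def matrix_from_rows(rows, strains) -> StrainGenotypeMatrix:
    """rows: list of dicts strain -> GTClass (one per site)."""
    sites = []
    for i, row in enumerate(rows):
        sites.append(
            SiteRecord(
                chrom="chr1",
                pos=i + 1,
                ref="A",
                alt="G",
                vclass=VariantClass.SNP,
                calls={s: _call(s, row[s]) for s in strains},
            )
        )
    return StrainGenotypeMatrix(strains=list(strains), sites=sites)


def brute_force_private(matrix, rule):
    """Independent per-site transcription of the privacy rule text: exactly
    one high-quality hom-alt; others all high-quality hom-ref except at most
    max_missing_lq missing/low-quality; at least min_homref_others hom-ref;
    any het disqualifies."""
    out = {s: [] for s in matrix.strains}
    for rec in matrix.sites:
        classes = {s: rec.calls[s].gt_class for s in matrix.strains}
        alt = [s for s, c in classes.items() if c is GTClass.HOM_ALT_HQ]
        if len(alt) != 1:
            continue
        focal = alt[0]
        others = [c for s, c in classes.items() if s != focal]
        if any(c is GTClass.HET_HQ for c in others):
            continue
        n_mlq = sum(c in (GTClass.MISSING, GTClass.LOW_QUALITY) for c in others)
        n_ref = sum(c is GTClass.HOM_REF_HQ for c in others)
        if n_mlq <= rule.max_missing_lq and n_ref >= rule.min_homref_others:
            out[focal].append(rec.key)
    for s in out:
        out[s].sort(key=lambda k: (k[0], k[1], k[2], k[3]))
    return out


@pytest.fixture
def small_panel():
    """8-strain, 300-site synthetic panel with noise, plus its truth."""
    from strainvar.synthetic_data import simulate_strain_panel

    records, strains, truth = simulate_strain_panel(
        n_strains=8,
        n_sites=300,
        n_private_per_strain=4,
        missing_rate=0.03,
        lowqual_rate=0.02,
        het_rate=0.01,
        indel_fraction=0.2,
        seed=11,
    )
    return records, strains, truth


@pytest.fixture
def annotated_panel(small_panel):
    from strainvar.synthetic_data import simulate_annotations

    records, strains, truth = small_panel
    records, ann_truth = simulate_annotations(
        records, gene_catalog_size=40, missense_fraction=0.4,
        deleterious_fraction=0.4, seed=11)
    return records, strains, truth, ann_truth
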