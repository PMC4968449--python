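"""Damage scoring of coding variants: physicochemical substitution distances,
band classification, SIFT classes and consequence-term filtering.

The substitution distance between residues i and j is

    D_ij = rho * (alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)^(1/2)

over side-chain composition c, polarity p and volume v, with rho scaled so the
mean over the 190 unordered residue pairs is 100. Bands: <=100 conservative,
100 < D <= 150 moderately radical, > 150 radical.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

from .variant_model import ConsequenceAnnotation, SiteRecord

# Side-chain properties per residue: (composition, polarity, volume).
AA_PROPERTIES = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399

STANDARD_RESIDUES = frozenset(AA_PROPERTIES)


def _unscaled(a: str, b: str) -> float:
    ca, pa, va = AA_PROPERTIES[a]
    cb, pb, vb = AA_PROPERTIES[b]
    return (ALPHA * (ca - cb) ** 2 + BETA * (pa - pb) ** 2 + GAMMA * (va - vb) ** 2) ** 0.5


def _rho() -> float:
    # normalise the mean over the 190 unordered pairs to 100
    pairs = list(combinations(sorted(AA_PROPERTIES), 2))
    return 100.0 * len(pairs) / sum(_unscaled(a, b) for a, b in pairs)


RHO = _rho()


def grantham_distance(aa_from: str, aa_to: str) -> float:
    """Raw (unrounded) substitution distance; symmetric, 0 iff identical."""
    for aa in (aa_from, aa_to):
        if aa not in STANDARD_RESIDUES:
            raise ValueError(f"non-standard residue {aa!r} cannot be scored")
    if aa_from == aa_to:
        return 0.0
    return RHO * _unscaled(aa_from, aa_to)


def grantham_score(aa_from: str, aa_to: str) -> int:
    """Integer-rounded distance, the value used for band classification."""
    return int(round(grantham_distance(aa_from, aa_to)))


def try_grantham_score(aa_from: str, aa_to: str) -> Optional[int]:
    """As :func:`grantham_score` but None (unscored) for non-standard residues
    such as X, * or U."""
    if aa_from in STANDARD_RESIDUES and aa_to in STANDARD_RESIDUES:
        return grantham_score(aa_from, aa_to)
    return None


class GmsBand(enum.Enum):
    CONSERVATIVE = "conservative"
    MODERATELY_RADICAL = "moderately_radical"
    RADICAL = "radical"


def classify_gms(score: float) -> GmsBand:
    """Band a substitution score: <=100 conservative, (100,150] moderately
    radical, >150 radical."""
    if score < 0:
        raise ValueError(f"negative substitution score {score}")
    if score > 150:
        return GmsBand.RADICAL
    if score > 100:
        return GmsBand.MODERATELY_RADICAL
    return GmsBand.CONSERVATIVE


class SiftClass(enum.Enum):
    TOLERATED = "tolerated"
    DELETERIOUS = "deleterious"
    UNSCORED = "unscored"


SIFT_DELETERIOUS_THRESHOLD = 0.05


def classify_sift(
    annotation: ConsequenceAnnotation, threshold: float = SIFT_DELETERIOUS_THRESHOLD
) -> SiftClass:
    """Classify an annotation's SIFT evidence.

    A categorical call takes precedence; otherwise score <= threshold is
    deleterious; no evidence at all is unscored.
    """
    if annotation.sift_call is not None:
        return SiftClass(annotation.sift_call)
    if annotation.sift_score is not None:
        return (
            SiftClass.DELETERIOUS
            if annotation.sift_score <= threshold
            else SiftClass.TOLERATED
        )
    return SiftClass.UNSCORED


def filter_by_consequence(sites: Iterable[SiteRecord], terms) -> list:
    """Retain (site, annotation) pairs whose annotation carries any requested
    consequence term; one pair per matching annotation, so a variant hitting
    several transcripts can appear several times."""
    terms = set(terms)
    if not terms:
        raise ValueError("empty consequence term set")
    out = []
    for rec in sites:
        for ann in rec.annotations:
            if ann.terms & terms:
                out.append((rec, ann))
    return out


@dataclass(frozen=True)
class DamageSummary:
    """Worst-case per-variant damage summary over all transcript annotations."""

    max_gms: Optional[int]
    gms_band: Optional[GmsBand]
    sift: SiftClass
    n_missense_annotations: int


def summarize_damage(rec: SiteRecord) -> DamageSummary:
    """Aggregate transcript-level annotations to one per-variant label using
    the most damaging evidence (max score; deleterious over tolerated)."""
    max_gms: Optional[int] = None
    n_mis = 0
    sift = SiftClass.UNSCORED
    rank = {SiftClass.UNSCORED: 0, SiftClass.TOLERATED: 1, SiftClass.DELETERIOUS: 2}
    for ann in rec.annotations:
        if "missense_variant" in ann.terms:
            n_mis += 1
            score = try_grantham_score(ann.aa_ref, ann.aa_alt)
            if score is not None and (max_gms is None or score > max_gms):
                max_gms = score
        cls = classify_sift(ann)
        if rank[cls] > rank[sift]:
            sift = cls
    band = classify_gms(max_gms) if max_gms is not None else None
    return DamageSummary(max_gms=max_gms, gms_band=band, sift=sift, n_missense_annotations=n_mis)


def damage_table(sites: Iterable[SiteRecord]):
    """Per-annotation damage rows (one per transcript annotation), as a
    pandas DataFrame ready for TSV export."""
    import pandas as pd

    rows = []
    for rec in sites:
        for ann in rec.annotations:
            gms = None
            if "missense_variant" in ann.terms:
                gms = try_grantham_score(ann.aa_ref, ann.aa_alt)
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "gene": ann.gene_id,
                    "transcript": ann.transcript_id,
                    "consequence": "&".join(sorted(ann.terms)),
                    "aa_change": f"{ann.aa_ref}{ann.aa_pos or ''}{ann.aa_alt}"
                    if ann.aa_ref
                    else "",
                    "sift_score": ann.sift_score,
                    "sift_class": classify_sift(ann).value,
                    "gms": gms,
                    "gms_band": classify_gms(gms).value if gms is not None else "",
                }
            )
    return pd.DataFrame(rows)
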