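"""Strains x sites genotype matrix and the private/shared variant rules.

A variant is *private* to a strain when that strain carries the only
high-quality homozygous alternate genotype in the panel, nearly all other
strains are high-quality homozygous reference, and only a bounded number of
strains are allowed a missing or low-quality genotype. High-quality
heterozygous calls anywhere else in the panel disqualify the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .variant_model import GTClass, SiteRecord, VariantClass

# integer codes for vectorised rule evaluation
_CODE = {
    GTClass.HOM_REF_HQ: 0,
    GTClass.HOM_ALT_HQ: 1,
    GTClass.HET_HQ: 2,
    GTClass.LOW_QUALITY: 3,
    GTClass.MISSING: 4,
}


@dataclass(frozen=True)
class PrivacyRule:
    """Parameters of the private-variant rule.

    ``min_homref_others``: minimum count of high-quality homozygous-reference
    strains among the S-1 non-focal strains (default 30).
    ``max_missing_lq``: maximum count of missing or low-quality genotypes
    allowed among the non-focal strains (default 5).
    """

    min_homref_others: int = 30
    max_missing_lq: int = 5

    def validate_for_panel(self, n_strains: int) -> None:
        if self.min_homref_others + self.max_missing_lq + 1 > n_strains:
            raise ValueError(
                f"privacy rule (min_homref_others={self.min_homref_others}, "
                f"max_missing_lq={self.max_missing_lq}) incompatible with panel of "
                f"{n_strains} strains"
            )

    @classmethod
    def for_panel(cls, n_strains: int, max_missing_lq: int = 5) -> "PrivacyRule":
        """Default generalisation: all non-focal strains must be hom-ref except
        the allowed missing/low-quality slack."""
        return cls(min_homref_others=n_strains - 1 - max_missing_lq, max_missing_lq=max_missing_lq)


@dataclass
class StrainGenotypeMatrix:
    """Ordered strain panel plus its decomposed site records."""

    strains: list
    sites: list = field(default_factory=list)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if len(self.strains) < 2:
            raise ValueError("panel must contain at least 2 strains")
        for rec in self.sites:
            self._check(rec)
        self._index = {rec.key: i for i, rec in enumerate(self.sites)}
        if len(self._index) != len(self.sites):
            raise ValueError("duplicate site keys in matrix")

    def _check(self, rec: SiteRecord) -> None:
        if set(rec.calls) != set(self.strains):
            raise ValueError(f"site {rec.key}: calls do not match panel strains")

    @classmethod
    def from_records(cls, records: Iterable[SiteRecord], strains: list) -> "StrainGenotypeMatrix":
        return cls(strains=list(strains), sites=list(records))

    def __len__(self) -> int:
        return len(self.sites)

    def get(self, key) -> Optional[SiteRecord]:
        i = self._index.get(tuple(key))
        return None if i is None else self.sites[i]

    def class_codes(self, vclass_filter: Optional[VariantClass] = None):
        """(site_indices, n_sites x S int8 array of genotype class codes)."""
        idx = [
            i
            for i, rec in enumerate(self.sites)
            if vclass_filter is None or rec.vclass is vclass_filter
        ]
        codes = np.empty((len(idx), len(self.strains)), dtype=np.int8)
        for row, i in enumerate(idx):
            calls = self.sites[i].calls
            for col, strain in enumerate(self.strains):
                codes[row, col] = _CODE[calls[strain].gt_class]
        return idx, codes


def identify_private_variants(
    matrix: StrainGenotypeMatrix,
    rule: PrivacyRule = PrivacyRule(),
    vclass_filter: Optional[VariantClass] = None,
) -> dict:
    """Map strain -> sorted list of site keys private to that strain.

    A site is private to strain X iff X is the panel's only HOM_ALT_HQ call,
    no other strain is HET_HQ, the missing/low-quality count among others is
    <= ``rule.max_missing_lq``, and the remaining others are all HOM_REF_HQ
    and number >= ``rule.min_homref_others``.
    """
    S = len(matrix.strains)
    rule.validate_for_panel(S)
    out = {s: [] for s in matrix.strains}
    idx, codes = matrix.class_codes(vclass_filter)
    if not idx:
        return out
    is_alt = codes == _CODE[GTClass.HOM_ALT_HQ]
    n_alt = is_alt.sum(axis=1)
    n_het = (codes == _CODE[GTClass.HET_HQ]).sum(axis=1)
    n_mlq = ((codes == _CODE[GTClass.LOW_QUALITY]) | (codes == _CODE[GTClass.MISSING])).sum(axis=1)
    n_ref = (codes == _CODE[GTClass.HOM_REF_HQ]).sum(axis=1)
    ok = (
        (n_alt == 1)
        & (n_het == 0)
        & (n_mlq <= rule.max_missing_lq)
        & (n_ref >= rule.min_homref_others)
        & (n_ref + n_mlq == S - 1)
    )
    for row in np.flatnonzero(ok):
        strain = matrix.strains[int(np.flatnonzero(is_alt[row])[0])]
        out[strain].append(matrix.sites[idx[row]].key)
    for strain in out:
        out[strain].sort(key=lambda k: (k[0], k[1], k[2], k[3]))
    return out


@dataclass(frozen=True)
class SharedFraction:
    fraction: Optional[float]
    numerator: int
    denominator: int
    defined: bool


def shared_fraction(
    matrix: StrainGenotypeMatrix,
    strain_a: str,
    strain_b: str,
    vclass_filter: Optional[VariantClass] = None,
) -> SharedFraction:
    """Fraction of strain_a's HOM_ALT_HQ sites at which strain_b is also
    HOM_ALT_HQ for the same alternate allele."""
    for s in (strain_a, strain_b):
        if s not in matrix.strains:
            raise ValueError(f"unknown strain {s!r}")
    num = den = 0
    for rec in matrix.sites:
        if vclass_filter is not None and rec.vclass is not vclass_filter:
            continue
        if rec.calls[strain_a].gt_class is GTClass.HOM_ALT_HQ:
            den += 1
            if rec.calls[strain_b].gt_class is GTClass.HOM_ALT_HQ:
                num += 1
    if den == 0:
        return SharedFraction(fraction=None, numerator=0, denominator=0, defined=False)
    return SharedFraction(fraction=num / den, numerator=num, denominator=den, defined=True)


def pairwise_sharing_table(
    matrix: StrainGenotypeMatrix, vclass_filter: Optional[VariantClass] = None
) -> pd.DataFrame:
    """S x S table of HOM_ALT_HQ sharing counts; diagonal = per-strain totals."""
    _, codes = matrix.class_codes(vclass_filter)
    is_alt = (codes == _CODE[GTClass.HOM_ALT_HQ]).astype(np.int64)
    shared = is_alt.T @ is_alt if len(is_alt) else np.zeros(
        (len(matrix.strains), len(matrix.strains)), dtype=np.int64
    )
    return pd.DataFrame(shared, index=matrix.strains, columns=matrix.strains)


def catalog_summary(matrix: StrainGenotypeMatrix, rule: PrivacyRule = PrivacyRule()) -> pd.DataFrame:
    """Per-strain variant and private-variant counts, split SNPs vs indels."""
    priv_snp = identify_private_variants(matrix, rule, VariantClass.SNP)
    priv = identify_private_variants(matrix, rule, None)
    rows = []
    for strain in matrix.strains:
        n_snps = n_indels = 0
        for rec in matrix.sites:
            if rec.calls[strain].gt_class is GTClass.HOM_ALT_HQ:
                if rec.vclass is VariantClass.SNP:
                    n_snps += 1
                else:
                    n_indels += 1
        n_priv_snp = len(priv_snp[strain])
        rows.append(
            {
                "strain": strain,
                "n_snps": n_snps,
                "n_private_snps": n_priv_snp,
                "n_indels": n_indels,
                "n_private_indels": len(priv[strain]) - n_priv_snp,
            }
        )
    return pd.DataFrame(rows)
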