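"""Genotype concordance between the call set and an external genotype panel,
yielding per-strain sensitivity estimates.

Panel entries with missing genotypes are removed on load (see
:func:`strainvar.variant_model.read_genotype_panel_tsv`). A panel entry is
compared only when the position is callable in the strain; hom-ref call-side
evidence counts as a reference genotype by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .genotype_catalog import StrainGenotypeMatrix
from .variant_model import GTClass


@dataclass
class ConcordancePanel:
    """External genotype truth set: (chrom, pos, strain, allele-pair) rows."""

    entries: list
    provenance: str = ""

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "ConcordancePanel":
        from .variant_model import read_genotype_panel_tsv

        return cls(entries=read_genotype_panel_tsv(path), provenance=provenance or str(path))

    def for_strain(self, strain: str) -> list:
        return [e for e in self.entries if e[2] == strain]


@dataclass(frozen=True)
class ConcordanceReport:
    strain: str
    n_compared: int
    n_concordant: int
    rate: Optional[float]  # percent
    defined: bool


def _called_genotype(matrix: StrainGenotypeMatrix, chrom: str, pos: int, strain: str,
                     include_homref: bool):
    """The strain's called allele pair at a position, or None when uncallable.

    Scans all decomposed records at the position: a HOM_ALT_HQ call wins,
    then HET_HQ, then (optionally) hom-ref evidence. LOW_QUALITY/MISSING
    yield no evidence.
    """
    records = [rec for rec in matrix.sites if rec.chrom == chrom and rec.pos == pos]
    if not records:
        return None
    homref = None
    for rec in records:
        call = rec.calls[strain]
        if call.gt_class is GTClass.HOM_ALT_HQ:
            return (rec.alt, rec.alt)
        if call.gt_class is GTClass.HET_HQ:
            return (rec.ref, rec.alt)
        if call.gt_class is GTClass.HOM_REF_HQ:
            homref = (rec.ref, rec.ref)
    if include_homref:
        return homref
    return None


def genotype_concordance(
    matrix: StrainGenotypeMatrix,
    panel: ConcordancePanel,
    strain: str,
    include_homref: bool = True,
) -> ConcordanceReport:
    """Concordance rate between the strain's calls and its panel genotypes.

    Uncallable positions (no high-quality evidence in the strain) are
    excluded from the denominator.
    """
    if strain not in matrix.strains:
        raise ValueError(f"strain {strain!r} absent from call set")
    # index positions once; panel may be large
    pos_index: dict = {}
    for rec in matrix.sites:
        pos_index.setdefault((rec.chrom, rec.pos), []).append(rec)

    n_compared = n_concordant = 0
    for chrom, pos, pstrain, expected in panel.for_strain(strain):
        records = pos_index.get((chrom, pos))
        called = None
        if records:
            homref = None
            for rec in records:
                call = rec.calls[strain]
                if call.gt_class is GTClass.HOM_ALT_HQ:
                    called = (rec.alt, rec.alt)
                    break
                if call.gt_class is GTClass.HET_HQ:
                    called = (rec.ref, rec.alt)
                    break
                if call.gt_class is GTClass.HOM_REF_HQ:
                    homref = (rec.ref, rec.ref)
            if called is None and include_homref:
                called = homref
        if called is None:
            continue
        n_compared += 1
        if frozenset(called) == frozenset(expected):
            n_concordant += 1
    rate = 100.0 * n_concordant / n_compared if n_compared else None
    return ConcordanceReport(
        strain=strain,
        n_compared=n_compared,
        n_concordant=n_concordant,
        rate=rate,
        defined=n_compared > 0,
    )


def concordance_table(matrix: StrainGenotypeMatrix, panel: ConcordancePanel,
                      include_homref: bool = True) -> pd.DataFrame:
    """Per-strain concordance report (strain, n_genotypes, n_concordant, rate)."""
    rows = []
    for strain in matrix.strains:
        rep = genotype_concordance(matrix, panel, strain, include_homref)
        rows.append(
            {
                "strain": strain,
                "n_genotypes": rep.n_compared,
                "n_concordant": rep.n_concordant,
                "rate": rep.rate,
            }
        )
    return pd.DataFrame(rows)
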