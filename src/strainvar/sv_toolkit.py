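"""Structural-variant post-processing: proximity/size filtering, within-strain
merging of deletions by reciprocal overlap, insertion window merging,
cross-strain private-SV identification, CDS overlap and validation
sensitivity.

Intervals are 1-based inclusive. Deletions merge when their reciprocal
overlap strictly exceeds the threshold (default 0.9); merging is
single-linkage transitive closure, deterministic regardless of input order.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

CALLER_PRIORITY = ("breakdancer", "lumpy", "cnd", "retroseq", "scalpel", "manta", "other")


@dataclass(frozen=True)
class StructuralVariant:
    chrom: str
    start: int
    end: int
    svtype: str  # "DEL" | "INS"
    strain: str
    caller: str = "other"
    ins_length: Optional[int] = None  # inserted bp for INS records

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"SV start {self.start} > end {self.end}")
        if self.svtype not in ("DEL", "INS"):
            raise ValueError(f"bad svtype {self.svtype!r}")

    @property
    def length(self) -> int:
        if self.svtype == "INS":
            return self.ins_length if self.ins_length is not None else 0
        return self.end - self.start + 1

    @property
    def interval(self):
        return (self.chrom, self.start, self.end)


@dataclass
class SVCluster:
    """A merged set of SV calls with primary (representative) and secondary
    (outer-bound) breakpoints."""

    members: list
    primary_start: int = 0
    primary_end: int = 0
    secondary_start: int = 0
    secondary_end: int = 0
    strains: frozenset = frozenset()

    def __post_init__(self):
        if not self.members:
            raise ValueError("empty cluster")
        chroms = {m.chrom for m in self.members}
        if len(chroms) > 1:
            raise ValueError("cluster spans chromosomes")
        self.chrom = self.members[0].chrom
        self.secondary_start = min(m.start for m in self.members)
        self.secondary_end = max(m.end for m in self.members)
        rep = _representative(self.members)
        self.primary_start, self.primary_end = rep.start, rep.end
        self.strains = frozenset(m.strain for m in self.members)
        self.svtype = self.members[0].svtype


def _caller_rank(caller: str) -> int:
    try:
        return CALLER_PRIORITY.index(caller)
    except ValueError:
        return len(CALLER_PRIORITY)


def _representative(members: Sequence[StructuralVariant]) -> StructuralVariant:
    # caller-priority first, then deterministic positional tie-break
    return min(members, key=lambda m: (_caller_rank(m.caller), m.start, m.end, m.caller))


def reciprocal_overlap(a, b) -> float:
    """min(overlap/len_a, overlap/len_b) for 1-based inclusive intervals;
    0 for different chromosomes or disjoint intervals."""
    chrom_a, sa, ea = a
    chrom_b, sb, eb = b
    if chrom_a != chrom_b:
        return 0.0
    la, lb = ea - sa + 1, eb - sb + 1
    if la <= 0 or lb <= 0:
        raise ValueError("intervals must have positive length")
    ov = min(ea, eb) - max(sa, sb) + 1
    if ov <= 0:
        return 0.0
    return min(ov / la, ov / lb)


# ---------------------------------------------------------------------------
# Proximity / size filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rejection:
    sv: StructuralVariant
    reason: str


def _min_distance(sv: StructuralVariant, intervals: Sequence[tuple]) -> Optional[int]:
    """Distance in bp from the SV span to the nearest interval (0 if they
    touch or overlap); None when no interval shares the chromosome."""
    best = None
    for chrom, s, e in intervals:
        if chrom != sv.chrom:
            continue
        if sv.end < s:
            d = s - sv.end
        elif e < sv.start:
            d = sv.start - e
        else:
            d = 0
        best = d if best is None else min(best, d)
    return best


def filter_svs(
    svs: Iterable[StructuralVariant],
    assembly_gaps: Sequence[tuple] = (),
    telomere_centromere: Sequence[tuple] = (),
    gap_pad: int = 500,
    telo_pad: int = 20_000,
    max_len: int = 1_000_000,
):
    """Drop SVs within ``gap_pad`` bp of an assembly gap, within ``telo_pad``
    bp of a telomere/centromere, or longer than ``max_len`` bp.

    Returns (retained list, rejection log)."""
    retained, rejected = [], []
    for sv in svs:
        span = sv.end - sv.start + 1
        d_gap = _min_distance(sv, assembly_gaps)
        d_telo = _min_distance(sv, telomere_centromere)
        if span > max_len:
            rejected.append(Rejection(sv, f"length {span} > {max_len}"))
        elif d_gap is not None and d_gap <= gap_pad:
            rejected.append(Rejection(sv, f"within {gap_pad} bp of assembly gap"))
        elif d_telo is not None and d_telo <= telo_pad:
            rejected.append(Rejection(sv, f"within {telo_pad} bp of telomere/centromere"))
        else:
            retained.append(sv)
    return retained, rejected


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _cluster_components(svs, related) -> list:
    """Connected components (single linkage) under a pairwise relation,
    with a sorted sweep so only overlapping candidates are compared."""
    order = sorted(range(len(svs)), key=lambda i: (svs[i].chrom, svs[i].start, svs[i].end))
    uf = _UnionFind(len(svs))
    active: list = []  # indices of sweep candidates on current chrom
    cur_chrom = None
    max_end = 0
    for i in order:
        sv = svs[i]
        if sv.chrom != cur_chrom:
            active, cur_chrom = [], sv.chrom
        active = [j for j in active if svs[j].end >= sv.start - _MAX_GAP]
        for j in active:
            if related(svs[i], svs[j]):
                uf.union(i, j)
        active.append(i)
    comps: dict = {}
    for i in range(len(svs)):
        comps.setdefault(uf.find(i), []).append(i)
    clusters = [SVCluster(members=sorted((svs[i] for i in comp),
                                         key=lambda m: (m.start, m.end, m.caller, m.strain)))
                for comp in comps.values()]
    clusters.sort(key=lambda c: (c.chrom, c.secondary_start, c.secondary_end))
    return clusters


_MAX_GAP = 10_000  # sweep slack; window merges never exceed this


def merge_deletions(
    svs: Sequence[StructuralVariant], threshold: float = 0.9
) -> list:
    """Collapse deletion calls into non-redundant clusters by single-linkage
    merging of pairs with reciprocal overlap strictly greater than
    ``threshold``."""
    svs = list(svs)
    for sv in svs:
        if sv.svtype != "DEL":
            raise ValueError(f"merge_deletions given non-DEL record {sv}")

    def related(a, b):
        return reciprocal_overlap(a.interval, b.interval) > threshold

    return _cluster_components(svs, related)


def merge_insertions(svs: Sequence[StructuralVariant], window: int = 100) -> list:
    """Cluster insertion calls whose breakpoints lie within ``window`` bp on
    the same chromosome (single linkage)."""
    svs = list(svs)
    for sv in svs:
        if sv.svtype != "INS":
            raise ValueError(f"merge_insertions given non-INS record {sv}")
    if window > _MAX_GAP:
        raise ValueError(f"window {window} exceeds sweep limit {_MAX_GAP}")

    def related(a, b):
        return abs(a.start - b.start) <= window

    return _cluster_components(svs, related)


def cross_strain_private_svs(
    per_strain_clusters: dict,
    threshold: float = 0.9,
    svtype: str = "DEL",
    window: int = 100,
) -> dict:
    """From per-strain cluster lists, keep the clusters that do not satisfy
    the merge relation with any cluster of another strain.

    The relation is evaluated on secondary (outer) bounds: reciprocal overlap
    > ``threshold`` for deletions, breakpoint distance <= ``window`` for
    insertions.
    """
    def related(c1, c2):
        if svtype == "DEL":
            iv1 = (c1.chrom, c1.secondary_start, c1.secondary_end)
            iv2 = (c2.chrom, c2.secondary_start, c2.secondary_end)
            return reciprocal_overlap(iv1, iv2) > threshold
        return c1.chrom == c2.chrom and abs(c1.secondary_start - c2.secondary_start) <= window

    out = {}
    for strain, clusters in per_strain_clusters.items():
        others = [c for s, cs in per_strain_clusters.items() if s != strain for c in cs]
        out[strain] = [c for c in clusters if not any(related(c, o) for o in others)]
    return out


# ---------------------------------------------------------------------------
# CDS overlap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CdsOverlapResult:
    per_cluster: tuple  # tuple of (cluster_index, frozenset of gene_ids)
    n_clusters_hit: int
    n_genes_hit: int


def cds_overlap(clusters: Sequence[SVCluster], gene_models: Sequence) -> CdsOverlapResult:
    """Overlap cluster secondary bounds against CDS intervals only (not gene
    bodies). Returns per-cluster gene hits plus summary counts."""
    by_chrom: dict = {}
    for gm in gene_models:
        for s, e in gm.cds_intervals:
            by_chrom.setdefault(gm.chrom, []).append((s, e, gm.gene_id))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    starts = {c: [iv[0] for iv in ivs] for c, ivs in by_chrom.items()}

    per_cluster = []
    all_genes: set = set()
    n_hit = 0
    for ci, cl in enumerate(clusters):
        hits: set = set()
        ivs = by_chrom.get(cl.chrom, [])
        if ivs:
            lo = bisect.bisect_right(starts[cl.chrom], cl.secondary_end)
            for s, e, gene in ivs[:lo]:
                if e >= cl.secondary_start:
                    hits.add(gene)
        if hits:
            n_hit += 1
            all_genes |= hits
        per_cluster.append((ci, frozenset(hits)))
    return CdsOverlapResult(
        per_cluster=tuple(per_cluster), n_clusters_hit=n_hit, n_genes_hit=len(all_genes)
    )


# ---------------------------------------------------------------------------
# Validation sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityReport:
    n_found: int
    n_comparable: int
    sensitivity: Optional[float]  # percent
    defined: bool


def sensitivity_from_counts(n_validated: int, n_found: int, n_excluded: int = 0) -> SensitivityReport:
    """Sensitivity = 100 * n_found / (n_validated - n_excluded)."""
    n_comparable = n_validated - n_excluded
    if n_comparable <= 0:
        return SensitivityReport(n_found=n_found, n_comparable=n_comparable,
                                 sensitivity=None, defined=False)
    return SensitivityReport(
        n_found=n_found,
        n_comparable=n_comparable,
        sensitivity=100.0 * n_found / n_comparable,
        defined=True,
    )


def validation_sensitivity(
    called: Sequence[SVCluster],
    validated: Sequence[tuple],
    excluded: Sequence[tuple] = (),
    min_ro: Optional[float] = None,
) -> SensitivityReport:
    """Fraction of validated intervals recovered by the call set.

    ``validated``/``excluded`` are (chrom, start, end) intervals; excluded
    entries (true inter-strain differences) are removed from the denominator.
    A validated interval counts as found when it overlaps >= 1 called
    cluster's secondary bounds — any 1-bp overlap by default, or reciprocal
    overlap > ``min_ro`` when given.
    """
    excluded_set = {tuple(iv) for iv in excluded}
    comparable = [iv for iv in validated if tuple(iv) not in excluded_set]
    n_found = 0
    for iv in comparable:
        for cl in called:
            civ = (cl.chrom, cl.secondary_start, cl.secondary_end)
            ro = reciprocal_overlap(tuple(iv), civ)
            hit = ro > min_ro if min_ro is not None else ro > 0
            if hit:
                n_found += 1
                break
    return sensitivity_from_counts(len(validated), n_found, len(excluded_set))


# ---------------------------------------------------------------------------
# BED-like I/O
# ---------------------------------------------------------------------------


def read_sv_table(path) -> list:
    """Read SVs from a BED-like TSV: chrom, start(0-based), end, svtype,
    strain, caller[, ins_length]."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >=6 columns")
            ins_len = int(parts[6]) if len(parts) > 6 and parts[6] not in (".", "") else None
            out.append(
                StructuralVariant(
                    chrom=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    svtype=parts[3],
                    strain=parts[4],
                    caller=parts[5],
                    ins_length=ins_len,
                )
            )
    return out


def write_sv_table(path, svs: Iterable[StructuralVariant]):
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsvtype\tstrain\tcaller\tins_length\n")
        for sv in svs:
            fh.write(
                f"{sv.chrom}\t{sv.start - 1}\t{sv.end}\t{sv.svtype}\t{sv.strain}"
                f"\t{sv.caller}\t{sv.ins_length if sv.ins_length is not None else '.'}\n"
            )


def write_cluster_bed(path, clusters: Iterable[SVCluster]):
    """Merged clusters as BED with primary/secondary bounds in extra columns."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tsecondary_start\tsecondary_end\tsvtype\tn_members"
            "\tprimary_start\tprimary_end\tstrains\n"
        )
        for cl in clusters:
            fh.write(
                f"{cl.chrom}\t{cl.secondary_start - 1}\t{cl.secondary_end}\t{cl.svtype}"
                f"\t{len(cl.members)}\t{cl.primary_start - 1}\t{cl.primary_end}"
                f"\t{','.join(sorted(cl.strains))}\n"
            )


def read_bed_intervals(path) -> list:
    """(chrom, start, end) 1-based inclusive intervals from a plain BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out
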