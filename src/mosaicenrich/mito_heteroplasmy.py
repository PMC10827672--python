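"""Mitochondrial heteroplasmy analysis on a circular genome.

Genic SNVs are assigned one of four classes — synonymous, non-synonymous,
tRNA, rRNA — with class priority tRNA > rRNA > protein at overlapping sites;
protein-coding calls use the vertebrate mitochondrial translation table
(AGA/AGG stop, ATA Met, TGA Trp).  The theoretical comparison group is the
exhaustive enumeration of every possible genic SNV (each genic position times
its three alternates), against which class proportions of observed variant
sets are compared by the two-sided Fisher exact test.

Records that cross the replication origin are split into two records by the
caller; the listed record order defines the 5'->3' concatenation of the
coding sequence on the plus strand.  An incomplete terminal codon is
completed with adenines, mirroring the post-transcriptional polyadenylation
that completes mitochondrial stop codons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataIntegrityError,
    DegenerateInputError,
    InvalidInputError,
)
from .mutation_model import AA_VERTEBRATE_MITO, _B2I, _encode
from .stats_core import fisher_exact_two_sided

logger = logging.getLogger(__name__)

__all__ = [
    "MitoClass",
    "MitoRecord",
    "MitoAnnotation",
    "HeteroplasmyCall",
    "MitoClassifier",
    "classify_mito_snv",
    "enumerate_genic_snvs",
    "partition_het_hom",
    "class_proportion_compare",
    "class_proportion_table",
    "carrier_frequency_compare",
    "flag_numt_suspect",
    "counts_by_class",
]

BASES = "ACGT"
_STOP = ord("*")


class MitoClass(str, Enum):
    SYNONYMOUS = "synonymous"
    NON_SYNONYMOUS = "non_synonymous"
    TRNA = "tRNA"
    RRNA = "rRNA"
    INTERGENIC = "intergenic"  # excluded upstream; not one of the four classes


FOUR_CLASSES = (MitoClass.SYNONYMOUS, MitoClass.NON_SYNONYMOUS, MitoClass.TRNA, MitoClass.RRNA)


@dataclass(frozen=True)
class MitoRecord:
    gene_id: str
    start_1based: int
    end_1based: int  # inclusive
    strand: str
    type: str  # protein | tRNA | rRNA

    def __post_init__(self):
        if self.type not in ("protein", "tRNA", "rRNA"):
            raise InvalidInputError(f"unknown record type {self.type!r}")
        if self.strand not in "+-":
            raise InvalidInputError(f"bad strand {self.strand!r}")
        if not 1 <= self.start_1based <= self.end_1based:
            raise InvalidInputError(
                f"bad coordinates for {self.gene_id}: {self.start_1based}-{self.end_1based}"
            )

    @property
    def length(self) -> int:
        return self.end_1based - self.start_1based + 1


@dataclass
class MitoAnnotation:
    """Gene table of a circular mitochondrial genome."""

    genome_length: int
    records: list

    def __post_init__(self):
        self.records = [r if isinstance(r, MitoRecord) else MitoRecord(*r) for r in self.records]
        for r in self.records:
            if r.end_1based > self.genome_length:
                raise InvalidInputError(
                    f"{r.gene_id} ends beyond the genome length {self.genome_length}"
                )

    def genic_positions(self) -> np.ndarray:
        """Sorted unique 1-based positions covered by any record."""
        cov = np.zeros(self.genome_length + 1, dtype=bool)
        for r in self.records:
            cov[r.start_1based : r.end_1based + 1] = True
        return np.flatnonzero(cov)


@dataclass(frozen=True)
class HeteroplasmyCall:
    sample_id: str
    pos_1based: int
    ref: str
    alt: str
    vaf: float
    depth: int
    mother_vaf: float | None = None
    father_vaf: float | None = None
    status: str | None = None  # heteroplasmic | homoplasmic

    def __post_init__(self):
        if not 0 <= self.vaf <= 1:
            raise InvalidInputError("vaf must lie in [0, 1]")


class MitoClassifier:
    """Pre-computed per-position classification machinery for one
    (annotation, reference) pair."""

    def __init__(self, annotation: MitoAnnotation, reference: str):
        if len(reference) != annotation.genome_length:
            raise InvalidInputError("reference length does not match the annotation")
        self.annotation = annotation
        self.reference = reference.upper()
        self.genome = _encode(reference)
        # records overlapping each position
        self._pos2rec: dict[int, list[int]] = {}
        for ri, r in enumerate(annotation.records):
            for p in range(r.start_1based, r.end_1based + 1):
                self._pos2rec.setdefault(p, []).append(ri)
        # per protein gene: padded CDS and genomic-position -> CDS-offset map
        self._genes: dict[str, dict] = {}
        n_padded = 0
        by_gene: dict[str, list[MitoRecord]] = {}
        for r in annotation.records:
            if r.type == "protein":
                by_gene.setdefault(r.gene_id, []).append(r)
        for gid, recs in by_gene.items():
            strands = {r.strand for r in recs}
            if len(strands) != 1:
                raise InvalidInputError(f"{gid} records disagree on strand")
            strand = strands.pop()
            pos = np.concatenate(
                [np.arange(r.start_1based, r.end_1based + 1) for r in recs]
            )
            if strand == "-":
                pos = pos[::-1]
            cds = self.genome[pos - 1]
            if strand == "-":
                cds = 3 - cds
            if np.any(cds < 0):
                raise DataIntegrityError(f"{gid} overlaps non-ACGT bases")
            pad = (-len(cds)) % 3
            if pad:
                n_padded += 1
                cds = np.concatenate([cds, np.zeros(pad, dtype=cds.dtype)])  # pad with A
            self._genes[gid] = {
                "strand": strand,
                "cds": cds,
                "offset": {int(p): i for i, p in enumerate(pos)},
            }
        if n_padded:
            logger.info("completed incomplete terminal codons with adenines in %d genes", n_padded)

    def classify(self, pos_1based: int, ref: str, alt: str) -> MitoClass:
        ref, alt = ref.upper(), alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            raise InvalidInputError(f"not an SNV: {ref}>{alt}")
        if not 1 <= pos_1based <= len(self.reference):
            raise InvalidInputError(f"position {pos_1based} outside the genome")
        if self.reference[pos_1based - 1] != ref:
            raise DataIntegrityError(
                f"reference mismatch at m.{pos_1based}: expected {ref}, "
                f"found {self.reference[pos_1based - 1]}"
            )
        recs = [self.annotation.records[i] for i in self._pos2rec.get(pos_1based, [])]
        if not recs:
            return MitoClass.INTERGENIC
        if any(r.type == "tRNA" for r in recs):
            return MitoClass.TRNA
        if any(r.type == "rRNA" for r in recs):
            return MitoClass.RRNA
        # protein records: non-synonymous if the amino acid (or stop status)
        # changes in ANY overlapping record
        for r in recs:
            info = self._genes[r.gene_id]
            off = info["offset"][pos_1based]
            cds = info["cds"]
            alt_i = _B2I[alt] if info["strand"] == "+" else 3 - _B2I[alt]
            ci = off // 3
            codon = cds[3 * ci : 3 * ci + 3]
            ref_aa = AA_VERTEBRATE_MITO[codon[0] * 16 + codon[1] * 4 + codon[2]]
            mut = codon.copy()
            mut[off % 3] = alt_i
            alt_aa = AA_VERTEBRATE_MITO[mut[0] * 16 + mut[1] * 4 + mut[2]]
            if alt_aa != ref_aa:
                return MitoClass.NON_SYNONYMOUS
        return MitoClass.SYNONYMOUS


def classify_mito_snv(
    annotation: MitoAnnotation, reference: str, pos_1based: int, ref: str, alt: str
) -> MitoClass:
    """Classify one mitochondrial SNV (see :class:`MitoClassifier`)."""
    cache = getattr(annotation, "_classifier_cache", None)
    key = (id(reference), len(reference))
    if cache is None or cache[0] != key:
        annotation._classifier_cache = (key, MitoClassifier(annotation, reference))
        cache = annotation._classifier_cache
    return cache[1].classify(pos_1based, ref, alt)


@dataclass
class ExhaustiveSnvSet:
    """Every possible genic, non-excluded SNV with its class."""

    table: pd.DataFrame  # pos_1based, ref, alt, mito_class
    class_totals: dict
    n_positions: int

    @property
    def total(self) -> int:
        return int(sum(self.class_totals.values()))


def _excluded_mask(genome_length: int, excluded_regions) -> np.ndarray:
    mask = np.zeros(genome_length + 1, dtype=bool)
    for iv in excluded_regions or []:
        if len(iv) == 3:  # (chrom, start0, end0)
            _, s, e = iv
        else:
            s, e = iv
        if not 0 <= s < e <= genome_length:
            raise InvalidInputError(f"excluded interval {iv} outside the genome")
        mask[s + 1 : e + 1] = True  # BED 0-based half-open -> 1-based inclusive
    return mask


def enumerate_genic_snvs(
    annotation: MitoAnnotation, reference: str, excluded_regions=None
) -> ExhaustiveSnvSet:
    """Exhaustively classify every genic, non-excluded position x 3 alternates."""
    clf = MitoClassifier(annotation, reference)
    excl = _excluded_mask(annotation.genome_length, excluded_regions)
    rows = []
    totals = {c: 0 for c in FOUR_CLASSES}
    positions = [int(p) for p in annotation.genic_positions() if not excl[p]]
    for p in positions:
        ref = reference[p - 1].upper()
        if ref not in BASES:
            continue
        for alt in BASES:
            if alt == ref:
                continue
            cls = clf.classify(p, ref, alt)
            rows.append((p, ref, alt, cls.value))
            totals[cls] += 1
    table = pd.DataFrame(rows, columns=["pos_1based", "ref", "alt", "mito_class"])
    return ExhaustiveSnvSet(table=table, class_totals=totals, n_positions=len(positions))


@dataclass
class HetHomPartition:
    heteroplasmic: list
    homoplasmic: list
    discarded: list  # (call, reason)


def partition_het_hom(
    calls: Iterable[HeteroplasmyCall], het_min_vaf: float = 0.01, hom_min_vaf: float = 0.95
) -> HetHomPartition:
    """Split calls into heteroplasmic (het_min <= VAF < hom_min), homoplasmic
    (VAF >= hom_min) and discarded (below the detection floor)."""
    if not 0 < het_min_vaf < hom_min_vaf <= 1:
        raise InvalidInputError("require 0 < het_min_vaf < hom_min_vaf <= 1")
    het, hom, out = [], [], []
    for c in calls:
        if c.vaf >= hom_min_vaf:
            hom.append(replace(c, status="homoplasmic"))
        elif c.vaf >= het_min_vaf:
            het.append(replace(c, status="heteroplasmic"))
        else:
            out.append((c, "below_het_min_vaf"))
    return HetHomPartition(heteroplasmic=het, homoplasmic=hom, discarded=out)


def counts_by_class(classes: Iterable) -> dict:
    """Tally MitoClass labels (enum members or their string values)."""
    out = {c: 0 for c in FOUR_CLASSES}
    for c in classes:
        c = MitoClass(c)
        if c is MitoClass.INTERGENIC:
            continue
        out[c] += 1
    return out


@dataclass
class ClassProportionEntry:
    target_class: MitoClass
    target_a: int
    total_a: int
    target_b: int
    total_b: int
    fold: float
    p: float

    @property
    def proportion_a(self) -> float:
        return self.target_a / self.total_a

    @property
    def proportion_b(self) -> float:
        return self.target_b / self.total_b


def class_proportion_compare(
    counts_a: Mapping, counts_b: Mapping, target_class: MitoClass
) -> ClassProportionEntry:
    """Compare the proportion of ``target_class`` variants between two variant
    sets (e.g. observed heteroplasmies vs the exhaustive genic-SNV null) by a
    two-sided Fisher exact test on the literal 2x2 table."""
    target_class = MitoClass(target_class)
    ta = int(counts_a.get(target_class, 0))
    tb = int(counts_b.get(target_class, 0))
    na = int(sum(counts_a.get(c, 0) for c in FOUR_CLASSES))
    nb = int(sum(counts_b.get(c, 0) for c in FOUR_CLASSES))
    if na == 0 or nb == 0:
        raise DegenerateInputError("both variant sets must be non-empty")
    p = fisher_exact_two_sided((ta, na - ta, tb, nb - tb))
    prop_b = tb / nb
    fold = (ta / na) / prop_b if prop_b > 0 else math.inf
    return ClassProportionEntry(
        target_class=target_class, target_a=ta, total_a=na, target_b=tb, total_b=nb,
        fold=fold, p=p,
    )


def class_proportion_table(counts_a: Mapping, counts_b: Mapping) -> pd.DataFrame:
    """One Fisher-exact class-proportion comparison per class."""
    rows = []
    for c in FOUR_CLASSES:
        e = class_proportion_compare(counts_a, counts_b, c)
        rows.append(
            {
                "class": c.value,
                "count_a": e.target_a,
                "total_a": e.total_a,
                "proportion_a": e.proportion_a,
                "count_b": e.target_b,
                "total_b": e.total_b,
                "proportion_b": e.proportion_b,
                "fold": e.fold,
                "p": e.p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CarrierComparison:
    freq1: float
    freq2: float
    fet_p: float
    table: tuple


def carrier_frequency_compare(
    k1: int, n1: int, k2: int, n2: int, *, convention: str = "carriers_vs_total"
) -> CarrierComparison:
    """Compare carrier frequencies between two cohorts.

    ``carriers_vs_total`` (default) tests the table
    ``[[k1, n1], [k2, n2]]`` — the convention of population-database carrier
    screens where carriers are quoted against the cohort size;
    ``carriers_vs_noncarriers`` tests the textbook
    ``[[k1, n1-k1], [k2, n2-k2]]``.  With carrier counts this small the two
    differ only in the third significant digit.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise DegenerateInputError("cohort sizes must be positive")
        if not 0 <= k <= n:
            raise InvalidInputError("carrier counts must lie in [0, n]")
    if convention == "carriers_vs_total":
        table = (k1, n1, k2, n2)
    elif convention == "carriers_vs_noncarriers":
        table = (k1, n1 - k1, k2, n2 - k2)
    else:
        raise ConfigurationError(f"unknown convention {convention!r}")
    return CarrierComparison(
        freq1=k1 / n1, freq2=k2 / n2, fet_p=fisher_exact_two_sided(table), table=table
    )


@dataclass
class NumtFlag:
    status: str  # suspect | not_suspect | not_evaluable
    maternally_inherited: bool | None
    rationale: str


def flag_numt_suspect(call: HeteroplasmyCall, het_min_vaf: float = 0.01) -> NumtFlag:
    """Flag a heteroplasmy call whose trio VAF pattern suggests a nuclear
    mitochondrial segment (NUMT) misalignment.

    A constant allele fraction present in the proband and BOTH parents (each
    parent within a factor of two of the proband) is the transmitted-NUMT
    signature; a single carrier mother at or above the heteroplasmy floor is
    instead flagged as possible maternal inheritance.
    """
    if call.mother_vaf is None or call.father_vaf is None:
        return NumtFlag(status="not_evaluable", maternally_inherited=None,
                        rationale="parental VAFs missing")
    v = call.vaf
    both_within = all(
        pv > 0 and v / 2 <= pv <= 2 * v for pv in (call.mother_vaf, call.father_vaf)
    )
    maternal = call.mother_vaf >= het_min_vaf
    if both_within:
        return NumtFlag(
            status="suspect", maternally_inherited=maternal,
            rationale="allele present in both parents at a comparable fraction "
                      "(transmitted constant-fraction signal)",
        )
    return NumtFlag(
        status="not_suspect", maternally_inherited=maternal,
        rationale="maternal carrier at low heteroplasmy" if maternal
        else "allele absent from parents",
    )
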