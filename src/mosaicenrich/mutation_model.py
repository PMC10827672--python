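"""Reference-sequence machinery for the permutation null.

This module owns the 96 trinucleotide substitution categories (pyrimidine
central base after reverse-complement normalisation), mutational spectra,
codon-based consequence annotation of SNVs on simple gene models, and the
exhaustive per-(category, consequence-class) inventory of eligible sites
("site index") that the permutation test samples from.

Coordinate conventions: variants are 1-based (VCF), gene-model intervals are
0-based half-open (BED).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import (
    BoundaryError,
    DataIntegrityError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BASES",
    "N_CATEGORIES",
    "SUBSTITUTION_TYPES",
    "TrinucleotideSubstitution",
    "ConsequenceClass",
    "GeneModel",
    "SpectrumVector",
    "MutationRateTable",
    "SiteIndex",
    "trinucleotide_category",
    "build_spectrum",
    "annotate_consequence",
    "build_site_index",
]

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}
N_CATEGORIES = 96

#: the six pyrimidine-normalised substitution types, in canonical order
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# substitution-type rank by (pyrimidine centre index, alt index); -1 invalid
_ST = -np.ones((4, 4), dtype=np.int8)
for _i, (_c, _a) in enumerate([(1, 0), (1, 2), (1, 3), (3, 0), (3, 1), (3, 2)]):
    _ST[_c, _a] = _i


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _B2I.items():
        out[arr == ord(b)] = i
    return out


def _decode(idx: Iterable[int]) -> str:
    return "".join(BASES[i] for i in idx)


def _codon_aa_table(table_id: int) -> np.ndarray:
    """ord() codes of the amino acid (or '*') for each of the 64 codons."""
    out = np.empty(64, dtype=np.uint8)
    for i in range(64):
        codon = BASES[i >> 4] + BASES[(i >> 2) & 3] + BASES[i & 3]
        out[i] = ord(str(Seq(codon).translate(table=table_id)))
    return out


AA_STANDARD = _codon_aa_table(1)
AA_VERTEBRATE_MITO = _codon_aa_table(2)
_STOP = ord("*")


class TrinucleotideSubstitution(NamedTuple):
    """One of the 96 pyrimidine-normalised trinucleotide substitution
    categories: the 3-mer ``context`` (central base C or T) and the
    substituted central base ``alt``."""

    context: str
    alt: str

    @property
    def index(self) -> int:
        l, c, r = (_B2I[b] for b in self.context)
        st = _ST[c, _B2I[self.alt]]
        if st < 0:
            raise InvalidInputError(f"not a normalised category: {self}")
        return int(st) * 16 + l * 4 + r

    @classmethod
    def from_index(cls, idx: int) -> "TrinucleotideSubstitution":
        if not 0 <= idx < N_CATEGORIES:
            raise InvalidInputError(f"category index out of range: {idx}")
        st, rest = divmod(idx, 16)
        l, r = divmod(rest, 4)
        ref, alt = SUBSTITUTION_TYPES[st].split(">")
        return cls(context=BASES[l] + ref + BASES[r], alt=alt)

    @property
    def label(self) -> str:
        return f"{self.context[0]}[{self.context[1]}>{self.alt}]{self.context[2]}"


def category_labels() -> list[str]:
    """The 96 category labels in index order (COSMIC-style ordering)."""
    return [TrinucleotideSubstitution.from_index(i).label for i in range(N_CATEGORIES)]


class ConsequenceClass(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    CANONICAL_SPLICE = "canonical_splice"
    NONCODING = "noncoding"


# integer codes used in the site-index arrays; lower rank = more severe
_CLS_CODE = {
    ConsequenceClass.NONSENSE: 0,
    ConsequenceClass.CANONICAL_SPLICE: 1,
    ConsequenceClass.MISSENSE: 2,
    ConsequenceClass.SYNONYMOUS: 3,
    ConsequenceClass.NONCODING: 4,
}
_CODE_CLS = {v: k for k, v in _CLS_CODE.items()}

LOF_CLASSES = frozenset({ConsequenceClass.NONSENSE, ConsequenceClass.CANONICAL_SPLICE})


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene model.

    ``cds_intervals`` are 0-based half-open intervals on ``chrom``, sorted and
    non-overlapping; concatenated in genomic order (reversed for '-' strand
    genes) they form the coding sequence.  A CDS length not divisible by 3 is
    tolerated: the incomplete tail codon is excluded from classification.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple
    phase: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")
        iv = tuple((int(s), int(e)) for s, e in self.cds_intervals)
        object.__setattr__(self, "cds_intervals", iv)
        prev_end = None
        for s, e in iv:
            if s < 0 or e <= s:
                raise InvalidInputError(f"bad interval ({s}, {e}) in {self.gene_id}")
            if prev_end is not None and s < prev_end:
                raise InvalidInputError(f"intervals overlap or are unsorted in {self.gene_id}")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_positions(self) -> np.ndarray:
        """Genomic 0-based CDS positions, ascending."""
        return np.concatenate([np.arange(s, e) for s, e in self.cds_intervals])

    def splice_positions(self) -> np.ndarray:
        """Genomic 0-based positions of the canonical 2-bp splice
        dinucleotides (empty for single-interval models)."""
        if len(self.cds_intervals) < 2:
            return np.empty(0, dtype=int)
        pos = []
        for i, (s, e) in enumerate(self.cds_intervals):
            if i > 0:
                pos.extend([s - 2, s - 1])
            if i < len(self.cds_intervals) - 1:
                pos.extend([e, e + 1])
        return np.asarray(sorted(set(pos)), dtype=int)


def _check_ref(reference: Mapping[str, str], chrom: str, pos_1based: int, ref_base: str) -> str:
    try:
        seq = reference[chrom]
    except KeyError:
        raise InvalidInputError(f"unknown sequence {chrom!r}") from None
    if not 1 <= pos_1based <= len(seq):
        raise InvalidInputError(f"position {chrom}:{pos_1based} outside the reference")
    found = seq[pos_1based - 1].upper()
    if ref_base.upper() != found:
        raise DataIntegrityError(
            f"reference mismatch at {chrom}:{pos_1based}: expected {ref_base}, found {found}"
        )
    return seq


def trinucleotide_category(
    reference: Mapping[str, str], chrom: str, pos_1based: int, ref_base: str, alt_base: str
) -> TrinucleotideSubstitution:
    """Pyrimidine-normalised trinucleotide substitution category of an SNV."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base == alt_base or len(ref_base) != 1 or len(alt_base) != 1:
        raise InvalidInputError(f"not an SNV: {ref_base}>{alt_base}")
    if ref_base not in BASES or alt_base not in BASES:
        raise InvalidInputError(f"non-ACGT allele: {ref_base}>{alt_base}")
    seq = _check_ref(reference, chrom, pos_1based, ref_base)
    if pos_1based == 1 or pos_1based == len(seq):
        raise BoundaryError(f"{chrom}:{pos_1based} lacks a flanking base")
    ctx = seq[pos_1based - 2 : pos_1based + 1].upper()
    if any(b not in BASES for b in ctx):
        raise BoundaryError(f"non-ACGT context {ctx!r} at {chrom}:{pos_1based}")
    if ctx[1] in "AG":  # purine centre: reverse-complement normalise
        ctx = str(Seq(ctx).reverse_complement())
        alt_base = str(Seq(alt_base).complement())
    return TrinucleotideSubstitution(context=ctx, alt=alt_base)


@dataclass
class SpectrumVector:
    """A mutational spectrum: 96 trinucleotide categories (``trinuc96``) or
    the 6 substitution types (``subst6``)."""

    counts: np.ndarray
    mode: str
    n_skipped: int = 0

    def __post_init__(self):
        expected = {"trinuc96": N_CATEGORIES, "subst6": 6}
        if self.mode not in expected:
            raise InvalidInputError(f"unknown spectrum mode {self.mode!r}")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (expected[self.mode],):
            raise InvalidInputError("counts length does not match mode")
        if np.any(self.counts < 0):
            raise InvalidInputError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self):
        """Tab-friendly category/count table (96 labels or 6 substitution types)."""
        import pandas as pd

        labels = category_labels() if self.mode == "trinuc96" else list(SUBSTITUTION_TYPES)
        return pd.DataFrame({"category": labels, "count": self.counts})

    @property
    def fractions(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts)
        return self.counts / self.total


def _variant_tuple(v):
    if isinstance(v, tuple):
        return v
    return (v.chrom, v.pos_1based, v.ref, v.alt)


def build_spectrum(variants, reference: Mapping[str, str], mode: str = "trinuc96") -> SpectrumVector:
    """Histogram of SNV substitution categories.

    Non-SNV records and records without full flanking context are skipped
    (tallied in ``n_skipped``) rather than rejected.
    """
    size = N_CATEGORIES if mode == "trinuc96" else 6
    counts = np.zeros(size)
    skipped = 0
    for v in variants:
        chrom, pos, ref, alt = _variant_tuple(v)
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            skipped += 1
            continue
        try:
            cat = trinucleotide_category(reference, chrom, pos, ref, alt)
        except BoundaryError:
            skipped += 1
            continue
        idx = cat.index
        counts[idx if mode == "trinuc96" else idx // 16] += 1
    if skipped:
        logger.warning("build_spectrum skipped %d non-SNV or edge records", skipped)
    return SpectrumVector(counts=counts, mode=mode, n_skipped=skipped)


@dataclass(frozen=True)
class MutationRateTable:
    """Relative mutability of each of the 96 substitution categories."""

    rates: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (N_CATEGORIES,):
            raise InvalidInputError("rate table must have 96 entries")
        if np.any(r < 0) or not np.any(r > 0):
            raise InvalidInputError("rates must be non-negative and not all zero")
        object.__setattr__(self, "rates", r)

    @classmethod
    def flat_with_cpg(cls, cpg_multiplier: float = 10.0) -> "MutationRateTable":
        """Flat table with C>T transitions in a CpG context boosted.

        A deliberately simple stand-in for empirical context-specific rates:
        it preserves the qualitative dominance of CpG transitions and
        exercises the context stratification without claiming realism.
        """
        r = np.ones(N_CATEGORIES)
        for idx in range(N_CATEGORIES):
            cat = TrinucleotideSubstitution.from_index(idx)
            if cat.context[1] == "C" and cat.context[2] == "G" and cat.alt == "T":
                r[idx] = cpg_multiplier
        return cls(rates=r)


# ---------------------------------------------------------------------------
# consequence annotation
# ---------------------------------------------------------------------------


def _gene_coding_arrays(reference, model: GeneModel):
    """(genomic positions in CDS order, CDS base indices) for a gene.

    ``reference`` may map chromosome names to sequences or to pre-encoded
    int8 arrays (the site-index builder passes the latter).
    """
    g = reference[model.chrom]
    if not isinstance(g, np.ndarray):
        g = _encode(g)
    posf = model.cds_positions()
    if posf[-1] >= len(g):
        raise InvalidInputError(f"{model.gene_id} extends past the end of {model.chrom}")
    if model.strand == "+":
        pos = posf
        cds = g[pos]
    else:
        pos = posf[::-1]
        cds = 3 - g[pos]
    if np.any(cds < 0):
        raise DataIntegrityError(f"{model.gene_id} overlaps non-ACGT reference bases")
    return pos, cds


def _codon_consequence(cds: np.ndarray, offset: int, alt_cds_base: int, aa_table: np.ndarray) -> ConsequenceClass:
    """Class of substituting ``alt_cds_base`` at CDS ``offset`` (0-based)."""
    l3 = len(cds) - len(cds) % 3
    if offset >= l3:
        return ConsequenceClass.NONCODING  # incomplete tail codon, not classifiable
    ci = offset // 3
    codon = cds[3 * ci : 3 * ci + 3]
    ref_aa = aa_table[codon[0] * 16 + codon[1] * 4 + codon[2]]
    mutated = codon.copy()
    mutated[offset % 3] = alt_cds_base
    alt_aa = aa_table[mutated[0] * 16 + mutated[1] * 4 + mutated[2]]
    if alt_aa == ref_aa:
        return ConsequenceClass.SYNONYMOUS
    if alt_aa == _STOP:
        return ConsequenceClass.NONSENSE
    # amino-acid change, including stop loss
    return ConsequenceClass.MISSENSE


def annotate_consequence(
    reference: Mapping[str, str],
    gene_models: Sequence[GeneModel],
    chrom: str,
    pos_1based: int,
    ref: str,
    alt: str,
) -> ConsequenceClass:
    """Codon-based consequence of an SNV under the standard nuclear code.

    Positions in the 2-bp intronic dinucleotides flanking an internal CDS
    boundary are ``canonical_splice``; positions outside CDS and splice are
    ``noncoding``.  Overlapping gene models are resolved by severity
    (nonsense > canonical_splice > missense > synonymous).
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise InvalidInputError(f"not an SNV: {ref}>{alt}")
    _check_ref(reference, chrom, pos_1based, ref)
    p0 = pos_1based - 1
    calls: list[ConsequenceClass] = []
    for m in gene_models:
        if m.chrom != chrom:
            continue
        if len(m.cds_intervals) > 1 and p0 in m.splice_positions():
            calls.append(ConsequenceClass.CANONICAL_SPLICE)
            continue
        if not any(s <= p0 < e for s, e in m.cds_intervals):
            continue
        pos, cds = _gene_coding_arrays(reference, m)
        offset = int(np.nonzero(pos == p0)[0][0])
        alt_cds = _B2I[alt] if m.strand == "+" else 3 - _B2I[alt]
        calls.append(_codon_consequence(cds, offset, alt_cds, AA_STANDARD))
    if not calls:
        return ConsequenceClass.NONCODING
    return _CODE_CLS[min(_CLS_CODE[c] for c in calls)]


# ---------------------------------------------------------------------------
# site index
# ---------------------------------------------------------------------------


class SiteIndex:
    """Exhaustive inventory of every eligible (position, alternate) keyed by
    (trinucleotide category, consequence class).

    The index is a partition: each (chrom, pos, alt) appears under exactly
    one key.  Sites whose position lacks a full trinucleotide context (first
    and last reference base) and incomplete tail codons are excluded, with
    counts recorded.
    """

    def __init__(self, chroms, chrom_idx, pos, alt, cat, cls, gene_code, gene_ids,
                 n_edge_excluded=0, n_tail_excluded=0):
        order = np.lexsort((gene_code, cls, cat))
        self.chroms = list(chroms)
        self.chrom_idx = np.asarray(chrom_idx)[order]
        self.pos = np.asarray(pos)[order]            # 0-based genomic
        self.alt = np.asarray(alt)[order]            # base index on the genome strand
        self.cat = np.asarray(cat)[order]            # 0..95
        self.cls = np.asarray(cls)[order]            # _CLS_CODE values
        self.gene_code = np.asarray(gene_code)[order]
        self.gene_ids = list(gene_ids)
        self.n_edge_excluded = int(n_edge_excluded)
        self.n_tail_excluded = int(n_tail_excluded)
        # contiguous slices per (cat, cls) key
        keykern = self.cat.astype(np.int32) * 8 + self.cls.astype(np.int32)
        bounds = np.flatnonzero(np.diff(keykern)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(keykern)]])
        self._slices = {
            (int(self.cat[s]), _CODE_CLS[int(self.cls[s])]): (int(s), int(e))
            for s, e in zip(starts, ends)
        }

    def __len__(self) -> int:
        return len(self.pos)

    def keys(self):
        return set(self._slices)

    def total(self, cat_index: int, consequence: ConsequenceClass) -> int:
        s = self._slices.get((int(cat_index), consequence))
        return 0 if s is None else s[1] - s[0]

    def totals(self) -> dict:
        return {k: e - s for k, (s, e) in self._slices.items()}

    def sites_for_key(self, cat_index: int, consequence: ConsequenceClass):
        """(positions, genome-strand alt indices, gene codes) for one key."""
        s = self._slices.get((int(cat_index), consequence))
        if s is None:
            return (np.empty(0, int),) * 3
        sl = slice(*s)
        return self.pos[sl], self.alt[sl], self.gene_code[sl]

    def member_mask(self, members: Iterable[str], *, strict: bool = True) -> np.ndarray:
        """Boolean mask over the gene universe for a gene set."""
        from .errors import ConfigurationError

        idx = {g: i for i, g in enumerate(self.gene_ids)}
        mask = np.zeros(len(self.gene_ids), dtype=bool)
        unknown = []
        for g in members:
            i = idx.get(g)
            if i is None:
                unknown.append(g)
            else:
                mask[i] = True
        if unknown and strict:
            raise ConfigurationError(f"genes not in the model universe: {sorted(unknown)[:5]} ...")
        return mask

    def in_set_fraction(self, cat_index: int, consequence: ConsequenceClass, mask: np.ndarray) -> float:
        s = self._slices.get((int(cat_index), consequence))
        if s is None or s[1] == s[0]:
            from .errors import StratificationError

            raise StratificationError((cat_index, consequence.value))
        sl = slice(*s)
        return float(mask[self.gene_code[sl]].mean())


def _categories_vectorised(genome: np.ndarray, pos: np.ndarray, alt: np.ndarray):
    """Category index per (0-based pos, genome-strand alt index); -1 where the
    position lacks a full ACGT trinucleotide context."""
    n = len(genome)
    valid = (pos > 0) & (pos < n - 1)
    cat = np.full(len(pos), -1, dtype=np.int16)
    if not valid.any():
        return cat
    p = pos[valid]
    left, centre, right = genome[p - 1], genome[p], genome[p + 1]
    a = alt[valid]
    ok = (left >= 0) & (centre >= 0) & (right >= 0)
    pur = (centre == 0) | (centre == 2)
    l2 = np.where(pur, 3 - right, left)
    r2 = np.where(pur, 3 - left, right)
    c2 = np.where(pur, 3 - centre, centre)
    a2 = np.where(pur, 3 - a, a)
    st = np.where(ok, _ST[np.clip(c2, 0, 3), np.clip(a2, 0, 3)], -1)
    res = np.where((st >= 0) & ok, st * 16 + l2 * 4 + r2, -1)
    cat[valid] = res.astype(np.int16)
    return cat


def build_site_index(
    reference: Mapping[str, str],
    gene_models: Sequence[GeneModel],
    rate_table: MutationRateTable | None = None,
) -> SiteIndex:
    """Enumerate every (CDS ∪ splice) position × alternate of the gene models.

    ``rate_table`` is accepted for interface symmetry with the synthetic
    generator but does not weight the index: placement is uniform within each
    (category, class) stratum and rate differences act between strata through
    the conditioning on observed categories.
    """
    enc = {c: _encode(s) for c, s in reference.items()}
    chroms = sorted(enc)
    cmap = {c: i for i, c in enumerate(chroms)}
    gene_ids = [m.gene_id for m in gene_models]
    if len(set(gene_ids)) != len(gene_ids):
        raise InvalidInputError("duplicate gene_id in gene models")

    parts = {k: [] for k in ("chrom_idx", "pos", "alt", "cls", "gene")}
    n_tail = 0
    for gi, m in enumerate(gene_models):
        g = enc[m.chrom]
        pos, cds = _gene_coding_arrays(enc, m)
        L = len(cds)
        L3 = L - L % 3
        n_tail += (L - L3) * 3
        cds3, pos3 = cds[:L3], pos[:L3]
        codons = cds3[0::3] * 16 + cds3[1::3] * 4 + cds3[2::3]
        ref_aa = AA_STANDARD[codons]
        ci = np.arange(L3) // 3
        mult = np.array([16, 4, 1])[np.arange(L3) % 3]
        for k in (1, 2, 3):
            alt_cds = (cds3 + k) % 4
            mutated = codons[ci] + (alt_cds - cds3) * mult
            aa = AA_STANDARD[mutated]
            cls = np.where(
                aa == ref_aa[ci],
                _CLS_CODE[ConsequenceClass.SYNONYMOUS],
                np.where(aa == _STOP, _CLS_CODE[ConsequenceClass.NONSENSE],
                         _CLS_CODE[ConsequenceClass.MISSENSE]),
            ).astype(np.int8)
            galt = alt_cds if m.strand == "+" else 3 - alt_cds
            parts["pos"].append(pos3)
            parts["alt"].append(galt.astype(np.int8))
            parts["cls"].append(cls)
            parts["gene"].append(np.full(L3, gi, dtype=np.int32))
            parts["chrom_idx"].append(np.full(L3, cmap[m.chrom], dtype=np.int16))
        sp = m.splice_positions()
        if len(sp):
            centre = g[sp]
            for k in (1, 2, 3):
                parts["pos"].append(sp)
                parts["alt"].append(((centre + k) % 4).astype(np.int8))
                parts["cls"].append(
                    np.full(len(sp), _CLS_CODE[ConsequenceClass.CANONICAL_SPLICE], dtype=np.int8)
                )
                parts["gene"].append(np.full(len(sp), gi, dtype=np.int32))
                parts["chrom_idx"].append(np.full(len(sp), cmap[m.chrom], dtype=np.int16))

    chrom_idx = np.concatenate(parts["chrom_idx"])
    pos = np.concatenate(parts["pos"])
    alt = np.concatenate(parts["alt"])
    cls = np.concatenate(parts["cls"])
    gene = np.concatenate(parts["gene"])

    cat = np.empty(len(pos), dtype=np.int16)
    for c, i in cmap.items():
        m = chrom_idx == i
        cat[m] = _categories_vectorised(enc[c], pos[m], alt[m].astype(np.int16))

    keep = cat >= 0
    n_edge = int((~keep).sum())
    chrom_idx, pos, alt, cat, cls, gene = (
        a[keep] for a in (chrom_idx, pos, alt, cat, cls, gene)
    )

    # resolve overlapping gene models: keep the most severe class per site
    site_key = (chrom_idx.astype(np.int64) << 40) | (pos.astype(np.int64) << 2) | alt.astype(np.int64)
    if len(np.unique(site_key)) != len(site_key):
        order = np.lexsort((cls, site_key))
        sk = site_key[order]
        first = np.concatenate([[True], np.diff(sk) != 0])
        sel = order[first]
        chrom_idx, pos, alt, cat, cls, gene = (
            a[sel] for a in (chrom_idx, pos, alt, cat, cls, gene)
        )

    if n_edge:
        logger.info("site index excluded %d edge-context sites", n_edge)
    if n_tail:
        logger.info("site index excluded %d incomplete-tail-codon sites", n_tail)
    return SiteIndex(
        chroms, chrom_idx, pos, alt, cat, cls, gene, gene_ids,
        n_edge_excluded=n_edge, n_tail_excluded=n_tail,
    )


def consequence_from_code(code: int) -> ConsequenceClass:
    return _CODE_CLS[int(code)]


def consequence_code(cls: ConsequenceClass) -> int:
    return _CLS_CODE[cls]
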