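"""Trinucleotide-context, class-preserving permutation test of gene-set
enrichment for de novo and mosaic variants.

Each permutation independently re-places every observed (class-filtered)
variant uniformly at random among the eligible sites that share both its
trinucleotide substitution category and its consequence class, and records
the number landing in the gene set.  Conditioning on the observed categories
and classes is how gene length and mutational context are taken into
account; the empirical p-value is the fraction of permutations reaching at
least the observed in-set count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, StratificationError
from .mutation_model import (
    ConsequenceClass,
    SiteIndex,
    TrinucleotideSubstitution,
    LOF_CLASSES,
    trinucleotide_category,
)
from .stats_core import EmpiricalPValue, adjust_p, empirical_p

__all__ = [
    "ObservedVariant",
    "ObservedVariantSet",
    "GeneSet",
    "EnrichmentResult",
    "CLASS_FILTERS",
    "count_hits",
    "permutation_null",
    "enrichment_test",
    "multi_geneset_run",
    "observed_set_from_calls",
]


@dataclass(frozen=True)
class ObservedVariant:
    sample_id: str
    gene_id: str
    consequence: ConsequenceClass
    category: TrinucleotideSubstitution
    deleterious: bool = False


@dataclass
class ObservedVariantSet:
    """SNV observations feeding the permutation test."""

    entries: list
    cohort_size: int

    def __post_init__(self):
        if self.cohort_size <= 0:
            raise InvalidInputError("cohort_size must be positive")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols. An empty set is representable (hit counts
    are zero) but carries no information for testing."""

    name: str
    members: frozenset

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))


CLASS_FILTERS: dict[str, Callable[[ObservedVariant], bool]] = {
    "all": lambda e: True,
    "deleterious": lambda e: e.deleterious,
    "synonymous": lambda e: e.consequence is ConsequenceClass.SYNONYMOUS,
    "non_synonymous": lambda e: e.consequence
    in (ConsequenceClass.MISSENSE, ConsequenceClass.NONSENSE, ConsequenceClass.CANONICAL_SPLICE),
    "lof": lambda e: e.consequence in LOF_CLASSES,
}


def _predicate(class_filter) -> tuple[str, Callable]:
    if callable(class_filter):
        return getattr(class_filter, "__name__", "custom"), class_filter
    try:
        return class_filter, CLASS_FILTERS[class_filter]
    except KeyError:
        raise ConfigurationError(
            f"unknown class filter {class_filter!r}; known: {sorted(CLASS_FILTERS)}"
        ) from None


def count_hits(variants: ObservedVariantSet, gene_set: GeneSet, class_filter) -> int:
    """Number of class-filtered variants whose gene is in the set
    (variant-level counting: a gene hit twice counts twice)."""
    _, pred = _predicate(class_filter)
    return sum(1 for e in variants.entries if pred(e) and e.gene_id in gene_set.members)


def _stratum_fractions(variants, site_index: SiteIndex, gene_set: GeneSet, pred):
    """Per-(category, class) stratum: (#observed variants, in-set site fraction)."""
    mask = site_index.member_mask(gene_set.members)
    strata: dict[tuple, int] = {}
    for e in variants.entries:
        if not pred(e):
            continue
        key = (e.category.index, e.consequence)
        strata[key] = strata.get(key, 0) + 1
    out = []
    for key in sorted(strata, key=lambda k: (k[0], k[1].value)):
        cat_idx, cls = key
        if site_index.total(cat_idx, cls) == 0:
            raise StratificationError((TrinucleotideSubstitution.from_index(cat_idx).label, cls.value))
        out.append((key, strata[key], site_index.in_set_fraction(cat_idx, cls, mask)))
    return out


def permutation_null(
    variants: ObservedVariantSet,
    site_index: SiteIndex,
    gene_set: GeneSet,
    class_filter,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Null distribution of in-set hit counts over ``n_perm`` permutations.

    Within a stratum every eligible site is equally likely, so the in-set
    hits of the stratum's variants are i.i.d. Bernoulli draws with the
    stratum's in-set site fraction; strata are summed.  Per-stratum RNG
    streams are split deterministically from the master seed, so the result
    depends only on ``(inputs, seed, n_perm)``.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    _, pred = _predicate(class_filter)
    strata = _stratum_fractions(variants, site_index, gene_set, pred)
    null = np.zeros(n_perm, dtype=np.int64)
    children = np.random.SeedSequence(seed).spawn(len(strata))
    for (key, m, f), child in zip(strata, children):
        rng = np.random.default_rng(child)
        null += rng.binomial(m, f, size=n_perm)
    return null


@dataclass
class EnrichmentResult:
    gene_set: str
    class_filter: str
    observed_hits: int
    expected_hits: float
    fold: float | None
    p: EmpiricalPValue
    n_perm: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "gene_set": self.gene_set,
            "class_filter": self.class_filter,
            "observed": self.observed_hits,
            "expected": self.expected_hits,
            "fold": self.fold,
            "p": self.p.p,
            "exceedances": self.p.exceedances,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def enrichment_test(
    variants: ObservedVariantSet,
    site_index: SiteIndex,
    gene_set: GeneSet,
    class_filter,
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation gene-set enrichment test for one (set, class) pair.

    Ties at the observed count are exceedances (the p-value is the fraction
    of permutations with a count >= observed).
    """
    name, _ = _predicate(class_filter)
    observed = count_hits(variants, gene_set, class_filter)
    null = permutation_null(variants, site_index, gene_set, class_filter, n_perm, seed)
    r = int((null >= observed).sum())
    p = empirical_p(r, n_perm)
    expected = float(null.mean())
    fold = observed / expected if expected > 0 else None
    return EnrichmentResult(
        gene_set=gene_set.name,
        class_filter=name,
        observed_hits=observed,
        expected_hits=expected,
        fold=fold,
        p=p,
        n_perm=n_perm,
        seed=seed,
    )


def multi_geneset_run(
    variants: ObservedVariantSet,
    site_index: SiteIndex,
    gene_sets: Sequence[GeneSet],
    class_filters: Sequence,
    n_perm: int = 10_000,
    seed: int = 0,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """One enrichment test per (gene set, class filter) pair.

    Per-pair seeds are split deterministically from the master seed.  The
    result table carries Bonferroni (over ``n_tests``, default the number of
    pairs) and Benjamini-Hochberg adjusted p-values.
    """
    if not gene_sets:
        raise ConfigurationError("at least one gene set is required")
    names = [g.name for g in gene_sets]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate gene set names")
    pairs = [(g, f) for g in gene_sets for f in class_filters]
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    results = []
    for (g, f), child in zip(pairs, children):
        pair_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        results.append(enrichment_test(variants, site_index, g, f, n_perm=n_perm, seed=pair_seed))
    df = pd.DataFrame([r.as_dict() for r in results])
    raw = df["p"].tolist()
    df["p_bonferroni"] = adjust_p(raw, "bonferroni", n_tests or len(pairs)).adjusted_p
    df["p_bh"] = adjust_p(raw, "benjamini_hochberg").adjusted_p
    return df


def observed_set_from_calls(calls, reference, cohort_size: int) -> ObservedVariantSet:
    """Build the observed SNV set from filtered candidate calls.

    INDELs and calls without a gene or consequence annotation are dropped
    (they are bookkeeping-only for validation), matching the restriction of
    the enrichment comparison to SNVs.
    """
    entries = []
    for c in calls:
        if c.variant_type != "SNV" or c.gene_id is None or c.consequence is None:
            continue
        cat = trinucleotide_category(reference, c.chrom, c.pos_1based, c.ref, c.alt)
        entries.append(
            ObservedVariant(
                sample_id=c.sample_id,
                gene_id=c.gene_id,
                consequence=c.consequence,
                category=cat,
                deleterious=c.deleterious,
            )
        )
    return ObservedVariantSet(entries=entries, cohort_size=cohort_size)
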