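"""Hard-filter selection of mosaic and germline de novo variants from trio
candidate-call tables, per-individual Poisson outlier exclusion, and
validation bookkeeping.

A call passes the de novo filters when it has no parental evidence beyond the
configured tolerance, adequate depth and alternate-read support, is absent
from the population/panel blacklists, and is not above the population allele
frequency ceiling.  Passing calls are split into mosaic and germline by an
exact one-sided binomial test of the variant allele fraction against the
germline expectation of 0.5 combined with a hard VAF ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError
from .mutation_model import ConsequenceClass

__all__ = [
    "CandidateCall",
    "FilterConfig",
    "ValidationRecord",
    "RejectionReason",
    "DeNovoPartition",
    "vaf",
    "select_de_novo",
    "poisson_outlier_exclusion",
    "validation_summary",
    "per_sample_rate",
]


@dataclass(frozen=True)
class CandidateCall:
    """One candidate variant observation in one proband, with parental read
    evidence and annotations."""

    sample_id: str
    chrom: str
    pos_1based: int
    ref: str
    alt: str
    alt_reads: int
    depth: int
    father_alt_reads: int | None = None
    father_depth: int | None = None
    mother_alt_reads: int | None = None
    mother_depth: int | None = None
    pon_member: bool = False
    pop_af: float = 0.0
    blacklist_member: bool = False
    gene_id: str | None = None
    consequence: ConsequenceClass | None = None
    mpc_ge2: bool = False
    all7_damaging: bool = False
    variant_type: str = "SNV"

    def __post_init__(self):
        if not 0 <= self.alt_reads <= self.depth:
            raise InvalidInputError(
                f"alt_reads must lie in [0, depth] at {self.chrom}:{self.pos_1based}"
            )
        for who in ("father", "mother"):
            ar, dp = getattr(self, f"{who}_alt_reads"), getattr(self, f"{who}_depth")
            if ar is not None and dp is not None and not 0 <= ar <= dp:
                raise InvalidInputError(f"{who} read counts inconsistent at {self.chrom}:{self.pos_1based}")
        if not 0.0 <= self.pop_af <= 1.0:
            raise InvalidInputError("pop_af must lie in [0, 1]")
        if self.variant_type not in ("SNV", "INDEL"):
            raise InvalidInputError(f"unknown variant_type {self.variant_type!r}")

    @property
    def vaf(self) -> float:
        return vaf(self.alt_reads, self.depth)

    @property
    def deleterious(self) -> bool:
        """LoF (nonsense, canonical splice; frameshift for INDELs) or damaging
        missense (MPC >= 2 or all-seven-predictor consensus)."""
        if self.variant_type == "INDEL":
            return True  # frameshift assumption for coding INDELs
        if self.consequence in (ConsequenceClass.NONSENSE, ConsequenceClass.CANONICAL_SPLICE):
            return True
        return self.consequence is ConsequenceClass.MISSENSE and (self.mpc_ge2 or self.all7_damaging)


@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter thresholds.

    The defaults are documented operating points, not a claim about any
    particular study's unpublished supplementary values.
    """

    min_depth: int = 100
    min_alt_reads: int = 3
    vaf_min: float = 0.01
    vaf_max_mosaic: float = 0.35
    max_parent_alt_reads: int = 1
    max_pop_af: float = 0.0
    mosaic_binomial_alpha: float = 0.001
    outlier_alpha: float = 0.05

    def __post_init__(self):
        if not 0 <= self.vaf_min < self.vaf_max_mosaic <= 0.5:
            raise InvalidInputError("require 0 <= vaf_min < vaf_max_mosaic <= 0.5")
        for p in (self.mosaic_binomial_alpha, self.outlier_alpha):
            if not 0 < p < 1:
                raise InvalidInputError("alphas must lie in (0, 1)")


class RejectionReason(str, Enum):
    PARENTAL_EVIDENCE = "parental_evidence"
    LOW_DEPTH = "low_depth"
    LOW_ALT_READS = "low_alt_reads"
    LOW_VAF = "low_vaf"
    POPULATION_FREQUENCY = "population_frequency"
    PANEL_OF_NORMALS = "panel_of_normals"
    BLACKLIST = "blacklist"


@dataclass
class DeNovoPartition:
    mosaic: list
    germline: list
    rejected: list  # (call, tuple of RejectionReason)

    @property
    def attrition(self) -> dict:
        counts: dict[str, int] = {r.value: 0 for r in RejectionReason}
        for _, reasons in self.rejected:
            for r in reasons:
                counts[r.value] += 1
        counts["input"] = len(self.mosaic) + len(self.germline) + len(self.rejected)
        counts["mosaic"] = len(self.mosaic)
        counts["germline"] = len(self.germline)
        counts["rejected"] = len(self.rejected)
        return counts


def vaf(alt_reads: int, depth: int) -> float:
    """Variant allele fraction ``alt_reads / depth``."""
    if depth <= 0:
        raise DegenerateInputError("VAF undefined at zero depth")
    if not 0 <= alt_reads <= depth:
        raise InvalidInputError("alt_reads must lie in [0, depth]")
    return alt_reads / depth


def select_de_novo(calls: Iterable[CandidateCall], config: FilterConfig | None = None) -> DeNovoPartition:
    """Partition candidate trio calls into mosaic, germline and rejected sets.

    Every rejection carries the full tuple of machine-readable reason codes,
    so the outcome is independent of any filter evaluation order.
    """
    config = config or FilterConfig()
    mosaic, germline, rejected = [], [], []
    for call in calls:
        if call.father_alt_reads is None or call.mother_alt_reads is None:
            raise InvalidInputError(
                f"trio call at {call.chrom}:{call.pos_1based} is missing parental read counts"
            )
        reasons = []
        if (call.father_alt_reads > config.max_parent_alt_reads
                or call.mother_alt_reads > config.max_parent_alt_reads):
            reasons.append(RejectionReason.PARENTAL_EVIDENCE)
        if call.depth < config.min_depth:
            reasons.append(RejectionReason.LOW_DEPTH)
        if call.alt_reads < config.min_alt_reads:
            reasons.append(RejectionReason.LOW_ALT_READS)
        if call.depth > 0 and call.vaf < config.vaf_min:
            reasons.append(RejectionReason.LOW_VAF)
        if call.pop_af > config.max_pop_af:
            reasons.append(RejectionReason.POPULATION_FREQUENCY)
        if call.pon_member:
            reasons.append(RejectionReason.PANEL_OF_NORMALS)
        if call.blacklist_member:
            reasons.append(RejectionReason.BLACKLIST)
        if reasons:
            rejected.append((call, tuple(sorted(reasons, key=lambda r: r.value))))
            continue
        # mosaic iff the VAF deficit below 0.5 is binomially implausible AND
        # the VAF is under the mosaic ceiling
        p_low = float(stats.binom.cdf(call.alt_reads, call.depth, 0.5))
        if p_low < config.mosaic_binomial_alpha and call.vaf < config.vaf_max_mosaic:
            mosaic.append(call)
        else:
            germline.append(call)
    return DeNovoPartition(mosaic=mosaic, germline=germline, rejected=rejected)


@dataclass
class OutlierResult:
    kept: list
    excluded: list
    rate: float
    alpha: float

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def poisson_outlier_exclusion(per_sample_counts, outlier_alpha: float = 0.05) -> OutlierResult:
    """Exclude samples whose variant count is a Poisson upper-tail outlier.

    The cohort rate is estimated as the mean count; sample ``i`` is excluded
    when ``P(X >= count_i)`` under ``Poisson(mean)`` is below
    ``outlier_alpha / n_samples`` (Bonferroni across samples).
    """
    if isinstance(per_sample_counts, Mapping):
        ids = list(per_sample_counts)
        counts = np.asarray([per_sample_counts[i] for i in ids], dtype=float)
    else:
        counts = np.asarray(list(per_sample_counts), dtype=float)
        ids = list(range(len(counts)))
    if len(counts) < 2:
        raise InvalidInputError("outlier exclusion requires at least two samples")
    if np.any(counts < 0):
        raise InvalidInputError("counts must be non-negative")
    lam = float(counts.mean())
    tail = stats.poisson.sf(counts - 1, lam)  # P(X >= count)
    cut = outlier_alpha / len(counts)
    excluded = [i for i, t in zip(ids, tail) if t < cut]
    kept = [i for i in ids if i not in set(excluded)]
    return OutlierResult(kept=kept, excluded=excluded, rate=lam, alpha=outlier_alpha)


@dataclass(frozen=True)
class ValidationRecord:
    variant_key: str
    variant_type: str
    validated: bool


@dataclass
class ValidationSummary:
    per_type: dict  # type -> (validated, tested, rate)
    pooled: tuple   # (validated, tested, rate)


def validation_summary(records: Sequence) -> ValidationSummary:
    """Validation rates per variant type and pooled.

    Accepts :class:`ValidationRecord` objects or ``(variant_type, validated)``
    pairs.  Rates are kept at full precision; rounding is presentation-side.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("no validation records")
    per: dict[str, list[int]] = {}
    for r in records:
        vt, ok = (r.variant_type, r.validated) if hasattr(r, "variant_type") else r
        tested = per.setdefault(vt, [0, 0])
        tested[1] += 1
        tested[0] += bool(ok)
    per_type = {t: (v, n, v / n) for t, (v, n) in per.items()}
    v = sum(x[0] for x in per.values())
    n = sum(x[1] for x in per.values())
    return ValidationSummary(per_type=per_type, pooled=(v, n, v / n))


def per_sample_rate(n_variants: int, n_samples: int) -> float:
    """Variants per sample (also serves for simple detection-fold ratios)."""
    if n_samples <= 0:
        raise DegenerateInputError("n_samples must be positive")
    if n_variants < 0:
        raise InvalidInputError("n_variants must be non-negative")
    return n_variants / n_samples
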