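"""Synthetic fixtures with the statistical structure the pipeline assumes.

The trio generator emulates a deep-exome trio cohort: per-proband mosaic
variant counts are Poisson, variant placement follows a context-specific
mutability table, a planted gene set can carry a rate multiplier for
deleterious variants, mosaic allele fractions are Beta-distributed with a
low median and a tail into the mid-thirties of percent, germline de novo
variants sit at an allele fraction of one half, and artifact rows carry
panel-of-normals/blacklist signatures for the filters to remove.

The mitochondrial generator draws heteroplasmies from the exhaustive
genic-SNV class proportions with an optional tRNA-class multiplier, plus
homoplasmies from the unmodified proportions.

Every generator is a pure function of (config, seed): identical inputs give
identical outputs, and the truth manifests suffice to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError, InvalidInputError
from .enrichment import ObservedVariant, ObservedVariantSet
from .mito_heteroplasmy import (
    FOUR_CLASSES,
    ExhaustiveSnvSet,
    MitoAnnotation,
    MitoClass,
    MitoRecord,
    enumerate_genic_snvs,
)
from .mutation_model import (
    BASES,
    ConsequenceClass,
    GeneModel,
    MutationRateTable,
    SiteIndex,
    TrinucleotideSubstitution,
    build_site_index,
    consequence_code,
    consequence_from_code,
)

__all__ = [
    "SimulationConfig",
    "MitoFixture",
    "make_toy_reference",
    "simulate_trio_cohort",
    "make_mito_fixture",
    "simulate_mito_cohort",
    "observed_set_from_truth",
    "study_reference",
    "study_gene_set",
    "STUDY_N_GENES",
    "STUDY_GENE_CODONS",
    "STUDY_SET_SIZE",
]

# Study-scale universe: 285 planted genes inside a universe sized so that the
# expected in-set deleterious hit count under the null is about one per
# cohort, the operating point at which a ~5.7-fold enrichment corresponds to
# roughly six observed in-set hits in 190 trios.
STUDY_N_GENES = 8000
STUDY_GENE_CODONS = 50
STUDY_SET_SIZE = 285


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Rates are per proband.  ``deleterious_fold`` multiplies the placement
    weight of sites where a variant would be deleterious inside
    ``planted_gene_set``; ``trna_multiplier`` multiplies the tRNA class
    probability of heteroplasmies.  Both default to the enrichment magnitudes
    the pipeline is designed to detect; set them to 1 for null cohorts.
    """

    master_seed: int = 0
    n_trios: int = 190
    n_controls: int = 39
    lambda_mosaic: float = 0.85
    lambda_germline: float = 1.2
    planted_gene_set: tuple = ()
    deleterious_fold: float = 5.73
    p_damaging_missense: float = 0.2
    mosaic_vaf_beta: tuple = (1.3, 20.0)
    artifact_rate: float = 0.3
    nuclear_depth: float = 300.0
    mito_depth: float = 700.0
    mito_per_sample_het_rate: float = 33 / 190
    mito_per_sample_hom_rate: float = 382 / 190
    trna_multiplier: float = 2.82
    het_vaf_range: tuple = (0.01, 0.36)
    hom_vaf_range: tuple = (0.97, 1.0)
    maternal_rate: float = 0.0
    numt_mimic_rate: float = 0.0

    def __post_init__(self):
        for name in ("lambda_mosaic", "lambda_germline", "artifact_rate",
                     "mito_per_sample_het_rate", "mito_per_sample_hom_rate"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.deleterious_fold < 0 or self.trna_multiplier < 0:
            raise InvalidInputError("fold multipliers must be non-negative")
        if any(a <= 0 for a in self.mosaic_vaf_beta):
            raise InvalidInputError("Beta shape parameters must be positive")


_STOPS_NUCLEAR = {"TAA", "TAG", "TGA"}
_STOPS_MITO = {"TAA", "TAG", "AGA", "AGG"}


def _random_codons(rng: np.random.Generator, n: int, stops: set, gc: float) -> str:
    """``n`` random codons, none a stop codon of the given code."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    while len(out) < n:
        draw = rng.choice(4, size=(n - len(out), 3), p=p)
        for row in draw:
            codon = "".join(BASES[i] for i in row)
            if codon not in stops:
                out.append(codon)
    return "".join(out[:n])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_toy_reference(
    n_genes: int, gene_length_codons: int = 30, gc_bias: float = 0.0, seed: int = 0
):
    """Random single-chromosome reference with intronless ORF gene models.

    Each gene is a valid ORF (ATG, no internal stop, terminal stop codon) on
    a random strand, separated by 20-bp spacers.  ``gc_bias`` shifts the GC
    content away from 0.5 (range -0.4..0.4).  Deterministic per seed.

    Returns ``(reference, gene_models)`` where ``reference`` maps chromosome
    name to sequence.
    """
    if n_genes < 1 or gene_length_codons < 10:
        raise InvalidInputError("need n_genes >= 1 and gene_length_codons >= 10")
    if not -0.4 <= gc_bias <= 0.4:
        raise InvalidInputError("gc_bias must lie in [-0.4, 0.4]")
    gc = 0.5 + gc_bias
    rng = np.random.default_rng(seed)
    spacer = 20
    parts, models = [], []
    cursor = 0
    width = max(4, len(str(n_genes - 1)))
    for gi in range(n_genes):
        parts.append(_random_seq(rng, spacer, gc))
        cursor += spacer
        orf = "ATG" + _random_codons(rng, gene_length_codons - 2, _STOPS_NUCLEAR, gc) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        seg = orf if strand == "+" else _revcomp(orf)
        models.append(
            GeneModel(
                gene_id=f"g{gi:0{width}d}",
                chrom="chr1",
                strand=strand,
                cds_intervals=((cursor, cursor + len(seg)),),
            )
        )
        parts.append(seg)
        cursor += len(seg)
    parts.append(_random_seq(rng, spacer, gc))
    return {"chr1": "".join(parts)}, models


def study_reference(seed: int = 0):
    """The study-scale universe: reference and gene models."""
    return make_toy_reference(STUDY_N_GENES, STUDY_GENE_CODONS, 0.0, seed)


def study_gene_set(gene_models: Sequence[GeneModel], size: int = STUDY_SET_SIZE) -> tuple:
    """A deterministic planted gene set: the first ``size`` gene ids."""
    return tuple(m.gene_id for m in gene_models[:size])


# ---------------------------------------------------------------------------
# trio cohort
# ---------------------------------------------------------------------------

_CODE_LOF_MAX = consequence_code(ConsequenceClass.CANONICAL_SPLICE)
_CODE_MIS = consequence_code(ConsequenceClass.MISSENSE)


class _Placement:
    """Cumulative mutability weights over a site index, with the planted
    deleterious boost applied inside the gene set."""

    def __init__(self, site_index: SiteIndex, rate_table: MutationRateTable,
                 members, fold: float):
        rates = rate_table.rates[site_index.cat]
        if members:
            in_set = site_index.member_mask(members)[site_index.gene_code]
        else:
            in_set = np.zeros(len(site_index), dtype=bool)
        lof = site_index.cls <= _CODE_LOF_MAX
        mis = site_index.cls == _CODE_MIS
        self.index = site_index
        self.cum = {
            "plain": np.cumsum(rates),
            "lof_boost": np.cumsum(np.where(in_set & lof, fold, 1.0) * rates),
            "full_boost": np.cumsum(np.where(in_set & (lof | mis), fold, 1.0) * rates),
        }

    def sample(self, rng: np.random.Generator, kind: str) -> int:
        cum = self.cum[kind]
        total = cum[-1]
        if total <= 0:
            raise GenerationError("placement weights are all zero")
        return int(np.searchsorted(cum, rng.random() * total, side="right"))


def _site_row(site_index: SiteIndex, reference: Mapping[str, str], i: int) -> dict:
    chrom = site_index.chroms[site_index.chrom_idx[i]]
    pos0 = int(site_index.pos[i])
    return {
        "chrom": chrom,
        "pos_1based": pos0 + 1,
        "ref": reference[chrom][pos0].upper(),
        "alt": BASES[int(site_index.alt[i])],
        "gene_id": site_index.gene_ids[int(site_index.gene_code[i])],
        "category_index": int(site_index.cat[i]),
        "consequence": consequence_from_code(int(site_index.cls[i])).value,
    }


def simulate_trio_cohort(
    config: SimulationConfig,
    reference: Mapping[str, str],
    gene_models: Sequence[GeneModel],
    *,
    site_index: SiteIndex | None = None,
    rate_table: MutationRateTable | None = None,
):
    """Simulate one trio cohort.

    Returns ``(calls, truth)`` as data frames: ``calls`` in the candidate-call
    schema the filter consumes (with read evidence and artifact flags) and
    ``truth`` recording every planted variant with its kind
    (mosaic/germline/artifact), category, class and deleterious status.
    """
    site_index = site_index or build_site_index(reference, gene_models)
    rate_table = rate_table or MutationRateTable.flat_with_cpg()
    placement = _Placement(
        site_index, rate_table, config.planted_gene_set, config.deleterious_fold
    )
    rng = np.random.default_rng(np.random.SeedSequence(config.master_seed))
    a, b = config.mosaic_vaf_beta
    calls_rows, truth_rows = [], []

    def read_evidence(vaf_true: float) -> dict:
        depth = max(1, int(rng.poisson(config.nuclear_depth)))
        alt_reads = int(rng.binomial(depth, vaf_true))
        return {"depth": depth, "alt_reads": alt_reads}

    def parent_evidence() -> dict:
        return {
            "father_alt_reads": 0,
            "father_depth": max(1, int(rng.poisson(config.nuclear_depth))),
            "mother_alt_reads": 0,
            "mother_depth": max(1, int(rng.poisson(config.nuclear_depth))),
        }

    base_flags = {"pon_member": False, "pop_af": 0.0, "blacklist_member": False,
                  "mpc_ge2": False, "all7_damaging": False, "variant_type": "SNV"}

    for si in range(config.n_trios):
        sample = f"trio{si:04d}"
        # mosaic de novo variants
        for _ in range(rng.poisson(config.lambda_mosaic)):
            damaging = bool(rng.random() < config.p_damaging_missense)
            idx = placement.sample(rng, "full_boost" if damaging else "lof_boost")
            site = _site_row(site_index, reference, idx)
            cls = ConsequenceClass(site["consequence"])
            mpc = damaging and cls is ConsequenceClass.MISSENSE
            deleterious = cls in (ConsequenceClass.NONSENSE, ConsequenceClass.CANONICAL_SPLICE) or mpc
            vaf_true = float(rng.beta(a, b))
            row = {"sample_id": sample, **site, **read_evidence(vaf_true),
                   **parent_evidence(), **base_flags, "mpc_ge2": mpc}
            calls_rows.append(row)
            truth_rows.append({**row, "kind": "mosaic", "deleterious": deleterious,
                               "vaf_true": vaf_true})
        # germline de novo variants at VAF one half
        for _ in range(rng.poisson(config.lambda_germline)):
            idx = placement.sample(rng, "plain")
            site = _site_row(site_index, reference, idx)
            row = {"sample_id": sample, **site, **read_evidence(0.5),
                   **parent_evidence(), **base_flags}
            calls_rows.append(row)
            truth_rows.append({**row, "kind": "germline", "deleterious": False,
                               "vaf_true": 0.5})
        # artifact rows carrying blacklist signatures
        for _ in range(rng.poisson(config.artifact_rate)):
            idx = placement.sample(rng, "plain")
            site = _site_row(site_index, reference, idx)
            vaf_true = float(rng.beta(a, b))
            row = {"sample_id": sample, **site, **read_evidence(vaf_true),
                   **parent_evidence(), **base_flags}
            mode = rng.integers(4)
            if mode == 0:
                row["pon_member"] = True
            elif mode == 1:
                row["blacklist_member"] = True
            elif mode == 2:
                row["pop_af"] = float(rng.uniform(0.001, 0.05))
            else:
                row["father_alt_reads"] = int(rng.integers(5, 30))
            calls_rows.append(row)
            truth_rows.append({**row, "kind": "artifact", "deleterious": False,
                               "vaf_true": vaf_true})

    columns = ["sample_id", "chrom", "pos_1based", "ref", "alt", "alt_reads", "depth",
               "father_alt_reads", "father_depth", "mother_alt_reads", "mother_depth",
               "pon_member", "pop_af", "blacklist_member", "gene_id", "consequence",
               "category_index", "mpc_ge2", "all7_damaging", "variant_type"]
    calls = pd.DataFrame(calls_rows, columns=columns)
    truth = pd.DataFrame(truth_rows, columns=columns + ["kind", "deleterious", "vaf_true"])
    return calls, truth


def observed_set_from_truth(truth: pd.DataFrame, cohort_size: int) -> ObservedVariantSet:
    """Observed mosaic SNV set straight from a truth manifest (no filtering)."""
    entries = []
    sub = truth[truth["kind"] == "mosaic"]
    for row in sub.itertuples(index=False):
        entries.append(
            ObservedVariant(
                sample_id=row.sample_id,
                gene_id=row.gene_id,
                consequence=ConsequenceClass(row.consequence),
                category=TrinucleotideSubstitution.from_index(int(row.category_index)),
                deleterious=bool(row.deleterious),
            )
        )
    return ObservedVariantSet(entries=entries, cohort_size=cohort_size)


# ---------------------------------------------------------------------------
# mitochondrial fixtures and cohorts
# ---------------------------------------------------------------------------


@dataclass
class MitoFixture:
    reference: str
    annotation: MitoAnnotation
    excluded_regions: list
    style: str


def _mito_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    """A protein segment of exactly ``length`` bases, valid under the
    vertebrate mitochondrial code; a length not divisible by 3 ends in a
    truncated stop codon completed by polyadenylation ('T' or 'TA')."""
    n_codons, rem = divmod(length, 3)
    if n_codons < 2:
        raise InvalidInputError("protein record too short")
    body = "ATG" + _random_codons(rng, n_codons - 2 if rem == 0 else n_codons - 1,
                                  _STOPS_MITO, gc)
    tail = {0: "TAA", 1: "T", 2: "TA"}[rem]
    return body + tail


# (gene_id, start_1based, end_1based, strand, type): a synthetic layout with
# the gene order, name set and length scale of the human mitochondrial
# genome annotation (no overlapping records, nothing crossing the origin)
_RCRS_LIKE_LAYOUT = [
    ("MT-TF", 577, 647, "+", "tRNA"),
    ("MT-RNR1", 648, 1601, "+", "rRNA"),
    ("MT-TV", 1602, 1670, "+", "tRNA"),
    ("MT-RNR2", 1671, 3229, "+", "rRNA"),
    ("MT-TL1", 3230, 3304, "+", "tRNA"),
    ("MT-ND1", 3307, 4262, "+", "protein"),
    ("MT-TI", 4263, 4331, "+", "tRNA"),
    ("MT-TQ", 4332, 4400, "-", "tRNA"),
    ("MT-TM", 4402, 4469, "+", "tRNA"),
    ("MT-ND2", 4470, 5511, "+", "protein"),
    ("MT-TW", 5512, 5579, "+", "tRNA"),
    ("MT-TA", 5587, 5655, "-", "tRNA"),
    ("MT-TN", 5657, 5729, "-", "tRNA"),
    ("MT-TC", 5761, 5826, "-", "tRNA"),
    ("MT-TY", 5829, 5891, "-", "tRNA"),
    ("MT-CO1", 5904, 7445, "+", "protein"),
    ("MT-TS1", 7446, 7514, "-", "tRNA"),
    ("MT-TD", 7518, 7585, "+", "tRNA"),
    ("MT-CO2", 7586, 8269, "+", "protein"),
    ("MT-TK", 8295, 8364, "+", "tRNA"),
    ("MT-ATP8", 8366, 8524, "+", "protein"),
    ("MT-ATP6", 8527, 9204, "+", "protein"),
    ("MT-CO3", 9207, 9990, "+", "protein"),
    ("MT-TG", 9991, 10058, "+", "tRNA"),
    ("MT-ND3", 10059, 10404, "+", "protein"),
    ("MT-TR", 10405, 10469, "+", "tRNA"),
    ("MT-ND4L", 10470, 10766, "+", "protein"),
    ("MT-ND4", 10770, 12137, "+", "protein"),
    ("MT-TH", 12138, 12206, "+", "tRNA"),
    ("MT-TS2", 12207, 12265, "+", "tRNA"),
    ("MT-TL2", 12266, 12336, "+", "tRNA"),
    ("MT-ND5", 12337, 14148, "+", "protein"),
    ("MT-ND6", 14149, 14673, "-", "protein"),
    ("MT-TE", 14674, 14742, "-", "tRNA"),
    ("MT-CYB", 14747, 15887, "+", "protein"),
    ("MT-TT", 15888, 15953, "+", "tRNA"),
    ("MT-TP", 15956, 16023, "-", "tRNA"),
]

_RCRS_LIKE_LENGTH = 16569


def make_mito_fixture(style: str = "toy", seed: int = 0) -> MitoFixture:
    """A synthetic circular mitochondrial genome plus annotation.

    ``toy``: 1000 bp with one 70-bp tRNA and one 300-bp protein gene (known
    class length shares).  ``rcrs_like``: a 16.6-kb genome with 13 protein,
    22 tRNA and 2 rRNA records of realistic lengths (synthetic sequence and
    coordinates; no exclusion regions ship with either style).
    """
    rng = np.random.default_rng([1, seed])
    gc = 0.45
    if style == "toy":
        length = 1000
        layout = [("MT-T1", 101, 170, "+", "tRNA"), ("MT-P1", 201, 500, "+", "protein")]
    elif style == "rcrs_like":
        length = _RCRS_LIKE_LENGTH
        layout = _RCRS_LIKE_LAYOUT
    else:
        raise InvalidInputError(f"unknown style {style!r}")
    seq = list(_random_seq(rng, length, gc))
    for gid, s, e, strand, typ in layout:
        span = e - s + 1
        if typ == "protein":
            seg = _mito_orf(rng, span, gc)
            if strand == "-":
                seg = _revcomp(seg)
        else:
            seg = _random_seq(rng, span, gc)
        seq[s - 1 : e] = list(seg)
    annotation = MitoAnnotation(
        genome_length=length,
        records=[MitoRecord(*row) for row in layout],
    )
    return MitoFixture(reference="".join(seq), annotation=annotation,
                       excluded_regions=[], style=style)


def _adjusted_class_probs(exhaustive: ExhaustiveSnvSet, trna_multiplier: float) -> dict:
    totals = exhaustive.class_totals
    total = sum(totals.values())
    p = {c: totals[c] / total for c in FOUR_CLASSES}
    pt = p[MitoClass.TRNA] * trna_multiplier
    if pt >= 1:
        raise ConfigurationError("trna_multiplier pushes the tRNA proportion past 1")
    scale = (1 - pt) / (1 - p[MitoClass.TRNA])
    out = {c: p[c] * scale for c in FOUR_CLASSES}
    out[MitoClass.TRNA] = pt
    return out


def simulate_mito_cohort(
    config: SimulationConfig,
    fixture: MitoFixture,
    *,
    exhaustive: ExhaustiveSnvSet | None = None,
):
    """Simulate heteroplasmic/homoplasmic call tables for one cohort.

    Heteroplasmy sites are drawn class-first (exhaustive-null class
    proportions with the tRNA proportion multiplied and renormalised), then
    uniformly within the class; homoplasmies use the unmodified proportions.
    Optional planted rows: maternally transmitted heteroplasmies and
    NUMT-mimic rows where both parents share the proband's allele fraction.
    """
    exhaustive = exhaustive or enumerate_genic_snvs(
        fixture.annotation, fixture.reference, fixture.excluded_regions
    )
    probs_het = _adjusted_class_probs(exhaustive, config.trna_multiplier)
    probs_hom = _adjusted_class_probs(exhaustive, 1.0)
    by_class = {
        c: exhaustive.table[exhaustive.table["mito_class"] == c.value].reset_index(drop=True)
        for c in FOUR_CLASSES
    }
    for c in FOUR_CLASSES:
        if probs_het[c] > 0 and len(by_class[c]) == 0:
            raise GenerationError(f"no eligible sites of class {c.value}")
    rng = np.random.default_rng(np.random.SeedSequence(config.master_seed, spawn_key=(1,)))
    lo, hi = config.het_vaf_range
    classes = list(FOUR_CLASSES)
    calls_rows, truth_rows = [], []

    def draw(sample: str, probs: dict, vaf: float, kind: str,
             mother_vaf: float = 0.0, father_vaf: float = 0.0):
        c = classes[rng.choice(len(classes), p=[probs[c] for c in classes])]
        tbl = by_class[c]
        row = tbl.iloc[int(rng.integers(len(tbl)))]
        rec = {
            "sample_id": sample,
            "pos_1based": int(row.pos_1based),
            "ref": row.ref,
            "alt": row.alt,
            "vaf": vaf,
            "depth": max(1, int(rng.poisson(config.mito_depth))),
            "mother_vaf": mother_vaf,
            "father_vaf": father_vaf,
        }
        calls_rows.append(rec)
        truth_rows.append({**rec, "mito_class": c.value, "kind": kind})

    for si in range(config.n_trios):
        sample = f"trio{si:04d}"
        for _ in range(rng.poisson(config.mito_per_sample_het_rate)):
            draw(sample, probs_het, float(rng.uniform(lo, hi)), "het")
        for _ in range(rng.poisson(config.mito_per_sample_hom_rate)):
            draw(sample, probs_hom, float(rng.uniform(*config.hom_vaf_range)), "hom")
        if rng.random() < config.maternal_rate:
            v = float(rng.uniform(lo, hi))
            draw(sample, probs_het, v, "maternal", mother_vaf=float(rng.uniform(0.01, 0.05)))
        if rng.random() < config.numt_mimic_rate:
            v = float(rng.uniform(lo, hi))
            draw(sample, probs_het, v, "numt_mimic",
                 mother_vaf=v * float(rng.uniform(0.8, 1.2)),
                 father_vaf=v * float(rng.uniform(0.8, 1.2)))

    columns = ["sample_id", "pos_1based", "ref", "alt", "vaf", "depth",
               "mother_vaf", "father_vaf"]
    calls = pd.DataFrame(calls_rows, columns=columns)
    truth = pd.DataFrame(truth_rows, columns=columns + ["mito_class", "kind"])
    return calls, truth


# ---------------------------------------------------------------------------
# study-scale replicate experiments
# ---------------------------------------------------------------------------


def _child_seeds(master_seed: int, n: int, k: int = 3):
    for child in np.random.SeedSequence(master_seed).spawn(n):
        yield tuple(int(x & 0x7FFFFFFF) for x in child.generate_state(k))


def run_enrichment_replicates(
    n_replicates: int,
    deleterious_fold: float,
    master_seed: int,
    *,
    n_perm: int = 10_000,
    n_trios: int = 190,
    fixture_seed: int = 0,
    class_filter: str = "deleterious",
    resources=None,
):
    """Replicate cohorts at the study operating point, one permutation
    enrichment test each.

    Each replicate simulates ``n_trios`` trios on the study-scale universe
    (285-gene planted set), runs the permutation test for the planted set,
    and records the empirical p-value together with its uniformised
    (randomised) counterpart ``(r_> + U (r_= + 1)) / (n_perm + 1)``, which is
    exactly Uniform(0,1) under a calibrated null and is what the calibration
    diagnostics use, the plain empirical p being discrete at small expected
    hit counts.

    ``resources`` may carry a prebuilt ``(reference, models, site_index)``
    triple to share the fixture across calls.
    """
    from .enrichment import GeneSet, count_hits, permutation_null
    from .stats_core import empirical_p

    if resources is None:
        reference, models = study_reference(fixture_seed)
        index = build_site_index(reference, models)
    else:
        reference, models, index = resources
    members = study_gene_set(models)
    gene_set = GeneSet("planted", frozenset(members))
    rows = []
    for s_cohort, s_perm, s_unif in _child_seeds(master_seed, n_replicates):
        config = SimulationConfig(
            master_seed=s_cohort, n_trios=n_trios,
            planted_gene_set=members, deleterious_fold=deleterious_fold,
        )
        _, truth = simulate_trio_cohort(config, reference, models, site_index=index)
        variants = observed_set_from_truth(truth, n_trios)
        observed = count_hits(variants, gene_set, class_filter)
        null = permutation_null(variants, index, gene_set, class_filter, n_perm, s_perm)
        r_ge = int((null >= observed).sum())
        r_gt = int((null > observed).sum())
        p = empirical_p(r_ge, n_perm).p
        u = float(np.random.default_rng(s_unif).random())
        p_rand = (r_gt + u * (r_ge - r_gt + 1)) / (n_perm + 1)
        expected = float(null.mean())
        rows.append(
            {
                "observed": observed,
                "expected": expected,
                "fold": observed / expected if expected > 0 else np.nan,
                "p": p,
                "p_randomized": p_rand,
            }
        )
    return pd.DataFrame(rows)


def run_trna_replicates(
    n_replicates: int,
    trna_multiplier: float,
    master_seed: int,
    *,
    n_trios: int = 190,
    fixture_seed: int = 0,
    resources=None,
):
    """Replicate mitochondrial cohorts; per replicate, the tRNA class
    proportion of the heteroplasmies is compared against the exhaustive
    genic-SNV null by the two-sided Fisher exact test."""
    from .mito_heteroplasmy import MitoClass, class_proportion_compare, counts_by_class

    if resources is None:
        fixture = make_mito_fixture("rcrs_like", fixture_seed)
        exhaustive = enumerate_genic_snvs(fixture.annotation, fixture.reference,
                                          fixture.excluded_regions)
    else:
        fixture, exhaustive = resources
    rows = []
    for (s_cohort,) in _child_seeds(master_seed, n_replicates, k=1):
        config = SimulationConfig(
            master_seed=s_cohort, n_trios=n_trios, trna_multiplier=trna_multiplier
        )
        _, truth = simulate_mito_cohort(config, fixture, exhaustive=exhaustive)
        het = truth[truth["kind"] == "het"]
        if not len(het):
            rows.append({"n_het": 0, "trna": 0, "fold": np.nan, "p": 1.0})
            continue
        counts = counts_by_class(het["mito_class"])
        entry = class_proportion_compare(counts, exhaustive.class_totals, MitoClass.TRNA)
        rows.append(
            {"n_het": entry.total_a, "trna": entry.target_a,
             "fold": entry.fold, "p": entry.p}
        )
    return pd.DataFrame(rows)
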