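"""Readers and writers for the formats the pipeline touches.

Coordinate conventions are centralised here: variant positions are 1-based
(VCF convention); interval files are 0-based half-open (BED convention).
The VCF dialect is deliberately minimal — required columns plus AD/DP for
trio calls and AF/DP for mitochondrial calls — because the pipeline's inputs
are candidate-call tables, not raw caller output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InvalidInputError
from .enrichment import GeneSet
from .mito_heteroplasmy import HeteroplasmyCall, MitoAnnotation, MitoRecord
from .mosaic_filter import CandidateCall
from .mutation_model import ConsequenceClass, GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gene_set",
    "read_gene_models",
    "write_gene_models",
    "read_mito_annotation",
    "write_mito_annotation",
    "read_calls_tsv",
    "write_calls_tsv",
    "candidates_from_frame",
    "frame_from_candidates",
    "read_vcf_minimal",
    "write_vcf_minimal",
    "build_run_manifest",
    "write_manifest",
]


def read_fasta(path) -> dict:
    """FASTA file as a name -> uppercase sequence mapping."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise FormatError(f"no sequences in {path}")
    return seqs


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path, reference: Mapping[str, str] | None = None) -> list:
    """BED3 intervals as (chrom, start, end) with 0-based half-open coordinates."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: expected at least 3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start < 0 or end <= start:
            raise FormatError(f"{path}:{ln}: bad interval {start}-{end}")
        if reference is not None:
            if chrom not in reference:
                raise FormatError(f"{path}:{ln}: unknown sequence {chrom!r}")
            if end > len(reference[chrom]):
                raise FormatError(f"{path}:{ln}: interval beyond the end of {chrom}")
        out.append((chrom, start, end))
    return out


def write_bed(intervals: Iterable, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One gene symbol per line; '#' comments; duplicates deduplicated."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    unique = set(symbols)
    if len(unique) < len(symbols):
        logger.warning("%s: deduplicated %d repeated symbols", path, len(symbols) - len(unique))
    if not unique:
        logger.warning("%s: empty gene set", path)
    return GeneSet(name=name or Path(path).stem, members=frozenset(unique))


_GENE_MODEL_COLS = ["gene_id", "chrom", "strand", "cds_starts", "cds_ends"]


def read_gene_models(path) -> list:
    """Tab-separated gene models: gene_id, chrom, strand, comma-joined 0-based
    half-open cds_starts / cds_ends."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENE_MODEL_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    models = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.cds_starts).split(",")]
        ends = [int(x) for x in str(row.cds_ends).split(",")]
        if len(starts) != len(ends):
            raise FormatError(f"{path}: {row.gene_id}: cds_starts/cds_ends length mismatch")
        models.append(
            GeneModel(
                gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
                cds_intervals=tuple(zip(starts, ends)),
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path) -> None:
    rows = [
        {
            "gene_id": m.gene_id,
            "chrom": m.chrom,
            "strand": m.strand,
            "cds_starts": ",".join(str(s) for s, _ in m.cds_intervals),
            "cds_ends": ",".join(str(e) for _, e in m.cds_intervals),
        }
        for m in models
    ]
    pd.DataFrame(rows, columns=_GENE_MODEL_COLS).to_csv(path, sep="\t", index=False)


_MITO_COLS = ["gene_id", "start", "end", "strand", "type"]


def read_mito_annotation(path, genome_length: int) -> MitoAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(_MITO_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = [
        MitoRecord(r.gene_id, int(r.start), int(r.end), r.strand, r.type)
        for r in df.itertuples(index=False)
    ]
    return MitoAnnotation(genome_length=genome_length, records=records)


def write_mito_annotation(annotation: MitoAnnotation, path) -> None:
    rows = [
        {"gene_id": r.gene_id, "start": r.start_1based, "end": r.end_1based,
         "strand": r.strand, "type": r.type}
        for r in annotation.records
    ]
    pd.DataFrame(rows, columns=_MITO_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# candidate-call tables
# ---------------------------------------------------------------------------

_CALL_COLS = [
    "sample_id", "chrom", "pos_1based", "ref", "alt", "alt_reads", "depth",
    "father_alt_reads", "father_depth", "mother_alt_reads", "mother_depth",
    "pon_member", "pop_af", "blacklist_member", "gene_id", "consequence",
    "mpc_ge2", "all7_damaging", "variant_type",
]


def candidates_from_frame(df: pd.DataFrame) -> list:
    """Candidate-call objects from a flat table (see ``_CALL_COLS``)."""
    missing = set(_CALL_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"call table is missing columns {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        consequence = None
        if isinstance(row.consequence, str) and row.consequence:
            consequence = ConsequenceClass(row.consequence)
        calls.append(
            CandidateCall(
                sample_id=str(row.sample_id), chrom=str(row.chrom),
                pos_1based=int(row.pos_1based), ref=row.ref, alt=row.alt,
                alt_reads=int(row.alt_reads), depth=int(row.depth),
                father_alt_reads=int(row.father_alt_reads),
                father_depth=int(row.father_depth),
                mother_alt_reads=int(row.mother_alt_reads),
                mother_depth=int(row.mother_depth),
                pon_member=bool(row.pon_member), pop_af=float(row.pop_af),
                blacklist_member=bool(row.blacklist_member),
                gene_id=None if pd.isna(row.gene_id) else str(row.gene_id),
                consequence=consequence,
                mpc_ge2=bool(row.mpc_ge2), all7_damaging=bool(row.all7_damaging),
                variant_type=str(row.variant_type),
            )
        )
    return calls


def frame_from_candidates(calls: Iterable[CandidateCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        d = asdict(c)
        d["consequence"] = c.consequence.value if c.consequence else ""
        rows.append(d)
    return pd.DataFrame(rows, columns=_CALL_COLS)


def read_calls_tsv(path) -> list:
    return candidates_from_frame(pd.read_csv(path, sep="\t"))


def write_calls_tsv(calls, path) -> None:
    df = calls if isinstance(calls, pd.DataFrame) else frame_from_candidates(calls)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# minimal VCF dialect (pysam-backed)
# ---------------------------------------------------------------------------

_TRIO_SAMPLES = ("PROBAND", "FATHER", "MOTHER")


def _vcf_header(contig_lengths: Mapping[str, int], kind: str):
    import pysam

    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">')
    header.add_line('##INFO=<ID=PON,Number=0,Type=Flag,Description="Panel-of-normals member">')
    header.add_line('##INFO=<ID=BL,Number=0,Type=Flag,Description="Blacklist member">')
    header.add_line('##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">')
    header.add_line('##INFO=<ID=MPC2,Number=0,Type=Flag,Description="MPC >= 2">')
    header.add_line('##INFO=<ID=ALL7,Number=0,Type=Flag,Description="Damaging by all seven predictors">')
    header.add_line('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Cohort sample id">')
    header.add_line('##INFO=<ID=MVAF,Number=1,Type=Float,Description="Mother VAF">')
    header.add_line('##INFO=<ID=FVAF,Number=1,Type=Float,Description="Father VAF">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">')
    samples = _TRIO_SAMPLES if kind == "trio" else ("SAMPLE",)
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf_minimal(records, path, contig_lengths: Mapping[str, int], kind: str = "trio") -> None:
    """Write candidate calls (``kind='trio'``) or heteroplasmy calls
    (``kind='mito'``) to a plain-text minimal VCF."""
    import pysam

    header = _vcf_header(contig_lengths, kind)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record()
            rec.pos = r.pos_1based
            rec.ref = r.ref
            rec.alts = (r.alt,)
            rec.info["SAMPLE"] = r.sample_id
            if kind == "trio":
                rec.contig = r.chrom
                if r.gene_id:
                    rec.info["GENE"] = r.gene_id
                if r.consequence:
                    rec.info["CSQ"] = r.consequence.value
                if r.pon_member:
                    rec.info["PON"] = True
                if r.blacklist_member:
                    rec.info["BL"] = True
                if r.mpc_ge2:
                    rec.info["MPC2"] = True
                if r.all7_damaging:
                    rec.info["ALL7"] = True
                rec.info["POPAF"] = r.pop_af
                rec.samples["PROBAND"]["AD"] = (r.depth - r.alt_reads, r.alt_reads)
                rec.samples["PROBAND"]["DP"] = r.depth
                rec.samples["FATHER"]["AD"] = (r.father_depth - r.father_alt_reads, r.father_alt_reads)
                rec.samples["FATHER"]["DP"] = r.father_depth
                rec.samples["MOTHER"]["AD"] = (r.mother_depth - r.mother_alt_reads, r.mother_alt_reads)
                rec.samples["MOTHER"]["DP"] = r.mother_depth
            else:
                rec.contig = next(iter(contig_lengths))
                rec.samples["SAMPLE"]["AF"] = r.vaf
                rec.samples["SAMPLE"]["DP"] = r.depth
                if r.mother_vaf is not None:
                    rec.info["MVAF"] = r.mother_vaf
                if r.father_vaf is not None:
                    rec.info["FVAF"] = r.father_vaf
            vcf.write(rec)


def _round6(x: float | None) -> float | None:
    return None if x is None else float(f"{float(x):.6g}")


def _info_get(rec, key, default=None):
    """INFO lookup tolerant of fields absent from the header."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def read_vcf_minimal(path, kind: str = "trio") -> list:
    """Read a minimal VCF into call objects; multi-allelic rows are split."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                where = f"{rec.contig}:{rec.pos}"
                sample_id = _info_get(rec, "SAMPLE", "SAMPLE")
                if kind == "trio":
                    try:
                        pro, fat, mot = (rec.samples[s] for s in _TRIO_SAMPLES)
                        ad = pro["AD"]
                        depth = pro["DP"]
                        fad, fdp = fat["AD"], fat["DP"]
                        mad, mdp = mot["AD"], mot["DP"]
                        if ad is None or ad[ai + 1] is None or depth is None:
                            raise KeyError("AD/DP")
                    except (KeyError, TypeError, IndexError) as exc:
                        raise FormatError(f"{path}: {where}: missing or malformed AD/DP") from exc
                    csq = _info_get(rec, "CSQ")
                    out.append(
                        CandidateCall(
                            sample_id=sample_id, chrom=rec.contig, pos_1based=rec.pos,
                            ref=rec.ref, alt=alt,
                            alt_reads=int(ad[ai + 1]), depth=int(depth),
                            father_alt_reads=int(fad[ai + 1]), father_depth=int(fdp),
                            mother_alt_reads=int(mad[ai + 1]), mother_depth=int(mdp),
                            pon_member=bool(_info_get(rec, "PON", False)),
                            pop_af=_round6(_info_get(rec, "POPAF", 0.0)) or 0.0,
                            blacklist_member=bool(_info_get(rec, "BL", False)),
                            gene_id=_info_get(rec, "GENE"),
                            consequence=ConsequenceClass(csq) if csq else None,
                            mpc_ge2=bool(_info_get(rec, "MPC2", False)),
                            all7_damaging=bool(_info_get(rec, "ALL7", False)),
                            variant_type="SNV" if len(rec.ref) == 1 and len(alt) == 1 else "INDEL",
                        )
                    )
                else:
                    s = rec.samples["SAMPLE"]
                    af, dp = s.get("AF"), s.get("DP")
                    if af is None or dp is None:
                        raise FormatError(f"{path}: {where}: missing AF/DP")
                    out.append(
                        HeteroplasmyCall(
                            sample_id=sample_id, pos_1based=rec.pos, ref=rec.ref, alt=alt,
                            vaf=_round6(af), depth=int(dp),
                            mother_vaf=_round6(_info_get(rec, "MVAF")),
                            father_vaf=_round6(_info_get(rec, "FVAF")),
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_run_manifest(seed, config, input_paths: Sequence, counts: Mapping | None = None) -> dict:
    """Provenance record emitted by every CLI run: version, seed, input
    digests, config echo, timestamp and per-stage record counts."""
    from . import __version__

    if hasattr(config, "__dataclass_fields__"):
        config = asdict(config)
    return {
        "tool": "mosaicenrich",
        "version": __version__,
        "master_seed": seed,
        "inputs": {str(p): _sha256(p) for p in input_paths},
        "config": config,
        "created": datetime.now(timezone.utc).isoformat(),
        "counts": dict(counts or {}),
    }


def write_manifest(manifest: Mapping, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
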