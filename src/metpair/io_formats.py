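"""Readers and writers for every external file the pipeline touches.

Conventions are fixed package-wide: coordinates are 1-based inclusive
everywhere (SEG, site tables, gene models; VCF is natively 1-based),
chromosome names are normalized by stripping a leading ``chr``, and
every reader validates its records on ingest so downstream stages can
assume invariants hold.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import pandas as pd

EFFECTS = frozenset({
    "missense", "stop-gain", "splicing", "frameshift-indel",
    "inframe-indel", "synonymous", "other",
})

MUTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample_id", "t_depth", "t_alt",
    "n_depth", "n_alt", "pop_af", "gene", "effect", "context",
]

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "log2_ratio"]
SITE_COLUMNS = ["chrom", "pos", "hap", "ref_count", "alt_count", "sample_id"]


class FormatError(ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. alt reads > depth)."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call in one sample, with paired-normal counts.

    ``pop_af`` is the population allele frequency (0 when unknown: absence
    of evidence of commonness never triggers the common-variant removal
    rule). ``context`` is the pyrimidine-or-purine-centered trinucleotide
    context as annotated upstream; catalog building standardizes strand.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    t_depth: int
    t_alt: int
    n_depth: int
    n_alt: int
    pop_af: float = 0.0
    gene: str = ""
    effect: str = "other"
    context: str = ""

    def __post_init__(self):
        if self.t_alt > self.t_depth:
            raise ValidationError(
                f"t_alt ({self.t_alt}) > t_depth ({self.t_depth}) at "
                f"{self.chrom}:{self.pos}"
            )
        if self.n_alt > self.n_depth:
            raise ValidationError(
                f"n_alt ({self.n_alt}) > n_depth ({self.n_depth}) at "
                f"{self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValidationError(
                f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}"
            )
        if min(self.t_depth, self.t_alt, self.n_depth, self.n_alt) < 0:
            raise ValidationError("read counts must be non-negative")
        if self.effect and self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect category {self.effect!r}")

    @property
    def key(self) -> tuple:
        """Identity of the variant irrespective of sample."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        return self.t_alt / self.t_depth if self.t_depth else 0.0

    @property
    def n_vaf(self) -> float:
        return self.n_alt / self.n_depth if self.n_depth else 0.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class CNSegmentRecord:
    """A copy-number segment: observed tumor/normal ratio on log2 scale."""

    chrom: str
    start: int
    end: int
    log2_ratio: float
    sample_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"segment start > end ({self.start} > {self.end})"
            )
        if self.start < 1:
            raise ValidationError("segment start must be >= 1")


@dataclass(frozen=True)
class PhasedSiteRecord:
    """A phased heterozygous site with allele-specific read counts.

    ``hap`` in {0, 1} assigns the reference allele to a haplotype.
    """

    chrom: str
    pos: int
    hap: int
    ref_count: int
    alt_count: int
    sample_id: str

    def __post_init__(self):
        if self.hap not in (0, 1):
            raise ValidationError(f"hap must be 0 or 1, got {self.hap}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError("allele counts must be non-negative")
        if self.pos < 1:
            raise ValidationError("position must be >= 1")


@dataclass(frozen=True)
class SampleMeta:
    """Sample metadata; purity is required for tumor samples."""

    sample_id: str
    patient_id: str
    role: str
    organ: str = ""
    purity: float = float("nan")

    def __post_init__(self):
        if self.role not in ("primary", "metastasis", "normal"):
            raise ValidationError(f"unknown role {self.role!r}")
        if self.role != "normal":
            if not (0 < self.purity <= 1):
                raise ValidationError(
                    f"tumor sample {self.sample_id} needs purity in (0, 1], "
                    f"got {self.purity}"
                )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_mutations(path, dialect: str = "maf_like_tsv") -> list[MutationRecord]:
    """Read somatic mutations from a MAF-like TSV or a VCF.

    TSV dialect expects the columns in :data:`MUTATION_COLUMNS` (``pop_af``,
    ``gene``, ``effect``, ``context`` optional). VCF dialect reads the
    per-sample ``AD`` field: depth is the sum of allelic depths, alt count
    the second entry; normal counts default to 0/0 unless a sample named
    in ``*_N``/``normal`` style pairs are present — callers merging tumor
    and normal VCF columns should prefer the TSV dialect.
    """
    if dialect == "maf_like_tsv":
        return _read_mutations_tsv(path)
    if dialect == "vcf":
        return _read_mutations_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_mutations_tsv(path) -> list[MutationRecord]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, MUTATION_COLUMNS[:9], path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            rec = MutationRecord(
                chrom=normalize_chrom(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                sample_id=str(row["sample_id"]),
                t_depth=int(row["t_depth"]),
                t_alt=int(row["t_alt"]),
                n_depth=int(row["n_depth"]),
                n_alt=int(row["n_alt"]),
                pop_af=_opt_float(row.get("pop_af")),
                gene=_opt_str(row.get("gene")),
                effect=_opt_str(row.get("effect")) or "other",
                context=_opt_str(row.get("context")),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
        records.append(rec)
    return records


def _opt_float(value) -> float:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return 0.0
    s = str(value).strip()
    return float(s) if s and s.lower() not in ("nan", "na", ".", "") else 0.0


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = str(value).strip()
    return "" if s.lower() in ("nan", "na", ".") else s


def _read_mutations_vcf(path) -> list[MutationRecord]:
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for variant in vcf:
        ad = variant.format("AD")
        if ad is None:
            raise FormatError(f"{path}: variant {variant.CHROM}:{variant.POS} lacks AD")
        for si, sample in enumerate(samples):
            counts = [int(c) for c in ad[si] if c >= 0]
            depth = sum(counts)
            alt = counts[1] if len(counts) > 1 else 0
            records.append(MutationRecord(
                chrom=normalize_chrom(variant.CHROM),
                pos=int(variant.POS),
                ref=str(variant.REF),
                alt=str(variant.ALT[0]) if variant.ALT else "N",
                sample_id=sample,
                t_depth=depth,
                t_alt=alt,
                n_depth=0,
                n_alt=0,
            ))
    return records


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    df = pd.DataFrame(
        [{
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "sample_id": r.sample_id, "t_depth": r.t_depth, "t_alt": r.t_alt,
            "n_depth": r.n_depth, "n_alt": r.n_alt, "pop_af": r.pop_af,
            "gene": r.gene, "effect": r.effect, "context": r.context,
        } for r in records],
        columns=MUTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[CNSegmentRecord]:
    """Read a SEG file (sample, chrom, start, end, log2_ratio).

    Segments of one sample must be non-overlapping; overlaps raise
    :class:`ValidationError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, SEG_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            records.append(CNSegmentRecord(
                chrom=normalize_chrom(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                log2_ratio=float(row["log2_ratio"]),
                sample_id=str(row["sample_id"]),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    _check_segment_overlaps(records)
    return records


def _check_segment_overlaps(records: Sequence[CNSegmentRecord]) -> None:
    by_key: dict[tuple, list[CNSegmentRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.sample_id, rec.chrom), []).append(rec)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise ValidationError(
                    f"overlapping segments in sample {sample} chrom {chrom}: "
                    f"[{prev.start},{prev.end}] and [{cur.start},{cur.end}]"
                )


def write_segments(records: Iterable[CNSegmentRecord], path) -> None:
    df = pd.DataFrame(
        [{
            "sample_id": r.sample_id, "chrom": r.chrom, "start": r.start,
            "end": r.end, "log2_ratio": r.log2_ratio,
        } for r in records],
        columns=SEG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_phased_sites(path) -> list[PhasedSiteRecord]:
    """Read a phased heterozygous-site table (TSV).

    Sites must be unique per sample by (chrom, pos).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, SITE_COLUMNS, path)
    records = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            rec = PhasedSiteRecord(
                chrom=normalize_chrom(row["chrom"]),
                pos=int(row["pos"]),
                hap=int(row["hap"]),
                ref_count=int(row["ref_count"]),
                alt_count=int(row["alt_count"]),
                sample_id=str(row["sample_id"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
        ident = (rec.sample_id, rec.chrom, rec.pos)
        if ident in seen:
            raise ValidationError(
                f"{path} line {i}: duplicate site {rec.chrom}:{rec.pos} "
                f"for sample {rec.sample_id}"
            )
        seen.add(ident)
        records.append(rec)
    return records


def write_phased_sites(records: Iterable[PhasedSiteRecord], path) -> None:
    df = pd.DataFrame(
        [{
            "chrom": r.chrom, "pos": r.pos, "hap": r.hap,
            "ref_count": r.ref_count, "alt_count": r.alt_count,
            "sample_id": r.sample_id,
        } for r in records],
        columns=SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a labeled numeric matrix (genes/probes x samples) from TSV."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:3]
        raise ValidationError(f"{path}: duplicate row labels, e.g. {dupes}")
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate column labels")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_gene_set(path, format: str = "plain") -> dict[str, list[str]]:
    """Read gene sets: one gene per line (``plain``, set named after the
    file) or GMT (name, description, genes...)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "plain":
        with open(path) as fh:
            genes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        name = os.path.splitext(os.path.basename(str(path)))[0]
        return {name: genes}
    if format == "gmt":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for ln in fh:
                parts = ln.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}: GMT line with <3 fields")
                sets[parts[0]] = [g for g in parts[2:] if g]
        return sets
    raise ValueError(f"unknown gene set format {format!r}")


def read_sample_meta(path) -> list[SampleMeta]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "patient_id", "role"], path)
    out = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        purity = row.get("purity")
        out.append(SampleMeta(
            sample_id=str(row["sample_id"]),
            patient_id=str(row["patient_id"]),
            role=str(row["role"]),
            organ=_opt_str(row.get("organ")),
            purity=float(purity) if purity not in (None, "", "nan") else float("nan"),
        ))
    return out


def write_sample_meta(metas: Iterable[SampleMeta], path) -> None:
    df = pd.DataFrame([{
        "sample_id": m.sample_id, "patient_id": m.patient_id,
        "role": m.role, "organ": m.organ, "purity": m.purity,
    } for m in metas])
    df.to_csv(path, sep="\t", index=False)


def record_fields(cls) -> list[str]:
    return [f.name for f in fields(cls)]
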