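"""Somatic variant tables: domain types and VCF/MAF/TSV input-output.

Coordinates are 1-based fully closed, as in VCF and MAF. Only single-nucleotide
substitutions are modeled; indels and MNVs are dropped at ingest. Variants are
matched across samples purely by (chrom, pos, ref, alt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")

EFFECT_CLASSES = frozenset(
    {"synonymous", "nonsynonymous", "splice", "noncoding", "other", "unknown"}
)

#: TCGA MAF Variant_Classification -> collapsed effect class
MAF_CLASSIFICATION_MAP = {
    "Silent": "synonymous",
    "Missense_Mutation": "nonsynonymous",
    "Nonsense_Mutation": "nonsynonymous",
    "Nonstop_Mutation": "nonsynonymous",
    "Splice_Site": "splice",
}

TIMEPOINTS = frozenset({"PRE", "POST", "BC", "Nrx", "NA"})

TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "effect_class",
]


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one somatic SNV: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical ({self.ref}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # chr1:100A>T
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class VariantObservation:
    """One SNV observed in one sample, with supporting read counts.

    ``maf`` (mutant allele frequency) is derived as alt_count / (ref_count +
    alt_count) and is only defined when at least one read covers the site.
    """

    key: VariantKey
    sample_id: str
    ref_count: int
    alt_count: int
    effect_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"negative read count at {self.key}: ref={self.ref_count} alt={self.alt_count}"
            )
        if self.effect_class not in EFFECT_CLASSES:
            raise ValidationError(
                f"unknown effect class {self.effect_class!r} at {self.key}"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def maf(self) -> float:
        if self.depth == 0:
            raise ValidationError(f"MAF undefined at zero depth for {self.key}")
        return self.alt_count / self.depth


@dataclass
class SampleTable:
    """All variant observations for one sample, plus clinical metadata."""

    sample_id: str
    observations: list[VariantObservation] = field(default_factory=list)
    timepoint: str = "NA"
    purity: float | None = None
    stage: str = "NA"
    nodal: str = "NA"
    cnv_count: int | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"timepoint must be one of {sorted(TIMEPOINTS)}")
        seen: set[VariantKey] = set()
        for obs in self.observations:
            if obs.sample_id != self.sample_id:
                raise ValidationError(
                    f"observation sample_id {obs.sample_id!r} != table sample_id {self.sample_id!r}"
                )
            if obs.key in seen:
                raise ValidationError(f"duplicate variant {obs.key} in sample {self.sample_id}")
            seen.add(obs.key)
        self._index = {obs.key: obs for obs in self.observations}

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def keys(self) -> set[VariantKey]:
        return set(self._index)

    def get(self, key: VariantKey) -> VariantObservation | None:
        return self._index.get(key)

    def to_frame(self) -> pd.DataFrame:
        """Observations as a DataFrame (one row per variant)."""
        rows = [
            {
                "sample_id": o.sample_id,
                "chrom": o.key.chrom,
                "pos": o.key.pos,
                "ref": o.key.ref,
                "alt": o.key.alt,
                "ref_count": o.ref_count,
                "alt_count": o.alt_count,
                "effect_class": o.effect_class,
                "maf": o.maf if o.depth > 0 else float("nan"),
            }
            for o in self.observations
        ]
        return pd.DataFrame(
            rows, columns=TSV_COLUMNS + ["maf"]
        )


@dataclass
class VariantPartition:
    """Shared / private split of variant keys between two samples."""

    shared: list[VariantKey]
    a_only: list[VariantKey]
    b_only: list[VariantKey]

    @property
    def n_union(self) -> int:
        return len(self.shared) + len(self.a_only) + len(self.b_only)

    def shared_fraction(self, side: str = "a") -> float:
        """|shared| / |side|, the overlap convention used for paired call sets."""
        n_side = len(self.shared) + (len(self.a_only) if side == "a" else len(self.b_only))
        if n_side == 0:
            raise ValidationError(f"side {side!r} has no variants")
        return len(self.shared) / n_side


def _dedupe(observations: Iterable[VariantObservation], origin: str) -> list[VariantObservation]:
    """Resolve duplicate keys within one sample: keep the deeper record."""
    best: dict[VariantKey, VariantObservation] = {}
    n_collisions = 0
    for obs in observations:
        prev = best.get(obs.key)
        if prev is None:
            best[obs.key] = obs
        else:
            n_collisions += 1
            if obs.depth > prev.depth:
                best[obs.key] = obs
    if n_collisions:
        logger.warning("%s: %d duplicate variant keys collapsed (kept deeper record)", origin, n_collisions)
    return list(best.values())


def _maybe_strip_chr(chrom: str, strip_chr_prefix: bool) -> str:
    if strip_chr_prefix and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_id: str, *, strip_chr_prefix: bool = False) -> SampleTable:
    """Read biallelic SNV observations for one sample from a VCF 4.x file.

    Allele counts come from the per-sample ``AD`` FORMAT field (ref, alt...);
    total depth falls back to ``DP`` when ``AD`` carries no usable ref count.
    Multi-allelic records are split per alternate allele; non-SNV alleles are
    dropped. Records with neither AD nor DP are skipped with a warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    if sample_id not in vcf.samples:
        raise FormatError(
            f"sample {sample_id!r} not in VCF {path} (has: {', '.join(vcf.samples)})"
        )
    sidx = vcf.samples.index(sample_id)

    observations: list[VariantObservation] = []
    n_skipped = 0
    for rec in vcf:
        if rec.REF is None or len(rec.REF) != 1 or rec.REF not in BASES:
            continue
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        ad_row = None if ad is None else [int(x) for x in ad[sidx]]
        for ai, alt in enumerate(rec.ALT):
            if len(alt) != 1 or alt not in BASES:
                continue  # indel / MNV / symbolic allele
            if ad_row is None or len(ad_row) <= ai + 1 or ad_row[ai + 1] < 0:
                n_skipped += 1
                logger.warning(
                    "%s:%d lacks a usable allele-depth entry for sample %s; allele skipped",
                    rec.CHROM, rec.POS, sample_id,
                )
                continue
            alt_count = ad_row[ai + 1]
            # MAF denominator is the site's total depth: sum of all allele
            # depths, or the DP field when AD is incomplete
            valid = [x for x in ad_row if x >= 0]
            total = sum(valid)
            if ad_row[0] < 0:  # ref depth missing in AD: fall back to DP
                dp = rec.format("DP")
                if dp is not None and int(dp[sidx][0]) >= total:
                    total = int(dp[sidx][0])
            key = VariantKey(
                _maybe_strip_chr(rec.CHROM, strip_chr_prefix), rec.POS, rec.REF, alt
            )
            observations.append(
                VariantObservation(key, sample_id, max(total - alt_count, 0), alt_count)
            )
    if n_skipped:
        logger.warning("%s: %d records skipped (no depth information)", path, n_skipped)
    return SampleTable(sample_id, _dedupe(observations, str(path)))


# ---------------------------------------------------------------------------
# TCGA-style MAF tables
# ---------------------------------------------------------------------------

_MAF_REQUIRED = [
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
    "t_ref_count",
    "t_alt_count",
]


def read_maf_table(path: str | Path, *, strip_chr_prefix: bool = False) -> list[SampleTable]:
    """Read a TCGA-style MAF (Mutation Annotation Format) table, one SampleTable per barcode.

    Variant_Classification, when present, is collapsed to the package's effect
    classes (Silent -> synonymous; Missense/Nonsense/Nonstop -> nonsynonymous;
    Splice_Site -> splice; anything else -> other). Rows with non-SNV alleles
    or missing counts are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"MAF table {path} lacks required column {col!r}")
    has_class = "Variant_Classification" in df.columns

    tables: list[SampleTable] = []
    n_dropped = 0
    for barcode, grp in df.groupby("Tumor_Sample_Barcode", sort=True):
        observations = []
        for _, row in grp.iterrows():
            ref, alt = str(row["Reference_Allele"]), str(row["Tumor_Seq_Allele2"])
            if ref not in BASES or alt not in BASES or ref == alt:
                n_dropped += 1
                continue
            try:
                ref_count = int(float(row["t_ref_count"]))
                alt_count = int(float(row["t_alt_count"]))
                pos = int(float(row["Start_Position"]))
            except (TypeError, ValueError):
                n_dropped += 1
                continue
            if ref_count < 0 or alt_count < 0:
                n_dropped += 1
                continue
            if has_class:
                effect = MAF_CLASSIFICATION_MAP.get(str(row["Variant_Classification"]), "other")
            else:
                effect = "unknown"
            key = VariantKey(
                _maybe_strip_chr(str(row["Chromosome"]), strip_chr_prefix), pos, ref, alt
            )
            observations.append(
                VariantObservation(key, str(barcode), ref_count, alt_count, effect)
            )
        tables.append(SampleTable(str(barcode), _dedupe(observations, f"{path}:{barcode}")))
    if n_dropped:
        logger.warning("%s: %d rows dropped (non-SNV alleles or unparseable counts)", path, n_dropped)
    return tables


# ---------------------------------------------------------------------------
# Plain TSV dialect
# ---------------------------------------------------------------------------

def read_variant_tsv(path: str | Path, *, strip_chr_prefix: bool = False) -> SampleTable:
    """Read the package's plain TSV variant dialect (one sample per file).

    Header (tab-separated, exactly): sample_id, chrom, pos, ref, alt,
    ref_count, alt_count, effect_class. Lines starting with ``#`` are
    provenance comments and are ignored.
    """
    path = Path(path)
    observations: list[VariantObservation] = []
    sample_id: str | None = None
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != TSV_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: bad header; expected {TSV_COLUMNS}, got {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != len(TSV_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(TSV_COLUMNS)} fields, got {len(fields)}"
                )
            sid, chrom, pos, ref, alt, rc, ac, effect = fields
            if sample_id is None:
                sample_id = sid
            elif sid != sample_id:
                raise FormatError(
                    f"{path}:{lineno}: mixed sample ids ({sid!r} vs {sample_id!r}); one sample per file"
                )
            try:
                key = VariantKey(_maybe_strip_chr(chrom, strip_chr_prefix), int(pos), ref, alt)
                obs = VariantObservation(key, sid, int(rc), int(ac), effect or "unknown")
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            observations.append(obs)
    if not header_seen:
        raise FormatError(f"{path}: empty file (header line required)")
    if sample_id is None:
        sample_id = path.stem
    return SampleTable(sample_id, _dedupe(observations, str(path)))


def write_variant_tsv(
    table: SampleTable, path: str | Path, *, header_comments: Sequence[str] = ()
) -> None:
    """Write a SampleTable in the plain TSV dialect; round-trips exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for o in table.observations:
            fh.write(
                f"{o.sample_id}\t{o.key.chrom}\t{o.key.pos}\t{o.key.ref}\t{o.key.alt}"
                f"\t{o.ref_count}\t{o.alt_count}\t{o.effect_class}\n"
            )


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def partition_variants(a: SampleTable, b: SampleTable) -> VariantPartition:
    """Split the union of two samples' variant keys into shared / a-only / b-only.

    Keys are compared by exact (chrom, pos, ref, alt) equality. The three
    lists are returned in sorted key order and are pairwise disjoint.
    """
    ka, kb = a.keys(), b.keys()
    return VariantPartition(
        shared=sorted(ka & kb),
        a_only=sorted(ka - kb),
        b_only=sorted(kb - ka),
    )
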