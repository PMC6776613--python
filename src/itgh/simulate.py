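"""Synthetic paired-tumor generator with known clonal ground truth.

Emulates the observational design of a neoadjuvant-therapy study: a tumor
sampled at diagnosis (PRE) and at surgery (POST), plus a matched germline
pair (blood vs irradiated normal mucosa). Each tumor is a founder clone
(cancer-cell fraction 1 at both timepoints) plus mutually exclusive subclones
whose CCFs may shift under treatment selection. Every mutation is a
heterozygous SNV in a diploid, copy-number-neutral genome, so its expected
mutant allele frequency is

    E[MAF] = purity * CCF / 2.

Reads are simulated per variant and timepoint: depth ~ Poisson(mean_depth)
truncated at 1, alt reads ~ Binomial(depth, E[MAF]). A variant is detected at
a timepoint only when at least ``min_alt_reads`` alternate reads are drawn,
which produces realistic partial sharing between the paired tables. Random
streams are seeded per (clone, purpose), so changing one clone's mutation
count does not perturb another clone's draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .variants import SampleTable, VariantKey, VariantObservation

_BASES = "ACGT"

# purpose codes for per-(clone, purpose) seed streams
_P_IDENTITY, _P_COUNTS_PRE, _P_COUNTS_POST = 0, 1, 2

#: position block size per clone; mutations of clone i live in
#: [i*BLOCK+1, (i+1)*BLOCK], guaranteeing cross-clone uniqueness
_POS_BLOCK = 100_000


@dataclass
class CloneSpec:
    """One tumor cell population and its cancer-cell fraction at each timepoint."""

    clone_id: str
    ccf_pre: float
    ccf_post: float
    n_private: int  # mutations private to this clone

    def __post_init__(self) -> None:
        for name in ("ccf_pre", "ccf_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"clone {self.clone_id}: {name}={v} outside [0, 1]")
        if self.n_private < 0:
            raise ValidationError(f"clone {self.clone_id}: n_private must be >= 0")

    @property
    def selected(self) -> bool:
        return self.ccf_post > self.ccf_pre


def default_clones() -> list[CloneSpec]:
    """Default clonal architecture: a founder, a regressing subclone, and a
    treatment-selected subclone (CCF 0.08 -> 0.55)."""
    return [
        CloneSpec("founder", 1.0, 1.0, 25),
        CloneSpec("regressing", 0.60, 0.02, 55),
        CloneSpec("selected", 0.08, 0.55, 35),
    ]


@dataclass
class SimConfig:
    """Simulation conditions for one matched PRE/POST pair.

    Defaults mirror the study setting being emulated: macrodissected samples
    with >= 80% tumor cell content (purity 0.8), exome-scale coverage
    (mean depth 100x), roughly a hundred somatic point mutations per sample,
    mostly coding with a nonsynonymous excess.
    """

    clones: list[CloneSpec] = field(default_factory=default_clones)
    purity_pre: float = 0.8
    purity_post: float = 0.8
    mean_depth: float = 100.0
    n_germline: int = 2000
    ns_fraction: float = 0.75  # P(nonsynonymous | coding, non-splice)
    coding_fraction: float = 0.85
    splice_fraction: float = 0.05  # P(splice | coding)
    post_private_mutations: int = 30  # de novo / undetected-before, POST only
    post_private_ccf: float = 0.2
    min_alt_reads: int = 1  # detection threshold
    seed: int = 0

    def validate(self) -> None:
        for name in ("purity_pre", "purity_post"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name}={v} outside (0, 1]")
        if self.mean_depth <= 0:
            raise ValidationError(f"mean_depth={self.mean_depth} must be positive")
        for name in ("ns_fraction", "coding_fraction", "splice_fraction", "post_private_ccf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.min_alt_reads < 1:
            raise ValidationError("min_alt_reads must be >= 1")
        if self.n_germline < 0 or self.post_private_mutations < 0:
            raise ValidationError("counts must be non-negative")
        founders = [c for c in self.clones if c.ccf_pre == 1.0 and c.ccf_post == 1.0]
        if len(founders) != 1:
            raise ValidationError(
                f"clones: exactly one founder with ccf_pre = ccf_post = 1 required, found {len(founders)}"
            )
        subs = [c for c in self.clones if c is not founders[0]]
        extra_post = self.post_private_ccf if self.post_private_mutations > 0 else 0.0
        if sum(c.ccf_pre for c in subs) > 1.0 + 1e-9:
            raise ValidationError("clones: subclone ccf_pre values sum above 1")
        if sum(c.ccf_post for c in subs) + extra_post > 1.0 + 1e-9:
            raise ValidationError("clones: subclone ccf_post values (plus post-private clone) sum above 1")
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValidationError("clones: duplicate clone_id")


@dataclass
class TruthRecord:
    """Ground truth for one simulated somatic mutation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    clone_id: str
    ccf_pre: float
    ccf_post: float
    expected_maf_pre: float
    expected_maf_post: float
    selected: bool
    effect_class: str
    context: str

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulationTruth:
    """Complete ground truth of one simulated pair."""

    records: list[TruthRecord]

    def by_key(self) -> dict[VariantKey, TruthRecord]:
        return {r.key: r for r in self.records}

    def clone_of(self) -> dict[VariantKey, str]:
        return {r.key: r.clone_id for r in self.records}

    def contexts(self) -> dict[VariantKey, str]:
        return {r.key: r.context for r in self.records}

    def to_json(self, path: str | Path) -> None:
        payload = [
            {k: v for k, v in asdict(r).items()}
            for r in self.records
        ]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def expected_maf(ccf: float, purity: float) -> float:
    """Expected mutant allele frequency of a heterozygous mutation in a
    diploid, CNV-free tumor: purity * ccf / 2."""
    if not 0.0 <= ccf <= 1.0 or not 0.0 <= purity <= 1.0:
        raise ValidationError("ccf and purity must be in [0, 1]")
    return purity * ccf / 2.0


def _rng(seed: int, clone_index: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(clone_index, purpose))
    )


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1 (every site has at least one read)."""
    d = rng.poisson(mean, size)
    while True:
        zeros = d == 0
        if not zeros.any():
            return d
        d[zeros] = rng.poisson(mean, int(zeros.sum()))


def _draw_effect(rng: np.random.Generator, config: SimConfig) -> str:
    if rng.random() >= config.coding_fraction:
        return "noncoding"
    if rng.random() < config.splice_fraction:
        return "splice"
    return "nonsynonymous" if rng.random() < config.ns_fraction else "synonymous"


def _make_mutations(
    rng: np.random.Generator, config: SimConfig, clone_index: int, n: int
) -> list[tuple[VariantKey, str, str]]:
    """(key, effect_class, context) triples for one clone, in its position block."""
    base = clone_index * _POS_BLOCK
    positions = np.sort(rng.choice(_POS_BLOCK, size=n, replace=False)) + base + 1
    out = []
    for pos in positions:
        ref = _BASES[rng.integers(4)]
        alt = rng.choice([b for b in _BASES if b != ref])
        context = _BASES[rng.integers(4)] + ref + _BASES[rng.integers(4)]
        out.append((VariantKey("1", int(pos), ref, str(alt)), _draw_effect(rng, config), context))
    return out


def _sample_reads(
    rng: np.random.Generator, config: SimConfig, emaf: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    depths = _truncated_poisson(rng, config.mean_depth, n)
    alts = rng.binomial(depths, emaf) if emaf > 0 else np.zeros(n, dtype=int)
    return depths, alts


def simulate_pair(config: SimConfig) -> tuple[SampleTable, SampleTable, SimulationTruth]:
    """Simulate one matched PRE/POST tumor pair with ground truth.

    Identical config (including seed) yields identical output. POST
    additionally carries ``post_private_mutations`` on a clone absent from
    PRE (CCF 0 -> ``post_private_ccf``), representing mutations arising or
    expanding below detection before treatment.
    """
    config.validate()
    clones = list(config.clones)
    if config.post_private_mutations > 0:
        clones.append(
            CloneSpec("post_private", 0.0, config.post_private_ccf, config.post_private_mutations)
        )

    pre_obs: list[VariantObservation] = []
    post_obs: list[VariantObservation] = []
    records: list[TruthRecord] = []

    for ci, clone in enumerate(clones):
        ident = _rng(config.seed, ci, _P_IDENTITY)
        muts = _make_mutations(ident, config, ci, clone.n_private)
        emaf_pre = expected_maf(clone.ccf_pre, config.purity_pre)
        emaf_post = expected_maf(clone.ccf_post, config.purity_post)
        d_pre, a_pre = _sample_reads(_rng(config.seed, ci, _P_COUNTS_PRE), config, emaf_pre, len(muts))
        d_post, a_post = _sample_reads(_rng(config.seed, ci, _P_COUNTS_POST), config, emaf_post, len(muts))
        for j, (key, effect, context) in enumerate(muts):
            records.append(
                TruthRecord(
                    key.chrom, key.pos, key.ref, key.alt, clone.clone_id,
                    clone.ccf_pre, clone.ccf_post, emaf_pre, emaf_post,
                    clone.selected, effect, context,
                )
            )
            if a_pre[j] >= config.min_alt_reads:
                pre_obs.append(
                    VariantObservation(key, "PRE", int(d_pre[j] - a_pre[j]), int(a_pre[j]), effect)
                )
            if a_post[j] >= config.min_alt_reads:
                post_obs.append(
                    VariantObservation(key, "POST", int(d_post[j] - a_post[j]), int(a_post[j]), effect)
                )

    pre = SampleTable("PRE", pre_obs, timepoint="PRE", purity=config.purity_pre)
    post = SampleTable("POST", post_obs, timepoint="POST", purity=config.purity_post)
    return pre, post, SimulationTruth(records)


# germline streams use clone indices far above any tumor clone
_G_BASE = 1000


def simulate_germline_pair(
    config: SimConfig,
    hom_fraction: float = 1 / 3,
    n_private_b: int = 0,
    low_coverage_rate: float = 0.002,
) -> tuple[SampleTable, SampleTable]:
    """Matched germline samples: blood (BC) and treatment-exposed mucosa (Nrx).

    ``n_germline`` inherited variant sites are drawn once and read-sampled
    independently in each sample. Sites are heterozygous (expected MAF 0.5)
    or, with probability ``hom_fraction``, homozygous-alternate (expected MAF
    1.0); the het/hom mixture is what gives real germline call sets their
    tight cross-sample allele-frequency correlation. A small
    ``low_coverage_rate`` fraction of site/sample pairs is read at Poisson(2)
    depth, the poorly-covered tail of exome data responsible for occasional
    detection dropout. ``n_private_b`` extra het sites present only in the
    second sample model putative treatment-induced ("iatrogenic") variants
    for power experiments.
    """
    config.validate()
    if config.n_germline < 1:
        raise ValidationError("n_germline must be >= 1")
    if not 0.0 <= hom_fraction <= 1.0:
        raise ValidationError("hom_fraction must be in [0, 1]")

    ident = _rng(config.seed, _G_BASE, _P_IDENTITY)
    muts = _make_mutations(ident, config, _G_BASE, config.n_germline + n_private_b)
    is_hom = ident.random(len(muts)) < hom_fraction
    emafs = np.where(is_hom, 1.0, 0.5)
    private_b = np.zeros(len(muts), dtype=bool)
    if n_private_b:
        private_b[-n_private_b:] = True
        emafs[private_b] = 0.5  # injected variants are het

    def _sample(purpose: int, sample_id: str, skip_mask: np.ndarray) -> SampleTable:
        rng = _rng(config.seed, _G_BASE, purpose)
        depths = _truncated_poisson(rng, config.mean_depth, len(muts))
        low = rng.random(len(muts)) < low_coverage_rate
        if low.any():
            depths[low] = _truncated_poisson(rng, 2.0, int(low.sum()))
        alts = rng.binomial(depths, emafs)
        obs = [
            VariantObservation(key, sample_id, int(depths[j] - alts[j]), int(alts[j]), effect)
            for j, (key, effect, _ctx) in enumerate(muts)
            if alts[j] >= config.min_alt_reads and not skip_mask[j]
        ]
        return SampleTable(sample_id, obs, timepoint="BC" if sample_id == "BC" else "Nrx")

    bc = _sample(_P_COUNTS_PRE, "BC", skip_mask=private_b)
    nrx = _sample(_P_COUNTS_POST, "Nrx", skip_mask=np.zeros(len(muts), dtype=bool))
    return bc, nrx


# ---------------------------------------------------------------------------
# Config file round trip
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML file (clones as a list of mappings)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    clones = data.pop("clones", None)
    known = {f for f in SimConfig.__dataclass_fields__ if f != "clones"}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = SimConfig(**data) if clones is None else SimConfig(
        clones=[CloneSpec(**c) for c in clones], **data
    )
    cfg.validate()
    return cfg


def save_config(config: SimConfig, path: str | Path) -> None:
    data = asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
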