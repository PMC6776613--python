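"""Substitution spectra: 6-class base changes, 96 trinucleotide contexts, and
non-negative least-squares refitting of exposures against a signature matrix.

Substitutions are collapsed to the pyrimidine-reference representation: a
G>T change is counted as C>A on the opposite strand, and likewise contexts
are reverse-complemented jointly with the substitution. De novo signature
extraction is out of scope; only refitting against a user-supplied matrix
(COSMIC-format TSV) is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import FormatError, ValidationError
from .variants import SampleTable, VariantKey

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")

#: The six pyrimidine-reference substitution classes.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical 96-channel labels, COSMIC ordering: substitution class major,
#: then 5' flank, then 3' flank (A[C>A]A ... T[T>G]T).
SBS96_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-reference class of a substitution (G>T -> C>A, etc.)."""
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}"
    return f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"


def collapse_context(ref: str, alt: str, context: str) -> str:
    """96-channel label for a substitution with its trinucleotide context."""
    if len(context) != 3 or any(b not in COMPLEMENT for b in context):
        raise ValidationError(f"context must be 3 bases of ACGT, got {context!r}")
    if context[1] != ref:
        raise ValidationError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class SpectrumResult:
    """Substitution counts for one sample: always 6-class, optionally 96-channel."""

    counts6: dict[str, int]
    counts96: dict[str, int] | None
    n_total: int

    def counts96_vector(self) -> np.ndarray:
        """counts96 as a length-96 array in canonical label order."""
        if self.counts96 is None:
            raise ValidationError("no 96-channel counts present")
        return np.array([self.counts96[lab] for lab in SBS96_LABELS], dtype=float)


def substitution_spectrum(table: SampleTable) -> SpectrumResult:
    """6-class substitution spectrum of a sample (strand-collapsed)."""
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for obs in table:
        counts[collapse_substitution(obs.key.ref, obs.key.alt)] += 1
    return SpectrumResult(counts, None, len(table))


def context_spectrum(
    table: SampleTable, contexts: dict[VariantKey, str]
) -> SpectrumResult:
    """96-channel trinucleotide-context spectrum of a sample.

    ``contexts`` maps every variant key to its 3-base reference context; a
    missing or inconsistent context is an error naming the offending variants.
    """
    counts6 = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    counts96 = {lab: 0 for lab in SBS96_LABELS}
    offenders: list[str] = []
    for obs in table:
        ctx = contexts.get(obs.key)
        if ctx is None:
            offenders.append(f"{obs.key}: no context supplied")
            continue
        try:
            label = collapse_context(obs.key.ref, obs.key.alt, ctx)
        except ValidationError as exc:
            offenders.append(f"{obs.key}: {exc}")
            continue
        counts96[label] += 1
        counts6[collapse_substitution(obs.key.ref, obs.key.alt)] += 1
    if offenders:
        raise ValidationError(
            "context errors for %d variant(s): %s" % (len(offenders), "; ".join(offenders))
        )
    return SpectrumResult(counts6, counts96, len(table))


@dataclass
class ExposureResult:
    """NNLS refit of a 96-channel spectrum against known signatures."""

    exposures: pd.Series  # per-signature, normalized to sum 1 when possible
    residual: float  # Euclidean norm of the fit residual (on normalized counts)


def signature_exposures(counts96, signatures: pd.DataFrame) -> ExposureResult:
    """Non-negative least-squares exposures of a spectrum over signature columns.

    ``counts96`` is a length-96 vector (canonical order) or a label->count
    mapping; ``signatures`` is a 96 x k matrix whose columns each sum to 1.
    Counts are normalized to proportions before fitting; exposures are
    normalized to sum 1 and the residual norm is reported.
    """
    if isinstance(counts96, dict):
        v = np.array([counts96.get(lab, 0) for lab in SBS96_LABELS], dtype=float)
    else:
        v = np.asarray(counts96, dtype=float)
    if v.shape != (96,):
        raise ValidationError(f"counts96 must have length 96, got shape {v.shape}")
    if np.any(v < 0):
        raise ValidationError("counts96 must be non-negative")
    total = v.sum()
    if total == 0:
        raise ValidationError("all-zero spectrum: exposures undefined")

    sig = signatures.reindex(SBS96_LABELS)
    if sig.isna().any().any():
        missing = set(SBS96_LABELS) - set(signatures.index)
        raise FormatError(f"signature matrix lacks contexts: {sorted(missing)[:5]}...")
    mat = sig.to_numpy(dtype=float)
    colsums = mat.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValidationError("signature columns must each sum to 1")

    x, rnorm = nnls(mat, v / total)
    s = x.sum()
    exposures = x / s if s > 0 else x
    return ExposureResult(pd.Series(exposures, index=signatures.columns), float(rnorm))


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a COSMIC-format signature TSV: first column 96 context labels, one
    column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if set(df.index) != set(SBS96_LABELS):
        raise FormatError(
            f"{path}: first column must contain exactly the 96 trinucleotide context labels"
        )
    return df
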