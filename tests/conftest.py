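import pytest

from itgh import SampleTable, VariantKey, VariantObservation


def make_table(sample_id, rows, **meta):
    """rows: iterable of (chrom, pos, ref, alt, ref_count, alt_count[, effect])."""
    obs = []
    for row in rows:
        chrom, pos, ref, alt, rc, ac = row[:6]
        effect = row[6] if len(row) > 6 else "unknown"
        obs.append(VariantObservation(VariantKey(chrom, pos, ref, alt), sample_id, rc, ac, effect))
    return SampleTable(sample_id, obs, **meta)


@pytest.fixture
def small_pair():
    """Two matched samples sharing two of three variants."""
    a = make_table("A", [
        ("1", 100, "A", "T", 60, 40, "nonsynonymous"),
        ("1", 200, "C", "G", 50, 50, "synonymous"),
        ("2", 300, "G", "A", 90, 10, "splice"),
    ])
    b = make_table("B", [
        ("1", 100, "A", "T", 55, 45, "nonsynonymous"),
        ("1", 200, "C", "G", 48, 52, "synonymous"),
        ("3", 400, "T", "C", 70, 30, "noncoding"),
    ])
    return a, b
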