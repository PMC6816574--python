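"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

from mrdseq.panel_io import GenomicInterval, TrackableVariant
from mrdseq.sequence import Reference, encode
from mrdseq.simulate import RawRead

TRANSVERSION = {"A": "T", "C": "A", "G": "T", "T": "C"}


def make_reference(length=3000, seed=123, chrom="chr1") -> Reference:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Reference.from_sequences({chrom: seq})


def snv_at(reference: Reference, pos: int, chrom="chr1", label="") -> TrackableVariant:
    ref = reference.base(chrom, pos)
    return TrackableVariant(chrom=chrom, pos=pos, ref=ref, alt=TRANSVERSION[ref], label=label)


def insertion_at(reference: Reference, pos: int, seq="GT", chrom="chr1") -> TrackableVariant:
    ref = reference.base(chrom, pos)
    return TrackableVariant(chrom=chrom, pos=pos, ref=ref, alt=ref + seq)


def deletion_at(reference: Reference, pos: int, length=2, chrom="chr1") -> TrackableVariant:
    ref = reference.slice(chrom, pos, pos + 1 + length)
    return TrackableVariant(chrom=chrom, pos=pos, ref=ref, alt=ref[0])


def make_read(reference: Reference, start: int, end: int, umi="AAAAAA", *, chrom="chr1",
              subs=(), insertions=(), deletions=(), read_id="r", sample_id="s") -> RawRead:
    """Build a RawRead whose bases equal the reference except for ``subs``.

    ``subs`` is a list of (absolute position, base character).
    """
    bases = reference[chrom][start:end].copy()
    for pos, base in subs:
        bases[pos - start] = encode(base)[0]
    dels = [GenomicInterval(chrom, ds, de) for ds, de in deletions]
    from mrdseq.sequence import GAP
    for d in dels:
        bases[d.start - start:d.end - start] = GAP
    return RawRead(id=read_id, chrom=chrom, start=start, end=end, umi=umi, bases=bases,
                   insertions=list(insertions), deletions=dels, sample_id=sample_id)


# ---------------------------------------------------------------------------
# independent oracles used by unit and acceptance tests

def oracle_consensus_bases(member_bases, majority_fraction=0.5):
    """Per-column vote oracle: plain Python counting, no shared code paths."""
    from collections import Counter
    from mrdseq.sequence import GAP, N_CODE

    span = len(member_bases[0])
    out = []
    for col in range(span):
        votes = Counter(row[col] for row in member_bases)
        votes.pop(N_CODE, None)
        votes.pop(GAP, None)
        covering = sum(votes.values())
        call = N_CODE
        for base, count in sorted(votes.items()):
            if count > majority_fraction * covering and count == max(votes.values()):
                call = base
                break
        out.append(call)
    return np.array(out, dtype=np.uint8)


def exact_consensus_error_oracle(e: float, size: int = 3):
    """Exact single-column error model for a size-k family under error rate e.

    Enumerates all 4^k member-base combinations (each read keeps the
    reference base with probability 1-e, or one of three alternates with
    probability e/3 each) and applies the strict-majority rule.  Returns
    (P(consensus != ref | a base was called), P(consensus is N)).
    """
    import itertools
    from collections import Counter

    p = [1 - e, e / 3, e / 3, e / 3]  # index 0 = reference base
    p_err = p_n = 0.0
    for combo in itertools.product(range(4), repeat=size):
        prob = 1.0
        for b in combo:
            prob *= p[b]
        best_base, best_count = Counter(combo).most_common(1)[0]
        if best_count > size / 2:
            if best_base != 0:
                p_err += prob
        else:
            p_n += prob
    return p_err / (1 - p_n), p_n


def fisher_oracle(a, b, c, d):
    """Exhaustive margin-preserving table enumeration (two-sided)."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c
    if min(r1, n - r1, c1, n - c1) == 0:
        return 1.0
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(n - r1, c1 - a) / denom
    total = 0.0
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = comb(r1, k) * comb(n - r1, c1 - k) / denom
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def mwu_oracle(a, b):
    """O(n*m) pairwise-comparison count with half-credit for ties."""
    u_a = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    return min(u_a, len(a) * len(b) - u_a)
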