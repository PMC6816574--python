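"""Per-position allele summaries and trackable-variant quantification.

Builds mpileup-style columns from consensus (or raw) reads and measures
a variant's allele fraction: alt-supporting consensus reads over the
N-excluded consensus depth at the locus.  Consensus N calls never enter
a depth denominator.  Reads whose called deletion spans a column still
count toward that column's spanning total (but to no base count);
deletion events are tallied at their VCF anchor base, insertions at the
anchor position they follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import (DELETION, GenomicInterval, INSERTION, SNV, TrackableVariant)
from .sequence import GAP, N_CODE, decode
from .collapse import ConsensusRead, ConsensusSet
from .simulate import RawRead, ReadSet

_BASES = "ACGT"


@dataclass
class PileupColumn:
    """Allele counts for one reference position.

    Conservation: sum(base counts) + n_count + del_spanning equals the
    number of spanning reads; ``depth`` (the variant-calling denominator)
    excludes N calls only.
    """

    chrom: str
    pos: int
    ref: str
    counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in _BASES})
    n_count: int = 0
    del_spanning: int = 0
    deletion_count: dict[tuple[int, int], int] = field(default_factory=dict)
    insertion_count: dict[str, int] = field(default_factory=dict)
    spanning: int = 0

    @property
    def depth(self) -> int:
        return self.spanning - self.n_count


@dataclass
class VariantObservation:
    """One trackable variant's measurement in one sample."""

    variant: TrackableVariant
    alt_count: int
    depth: int
    sample_id: str = ""
    no_coverage: bool = False

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth > 0 else 0.0


def _as_sparse(obj, reference=None):
    """Normalise any read/consensus container to sparse arrays.

    Returns (chrom, starts, ends, subs(pos, alt, unit), ns(pos), dels, inss)
    where dels/inss are event lists [(unit, start, end)] / [(unit, pos, seq)].
    """
    if isinstance(obj, ConsensusSet):
        return (obj.chrom, obj.start, obj.end,
                (obj.sub_pos, obj.sub_alt, obj.sub_cons),
                (obj.n_pos, obj.n_cons),
                list(zip(obj.del_cons.tolist(), obj.del_start.tolist(), obj.del_end.tolist())),
                list(zip(obj.ins_cons.tolist(), obj.ins_pos.tolist(), obj.ins_seq)))
    if isinstance(obj, ReadSet):
        isN = obj.sub_alt == N_CODE
        return (obj.chrom, obj.start, obj.end,
                (obj.sub_pos[~isN], obj.sub_alt[~isN], obj.sub_read[~isN]),
                (obj.sub_pos[isN], obj.sub_read[isN]),
                list(zip(obj.del_read.tolist(), obj.del_start.tolist(), obj.del_end.tolist())),
                list(zip(obj.ins_read.tolist(), obj.ins_pos.tolist(), obj.ins_seq)))
    # iterable of ConsensusRead / RawRead with dense bases
    items = list(obj)
    if not items:
        return ("", np.zeros(0, np.int64), np.zeros(0, np.int64),
                (np.zeros(0, np.int64), np.zeros(0, np.uint8), np.zeros(0, np.int64)),
                (np.zeros(0, np.int64), np.zeros(0, np.int64)), [], [])
    if reference is None:
        raise ValueError("reference required for dense read input")
    chrom = items[0].chrom
    ref = reference[chrom]
    starts = np.array([r.start for r in items], dtype=np.int64)
    ends = np.array([r.end for r in items], dtype=np.int64)
    sp, sa, su, npos, nunit, dels, inss = [], [], [], [], [], [], []
    for i, r in enumerate(items):
        span = np.arange(r.start, r.end)
        isN = r.bases == N_CODE
        npos.extend(span[isN].tolist())
        nunit.extend([i] * int(isN.sum()))
        diff = (~isN) & (r.bases != GAP) & (r.bases != ref[r.start:r.end])
        sp.extend(span[diff].tolist())
        sa.extend(r.bases[diff].tolist())
        su.extend([i] * int(diff.sum()))
        if isinstance(r, ConsensusRead):
            for iv, _ in r.deletions:
                dels.append((i, iv.start, iv.end))
            for p, s, _ in r.insertions:
                inss.append((i, p, s))
        else:
            for iv in r.deletions:
                dels.append((i, iv.start, iv.end))
            for p, s in r.insertions:
                inss.append((i, p, s))
    return (chrom, starts, ends,
            (np.array(sp, np.int64), np.array(sa, np.uint8), np.array(su, np.int64)),
            (np.array(npos, np.int64), np.array(nunit, np.int64)), dels, inss)


def build_pileup(consensus, intervals=None, reference=None) -> list[PileupColumn]:
    """One :class:`PileupColumn` per covered position of ``intervals``.

    ``consensus`` may be a ConsensusSet, a ReadSet (raw pileup), or an
    iterable of ConsensusRead/RawRead (dense; requires ``reference``).
    Uncovered positions yield no column.
    """
    chrom, starts, ends, subs, ns, dels, inss = _as_sparse(consensus, reference)
    if len(starts) == 0:
        return []
    if intervals is None:
        intervals = [GenomicInterval(chrom, int(starts.min()), int(ends.max()))]
    if reference is None:
        raise ValueError("reference required to report the REF column")
    ref = reference[chrom]
    columns: list[PileupColumn] = []
    sub_pos, sub_alt, _ = subs
    n_pos, _ = ns
    for iv in intervals:
        if iv.chrom != chrom:
            continue
        lo, hi = iv.start, iv.end
        span = hi - lo
        cov = np.zeros(span + 1, dtype=np.int64)
        np.add.at(cov, np.clip(starts - lo, 0, span), 1)
        np.add.at(cov, np.clip(ends - lo, 0, span), -1)
        cov = np.cumsum(cov[:-1])
        inside = (sub_pos >= lo) & (sub_pos < hi)
        alt_counts = np.zeros((4, span), dtype=np.int64)
        np.add.at(alt_counts, (sub_alt[inside], sub_pos[inside] - lo), 1)
        n_inside = (n_pos >= lo) & (n_pos < hi)
        n_arr = np.bincount(n_pos[n_inside] - lo, minlength=span)
        del_span = np.zeros(span + 1, dtype=np.int64)
        del_events: dict[int, dict[tuple[int, int], int]] = {}
        for _, ds, de in dels:
            np.add.at(del_span, np.clip(ds - lo, 0, span), 1)
            np.add.at(del_span, np.clip(de - lo, 0, span), -1)
            anchor = ds - 1
            del_events.setdefault(anchor, {})
            del_events[anchor][(ds, de)] = del_events[anchor].get((ds, de), 0) + 1
        del_span = np.cumsum(del_span[:-1])
        ins_events: dict[int, dict[str, int]] = {}
        for _, p, s in inss:
            ins_events.setdefault(p, {})
            ins_events[p][s] = ins_events[p].get(s, 0) + 1
        for off in np.flatnonzero(cov > 0):
            pos = lo + int(off)
            base_counts = {b: int(alt_counts[i, off]) for i, b in enumerate(_BASES)}
            ref_base = decode(ref[pos:pos + 1])
            if ref_base in base_counts:
                base_counts[ref_base] = int(
                    cov[off] - n_arr[off] - del_span[off] - alt_counts[:, off].sum()
                    + alt_counts[_BASES.index(ref_base), off])
            columns.append(PileupColumn(
                chrom=chrom, pos=pos, ref=ref_base, counts=base_counts,
                n_count=int(n_arr[off]), del_spanning=int(del_span[off]),
                deletion_count=dict(del_events.get(pos, {})),
                insertion_count=dict(ins_events.get(pos, {})),
                spanning=int(cov[off])))
    return columns


def _summarize_from_set(cset: ConsensusSet, variant: TrackableVariant) -> VariantObservation:
    pos = variant.pos
    spanning = int(np.count_nonzero((cset.start <= pos) & (cset.end > pos))) \
        if cset.chrom == variant.chrom else 0
    if spanning == 0:
        return VariantObservation(variant, 0, 0, sample_id=cset.sample_id, no_coverage=True)
    n_at = int(np.count_nonzero(cset.n_pos == pos)) if len(cset.n_pos) else 0
    depth = spanning - n_at
    if variant.var_type == SNV:
        alt_code = {b: i for i, b in enumerate(_BASES)}[variant.alt]
        alt = int(np.count_nonzero((cset.sub_pos == pos) & (cset.sub_alt == alt_code)))
    elif variant.var_type == INSERTION:
        seq = variant.inserted_sequence
        alt = sum(1 for p, s in zip(cset.ins_pos, cset.ins_seq)
                  if p == pos and s == seq)
    else:
        d = variant.deleted_interval
        alt = int(np.count_nonzero((cset.del_start == d.start) & (cset.del_end == d.end)))
    return VariantObservation(variant, alt, depth, sample_id=cset.sample_id,
                              no_coverage=depth <= 0)


def summarize_variant(pileup, variant: TrackableVariant) -> VariantObservation:
    """Measure one trackable variant: alt count, N-excluded depth, VAF.

    ``pileup`` is either a :class:`~mrdseq.collapse.ConsensusSet` or a
    list of :class:`PileupColumn`.  A locus with no spanning consensus
    read yields a flagged no-coverage observation.
    """
    if isinstance(pileup, ConsensusSet):
        return _summarize_from_set(pileup, variant)
    col = next((c for c in pileup if c.chrom == variant.chrom and c.pos == variant.pos), None)
    if col is None or col.spanning == 0:
        return VariantObservation(variant, 0, 0, no_coverage=True)
    if variant.var_type == SNV:
        alt = col.counts.get(variant.alt, 0)
    elif variant.var_type == INSERTION:
        alt = col.insertion_count.get(variant.inserted_sequence, 0)
    else:
        d = variant.deleted_interval
        alt = col.deletion_count.get((d.start, d.end), 0)
    return VariantObservation(variant, alt, col.depth, no_coverage=col.depth <= 0)


def pileup_to_frame(columns: list[PileupColumn]) -> pd.DataFrame:
    rows = []
    for c in columns:
        rows.append({
            "chrom": c.chrom, "pos": c.pos + 1, "ref": c.ref,
            **{b: c.counts.get(b, 0) for b in _BASES},
            "N": c.n_count, "del": c.del_spanning,
            "ins": sum(c.insertion_count.values()), "depth": c.depth,
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", *_BASES, "N", "del", "ins", "depth"])


def observations_to_frame(observations: list[VariantObservation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        v = o.variant
        rows.append({
            "chrom": v.chrom, "pos": v.pos + 1, "ref": v.ref, "alt": v.alt,
            "type": v.var_type, "gene": v.gene, "label": v.label,
            "alt_count": o.alt_count, "depth": o.depth,
            "vaf": o.vaf, "no_coverage": o.no_coverage, "sample_id": o.sample_id,
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "type", "gene", "label",
                                       "alt_count", "depth", "vaf", "no_coverage", "sample_id"])
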