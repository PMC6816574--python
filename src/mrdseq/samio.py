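"""SAM import/export for raw and consensus reads (via pysam).

Raw reads carry their UMI in the RX tag and (when simulated) their true
molecule of origin in the MI tag.  Consensus reads additionally carry
the family size in cN and the N fraction in cf.  CIGAR strings encode
the indel events; base qualities are emitted as a constant.
"""

from __future__ import annotations

import numpy as np
import pysam

from .panel_io import GenomicInterval
from .sequence import GAP, Reference, encode
from .simulate import RawRead, ReadSet
from .collapse import ConsensusRead, FamilyKey


def _cigar(start: int, end: int, deletions, insertions) -> list[tuple[int, int]]:
    """CIGAR ops for a read spanning [start, end) with the given events."""
    events = []
    for ds, de in deletions:
        events.append((ds, 1, de - ds, None))          # boundary ds, del after ins
    for pos, seq in insertions:
        events.append((pos + 1, 0, len(seq), None))    # boundary after the anchor
    events.sort(key=lambda t: (t[0], t[1]))
    ops: list[tuple[int, int]] = []
    cur = start
    for boundary, kind, length, _ in events:
        if boundary > cur:
            ops.append((0, boundary - cur))            # M
            cur = boundary
        if kind == 0:
            ops.append((1, length))                    # I
        else:
            ops.append((2, length))                    # D
            cur += length
    if end > cur:
        ops.append((0, end - cur))
    merged: list[tuple[int, int]] = []
    for op, length in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + length)
        else:
            merged.append((op, length))
    return merged


def _header(reference: Reference, comments=()) -> pysam.AlignmentHeader:
    d = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(len(arr))} for name, arr in reference.contigs.items()],
    }
    if comments:
        d["CO"] = list(comments)
    return pysam.AlignmentHeader.from_dict(d)


def _check_sorted(items) -> None:
    prev = None
    for it in items:
        key = (it.chrom, it.start)
        if prev is not None and key < prev:
            raise ValueError("reads must be sorted by (chrom, start) before writing SAM")
        prev = key


def write_sam(reads, path, reference: Reference, comments=()) -> None:
    """Write raw reads (ReadSet or RawRead list) as coordinate-sorted SAM."""
    if isinstance(reads, ReadSet):
        order = np.argsort(reads.start, kind="stable")
        items = (reads.get_read(int(i), reference) for i in order)
    else:
        items = list(reads)
        _check_sorted(items)
    header = _header(reference, comments)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in items:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.id
            seg.reference_name = r.chrom
            seg.reference_start = r.start
            seg.mapping_quality = 60
            seg.flag = 0
            dels = [(d.start, d.end) for d in r.deletions]
            seg.cigartuples = _cigar(r.start, r.end, dels, r.insertions)
            seq = r.query_sequence()
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            seg.set_tag("RX", r.umi if r.umi else "", value_type="Z")
            if r.molecule_id >= 0:
                seg.set_tag("MI", str(r.molecule_id), value_type="Z")
            out.write(seg)


def _decode_alignment(seg: pysam.AlignedSegment):
    """Recover (bases over [start, end), insertions, deletions) from one record."""
    start = seg.reference_start
    end = seg.reference_end
    bases = np.full(end - start, GAP, dtype=np.uint8)
    insertions: list[tuple[int, str]] = []
    deletions: list[GenomicInterval] = []
    q = seg.query_sequence
    qpos, rpos = 0, start
    for op, length in seg.cigartuples:
        if op in (0, 7, 8):                            # M / = / X
            bases[rpos - start:rpos - start + length] = encode(q[qpos:qpos + length])
            qpos += length
            rpos += length
        elif op == 1:                                  # I
            insertions.append((rpos - 1, q[qpos:qpos + length]))
            qpos += length
        elif op == 2:                                  # D
            deletions.append(GenomicInterval(seg.reference_name, rpos, rpos + length))
            rpos += length
        elif op == 4:                                  # S
            qpos += length
        else:
            raise ValueError(f"unsupported CIGAR op {op} in read {seg.query_name}")
    return bases, insertions, deletions


def read_sam(path) -> list[RawRead]:
    """Read raw reads back from SAM (inverse of :func:`write_sam`)."""
    reads: list[RawRead] = []
    with pysam.AlignmentFile(str(path), "r") as f:
        for seg in f:
            if seg.is_unmapped:
                continue
            bases, insertions, deletions = _decode_alignment(seg)
            umi = seg.get_tag("RX") if seg.has_tag("RX") else ""
            mol = int(seg.get_tag("MI")) if seg.has_tag("MI") else -1
            reads.append(RawRead(
                id=seg.query_name, chrom=seg.reference_name,
                start=seg.reference_start, end=seg.reference_end,
                umi=umi, bases=bases, insertions=insertions, deletions=deletions,
                molecule_id=mol))
    return reads


def write_consensus_sam(consensus, path, reference: Reference, comments=()) -> None:
    """Write consensus reads with cN (family size) and cf (N fraction) tags."""
    if hasattr(consensus, "to_consensus_reads"):
        consensus = consensus.to_consensus_reads(reference)
    consensus = sorted(consensus, key=lambda c: (c.chrom, c.start, c.end, c.key.umi))
    header = _header(reference, comments)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, c in enumerate(consensus):
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"consensus{i}"
            seg.reference_name = c.chrom
            seg.reference_start = c.start
            seg.mapping_quality = 60
            seg.flag = 0
            dels = [(iv.start, iv.end) for iv, _ in c.deletions]
            inss = [(p, s) for p, s, _ in c.insertions]
            seg.cigartuples = _cigar(c.start, c.end, dels, inss)
            keep = c.bases != GAP
            parts = []
            from .sequence import decode
            ins_sorted = sorted(inss)
            j = 0
            for off in range(c.end - c.start):
                if keep[off]:
                    parts.append(decode(c.bases[off:off + 1]))
                while j < len(ins_sorted) and ins_sorted[j][0] == c.start + off:
                    parts.append(ins_sorted[j][1])
                    j += 1
            seq = "".join(parts)
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            seg.set_tag("RX", c.key.umi, value_type="Z")
            seg.set_tag("cN", int(c.family_size), value_type="i")
            seg.set_tag("cf", float(c.n_fraction), value_type="f")
            out.write(seg)


def read_consensus_sam(path) -> list[ConsensusRead]:
    """Read consensus reads back from SAM (inverse of :func:`write_consensus_sam`)."""
    out: list[ConsensusRead] = []
    with pysam.AlignmentFile(str(path), "r") as f:
        for seg in f:
            if seg.is_unmapped:
                continue
            bases, insertions, deletions = _decode_alignment(seg)
            fam = int(seg.get_tag("cN")) if seg.has_tag("cN") else 0
            umi = seg.get_tag("RX") if seg.has_tag("RX") else ""
            out.append(ConsensusRead(
                key=FamilyKey(seg.reference_name, seg.reference_start,
                              seg.reference_end, umi),
                bases=bases,
                insertions=[(p, s, fam) for p, s in insertions],
                deletions=[(iv, fam) for iv in deletions],
                family_size=fam))
    return out
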