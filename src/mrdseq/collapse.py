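"""UMI read-family grouping and consensus building.

Reads are aggregated into families keyed by (contig, start, end, UMI) —
each family ideally representing one original DNA molecule — and every
family with at least ``min_family_size`` members (default 3) is reduced
to a consensus sequence by per-position majority vote.  A position where
no base is carried by a strict majority of the covering members is
called N, an undetermined base that is excluded from downstream depth
statistics and variant calling.  Indel events are called when a strict
majority of the family carries the identical event.

Two equivalent code paths exist: a dense per-family vote
(:func:`build_consensus`, the reference implementation used for small
inputs and oracles) and a vectorised sparse path inside
:func:`collapse_sample` used when the input is a :class:`~mrdseq.simulate.ReadSet`.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import GenomicInterval
from .sequence import GAP, N_CODE, decode
from .simulate import RawRead, ReadSet

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class FamilyKey:
    chrom: str
    start: int
    end: int
    umi: str


@dataclass
class ReadFamily:
    """All raw reads sharing a family key (same fragment, same UMI)."""

    key: FamilyKey
    members: list[RawRead]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusRead:
    """Majority-vote consensus of one read family.

    ``bases`` covers [key.start, key.end): base codes, N where no strict
    majority was reached, GAP under a called deletion.
    """

    key: FamilyKey
    bases: np.ndarray
    insertions: list[tuple[int, str, int]] = field(default_factory=list)  # (pos, seq, support)
    deletions: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    family_size: int = 0

    @property
    def n_fraction(self) -> float:
        return float(np.count_nonzero(self.bases == N_CODE)) / max(len(self.bases), 1)

    @property
    def chrom(self) -> str:
        return self.key.chrom

    @property
    def start(self) -> int:
        return self.key.start

    @property
    def end(self) -> int:
        return self.key.end


class GroupingResult(list):
    """List of :class:`ReadFamily` plus a count of reads rejected for missing UMIs."""

    def __init__(self, families, rejected: int = 0):
        super().__init__(families)
        self.rejected = rejected


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return sum(x != y for x, y in zip(a, b)) == 1


def group_reads(reads, umi_mismatch_tolerance: int = 0) -> GroupingResult:
    """Partition reads into families by exact (chrom, start, end, UMI) key.

    With tolerance 1, families at identical coordinates whose UMIs differ
    by a single substitution are merged, the larger family absorbing the
    smaller (ties broken lexicographically by UMI).  Reads with no UMI
    are rejected to a side-channel count, not silently dropped.
    """
    if isinstance(reads, ReadSet):
        raise TypeError("group_reads operates on RawRead objects; use collapse_sample for a ReadSet")
    buckets: dict[FamilyKey, list[RawRead]] = defaultdict(list)
    rejected = 0
    for r in reads:
        if not r.umi:
            rejected += 1
            continue
        buckets[FamilyKey(r.chrom, r.start, r.end, r.umi)].append(r)
    if umi_mismatch_tolerance > 0:
        by_coord: dict[tuple, list[FamilyKey]] = defaultdict(list)
        for key in buckets:
            by_coord[(key.chrom, key.start, key.end)].append(key)
        for keys in by_coord.values():
            # repeatedly absorb the smallest near-duplicate family into the largest
            merged = True
            while merged and len(keys) > 1:
                merged = False
                # deterministic order: descending size, then lexicographic UMI
                keys.sort(key=lambda k: (-len(buckets[k]), k.umi))
                for i in range(len(keys)):
                    for j in range(len(keys) - 1, i, -1):
                        if _hamming1(keys[i].umi, keys[j].umi):
                            buckets[keys[i]].extend(buckets.pop(keys[j]))
                            keys.pop(j)
                            merged = True
    families = [ReadFamily(key=k, members=v) for k, v in buckets.items()]
    families.sort(key=lambda f: f.key)
    for fam in families:
        fam.members.sort(key=lambda r: r.id)
    return GroupingResult(families, rejected)


def build_consensus(family: ReadFamily, min_family_size: int = 3,
                    majority_fraction: float = 0.5) -> ConsensusRead | None:
    """Per-column strict-majority vote over one family; None below the size cutoff.

    At each reference position the denominator is the number of members
    holding a real base there (member N bases and deletion-spanning
    members are excluded); a base must be carried by strictly more than
    ``majority_fraction`` of that denominator to be called, otherwise the
    consensus is N.  An indel event needs the identical event in strictly
    more than ``majority_fraction`` of the family.
    """
    if not family.members:
        raise ValueError("empty family")
    if family.size < min_family_size:
        return None
    key = family.key
    span = key.end - key.start
    k = family.size
    counts = np.zeros((6, span), dtype=np.int64)
    for r in family.members:
        if (r.start, r.end) != (key.start, key.end):
            raise ValueError("family members must share the key coordinates")
        np.add.at(counts, (r.bases.astype(np.int64), np.arange(span)), 1)
    covering = counts[:4].sum(axis=0)            # members with a real base
    need = majority_fraction * covering
    best = counts[:4].argmax(axis=0)
    best_count = counts[:4].max(axis=0)
    bases = np.where((covering > 0) & (best_count > need), best, N_CODE).astype(np.uint8)

    ins_votes = Counter((pos, seq) for r in family.members for pos, seq in r.insertions)
    insertions = [(pos, seq, c) for (pos, seq), c in sorted(ins_votes.items())
                  if c > majority_fraction * k]
    del_votes = Counter((d.start, d.end) for r in family.members for d in r.deletions)
    deletions = []
    for (ds, de), c in sorted(del_votes.items()):
        if c > majority_fraction * k:
            deletions.append((GenomicInterval(key.chrom, ds, de), c))
            bases[ds - key.start:de - key.start] = GAP
    return ConsensusRead(key=key, bases=bases, insertions=insertions,
                         deletions=deletions, family_size=k)


@dataclass
class CollapseParams:
    min_family_size: int = 3
    majority_fraction: float = 0.5
    umi_mismatch_tolerance: int = 0


@dataclass
class CollapseMetrics:
    """QC summary of one sample's collapse (the assay contract is >99%
    mapping, >95% on-target, >10,000x collapsed median depth)."""

    raw_read_count: int = 0
    family_count: int = 0
    families_passing: int = 0
    consensus_count: int = 0
    rejected_reads: int = 0
    mapping_rate: float = 0.0
    on_target_rate: float = 0.0
    collapsed_median_depth: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


class ConsensusSet:
    """Struct-of-arrays container for consensus reads (sparse, reference-relative).

    ``sub_*`` arrays record consensus positions whose call differs from
    the reference; ``n_*`` arrays record N (no-majority) positions.
    """

    def __init__(self, chrom, start, end, umi, family_size, *,
                 sub_cons=None, sub_pos=None, sub_alt=None,
                 n_cons=None, n_pos=None,
                 ins_cons=None, ins_pos=None, ins_seq=None, ins_support=None,
                 del_cons=None, del_start=None, del_end=None, del_support=None,
                 sample_id: str = ""):
        z = np.zeros(0, dtype=np.int64)
        self.chrom = chrom
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.umi = list(umi)
        self.family_size = np.asarray(family_size, dtype=np.int64)
        self.sub_cons = z if sub_cons is None else np.asarray(sub_cons, dtype=np.int64)
        self.sub_pos = z if sub_pos is None else np.asarray(sub_pos, dtype=np.int64)
        self.sub_alt = (np.zeros(0, np.uint8) if sub_alt is None
                        else np.asarray(sub_alt, dtype=np.uint8))
        self.n_cons = z if n_cons is None else np.asarray(n_cons, dtype=np.int64)
        self.n_pos = z if n_pos is None else np.asarray(n_pos, dtype=np.int64)
        self.ins_cons = z if ins_cons is None else np.asarray(ins_cons, dtype=np.int64)
        self.ins_pos = z if ins_pos is None else np.asarray(ins_pos, dtype=np.int64)
        self.ins_seq = list(ins_seq) if ins_seq is not None else []
        self.ins_support = z if ins_support is None else np.asarray(ins_support, dtype=np.int64)
        self.del_cons = z if del_cons is None else np.asarray(del_cons, dtype=np.int64)
        self.del_start = z if del_start is None else np.asarray(del_start, dtype=np.int64)
        self.del_end = z if del_end is None else np.asarray(del_end, dtype=np.int64)
        self.del_support = z if del_support is None else np.asarray(del_support, dtype=np.int64)
        self.sample_id = sample_id

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_fraction(self) -> np.ndarray:
        span = np.maximum(self.end - self.start, 1)
        n_counts = np.bincount(self.n_cons, minlength=len(self)) if len(self.n_cons) else \
            np.zeros(len(self), dtype=np.int64)
        return n_counts / span

    def to_consensus_reads(self, reference) -> list[ConsensusRead]:
        out = []
        sub_by = defaultdict(list)
        for c, p, a in zip(self.sub_cons, self.sub_pos, self.sub_alt):
            sub_by[int(c)].append((int(p), int(a)))
        n_by = defaultdict(list)
        for c, p in zip(self.n_cons, self.n_pos):
            n_by[int(c)].append(int(p))
        ins_by = defaultdict(list)
        for c, p, s, sup in zip(self.ins_cons, self.ins_pos, self.ins_seq, self.ins_support):
            ins_by[int(c)].append((int(p), s, int(sup)))
        del_by = defaultdict(list)
        for c, ds, de, sup in zip(self.del_cons, self.del_start, self.del_end, self.del_support):
            del_by[int(c)].append((GenomicInterval(self.chrom, int(ds), int(de)), int(sup)))
        ref = reference[self.chrom]
        for i in range(len(self)):
            s, e = int(self.start[i]), int(self.end[i])
            bases = ref[s:e].copy()
            for p, a in sub_by.get(i, ()):
                bases[p - s] = a
            for p in n_by.get(i, ()):
                bases[p - s] = N_CODE
            for iv, _ in del_by.get(i, ()):
                bases[iv.start - s:iv.end - s] = GAP
            out.append(ConsensusRead(
                key=FamilyKey(self.chrom, s, e, self.umi[i]), bases=bases,
                insertions=sorted(ins_by.get(i, ())),
                deletions=sorted(del_by.get(i, ()), key=lambda t: (t[0].start, t[0].end)),
                family_size=int(self.family_size[i])))
        return out

    @classmethod
    def from_consensus_reads(cls, consensus: list[ConsensusRead], reference,
                             sample_id: str = "") -> "ConsensusSet":
        if not consensus:
            return cls("", [], [], [], [], sample_id=sample_id)
        chrom = consensus[0].chrom
        ref = reference[chrom]
        start = [c.start for c in consensus]
        end = [c.end for c in consensus]
        umi = [c.key.umi for c in consensus]
        fam = [c.family_size for c in consensus]
        sub_c, sub_p, sub_a, n_c, n_p = [], [], [], [], []
        ins_c, ins_p, ins_s, ins_sup = [], [], [], []
        del_c, del_s, del_e, del_sup = [], [], [], []
        for i, c in enumerate(consensus):
            span = np.arange(c.start, c.end)
            isN = c.bases == N_CODE
            n_c.extend([i] * int(isN.sum()))
            n_p.extend(span[isN].tolist())
            diff = (~isN) & (c.bases != GAP) & (c.bases != ref[c.start:c.end])
            sub_c.extend([i] * int(diff.sum()))
            sub_p.extend(span[diff].tolist())
            sub_a.extend(c.bases[diff].tolist())
            for p, s, sup in c.insertions:
                ins_c.append(i); ins_p.append(p); ins_s.append(s); ins_sup.append(sup)
            for iv, sup in c.deletions:
                del_c.append(i); del_s.append(iv.start); del_e.append(iv.end); del_sup.append(sup)
        return cls(chrom, start, end, umi, fam, sub_cons=sub_c, sub_pos=sub_p, sub_alt=sub_a,
                   n_cons=n_c, n_pos=n_p, ins_cons=ins_c, ins_pos=ins_p, ins_seq=ins_s,
                   ins_support=ins_sup, del_cons=del_c, del_start=del_s, del_end=del_e,
                   del_support=del_sup, sample_id=sample_id)


def _consensus_depth(consensus: ConsensusSet, lo: int, hi: int) -> np.ndarray:
    """Per-position N-excluded consensus depth over [lo, hi)."""
    span = hi - lo
    depth = np.zeros(span + 1, dtype=np.int64)
    s = np.clip(consensus.start - lo, 0, span)
    e = np.clip(consensus.end - lo, 0, span)
    np.add.at(depth, s, 1)
    np.add.at(depth, e, -1)
    depth = np.cumsum(depth[:-1])
    if len(consensus.n_pos):
        inside = (consensus.n_pos >= lo) & (consensus.n_pos < hi)
        depth -= np.bincount(consensus.n_pos[inside] - lo, minlength=span)
    return depth


def _metrics(reads_total, rejected, fam_sizes, min_family_size, consensus, panel_intervals,
             on_target) -> CollapseMetrics:
    passing = int(np.count_nonzero(fam_sizes >= min_family_size)) if len(fam_sizes) else 0
    med = 0.0
    if len(consensus):
        if panel_intervals:
            depths = np.concatenate([
                _consensus_depth(consensus, iv.start, iv.end)
                for iv in panel_intervals if iv.chrom == consensus.chrom
            ]) if any(iv.chrom == consensus.chrom for iv in panel_intervals) else np.zeros(1)
        else:
            depths = _consensus_depth(consensus, int(consensus.start.min()),
                                      int(consensus.end.max()))
        med = float(np.median(depths))
    return CollapseMetrics(
        raw_read_count=reads_total, family_count=len(fam_sizes),
        families_passing=passing, consensus_count=len(consensus), rejected_reads=rejected,
        mapping_rate=1.0 if reads_total else 0.0, on_target_rate=on_target,
        collapsed_median_depth=med)


def _on_target_rate(start, end, chrom, panel_intervals) -> float:
    if not panel_intervals or len(start) == 0:
        return 1.0 if len(start) else 0.0
    ivs = sorted((iv.start, iv.end) for iv in panel_intervals if iv.chrom == chrom)
    if not ivs:
        return 0.0
    lo = np.array([a for a, _ in ivs])
    hi = np.array([b for _, b in ivs])
    # a read is on-target if it overlaps any interval
    idx = np.searchsorted(lo, end, side="left")  # first interval starting at/after read end
    prev = np.clip(idx - 1, 0, len(ivs) - 1)
    overlap = (idx > 0) & (hi[prev] > start)
    return float(np.count_nonzero(overlap)) / len(start)


def collapse_sample(reads, panel_intervals=None, params: CollapseParams | None = None,
                    reference=None):
    """Group one sample's reads and build all consensus reads plus QC metrics.

    ``reads`` may be a :class:`ReadSet` (vectorised path) or an iterable
    of :class:`RawRead` (dense path).  Returns ``(ConsensusSet, CollapseMetrics)``;
    with a dense input a ``reference`` is required to build the sparse
    consensus container.
    """
    params = params or CollapseParams()
    panel_intervals = list(panel_intervals or [])
    if isinstance(reads, ReadSet):
        return _collapse_readset(reads, panel_intervals, params)
    reads = list(reads)
    if not reads:
        log.warning("collapse_sample called with no reads")
        return ConsensusSet("", [], [], [], []), CollapseMetrics()
    if reference is None:
        raise ValueError("reference required to collapse plain RawRead input")
    grouping = group_reads(reads, params.umi_mismatch_tolerance)
    fam_sizes = np.array([f.size for f in grouping], dtype=np.int64)
    consensus_reads = []
    for fam in grouping:
        c = build_consensus(fam, params.min_family_size, params.majority_fraction)
        if c is not None:
            consensus_reads.append(c)
    cset = ConsensusSet.from_consensus_reads(consensus_reads, reference,
                                             sample_id=reads[0].sample_id)
    if not len(cset):
        cset.chrom = reads[0].chrom
    on_t = _on_target_rate(np.array([r.start for r in reads]),
                           np.array([r.end for r in reads]), reads[0].chrom, panel_intervals)
    return cset, _metrics(len(reads), grouping.rejected, fam_sizes, params.min_family_size,
                          cset, panel_intervals, on_t)


def _collapse_readset(reads: ReadSet, panel_intervals, params: CollapseParams):
    n = len(reads)
    if n == 0:
        log.warning("collapse_sample called with an empty ReadSet")
        return ConsensusSet(reads.chrom, [], [], [], []), CollapseMetrics()
    missing = reads.umi_missing
    rejected = int(missing.sum())
    ok = ~missing

    if params.umi_mismatch_tolerance > 0:
        # tolerance merging needs the per-family view; fall back to the dense path
        raise NotImplementedError(
            "UMI mismatch tolerance on a ReadSet: convert with to_reads() and use the dense path")

    # family key = (start, end, umi): lexsort then run-length encode.
    # UMIs are packed 3 bits per base into one integer for fast keying.
    ulen = reads.umi_codes.shape[1]
    umi_flat = np.zeros(n, dtype=np.int64)
    for i in range(ulen):
        umi_flat = (umi_flat << 3) | (reads.umi_codes[:, i].astype(np.int64) & 7)
    order = np.lexsort((umi_flat, reads.end, reads.start))
    order = order[ok[order]]
    s_o, e_o, u_o = reads.start[order], reads.end[order], umi_flat[order]
    if len(order) == 0:
        return ConsensusSet(reads.chrom, [], [], [], []), CollapseMetrics(
            raw_read_count=n, rejected_reads=rejected)
    new_fam = np.empty(len(order), dtype=bool)
    new_fam[0] = True
    new_fam[1:] = (s_o[1:] != s_o[:-1]) | (e_o[1:] != e_o[:-1]) | (u_o[1:] != u_o[:-1])
    fam_of_sorted = np.cumsum(new_fam) - 1
    n_fam = int(fam_of_sorted[-1]) + 1
    fam_of_read = np.full(n, -1, dtype=np.int64)
    fam_of_read[order] = fam_of_sorted
    fam_sizes = np.bincount(fam_of_sorted, minlength=n_fam)
    fam_start = s_o[new_fam]
    fam_end = e_o[new_fam]
    fam_umi = u_o[new_fam]

    passing = fam_sizes >= params.min_family_size
    # re-index passing families to consecutive consensus ids
    cons_id = np.cumsum(passing) - 1
    cons_of_read = np.where(
        (fam_of_read >= 0) & passing[np.clip(fam_of_read, 0, n_fam - 1)],
        cons_id[np.clip(fam_of_read, 0, n_fam - 1)], -1)
    n_cons = int(passing.sum())
    c_start, c_end = fam_start[passing], fam_end[passing]
    c_size = fam_sizes[passing]
    packed = fam_umi[passing]
    codes = np.empty((len(packed), ulen), dtype=np.uint8)
    for i in range(ulen):
        codes[:, ulen - 1 - i] = (packed >> (3 * i)) & 7
    c_umi = [decode(row) for row in codes]

    frac = params.majority_fraction
    pos_cap = int(reads.end.max()) + 1

    # --- substitution / N votes
    sc = cons_of_read[reads.sub_read]
    keep = sc >= 0
    sc, sp, sa = sc[keep], reads.sub_pos[keep], reads.sub_alt[keep]
    sub_cons, sub_pos, sub_alt = [], [], []
    nn_cons, nn_pos = [], []
    if len(sc):
        key = sc * pos_cap + sp
        o2 = np.lexsort((sa, key))
        key, sa2, sc2, sp2 = key[o2], sa[o2], sc[o2], sp[o2]
        # counts per (family, pos, alt)
        new_kpa = np.empty(len(key), dtype=bool)
        new_kpa[0] = True
        new_kpa[1:] = (key[1:] != key[:-1]) | (sa2[1:] != sa2[:-1])
        grp = np.cumsum(new_kpa) - 1
        cnt = np.bincount(grp)
        g_key, g_alt = key[new_kpa], sa2[new_kpa]
        g_cons, g_pos = sc2[new_kpa], sp2[new_kpa]
        # per (family, pos): total members deviating, count of member Ns, best alt
        new_kp = np.empty(len(g_key), dtype=bool)
        new_kp[0] = True
        new_kp[1:] = g_key[1:] != g_key[:-1]
        col = np.cumsum(new_kp) - 1
        n_col = int(col[-1]) + 1
        isN = g_alt == N_CODE
        tot = np.bincount(col, weights=cnt, minlength=n_col).astype(np.int64)
        n_members = np.bincount(col[isN], weights=cnt[isN], minlength=n_col).astype(np.int64)
        base_cnt = np.where(isN, 0, cnt)
        best = np.zeros(n_col, dtype=np.int64)
        np.maximum.at(best, col, base_cnt)
        # recover which alt achieved the best count; ties go to the smallest alt code
        is_best = (base_cnt == best[col]) & ~isN & (best[col] > 0)
        best_alt = np.full(n_col, -1, dtype=np.int64)
        rev = np.flatnonzero(is_best)[::-1]
        best_alt[col[rev]] = g_alt[rev].astype(np.int64)
        col_cons = g_cons[new_kp]
        col_pos = g_pos[new_kp]
        k = c_size[col_cons]
        cov = k - n_members                      # deletion adjustment patched below
        ref_cnt = cov - (tot - n_members)
        need = frac * cov
        call_alt = (best > need) & (best_alt >= 0)
        call_ref = ref_cnt > need
        call_n = ~(call_alt | call_ref)
        sub_cons = col_cons[call_alt]
        sub_pos = col_pos[call_alt]
        sub_alt = best_alt[call_alt].astype(np.uint8)
        nn_cons = col_cons[call_n]
        nn_pos = col_pos[call_n]

    # --- indel event votes (events are rare; small-array work)
    ins_cons, ins_pos, ins_seq, ins_sup = [], [], [], []
    del_cons, del_start, del_end, del_sup = [], [], [], []
    ins_events = defaultdict(int)
    for r, p, s in zip(reads.ins_read, reads.ins_pos, reads.ins_seq):
        c = cons_of_read[r]
        if c >= 0:
            ins_events[(int(c), int(p), s)] += 1
    for (c, p, s), cnt in sorted(ins_events.items()):
        if cnt > frac * c_size[c]:
            ins_cons.append(c); ins_pos.append(p); ins_seq.append(s); ins_sup.append(cnt)
    del_events = defaultdict(int)
    for r, ds, de in zip(reads.del_read, reads.del_start, reads.del_end):
        c = cons_of_read[r]
        if c >= 0:
            del_events[(int(c), int(ds), int(de))] += 1
    called_del_cols = {}
    for (c, ds, de), cnt in sorted(del_events.items()):
        if cnt > frac * c_size[c]:
            del_cons.append(c); del_start.append(ds); del_end.append(de); del_sup.append(cnt)
            for p in range(ds, de):
                called_del_cols[(c, p)] = True

    # patch base calls in families carrying (possibly minority) deletions:
    # a member's deleted positions leave the column denominator
    if del_events:
        dels_by_cons = defaultdict(list)
        for (c, ds, de), cnt in del_events.items():
            dels_by_cons[c].append((ds, de, cnt))
        # member deviations for affected families only
        aff = set(dels_by_cons)
        dev = defaultdict(lambda: defaultdict(Counter))  # cons -> pos -> Counter(alt)
        if len(sc):
            m = np.isin(sc, list(aff))
            for c, p, a in zip(sc[m], sp[m], sa[m]):
                dev[int(c)][int(p)][int(a)] += 1
        add_sub, add_n = [], []
        drop_sub, drop_n = set(), set()
        for c, devents in dels_by_cons.items():
            k = int(c_size[c])
            cols = set()
            for ds, de, _ in devents:
                cols.update(range(ds, de))
            for p in cols:
                if (c, p) in called_del_cols:
                    # called deletion: the column is a gap, not a base call
                    drop_sub.add((c, p)); drop_n.add((c, p))
                    continue
                del_members = sum(cnt for ds, de, cnt in devents if ds <= p < de)
                votes = dev.get(c, {}).get(p, Counter())
                n_mem = votes.get(N_CODE, 0)
                cov = k - del_members - n_mem
                tot_alt = sum(v for a, v in votes.items() if a != N_CODE)
                ref_cnt = cov - tot_alt
                base_votes = {a: v for a, v in votes.items() if a != N_CODE}
                best_a, best_v = (-1, 0)
                for a in sorted(base_votes):
                    if base_votes[a] > best_v:
                        best_a, best_v = a, base_votes[a]
                drop_sub.add((c, p)); drop_n.add((c, p))
                if cov > 0 and best_v > frac * cov:
                    add_sub.append((c, p, best_a))
                elif not (cov > 0 and ref_cnt > frac * cov):
                    add_n.append((c, p))
        if len(sub_cons):
            keep_m = np.array([(int(c), int(p)) not in drop_sub
                               for c, p in zip(sub_cons, sub_pos)], dtype=bool)
            sub_cons, sub_pos, sub_alt = sub_cons[keep_m], sub_pos[keep_m], sub_alt[keep_m]
        if len(nn_cons):
            keep_m = np.array([(int(c), int(p)) not in drop_n
                               for c, p in zip(nn_cons, nn_pos)], dtype=bool)
            nn_cons, nn_pos = nn_cons[keep_m], nn_pos[keep_m]
        if add_sub:
            sub_cons = np.concatenate([np.asarray(sub_cons, np.int64),
                                       np.array([t[0] for t in add_sub])])
            sub_pos = np.concatenate([np.asarray(sub_pos, np.int64),
                                      np.array([t[1] for t in add_sub])])
            sub_alt = np.concatenate([np.asarray(sub_alt, np.uint8),
                                      np.array([t[2] for t in add_sub], np.uint8)])
        if add_n:
            nn_cons = np.concatenate([np.asarray(nn_cons, np.int64),
                                      np.array([t[0] for t in add_n])])
            nn_pos = np.concatenate([np.asarray(nn_pos, np.int64),
                                     np.array([t[1] for t in add_n])])

    cset = ConsensusSet(reads.chrom, c_start, c_end, c_umi, c_size,
                        sub_cons=sub_cons, sub_pos=sub_pos, sub_alt=sub_alt,
                        n_cons=nn_cons, n_pos=nn_pos,
                        ins_cons=ins_cons, ins_pos=ins_pos, ins_seq=ins_seq,
                        ins_support=ins_sup, del_cons=del_cons, del_start=del_start,
                        del_end=del_end, del_support=del_sup, sample_id=reads.sample_id)
    on_t = _on_target_rate(reads.start[ok], reads.end[ok], reads.chrom, panel_intervals)
    return cset, _metrics(n, rejected, fam_sizes, params.min_family_size, cset,
                          panel_intervals, on_t)


def error_rate_profile(pileup_columns, reference, exclude=()) -> pd.Series:
    """Per-position background non-reference fraction from pileup columns.

    ``exclude`` removes true-variant positions.  Positions with zero
    depth are absent from the result (missing, not zero).
    """
    excluded = set(exclude)
    idx, vals = [], []
    for col in pileup_columns:
        if col.pos in excluded or col.depth <= 0:
            continue
        ref_base = decode(reference[col.chrom][col.pos:col.pos + 1])
        non_ref = sum(v for b, v in col.counts.items() if b != ref_base)
        idx.append(col.pos)
        vals.append(non_ref / col.depth)
    return pd.Series(vals, index=idx, dtype=float, name="background")
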