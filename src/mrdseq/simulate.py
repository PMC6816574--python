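"""Synthetic read generator with known molecular truth.

Emulates the molecular history of a hybrid-capture UMI library: unique
DNA fragments drawn over a target region, optional spike-in variant
molecules at a configured allele fraction, PCR duplication producing
UMI read families (with polymerase errors shared along a simple
two-generation lineage), and independent per-base sequencing errors.
Alignment is assumed perfect: reads carry their true coordinates.

Reads are materialised sparsely — a :class:`ReadSet` stores coordinates,
UMIs and *differences from the reference* (substitutions and indel
events) in flat numpy arrays — which keeps hundreds of thousands of
reads per sample cheap to generate and collapse.  Individual
:class:`RawRead` objects with dense base arrays are available on demand.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .panel_io import GenomicInterval, TrackableVariant, SNV, INSERTION, DELETION
from .sequence import Reference, decode, encode, A, C, G, T, N_CODE, GAP

log = logging.getLogger(__name__)

_UMI_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated sample.

    Defaults mirror the assay's operating point: 6-bp UMIs, per-base
    sequencing substitution rate 0.5%, a small polymerase error rate,
    and a zero-truncated negative-binomial family-size distribution
    (mean 6, dispersion 2) so that most families clear the 3-read
    consensus filter.
    """

    n_molecules: int
    region: GenomicInterval
    seed: int
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 60.0
    umi_length: int = 6
    spikes: list[tuple[TrackableVariant, float]] = field(default_factory=list)
    pcr_error_rate: float = 1e-6
    seq_error_rate: float = 0.005
    family_size_dist: tuple = ("ztnb", 6.0, 2.0)
    oxidation_bias: float = 0.0
    sample_id: str = "sim"

    def validate(self) -> None:
        if self.n_molecules < 1:
            raise ConfigError("n_molecules must be >= 1")
        for name in ("pcr_error_rate", "seq_error_rate", "oxidation_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for variant, vaf in self.spikes:
            if not 0.0 <= vaf <= 1.0:
                raise ConfigError(f"spike VAF must be in [0, 1], got {vaf}")
            end = variant.pos + len(variant.ref)
            if variant.chrom != self.region.chrom or not (
                self.region.start <= variant.pos and end <= self.region.end
            ):
                raise ConfigError(f"spike variant {variant.label or variant.key()} outside region")
        if sum(vaf for _, vaf in self.spikes) > 1.0:
            raise ConfigError("spike VAFs must sum to at most 1")
        if self.umi_length < 1:
            raise ConfigError("umi_length must be >= 1")
        if self.fragment_length_mean <= 0:
            raise ConfigError("fragment_length_mean must be positive")

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]

    def to_json(self) -> str:
        d = asdict(self)
        d["region"] = {"chrom": self.region.chrom, "start": self.region.start, "end": self.region.end}
        d["spikes"] = [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "gene": v.gene, "label": v.label, "vaf": vaf}
            for v, vaf in self.spikes
        ]
        d["family_size_dist"] = list(self.family_size_dist)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if "seed" not in d:
            raise ConfigError("config must specify a seed")
        region = GenomicInterval(**d.pop("region"))
        spikes = [
            (TrackableVariant(chrom=s["chrom"], pos=s["pos"], ref=s["ref"], alt=s["alt"],
                              gene=s.get("gene", ""), label=s.get("label", "")), s["vaf"])
            for s in d.pop("spikes", [])
        ]
        d["family_size_dist"] = tuple(d.get("family_size_dist", ("ztnb", 6.0, 2.0)))
        return cls(region=region, spikes=spikes, **d)


@dataclass(slots=True)
class Molecule:
    """One unique pre-amplification DNA fragment."""

    id: int
    interval: GenomicInterval
    umi: str
    carries_variant: TrackableVariant | None = None

    def sequence(self, reference: Reference) -> str:
        """Fragment bases (reference with the carried variant applied, if covered)."""
        iv = self.interval
        seq = reference.slice(iv.chrom, iv.start, iv.end)
        v = self.carries_variant
        if v is None or not _expressed(v, iv.start, iv.end):
            return seq
        off = v.pos - iv.start
        return seq[:off] + v.alt + seq[off + len(v.ref):]


def _expressed(v: TrackableVariant, start: int, end: int) -> bool:
    # a carried variant is visible only if the fragment spans the full ref allele
    return start <= v.pos and v.pos + len(v.ref) <= end


class MoleculeSet:
    """Sequence of :class:`Molecule` backed by flat arrays (fast to amplify)."""

    def __init__(self, chrom, start, end, umi_codes, carrier, config, reference):
        self.chrom = chrom
        self.start = start          # (n,) int64
        self.end = end              # (n,) int64
        self.umi_codes = umi_codes  # (n, umi_length) uint8 in 0..3
        self.carrier = carrier      # (n,) spike index or -1
        self.config = config
        self.reference = reference

    def __len__(self) -> int:
        return len(self.start)

    def __getitem__(self, i: int) -> Molecule:
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        spike = None
        if self.carrier[i] >= 0:
            spike = self.config.spikes[self.carrier[i]][0]
        return Molecule(
            id=int(i),
            interval=GenomicInterval(self.chrom, int(self.start[i]), int(self.end[i])),
            umi=decode(self.umi_codes[i]),
            carries_variant=spike,
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def n_carriers(self, spike_index: int) -> int:
        return int(np.count_nonzero(self.carrier == spike_index))


def simulate_molecules(config: SimConfig, reference: Reference, rng=None) -> MoleculeSet:
    """Draw unique molecules over the region; spike carriers are Binomial(n, VAF).

    Carrier status is drawn independently of fragment placement, so among
    molecules covering a spike locus the carrier fraction is the target
    VAF in expectation.
    """
    config.validate()
    if config.region.chrom not in reference:
        raise ConfigError(f"region contig {config.region.chrom} not in reference")
    if config.region.end > reference.length(config.region.chrom):
        raise ConfigError("region extends past the end of the reference contig")
    rng = np.random.default_rng([config.seed, 0]) if rng is None else rng
    n = config.n_molecules
    region = config.region
    span = len(region)

    length = np.rint(rng.normal(config.fragment_length_mean, config.fragment_length_sd, n))
    length = np.clip(length, 20, span).astype(np.int64)
    start = region.start + (rng.random(n) * (span - length + 1)).astype(np.int64)
    end = start + length
    umi_codes = rng.integers(0, 4, size=(n, config.umi_length), dtype=np.uint8)

    carrier = np.full(n, -1, dtype=np.int64)
    if config.spikes:
        perm = rng.permutation(n)
        used = 0
        for j, (_, vaf) in enumerate(config.spikes):
            n_carriers = int(rng.binomial(n, vaf))
            if used + n_carriers > n:
                raise ConfigError("spike VAFs draw more carrier molecules than exist")
            carrier[perm[used:used + n_carriers]] = j
            used += n_carriers
    return MoleculeSet(region.chrom, start, end, umi_codes, carrier, config, reference)


@dataclass
class RawRead:
    """One aligned sequencing fragment with its UMI and indel events.

    ``bases`` holds one code per reference position in [start, end);
    positions removed by a deletion are GAP.  Insertions are recorded as
    (anchor position, inserted sequence): the bases appear immediately
    after the anchor.
    """

    id: str
    chrom: str
    start: int
    end: int
    umi: str
    bases: np.ndarray
    insertions: list[tuple[int, str]] = field(default_factory=list)
    deletions: list[GenomicInterval] = field(default_factory=list)
    sample_id: str = ""
    molecule_id: int = -1

    def __post_init__(self):
        if len(self.bases) != self.end - self.start:
            raise ValueError("bases array must cover [start, end)")
        for pos, _ in self.insertions:
            if not self.start <= pos < self.end:
                raise ValueError("insertion anchor outside read span")
        for d in self.deletions:
            if not (self.start <= d.start and d.end <= self.end):
                raise ValueError("deletion outside read span")

    def query_sequence(self) -> str:
        """Read bases as sequenced (deletions removed, insertions inserted)."""
        parts = []
        ins = sorted(self.insertions)
        j = 0
        for off in range(self.end - self.start):
            if self.bases[off] != GAP:
                parts.append(decode(self.bases[off:off + 1]))
            while j < len(ins) and ins[j][0] == self.start + off:
                parts.append(ins[j][1])
                j += 1
        return "".join(parts)


class ReadSet:
    """Struct-of-arrays container for one sample's aligned reads.

    Substitutions are stored relative to the reference as parallel
    arrays (read index, absolute position, alt code); an alt code of N
    marks an undetermined base.  Indel events are stored the same way.
    A UMI row of all 0xFF marks a read whose UMI tag is missing.
    """

    def __init__(self, chrom, start, end, umi_codes, *, sub_read=None, sub_pos=None,
                 sub_alt=None, ins_read=None, ins_pos=None, ins_seq=None,
                 del_read=None, del_start=None, del_end=None,
                 mol_id=None, sample_id: str = ""):
        z = np.zeros(0, dtype=np.int64)
        self.chrom = chrom
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.umi_codes = np.asarray(umi_codes, dtype=np.uint8)
        self.sub_read = z if sub_read is None else np.asarray(sub_read, dtype=np.int64)
        self.sub_pos = z if sub_pos is None else np.asarray(sub_pos, dtype=np.int64)
        self.sub_alt = (np.zeros(0, np.uint8) if sub_alt is None
                        else np.asarray(sub_alt, dtype=np.uint8))
        self.ins_read = z if ins_read is None else np.asarray(ins_read, dtype=np.int64)
        self.ins_pos = z if ins_pos is None else np.asarray(ins_pos, dtype=np.int64)
        self.ins_seq = list(ins_seq) if ins_seq is not None else []
        self.del_read = z if del_read is None else np.asarray(del_read, dtype=np.int64)
        self.del_start = z if del_start is None else np.asarray(del_start, dtype=np.int64)
        self.del_end = z if del_end is None else np.asarray(del_end, dtype=np.int64)
        self.mol_id = (np.full(len(self.start), -1, np.int64) if mol_id is None
                       else np.asarray(mol_id, dtype=np.int64))
        self.sample_id = sample_id
        order = np.lexsort((self.sub_pos, self.sub_read))
        self.sub_read, self.sub_pos, self.sub_alt = (
            self.sub_read[order], self.sub_pos[order], self.sub_alt[order])

    def __len__(self) -> int:
        return len(self.start)

    @property
    def umi_missing(self) -> np.ndarray:
        return (self.umi_codes == 0xFF).all(axis=1)

    def umi_strings(self) -> list[str]:
        out = []
        for row in self.umi_codes:
            out.append("" if (row == 0xFF).all() else decode(row))
        return out

    def get_read(self, i: int, reference: Reference) -> RawRead:
        s, e = int(self.start[i]), int(self.end[i])
        bases = reference[self.chrom][s:e].copy()
        lo, hi = np.searchsorted(self.sub_read, [i, i + 1])
        bases[self.sub_pos[lo:hi] - s] = self.sub_alt[lo:hi]
        dels, ins = [], []
        for j in np.flatnonzero(self.del_read == i):
            ds, de = int(self.del_start[j]), int(self.del_end[j])
            bases[ds - s:de - s] = GAP
            dels.append(GenomicInterval(self.chrom, ds, de))
        for j in np.flatnonzero(self.ins_read == i):
            ins.append((int(self.ins_pos[j]), self.ins_seq[j]))
        row = self.umi_codes[i]
        umi = "" if (row == 0xFF).all() else decode(row)
        return RawRead(id=f"r{i}", chrom=self.chrom, start=s, end=e, umi=umi, bases=bases,
                       insertions=ins, deletions=dels, sample_id=self.sample_id,
                       molecule_id=int(self.mol_id[i]))

    def to_reads(self, reference: Reference) -> list[RawRead]:
        return [self.get_read(i, reference) for i in range(len(self))]

    @classmethod
    def from_reads(cls, reads: list[RawRead], reference: Reference) -> "ReadSet":
        if not reads:
            raise ValueError("empty read list")
        chrom = reads[0].chrom
        if any(r.chrom != chrom for r in reads):
            raise ValueError("a ReadSet holds reads from a single contig")
        ref = reference[chrom]
        start = np.array([r.start for r in reads])
        end = np.array([r.end for r in reads])
        ulen = max((len(r.umi) for r in reads if r.umi), default=6)
        umi_codes = np.full((len(reads), ulen), 0xFF, np.uint8)
        sub_read, sub_pos, sub_alt = [], [], []
        ins_read, ins_pos, ins_seq = [], [], []
        del_read, del_start, del_end = [], [], []
        for i, r in enumerate(reads):
            if r.umi:
                umi_codes[i] = encode(r.umi)
            diff = np.flatnonzero((r.bases != ref[r.start:r.end]) & (r.bases != GAP))
            sub_read.extend([i] * len(diff))
            sub_pos.extend((diff + r.start).tolist())
            sub_alt.extend(r.bases[diff].tolist())
            for pos, seq in r.insertions:
                ins_read.append(i); ins_pos.append(pos); ins_seq.append(seq)
            for d in r.deletions:
                del_read.append(i); del_start.append(d.start); del_end.append(d.end)
        return cls(chrom, start, end, umi_codes, sub_read=sub_read, sub_pos=sub_pos,
                   sub_alt=sub_alt, ins_read=ins_read, ins_pos=ins_pos, ins_seq=ins_seq,
                   del_read=del_read, del_start=del_start, del_end=del_end,
                   mol_id=[r.molecule_id for r in reads],
                   sample_id=reads[0].sample_id)


@dataclass
class SpikeTruth:
    variant: TrackableVariant
    target_vaf: float
    n_carrier_molecules: int
    true_vaf: float          # carrier molecules / total molecules, exactly
    n_expressed: int         # carrier molecules whose fragment covers the locus


@dataclass
class TruthReport:
    """Per-molecule read counts and exact per-spike truth for one simulation."""

    n_molecules: int
    family_sizes: np.ndarray
    spikes: list[SpikeTruth]

    @property
    def total_reads(self) -> int:
        return int(self.family_sizes.sum())

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"chrom": s.variant.chrom, "pos": s.variant.pos + 1, "ref": s.variant.ref,
              "alt": s.variant.alt, "target_vaf": s.target_vaf,
              "n_carrier_molecules": s.n_carrier_molecules, "true_vaf": s.true_vaf,
              "n_expressed": s.n_expressed} for s in self.spikes]
        )


def _draw_family_sizes(dist: tuple, n: int, rng) -> np.ndarray:
    kind = dist[0]
    if kind == "constant":
        size = int(dist[1])
        if size < 1:
            log.warning("degenerate family size %d; using 1", size)
            size = 1
        return np.full(n, size, dtype=np.int64)
    if kind == "ztnb":
        mean, disp = float(dist[1]), float(dist[2])
        if mean <= 0 or disp <= 0:
            log.warning("degenerate ztnb parameters %r; all families size 1", dist)
            return np.ones(n, dtype=np.int64)
        p = disp / (disp + mean)
        k = rng.negative_binomial(disp, p, n).astype(np.int64)
        zero = k == 0
        while zero.any():
            k[zero] = rng.negative_binomial(disp, p, int(zero.sum()))
            zero = k == 0
        return k
    raise ConfigError(f"unknown family size distribution {kind!r}")


def _last_wins_unique(read: np.ndarray, pos: np.ndarray, alt: np.ndarray):
    """Deduplicate (read, pos) pairs, keeping the entry appended last."""
    if len(read) == 0:
        return read, pos, alt
    key = read * (pos.max() + 1 if len(pos) else 1) + pos
    order = np.argsort(key, kind="stable")
    key_sorted = key[order]
    is_last = np.empty(len(key), dtype=bool)
    is_last[:-1] = key_sorted[:-1] != key_sorted[1:]
    is_last[-1] = True
    keep = order[is_last]
    return read[keep], pos[keep], alt[keep]


def amplify_and_sequence(molecules, config: SimConfig, reference: Reference | None = None,
                         rng=None):
    """PCR-duplicate and sequence molecules into a :class:`ReadSet` plus truth.

    Each molecule yields k reads with k ~ ``family_size_dist``.  Polymerase
    errors are drawn at ``pcr_error_rate`` per base on each of two
    first-cycle lineage branches (shared by all reads descending from the
    branch) and again independently per read; sequencing substitutions are
    drawn per read at ``seq_error_rate``.  With ``oxidation_bias`` > 0 the
    corresponding fraction of PCR errors is forced to C>A / G>T changes.
    """
    if len(molecules) == 0:
        raise ConfigError("no molecules to amplify")
    if isinstance(molecules, MoleculeSet):
        reference = molecules.reference if reference is None else reference
        mstart, mend = molecules.start, molecules.end
        mumi, mcarrier = molecules.umi_codes, molecules.carrier
        chrom = molecules.chrom
    else:
        if reference is None:
            raise ConfigError("reference required when molecules are plain objects")
        chrom = molecules[0].interval.chrom
        mstart = np.array([m.interval.start for m in molecules])
        mend = np.array([m.interval.end for m in molecules])
        mumi = np.stack([encode(m.umi) for m in molecules])
        mcarrier = np.full(len(molecules), -1, dtype=np.int64)
        spike_keys = {v.key(): j for j, (v, _) in enumerate(config.spikes)}
        for i, m in enumerate(molecules):
            if m.carries_variant is not None:
                mcarrier[i] = spike_keys[m.carries_variant.key()]
    rng = np.random.default_rng([config.seed, 1]) if rng is None else rng
    ref = reference[chrom]
    n_mol = len(mstart)

    fam = _draw_family_sizes(config.family_size_dist, n_mol, rng)
    read_mol = np.repeat(np.arange(n_mol), fam)
    n_reads = len(read_mol)
    rstart, rend = mstart[read_mol], mend[read_mol]
    rlen = rend - rstart
    offsets = np.zeros(n_reads + 1, dtype=np.int64)
    np.cumsum(rlen, out=offsets[1:])
    total_bases = int(offsets[-1])

    # per-read spike expression (spike index or -1)
    expressed_mol = np.full(n_mol, -1, dtype=np.int64)
    spike_pos = np.array([v.pos for v, _ in config.spikes], dtype=np.int64)
    spike_alt = np.array(
        [encode(v.alt)[0] if v.var_type == SNV else 255 for v, _ in config.spikes],
        dtype=np.uint8)
    for j, (v, _) in enumerate(config.spikes):
        m = (mcarrier == j) & (mstart <= v.pos) & (mend >= v.pos + len(v.ref))
        expressed_mol[m] = j
    expressed_read = expressed_mol[read_mol]

    # molecule-level variant alleles carried by every read of the molecule
    sub_r, sub_p, sub_a = [], [], []
    ins_r, ins_p, ins_s = [], [], []
    del_r, del_s, del_e = [], [], []
    for j, (v, _) in enumerate(config.spikes):
        reads_j = np.flatnonzero(expressed_read == j)
        if v.var_type == SNV:
            sub_r.append(reads_j)
            sub_p.append(np.full(len(reads_j), v.pos))
            sub_a.append(np.full(len(reads_j), spike_alt[j], dtype=np.uint8))
        elif v.var_type == INSERTION:
            ins_r.extend(reads_j.tolist())
            ins_p.extend([v.pos] * len(reads_j))
            ins_s.extend([v.inserted_sequence] * len(reads_j))
        elif v.var_type == DELETION:
            d = v.deleted_interval
            del_r.extend(reads_j.tolist())
            del_s.extend([d.start] * len(reads_j))
            del_e.extend([d.end] * len(reads_j))

    def current_base(read_idx, pos):
        cur = ref[pos].astype(np.uint8)
        sp = expressed_read[read_idx]
        for j in range(len(config.spikes)):
            if spike_alt[j] != 255:
                cur = np.where((sp == j) & (pos == spike_pos[j]), spike_alt[j], cur)
        return cur

    def draw_uniform_errors(rate, lengths, starts):
        """Uniform error positions over the concatenated spans described by lengths."""
        offs = np.zeros(len(lengths) + 1, dtype=np.int64)
        np.cumsum(lengths, out=offs[1:])
        total = int(offs[-1])
        n_err = rng.binomial(total, rate) if total else 0
        if n_err == 0:
            return np.zeros(0, np.int64), np.zeros(0, np.int64)
        flat = rng.integers(0, total, n_err)
        unit = np.searchsorted(offs, flat, side="right") - 1
        pos = starts[unit] + (flat - offs[unit])
        return unit, pos

    # --- PCR errors: lineage-shared (two first-cycle branches) + per-read
    branch = rng.integers(0, 2, n_reads)
    lin_key = read_mol * 2 + branch
    ulin, lin_inv, lin_counts = np.unique(lin_key, return_inverse=True, return_counts=True)
    lin_mol = ulin // 2
    lin_idx, lin_err_pos = draw_uniform_errors(
        config.pcr_error_rate, (mend - mstart)[lin_mol], mstart[lin_mol])
    # broadcast lineage errors to every member read
    order = np.argsort(lin_inv, kind="stable")
    lin_starts = np.zeros(len(ulin) + 1, dtype=np.int64)
    np.cumsum(lin_counts, out=lin_starts[1:])
    rep = lin_counts[lin_idx]
    if rep.sum():
        seg = np.zeros(len(rep) + 1, dtype=np.int64)
        np.cumsum(rep, out=seg[1:])
        within = np.arange(int(rep.sum())) - np.repeat(seg[:-1], rep)
        pcr_read = order[np.repeat(lin_starts[lin_idx], rep) + within]
        pcr_pos = np.repeat(lin_err_pos, rep)
    else:
        pcr_read = np.zeros(0, np.int64)
        pcr_pos = np.zeros(0, np.int64)
    r2, p2 = draw_uniform_errors(config.pcr_error_rate, rlen, rstart)
    pcr_read = np.concatenate([pcr_read, r2])
    pcr_pos = np.concatenate([pcr_pos, p2])

    # oxidation artifacts: a fraction of PCR errors become C>A / G>T
    pcr_alt = np.zeros(len(pcr_read), dtype=np.uint8)
    if len(pcr_read):
        ox = rng.random(len(pcr_read)) < config.oxidation_bias
        cg = np.flatnonzero((ref == C) | (ref == G))
        if ox.any() and len(cg):
            lo = np.searchsorted(cg, rstart[pcr_read[ox]])
            hi = np.searchsorted(cg, rend[pcr_read[ox]])
            cnt = hi - lo
            pickable = cnt > 0
            pick = lo[pickable] + (rng.random(int(pickable.sum())) * cnt[pickable]).astype(np.int64)
            ox_idx = np.flatnonzero(ox)[pickable]
            pcr_pos[ox_idx] = cg[pick]
            pcr_alt[ox_idx] = np.where(ref[cg[pick]] == C, A, T)
            ox_done = np.zeros(len(pcr_read), dtype=bool)
            ox_done[ox_idx] = True
        else:
            ox_done = np.zeros(len(pcr_read), dtype=bool)
        plain = ~ox_done
        cur = current_base(pcr_read[plain], pcr_pos[plain])
        pcr_alt[plain] = (cur + rng.integers(1, 4, int(plain.sum()))) % 4

    # --- sequencing errors, independent per read
    seq_read, seq_pos = draw_uniform_errors(config.seq_error_rate, rlen, rstart)
    cur = current_base(seq_read, seq_pos)
    seq_alt = ((cur + rng.integers(1, 4, len(seq_read))) % 4).astype(np.uint8)

    sub_read = np.concatenate([c.astype(np.int64) for c in sub_r] + [pcr_read, seq_read]) \
        if (sub_r or len(pcr_read) or len(seq_read)) else np.zeros(0, np.int64)
    sub_pos = np.concatenate([c.astype(np.int64) for c in sub_p] + [pcr_pos, seq_pos]) \
        if len(sub_read) else np.zeros(0, np.int64)
    sub_alt = np.concatenate([c for c in sub_a] + [pcr_alt, seq_alt]) \
        if len(sub_read) else np.zeros(0, np.uint8)

    sub_read, sub_pos, sub_alt = _last_wins_unique(sub_read, sub_pos, sub_alt)
    keep = sub_alt != ref[sub_pos]          # an error may revert a base to reference
    sub_read, sub_pos, sub_alt = sub_read[keep], sub_pos[keep], sub_alt[keep]

    # errors cannot land on positions a read has deleted
    if del_r:
        del_of_read = np.full(n_reads, -1, dtype=np.int64)
        del_of_read[np.array(del_r)] = np.arange(len(del_r))
        di = del_of_read[sub_read]
        has = di >= 0
        ds = np.array(del_s, dtype=np.int64)
        de = np.array(del_e, dtype=np.int64)
        bad = np.zeros(len(sub_read), dtype=bool)
        bad[has] = (sub_pos[has] >= ds[di[has]]) & (sub_pos[has] < de[di[has]])
        sub_read, sub_pos, sub_alt = sub_read[~bad], sub_pos[~bad], sub_alt[~bad]

    reads = ReadSet(chrom, rstart, rend, mumi[read_mol],
                    sub_read=sub_read, sub_pos=sub_pos, sub_alt=sub_alt,
                    ins_read=ins_r, ins_pos=ins_p, ins_seq=ins_s,
                    del_read=del_r, del_start=del_s, del_end=del_e,
                    mol_id=read_mol, sample_id=config.sample_id)

    spikes = []
    for j, (v, vaf) in enumerate(config.spikes):
        n_car = int(np.count_nonzero(mcarrier == j))
        spikes.append(SpikeTruth(variant=v, target_vaf=vaf, n_carrier_molecules=n_car,
                                 true_vaf=n_car / n_mol,
                                 n_expressed=int(np.count_nonzero(expressed_mol == j))))
    truth = TruthReport(n_molecules=n_mol, family_sizes=fam, spikes=spikes)
    return reads, truth


def simulate_sample(config: SimConfig, reference: Reference):
    """Convenience wrapper: molecules + amplification/sequencing in one call."""
    molecules = simulate_molecules(config, reference)
    reads, truth = amplify_and_sequence(molecules, config)
    return molecules, reads, truth
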