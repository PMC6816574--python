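"""Panel, variant, and sample-metadata I/O.

Data model for the assay's static inputs: the hybrid-capture panel
definition (gene/transcript/exon table), per-patient trackable pathogenic
variants, and the clinical sample table (patient, specimen source,
days-before-relapse, per-assay MRD status).

All coordinates are internally 0-based half-open; VCF input/output
converts at the boundary.  Indels are left-normalized against the
reference in the VCF-style anchored representation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import pysam

from .sequence import Reference

log = logging.getLogger(__name__)

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

SOURCES = ("BM", "PB")
GROUPS = ("RG", "NRG")
STATUSES = ("Negative", "Positive", "NotPerformed")


class ParseError(ValueError):
    """Malformed input table or record."""


class ValidationError(ValueError):
    """Record inconsistent with the reference or the data model."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval contig name must be non-empty")
        if not self.start < self.end:
            raise ValidationError(f"interval requires start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class PanelTarget:
    """One capture target: a gene with its transcript, exons, and intervals."""

    gene: str
    transcript: str
    exons: set[int]
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"panel target {self.gene} has no exons")
        ivs = sorted(self.intervals)
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValidationError(f"panel target {self.gene} has overlapping intervals")
        self.intervals = ivs


@dataclass(frozen=True)
class TrackableVariant:
    """A patient-specific pathogenic variant tracked across follow-up samples.

    ``pos`` is the 0-based reference position of the first changed base
    (SNV) or of the shared anchor base (indels, VCF-style).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_type: str = ""
    gene: str = ""
    label: str = ""

    def __post_init__(self):
        inferred = infer_var_type(self.ref, self.alt)
        if not self.var_type:
            object.__setattr__(self, "var_type", inferred)
        elif self.var_type != inferred:
            raise ValidationError(
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}: declared {self.var_type}, "
                f"alleles imply {inferred}"
            )

    @property
    def is_indel(self) -> bool:
        return self.var_type in (INSERTION, DELETION)

    @property
    def inserted_sequence(self) -> str:
        if self.var_type != INSERTION:
            raise ValueError("not an insertion")
        return self.alt[len(self.ref):]

    @property
    def deleted_interval(self) -> GenomicInterval:
        if self.var_type != DELETION:
            raise ValueError("not a deletion")
        return GenomicInterval(self.chrom, self.pos + len(self.alt), self.pos + len(self.ref))

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def infer_var_type(ref: str, alt: str) -> str:
    if not ref or not alt:
        raise ValidationError("empty allele; anchored representation required")
    if len(ref) == len(alt) == 1:
        return SNV
    if len(alt) > len(ref):
        if not alt.startswith(ref):
            raise ValidationError(f"insertion alleles must share the anchor: {ref}>{alt}")
        return INSERTION
    if len(ref) > len(alt):
        if not ref.startswith(alt):
            raise ValidationError(f"deletion alleles must share the anchor: {ref}>{alt}")
        return DELETION
    raise ValidationError(f"multi-nucleotide substitutions are not supported: {ref}>{alt}")


def left_normalize(chrom: str, pos: int, ref: str, alt: str, reference: Reference):
    """Left-align an anchored indel against the reference (VCF convention)."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == len(alt) == 1:
        return pos, ref, alt
    while True:
        # trim identical trailing bases, re-anchoring from the reference
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        if ref[-1] == alt[-1] and pos > 0:
            anchor = reference.base(chrom, pos - 1)
            ref, alt = anchor + ref[:-1], anchor + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class SampleRecord:
    """One clinical specimen and its MRD status under each assay."""

    patient_id: str
    source: str
    days_before_relapse: int | None
    group: str
    str_status: str = "NotPerformed"
    ngs_status: str = "NotPerformed"
    mfc_status: str = "NotPerformed"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ParseError(f"unknown specimen source {self.source!r} for {self.patient_id}")
        if self.group not in GROUPS:
            raise ParseError(f"unknown group {self.group!r} for {self.patient_id}")
        for name in ("str_status", "ngs_status", "mfc_status"):
            if getattr(self, name) not in STATUSES:
                raise ParseError(
                    f"unknown status token {getattr(self, name)!r} for {self.patient_id}"
                )
        if self.group == "RG" and (self.days_before_relapse is None or self.days_before_relapse < 0):
            raise ValidationError(
                f"RG sample {self.patient_id} requires days_before_relapse >= 0"
            )


# ---------------------------------------------------------------------------
# panel table

_RANGE_RE = re.compile(r"^(\d+)\s*(?:[–-]\s*(\d+))?$")


def parse_exon_spec(spec: str) -> set[int]:
    """Expand an exon spec like ``13–15,20`` to {13, 14, 15, 20}."""
    exons: set[int] = set()
    for token in str(spec).split(","):
        token = token.strip()
        if not token:
            continue  # tolerate trailing commas as printed in panel tables
        m = _RANGE_RE.match(token)
        if not m:
            raise ParseError(f"malformed exon range {token!r} in spec {spec!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise ParseError(f"descending exon range {token!r} in spec {spec!r}")
        exons.update(range(lo, hi + 1))
    if not exons:
        raise ParseError(f"empty exon spec {spec!r}")
    return exons


def load_panel(path) -> list[PanelTarget]:
    """Load a panel definition table (TSV: gene, transcript, exons[, chrom, start, end])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"gene", "transcript", "exons"}
    if not required.issubset(df.columns):
        raise ParseError(f"panel table must have columns {sorted(required)}, got {list(df.columns)}")
    targets: dict[tuple[str, str], PanelTarget] = {}
    for idx, row in df.iterrows():
        gene = str(row["gene"]).strip().strip("*")
        try:
            exons = parse_exon_spec(row["exons"])
        except ParseError as exc:
            raise ParseError(f"row {idx + 1} ({gene}): {exc}") from None
        key = (gene, str(row["transcript"]).strip())
        interval = None
        if "chrom" in df.columns and pd.notna(row.get("chrom")):
            interval = GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]))
        if key in targets:
            targets[key].exons |= exons
            if interval is not None:
                targets[key].intervals.append(interval)
        else:
            targets[key] = PanelTarget(
                gene=gene,
                transcript=key[1],
                exons=exons,
                intervals=[interval] if interval else [],
            )
    out = list(targets.values())
    for t in out:
        t.__post_init__()  # re-check interval overlap after merging rows
    return out


def panel_intervals(panel: list[PanelTarget]) -> list[GenomicInterval]:
    return sorted(iv for t in panel for iv in t.intervals)


# ---------------------------------------------------------------------------
# trackable variants

def _validate_against_reference(v: TrackableVariant, reference: Reference) -> None:
    if v.chrom not in reference:
        raise ValidationError(f"{v.chrom} not in reference")
    observed = reference.slice(v.chrom, v.pos, v.pos + len(v.ref))
    if observed != v.ref.upper():
        raise ValidationError(
            f"REF mismatch at {v.chrom}:{v.pos}: record says {v.ref!r}, reference holds {observed!r}"
        )


def _make_variant(chrom, pos0, ref, alt, gene="", label="", reference=None) -> TrackableVariant:
    ref, alt = str(ref).upper(), str(alt).upper()
    if reference is not None:
        pos0, ref, alt = left_normalize(chrom, pos0, ref, alt, reference)
    v = TrackableVariant(chrom=chrom, pos=int(pos0), ref=ref, alt=alt, gene=gene, label=label)
    if reference is not None:
        _validate_against_reference(v, reference)
    return v


def load_variants(path, reference: Reference | None = None) -> list[TrackableVariant]:
    """Load trackable variants from a VCF (1-based POS) or TSV (1-based pos) file.

    With a reference, indels are left-normalized and REF alleles validated.
    """
    path = Path(path)
    variants: list[TrackableVariant] = []
    if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                gene = ""
                if "GENE" in rec.info:
                    gi = rec.info["GENE"]
                    gene = gi[0] if isinstance(gi, tuple) else str(gi)
                for alt in rec.alts or ():
                    variants.append(
                        _make_variant(rec.chrom, rec.pos - 1, rec.ref, alt,
                                      gene=gene, label=rec.id or "", reference=reference)
                    )
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        for _, row in df.iterrows():
            variants.append(
                _make_variant(str(row["chrom"]), int(row["pos"]) - 1, row["ref"], row["alt"],
                              gene=str(row.get("gene", "") or ""),
                              label=str(row.get("label", "") or ""), reference=reference)
            )
    return variants


def write_variants(variants: list[TrackableVariant], path) -> None:
    """Write variants as VCF (``.vcf``) or the TSV dialect (1-based positions)."""
    path = Path(path)
    if path.suffix == ".vcf":
        header = pysam.VariantHeader()
        header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
        for chrom in dict.fromkeys(v.chrom for v in variants):
            header.contigs.add(chrom)
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for v in variants:
                rec = vf.new_record(contig=v.chrom, start=v.pos, stop=v.pos + len(v.ref),
                                    alleles=(v.ref, v.alt), id=v.label or None)
                if v.gene:
                    rec.info["GENE"] = v.gene
                vf.write(rec)
    else:
        rows = [
            {"chrom": v.chrom, "pos": v.pos + 1, "ref": v.ref, "alt": v.alt,
             "gene": v.gene, "label": v.label}
            for v in variants
        ]
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", "label"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# sample table

_STATUS_ALIASES = {
    "negative": "Negative",
    "positive": "Positive",
    "notperformed": "NotPerformed",
    "assay not performed": "NotPerformed",
    "negative/indeterminate": "Negative",
}


def _status(token) -> str:
    if pd.isna(token) or str(token).strip() == "":
        return "NotPerformed"
    norm = _STATUS_ALIASES.get(str(token).strip().lower())
    if norm is None:
        raise ParseError(f"unknown status token {token!r}")
    return norm


def load_sample_table(path) -> list[SampleRecord]:
    """Load a clinical sample table (TSV mirroring the cohort-table columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        log.warning("sample table %s is empty", path)
        return []
    df.columns = [c.strip().lower() for c in df.columns]
    records = []
    for idx, row in df.iterrows():
        days = row.get("days_before_relapse")
        days = None if pd.isna(days) or str(days).strip() == "" else int(days)
        group = str(row.get("group") or ("RG" if str(row["patient_id"]).startswith("RG") else "NRG"))
        try:
            records.append(
                SampleRecord(
                    patient_id=str(row["patient_id"]).strip(),
                    source=str(row["source"]).strip(),
                    days_before_relapse=days,
                    group=group.strip(),
                    str_status=_status(row.get("str_status")),
                    ngs_status=_status(row.get("ngs_status")),
                    mfc_status=_status(row.get("mfc_status")),
                )
            )
        except (ParseError, ValidationError) as exc:
            raise ParseError(f"sample table row {idx + 1}: {exc}") from None
    return records


def write_sample_table(records: list[SampleRecord], path) -> None:
    rows = [
        {"patient_id": r.patient_id, "source": r.source,
         "days_before_relapse": "" if r.days_before_relapse is None else r.days_before_relapse,
         "group": r.group, "str_status": r.str_status,
         "ngs_status": r.ngs_status, "mfc_status": r.mfc_status}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged fixtures

def _fixture_path(name: str):
    return resources.files("mrdseq.data").joinpath(name)


def load_panel_fixture() -> list[PanelTarget]:
    """The packaged 22-gene myeloid MRD panel definition."""
    with resources.as_file(_fixture_path("panel_22gene.tsv")) as p:
        return load_panel(p)


def load_cohort_fixture() -> list[SampleRecord]:
    """The packaged relapse-cohort sample table (30 RG patients)."""
    with resources.as_file(_fixture_path("cohort_rg_samples.tsv")) as p:
        return load_sample_table(p)


def load_nrg_fixture() -> list[SampleRecord]:
    """The packaged non-recurrence control samples (synthetic per-sample reconstruction)."""
    with resources.as_file(_fixture_path("nrg_samples_synthetic.tsv")) as p:
        return load_sample_table(p)


def load_trackable_fixture() -> list[TrackableVariant]:
    """The packaged 59-variant trackable-mutation list (mostly synthetic stand-ins)."""
    with resources.as_file(_fixture_path("trackable_variants_synthetic.tsv")) as p:
        return load_variants(p)
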