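"""Control-cohort noise profiling, blacklisting, and per-sample MRD calls.

Every trackable variant's false-positive noise is measured across
control samples; variants showing artifactual noise at or above the
0.1% VAF working limit (typically C>A/G>T oxidation artifacts) are
excluded from tracking.  A sample is MRD-positive if any retained
patient variant is observed at or above the detection threshold:
0.1% VAF for point mutations, 0.001% VAF for indels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import mean, stdev

import numpy as np
import pandas as pd

from .panel_io import SNV, SampleRecord, TrackableVariant
from .pileup import VariantObservation

log = logging.getLogger(__name__)

POSITIVE = "Positive"
NEGATIVE = "Negative"
UNTRACKABLE = "Untrackable"


@dataclass
class Thresholds:
    """Detection and blacklist cutoffs, as VAF fractions.

    The indel threshold (0.001%) sits below a single consensus read at
    routine collapsed depths, so ``min_alt_reads`` (default 1) is the
    effective indel rule.
    """

    snv_vaf: float = 0.001
    indel_vaf: float = 0.00001
    blacklist_noise_vaf: float = 0.001
    min_alt_reads: int = 1

    def __post_init__(self):
        for name in ("snv_vaf", "indel_vaf", "blacklist_noise_vaf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.indel_vaf > self.snv_vaf:
            raise ValueError("indel_vaf must not exceed snv_vaf")

    def triggers(self, obs: VariantObservation) -> bool:
        if obs.no_coverage or obs.alt_count < self.min_alt_reads:
            return False
        cutoff = self.snv_vaf if obs.variant.var_type == SNV else self.indel_vaf
        return obs.vaf >= cutoff


@dataclass
class NoiseProfile:
    """A variant's background VAF distribution across control samples."""

    variant: TrackableVariant
    control_vafs: list[tuple[str, float]]
    n_no_coverage: int = 0

    @property
    def evaluable(self) -> bool:
        return len(self.control_vafs) > 0

    @property
    def mean_vaf(self) -> float:
        return mean(v for _, v in self.control_vafs) if self.evaluable else float("nan")

    @property
    def sd_vaf(self) -> float:
        if len(self.control_vafs) < 2:
            return 0.0 if self.evaluable else float("nan")
        return stdev(v for _, v in self.control_vafs)


def build_noise_profiles(control_observations, variants: list[TrackableVariant]
                         ) -> list[NoiseProfile]:
    """One noise profile per variant over the control sample set.

    ``control_observations`` maps sample id to that sample's list of
    :class:`VariantObservation`.  Samples without coverage of a variant
    are excluded from its mean/SD and counted in ``n_no_coverage``.
    """
    if not control_observations:
        raise ValueError("at least one control sample is required")
    by_variant: dict[tuple, NoiseProfile] = {
        v.key(): NoiseProfile(variant=v, control_vafs=[]) for v in variants
    }
    for sample_id, observations in control_observations.items():
        for obs in observations:
            prof = by_variant.get(obs.variant.key())
            if prof is None:
                continue
            if obs.no_coverage:
                prof.n_no_coverage += 1
            else:
                prof.control_vafs.append((sample_id, obs.vaf))
    profiles = list(by_variant.values())
    for p in profiles:
        if not p.evaluable:
            log.warning("variant %s has no covered control sample; profile unevaluable",
                        p.variant.label or p.variant.key())
    return profiles


def blacklist(profiles: list[NoiseProfile], thresholds: Thresholds,
              rule: str = "mean_or_recurrent"):
    """Split variants into (excluded, retained) by control noise.

    Rules: ``mean`` excludes on mean control VAF >= cutoff; ``recurrent``
    on >= 2 control samples individually at/above the cutoff;
    ``mean_or_recurrent`` (default) on either.
    """
    if rule not in ("mean", "recurrent", "mean_or_recurrent"):
        raise ValueError(f"unknown blacklist rule {rule!r}")
    cutoff = thresholds.blacklist_noise_vaf
    excluded, retained = [], []
    for p in profiles:
        if not p.evaluable:
            retained.append(p.variant)
            continue
        by_mean = p.mean_vaf >= cutoff
        n_hot = sum(1 for _, v in p.control_vafs if v >= cutoff)
        by_recurrent = n_hot >= 2 or (len(p.control_vafs) == 1 and n_hot == 1)
        hit = {"mean": by_mean, "recurrent": by_recurrent,
               "mean_or_recurrent": by_mean or by_recurrent}[rule]
        (excluded if hit else retained).append(p.variant)
    return excluded, retained


def blacklist_report(profiles: list[NoiseProfile], excluded) -> pd.DataFrame:
    keys = {v.key() for v in excluded}
    rows = []
    for p in profiles:
        v = p.variant
        rows.append({
            "chrom": v.chrom, "pos": v.pos + 1, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "label": v.label,
            "n_controls": len(p.control_vafs), "n_no_coverage": p.n_no_coverage,
            "mean_vaf": p.mean_vaf, "sd_vaf": p.sd_vaf,
            "control_vafs": ";".join(f"{s}:{x:.6g}" for s, x in p.control_vafs),
            "excluded": v.key() in keys,
        })
    return pd.DataFrame(rows)


@dataclass
class MRDResult:
    """Per-sample MRD call with the observations that triggered it."""

    sample: SampleRecord | str
    observations: list[VariantObservation]
    status: str
    triggering_variants: list[VariantObservation] = field(default_factory=list)

    def __post_init__(self):
        if (self.status == POSITIVE) != bool(self.triggering_variants):
            raise ValueError("status Positive iff triggering_variants non-empty")


def call_mrd(sample_observations: list[VariantObservation],
             patient_variants: list[TrackableVariant],
             thresholds: Thresholds | None = None,
             blacklisted: list[TrackableVariant] | None = None,
             sample: SampleRecord | str = "") -> MRDResult:
    """Call one sample MRD-positive if any retained patient variant triggers.

    A patient whose variants are all blacklisted, or none of whose
    retained variants has coverage, yields ``Untrackable`` — never a
    false Negative.
    """
    thresholds = thresholds or Thresholds()
    black = {v.key() for v in (blacklisted or [])}
    retained = [v for v in patient_variants if v.key() not in black]
    if not retained:
        log.warning("all trackable variants blacklisted or absent for sample %r", sample)
        return MRDResult(sample=sample, observations=list(sample_observations),
                         status=UNTRACKABLE)
    retained_keys = {v.key() for v in retained}
    usable = [o for o in sample_observations if o.variant.key() in retained_keys]
    if not usable or all(o.no_coverage for o in usable):
        return MRDResult(sample=sample, observations=list(sample_observations),
                         status=UNTRACKABLE)
    triggering = [o for o in usable if thresholds.triggers(o)]
    status = POSITIVE if triggering else NEGATIVE
    return MRDResult(sample=sample, observations=list(sample_observations),
                     status=status, triggering_variants=triggering)


def results_to_frame(results: list[MRDResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        sid = r.sample.patient_id if isinstance(r.sample, SampleRecord) else str(r.sample)
        rows.append({
            "sample": sid, "status": r.status,
            "n_observations": len(r.observations),
            "triggering": ";".join(
                f"{o.variant.gene or o.variant.chrom}:{o.variant.pos + 1}"
                f"{o.variant.ref}>{o.variant.alt}@{o.vaf:.3%}"
                for o in r.triggering_variants),
        })
    return pd.DataFrame(rows, columns=["sample", "status", "n_observations", "triggering"])
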