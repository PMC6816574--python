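"""Cohort-level MRD summary statistics.

Reproduces the retrospective analysis of pre-relapse detection: samples
from relapsing (RG) patients are binned by days before relapse
(21–40, 41–60, 61–80, 81–100), detection rates are computed per bin,
per patient, and per specimen source (bone marrow vs peripheral blood),
and the association between MRD positivity and relapse is tested with
Fisher's exact test on the patient-level 2x2 table.  Group differences
in VAF use the Mann–Whitney U test with the tie-corrected normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import SampleRecord

DEFAULT_BINS: tuple[tuple[int, int], ...] = ((21, 40), (41, 60), (61, 80), (81, 100))
DEFAULT_WINDOW: tuple[int, int] = (20, 100)


@dataclass
class ContingencyTable2x2:
    """Counts with rows = relapse yes/no and columns = MRD positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class BinSummary:
    """Detection summary for one days-before-relapse bin (closed interval)."""

    bin_label: str
    lo: int
    hi: int
    n_samples: int = 0
    n_positive: int = 0

    @property
    def rate(self) -> float:
        """Detection rate in percent (NaN for an empty bin)."""
        return 100.0 * self.n_positive / self.n_samples if self.n_samples else float("nan")


def _rg_with_days(samples):
    return [s for s in samples
            if s.group == "RG" and s.days_before_relapse is not None
            and s.ngs_status != "NotPerformed"]


def bin_samples(samples: list[SampleRecord], bins=DEFAULT_BINS):
    """Assign RG samples to closed days-before-relapse bins.

    Returns (list of BinSummary, list of samples falling outside every bin).
    """
    summaries = [BinSummary(bin_label=f"{lo}–{hi}", lo=lo, hi=hi) for lo, hi in bins]
    unbinned: list[SampleRecord] = []
    for s in _rg_with_days(samples):
        days = s.days_before_relapse
        hit = next((b for b in summaries if b.lo <= days <= b.hi), None)
        if hit is None:
            unbinned.append(s)
            continue
        hit.n_samples += 1
        if s.ngs_status == "Positive":
            hit.n_positive += 1
    return summaries, unbinned


def patient_positivity(samples: list[SampleRecord], window=DEFAULT_WINDOW) -> dict[str, bool]:
    """Per-patient MRD status: positive iff any in-window sample is NGS-positive."""
    lo, hi = window
    status: dict[str, bool] = {}
    for s in _rg_with_days(samples):
        if not lo <= s.days_before_relapse <= hi:
            continue
        status[s.patient_id] = status.get(s.patient_id, False) or s.ngs_status == "Positive"
    return status


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p: the sum of hypergeometric probabilities of
    all margin-preserving tables no more probable than the observed one."""
    if isinstance(table, ContingencyTable2x2):
        table = table.as_array()
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def mann_whitney_u(group_a, group_b):
    """Mann–Whitney U with midranks; returns (U, z, two-sided p).

    U is the smaller of the two one-sided statistics; z uses the normal
    approximation with tie-corrected variance and no continuity
    correction.  Identical groups give z = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)                     # midranks for ties
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    u = min(u_a, u_b)
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 0.0, 1.0
    z = (u_a - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u), float(z), float(min(p, 1.0))


@dataclass
class CohortReport:
    """Assembled cohort summary (in-window counts, bins, source rates, Fisher p)."""

    window: tuple[int, int]
    bins: list[BinSummary]
    unbinned: list[SampleRecord]
    n_in_window: int
    n_bm: int
    n_bm_positive: int
    n_pb: int
    n_pb_positive: int
    n_patients: int
    n_patients_positive: int
    n_over_window_bm: int
    n_over_window_pb: int
    matched_pairs: list[tuple[str, int]]          # (patient, day) with both BM and PB
    n_matched_pair_patients: int
    fisher_table: ContingencyTable2x2 | None = None
    fisher_p: float | None = None
    nrg_n_patients: int = 0
    nrg_n_positive: int = 0

    @property
    def patient_rate(self) -> float:
        return 100.0 * self.n_patients_positive / self.n_patients if self.n_patients else float("nan")

    @property
    def bm_rate(self) -> float:
        return 100.0 * self.n_bm_positive / self.n_bm if self.n_bm else float("nan")

    @property
    def pb_rate(self) -> float:
        return 100.0 * self.n_pb_positive / self.n_pb if self.n_pb else float("nan")

    def render(self) -> str:
        lines = [
            f"In-window samples ({self.window[0]}-{self.window[1]} days): "
            f"{self.n_in_window} (BM {self.n_bm}, PB {self.n_pb})",
            f"Patient-level detection: {self.n_patients_positive}/{self.n_patients} "
            f"({self.patient_rate:.1f}%)",
            f"BM detection: {self.n_bm_positive}/{self.n_bm} ({self.bm_rate:.1f}%)",
            f"PB detection: {self.n_pb_positive}/{self.n_pb} ({self.pb_rate:.1f}%)",
        ]
        for b in self.bins:
            rate = f"{b.rate:.1f}%" if b.n_samples else "n/a"
            lines.append(f"Bin {b.bin_label} days: {b.n_positive}/{b.n_samples} ({rate})")
        lines.append(f"Samples beyond {self.window[1]} days: BM {self.n_over_window_bm}, "
                     f"PB {self.n_over_window_pb}")
        lines.append(f"Date-matched BM/PB pairs: {len(self.matched_pairs)} "
                     f"({self.n_matched_pair_patients} patients)")
        if self.fisher_p is not None:
            t = self.fisher_table
            lines.append(
                f"Fisher exact (patients, relapse x MRD): "
                f"[[{t.a},{t.b}],[{t.c},{t.d}]] p = {self.fisher_p:.4f}")
        return "\n".join(lines)


def cohort_report(samples: list[SampleRecord],
                  nrg_samples: list[SampleRecord] | None = None,
                  window=DEFAULT_WINDOW, bins=DEFAULT_BINS) -> CohortReport:
    """Assemble the full cohort summary from per-sample MRD statuses.

    ``samples`` are the relapse-group records; ``nrg_samples``, when
    given, provide the control row of the patient-level Fisher table.
    """
    lo, hi = window
    rg = _rg_with_days(samples)
    in_window = [s for s in rg if lo <= s.days_before_relapse <= hi]
    over = [s for s in rg if s.days_before_relapse > hi]
    bm = [s for s in in_window if s.source == "BM"]
    pb = [s for s in in_window if s.source == "PB"]
    patient_status = patient_positivity(samples, window)
    bin_summaries, unbinned = bin_samples(in_window, bins)

    seen: dict[tuple[str, int], set[str]] = {}
    for s in in_window:
        seen.setdefault((s.patient_id, s.days_before_relapse), set()).add(s.source)
    pairs = sorted(k for k, v in seen.items() if {"BM", "PB"} <= v)

    report = CohortReport(
        window=window, bins=bin_summaries, unbinned=unbinned,
        n_in_window=len(in_window),
        n_bm=len(bm), n_bm_positive=sum(s.ngs_status == "Positive" for s in bm),
        n_pb=len(pb), n_pb_positive=sum(s.ngs_status == "Positive" for s in pb),
        n_patients=len(patient_status),
        n_patients_positive=sum(patient_status.values()),
        n_over_window_bm=sum(s.source == "BM" for s in over),
        n_over_window_pb=sum(s.source == "PB" for s in over),
        matched_pairs=pairs,
        n_matched_pair_patients=len({p for p, _ in pairs}),
    )
    if nrg_samples:
        nrg_status: dict[str, bool] = {}
        for s in nrg_samples:
            if s.group != "NRG" or s.ngs_status == "NotPerformed":
                continue
            nrg_status[s.patient_id] = nrg_status.get(s.patient_id, False) or \
                s.ngs_status == "Positive"
        report.nrg_n_patients = len(nrg_status)
        report.nrg_n_positive = sum(nrg_status.values())
        if patient_status and nrg_status:
            table = ContingencyTable2x2(
                a=report.n_patients_positive,
                b=report.n_patients - report.n_patients_positive,
                c=report.nrg_n_positive,
                d=report.nrg_n_patients - report.nrg_n_positive)
            report.fisher_table = table
            report.fisher_p = fisher_exact_2x2(table)
    return report
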