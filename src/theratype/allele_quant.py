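"""Allele-specific transcript quantification by the comparative-CT method.

Allele-discriminating qPCR primer sets measure the two transcripts of a
compound-heterozygous *CFTR* patient separately.  CT values are normalised
to a reference gene (ΔCT), then to the mean ΔCT of calibrator samples
(ΔΔCT), and converted to fold change FC = 2^(−ΔΔCT).  Each allele's share
of total transcript is its fold change as a percentage of the summed fold
changes.

When one allele carries a splicing defect whose aberrant isoform is
degraded (e.g. by nonsense-mediated decay), the shortfall of that allele
relative to the intact one estimates the degraded fraction, assuming both
alleles are transcribed 50:50:

    % degradation = (Y − X) / Y × 100

with X the percent of transcript from the splicing-defective allele and Y
the percent from the intact allele.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "AlleleQuantResult",
    "delta_ct",
    "fold_change_ddct",
    "allele_percentages",
    "percent_degradation",
    "quantify_sample",
    "quantify_table",
]

REFERENCE_TARGET = "reference_gene"


@dataclass
class CtRecord:
    """Technical-replicate CT values for one primer target in one sample."""

    sample_id: str
    target: str
    ct_values: list[float]

    def __post_init__(self) -> None:
        cts = [c for c in self.ct_values if c is not None and math.isfinite(c)]
        if len(cts) < len(self.ct_values):
            # non-detect replicates are dropped, never imputed
            self.ct_values = cts
        if not self.ct_values:
            raise ValueError(
                f"{self.sample_id}/{self.target}: no detectable CT replicate"
            )
        if any(c <= 0 for c in self.ct_values):
            raise ValueError(f"{self.sample_id}/{self.target}: CT must be > 0")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_values))


@dataclass
class AlleleQuantResult:
    sample_id: str
    fc_allele_a: float
    fc_allele_b: float
    pct_allele_a: float
    pct_allele_b: float
    pct_degradation: float
    degradation_out_of_range: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def delta_ct(record: CtRecord, reference: CtRecord) -> float:
    """Mean target CT minus mean reference-gene CT for the same sample."""
    if record.sample_id != reference.sample_id:
        raise ValueError(
            f"sample mismatch: {record.sample_id!r} vs {reference.sample_id!r}"
        )
    if reference.target != REFERENCE_TARGET:
        raise ValueError(
            f"reference record has target {reference.target!r}, "
            f"expected {REFERENCE_TARGET!r}"
        )
    return record.mean_ct - reference.mean_ct


def fold_change_ddct(
    delta_ct_sample: float,
    calibrator_delta_cts: Sequence[float],
    efficiency: float = 2.0,
) -> float:
    """Fold change ``efficiency^(−ΔΔCT)`` against the calibrator mean ΔCT.

    ``efficiency`` is the per-cycle amplification factor; the canonical
    comparative-CT method assumes perfect doubling (2.0).
    """
    if len(calibrator_delta_cts) == 0:
        raise ValueError("calibrator ΔCT list is empty")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ddct = delta_ct_sample - float(np.mean(calibrator_delta_cts))
    return float(efficiency ** (-ddct))


def allele_percentages(fc_a: float, fc_b: float) -> tuple[float, float]:
    """Express each allele's fold change as a percentage of their sum."""
    if fc_a < 0 or fc_b < 0:
        raise ValueError("fold changes must be nonnegative")
    total = fc_a + fc_b
    if total == 0:
        raise ValueError("both fold changes are zero; percentages undefined")
    return 100.0 * fc_a / total, 100.0 * fc_b / total


def percent_degradation(x_pct: float, y_pct: float) -> float:
    """Percent of the splicing-defective allele's transcript inferred degraded.

    ``x_pct`` is the observed percent of transcript from the defective
    allele, ``y_pct`` from the intact allele; under 50:50 transcription the
    intact allele's share is the expected yield, so the relative shortfall
    (y − x)/y is the degraded fraction.  A negative value (x > y) means the
    assumption is violated; it is returned as-is with a warning rather than
    clamped.
    """
    if not (0 <= x_pct <= 100) or not (0 <= y_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    if y_pct == 0:
        raise ValueError("intact-allele percentage is zero; degradation undefined")
    result = 100.0 * (y_pct - x_pct) / y_pct
    if result < 0:
        warnings.warn(
            "negative inferred degradation: the 50:50 transcription "
            "assumption does not hold for this sample",
            stacklevel=2,
        )
    return result


@dataclass
class _SampleCts:
    sample_id: str
    by_target: dict = field(default_factory=dict)


def _collect(records: Iterable[CtRecord]) -> dict[str, _SampleCts]:
    samples: dict[str, _SampleCts] = {}
    for rec in records:
        s = samples.setdefault(rec.sample_id, _SampleCts(rec.sample_id))
        if rec.target in s.by_target:
            raise ValueError(f"duplicate target {rec.target!r} for {rec.sample_id!r}")
        s.by_target[rec.target] = rec
    return samples


def quantify_sample(
    records: Iterable[CtRecord],
    sample_id: str,
    calibrator_ids: Sequence[str],
    allele_a: str = "allele_a_primer",
    allele_b: str = "allele_b_primer",
    efficiency: float = 2.0,
) -> AlleleQuantResult:
    """Full comparative-CT pipeline for one sample.

    ``allele_a`` is the splicing-defective allele (X in the degradation
    formula), ``allele_b`` the intact allele (Y).  Calibrator samples must
    carry both allele targets and the reference gene.
    """
    samples = _collect(records)
    if sample_id not in samples:
        raise ValueError(f"sample {sample_id!r} not in CT table")
    missing = [c for c in calibrator_ids if c not in samples]
    if missing:
        raise ValueError(f"calibrator samples missing from CT table: {missing}")
    if not calibrator_ids:
        raise ValueError("at least one calibrator sample is required")

    def dct(sid: str, target: str) -> float:
        s = samples[sid]
        if target not in s.by_target or REFERENCE_TARGET not in s.by_target:
            raise ValueError(f"sample {sid!r} lacks target {target!r} or reference")
        return delta_ct(s.by_target[target], s.by_target[REFERENCE_TARGET])

    fcs = {}
    for allele in (allele_a, allele_b):
        cal = [dct(c, allele) for c in calibrator_ids]
        fcs[allele] = fold_change_ddct(dct(sample_id, allele), cal, efficiency)
    pct_a, pct_b = allele_percentages(fcs[allele_a], fcs[allele_b])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        deg = percent_degradation(pct_a, pct_b)
    return AlleleQuantResult(
        sample_id=sample_id,
        fc_allele_a=fcs[allele_a],
        fc_allele_b=fcs[allele_b],
        pct_allele_a=pct_a,
        pct_allele_b=pct_b,
        pct_degradation=deg,
        degradation_out_of_range=not (0 <= deg <= 100),
    )


def quantify_table(
    ct_table: pd.DataFrame,
    sample_id: str,
    calibrator_ids: Sequence[str],
    **kwargs,
) -> AlleleQuantResult:
    """Run :func:`quantify_sample` on a long-format CT table.

    Expected columns: ``sample_id``, ``target``, ``ct`` (one row per
    technical replicate; a ``replicate`` column is permitted and ignored).
    """
    required = {"sample_id", "target", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    records = [
        CtRecord(sample_id=str(sid), target=str(tgt), ct_values=list(grp["ct"]))
        for (sid, tgt), grp in ct_table.groupby(["sample_id", "target"], sort=True)
    ]
    return quantify_sample(records, sample_id, calibrator_ids, **kwargs)
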