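"""Assay-quality statistics: per-plate Z'-factor and duplicate-well CV.

Z' = 1 - 3(sigma_pos + sigma_neg)/|mu_pos - mu_neg| summarizes how well a
plate separates its positive (untreated WT) and negative (untreated MT)
control windows; 1 is ideal, <= 0 unusable.  FCCP wells are an assay-range
check, not the Z' negative group: the screening window of interest is WT
vs MT, and the fully depolarized FCCP level would artificially inflate it.
Duplicate reproducibility is the percent coefficient of variation across a
treatment's replicate wells.  QC is reported, never used to discard plates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .screen import (
    NormalizedValue,
    ScreenDataset,
    WellRole,
    aggregate_replicates,
)

__all__ = [
    "PlateQCReport",
    "ScreenQCReport",
    "InsufficientReplicatesError",
    "UndefinedWindowError",
    "z_prime",
    "duplicate_cv",
    "qc_screen",
    "write_qc_json",
]


class InsufficientReplicatesError(ValueError):
    """Fewer than two values in a control group or replicate set."""


class UndefinedWindowError(ValueError):
    """Z' is undefined because the control group means coincide."""


def z_prime(pos_values: Sequence[float], neg_values: Sequence[float]) -> float:
    """Z'-factor of a plate from its positive and negative control wells.

    Sample SDs (ddof=1); invariant under common affine rescaling of both
    groups.
    """
    if len(pos_values) < 2 or len(neg_values) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 wells per control group, got "
            f"{len(pos_values)} pos / {len(neg_values)} neg"
        )
    mu_p, mu_n = float(np.mean(pos_values)), float(np.mean(neg_values))
    if mu_p == mu_n:
        raise UndefinedWindowError("control group means coincide; window is zero")
    s_p = float(np.std(pos_values, ddof=1))
    s_n = float(np.std(neg_values, ddof=1))
    return 1.0 - 3.0 * (s_p + s_n) / abs(mu_p - mu_n)


def duplicate_cv(values: Sequence[float]) -> float:
    """Percent coefficient of variation, 100 x sample SD / mean."""
    if len(values) < 2:
        raise InsufficientReplicatesError(f"need >= 2 replicates, got {len(values)}")
    mean = float(np.mean(values))
    if mean <= 0:
        raise ValueError(f"CV undefined for non-positive mean {mean}")
    return 100.0 * float(np.std(values, ddof=1)) / mean


@dataclass
class PlateQCReport:
    plate_id: str
    z_prime: float | None
    mu_pos: float | None
    sigma_pos: float | None
    mu_neg: float | None
    sigma_neg: float | None
    n_pos: int
    n_neg: int
    failure: str | None = None


@dataclass
class ScreenQCReport:
    plates: list[PlateQCReport]
    cv_mean: float | None
    cv_median: float | None
    frac_cv_lt_10: float | None
    frac_cv_lt_15: float | None
    all_pass_cv15: bool
    n_treatments_with_cv: int


def qc_screen(
    screen: ScreenDataset,
    normalized: Mapping[str, Mapping[str, float]],
    aggregated: Sequence[NormalizedValue] | None = None,
) -> ScreenQCReport:
    """Per-plate Z' (normalized WT vs MT wells) and screen-wide CV summary.

    Plates with missing or degenerate controls become QC failures in the
    report rather than exceptions.
    """
    plate_reports: list[PlateQCReport] = []
    for plate in screen.plates:
        norm = normalized[plate.plate_id]
        pos = [norm[w.well] for w in plate.by_role(WellRole.WT_CONTROL)]
        neg = [norm[w.well] for w in plate.by_role(WellRole.MT_CONTROL)]
        try:
            zp = z_prime(pos, neg)
            plate_reports.append(
                PlateQCReport(
                    plate_id=plate.plate_id,
                    z_prime=zp,
                    mu_pos=float(np.mean(pos)),
                    sigma_pos=float(np.std(pos, ddof=1)),
                    mu_neg=float(np.mean(neg)),
                    sigma_neg=float(np.std(neg, ddof=1)),
                    n_pos=len(pos),
                    n_neg=len(neg),
                )
            )
        except (InsufficientReplicatesError, UndefinedWindowError) as e:
            plate_reports.append(
                PlateQCReport(
                    plate_id=plate.plate_id,
                    z_prime=None,
                    mu_pos=float(np.mean(pos)) if pos else None,
                    sigma_pos=None,
                    mu_neg=float(np.mean(neg)) if neg else None,
                    sigma_neg=None,
                    n_pos=len(pos),
                    n_neg=len(neg),
                    failure=str(e),
                )
            )

    if aggregated is None:
        aggregated = aggregate_replicates(screen, normalized)
    cvs = np.array([v.cv_percent for v in aggregated if len(v.replicates) >= 2])
    if cvs.size:
        return ScreenQCReport(
            plates=plate_reports,
            cv_mean=float(np.mean(cvs)),
            cv_median=float(np.median(cvs)),
            frac_cv_lt_10=float(np.mean(cvs < 10.0)),
            frac_cv_lt_15=float(np.mean(cvs < 15.0)),
            all_pass_cv15=bool(np.all(cvs < 15.0)),
            n_treatments_with_cv=int(cvs.size),
        )
    return ScreenQCReport(
        plates=plate_reports,
        cv_mean=None,
        cv_median=None,
        frac_cv_lt_10=None,
        frac_cv_lt_15=None,
        all_pass_cv15=True,
        n_treatments_with_cv=0,
    )


def write_qc_json(report: ScreenQCReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(report), fh, indent=2)
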