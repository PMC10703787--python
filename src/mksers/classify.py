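"""Subgroup assignment, receptor calling and endpoint coding.

Tumours are stratified by thresholding the MKS (proliferation) and ERS
(ER-related signalling) metagene scores, by default at the cohort-specific
medians, into four quadrant subgroups (or two ERS-only strata when every
tumour is assumed highly proliferative). Receptor status prefers the
pathology IHC call and falls back to mRNA cutoffs. Endpoints are coded from
residual cancer burden (RCB) class and from post-treatment Ki67.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FOUR_GROUP_LABELS",
    "ERS_ONLY_LABELS",
    "Thresholds",
    "median_threshold",
    "thresholds_from_scores",
    "assign_subgroups",
    "assign_receptor_status",
    "classify_pathological_response",
    "classify_ki67_response",
    "read_clinical_csv",
]

FOUR_GROUP_LABELS = ("MKSlo_ERShi", "MKSlo_ERSlo", "MKShi_ERShi", "MKShi_ERSlo")
ERS_ONLY_LABELS = ("ERShi", "ERSlo")

# mRNA fallback cutoffs for receptor calling (log2 FPKM, strict >)
ESR1_LOG2FPKM_CUT = 2.145
ERBB2_LOG2FPKM_CUT = 6.32

KI67_RESPONSE_CUT = 10.0  # percent; responder iff strictly below


@dataclass(frozen=True)
class Thresholds:
    """Score cutoffs used for stratification; source recorded for provenance."""

    mks_cut: float
    ers_cut: float
    source: str = "cohort_median"  # cohort_median | predefined

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mks_cut) and np.isfinite(self.ers_cut)):
            raise ValueError("thresholds must be finite")
        if self.source not in {"cohort_median", "predefined"}:
            raise ValueError(f"unknown threshold source {self.source!r}")


def median_threshold(scores) -> float:
    """Sample median (midpoint of the two central order statistics for even n)."""
    arr = np.asarray(scores, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("median threshold requires at least 2 finite scores")
    return float(np.median(arr))


def thresholds_from_scores(mks, ers) -> Thresholds:
    return Thresholds(median_threshold(mks), median_threshold(ers), source="cohort_median")


def assign_subgroups(mks, ers, thresholds: Thresholds, mode: str = "four_group"):
    """Label each sample by its MKS/ERS quadrant (or ERS stratum only).

    High means strictly above the cutoff; a score equal to the cutoff is low.
    NA scores yield NA labels with a warning. Returns an object array aligned
    with the inputs.
    """
    if mode not in {"four_group", "ers_only"}:
        raise ValueError(f"unknown mode {mode!r}")
    mks = np.asarray(mks, dtype=float)
    ers = np.asarray(ers, dtype=float)
    if mks.shape != ers.shape:
        raise ValueError("mks and ers vectors must be aligned to the same samples")
    labels = np.empty(mks.shape, dtype=object)
    na = ~np.isfinite(ers) if mode == "ers_only" else ~(np.isfinite(mks) & np.isfinite(ers))
    if na.any():
        warnings.warn(f"{int(na.sum())} samples with NA scores get NA labels",
                      RuntimeWarning, stacklevel=2)
    ers_hi = ers > thresholds.ers_cut
    if mode == "ers_only":
        labels[:] = np.where(ers_hi, "ERShi", "ERSlo")
    else:
        mks_hi = mks > thresholds.mks_cut
        quadrant = np.where(
            mks_hi,
            np.where(ers_hi, "MKShi_ERShi", "MKShi_ERSlo"),
            np.where(ers_hi, "MKSlo_ERShi", "MKSlo_ERSlo"),
        )
        labels[:] = quadrant
    labels[na] = None
    return labels


def _is_na(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    if isinstance(x, str) and x.strip().upper() in {"", "NA", "NAN"}:
        return True
    return pd.isna(x)


def assign_receptor_status(
    er_ihc=None, her2_ihc=None, esr1_log2fpkm=None, erbb2_log2fpkm=None
) -> tuple[str | None, str | None]:
    """Call (ER, HER2) status. Pathology IHC wins; mRNA is the fallback.

    mRNA positivity is strict: ESR1 log2 FPKM > 2.145, ERBB2 log2 FPKM > 6.32.
    Returns e.g. ``("ER+", "HER2-")``; a marker with neither source is None.
    """

    def call(ihc, mrna, cut, pos, neg):
        if not _is_na(ihc):
            token = str(ihc).strip().lower()
            if token in {"pos", "positive", "+", "1", "true"}:
                return pos
            if token in {"neg", "negative", "-", "0", "false"}:
                return neg
            raise ValueError(f"unrecognised IHC value {ihc!r}")
        if not _is_na(mrna):
            return pos if float(mrna) > cut else neg
        return None

    er = call(er_ihc, esr1_log2fpkm, ESR1_LOG2FPKM_CUT, "ER+", "ER-")
    her2 = call(her2_ihc, erbb2_log2fpkm, ERBB2_LOG2FPKM_CUT, "HER2+", "HER2-")
    return er, her2


def classify_pathological_response(rcb_class) -> tuple[str | None, bool | None]:
    """Code RCB class into (response group, pCR flag).

    RCB 0 (pCR) and RCB I (minimal residual cancer) form the pathological
    response group ``pathR``; RCB II/III form the residual-disease group
    ``RD``. The pCR flag is true only for RCB 0. NA propagates.
    """
    if _is_na(rcb_class):
        return None, None
    token = str(rcb_class).strip().upper()
    if token in {"0", "0.0", "PCR"}:
        return "pathR", True
    if token == "I" or token == "1":
        return "pathR", False
    if token == "II" or token == "2":
        return "RD", False
    if token == "III" or token == "3":
        return "RD", False
    raise ValueError(f"invalid RCB class {rcb_class!r}")


def classify_ki67_response(ki67_post_pct) -> str | None:
    """Endocrine response surrogate: post-treatment Ki67 < 10% is a responder."""
    if _is_na(ki67_post_pct):
        return None
    value = float(ki67_post_pct)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"Ki67 percentage out of [0,100]: {value}")
    return "responder" if value < KI67_RESPONSE_CUT else "non_responder"


CLINICAL_COLUMNS = [
    "sample_id", "rcb_class", "ki67_post_pct", "time_years", "event", "arm",
    "er_ihc", "her2_ihc", "esr1_log2fpkm", "erbb2_log2fpkm",
]


def read_clinical_csv(path) -> pd.DataFrame:
    """Read a clinical annotation CSV (documented column dictionary).

    Required column: ``sample_id``; all others optional. ``event`` is coerced
    to boolean, times must be non-negative and defined wherever event is.
    """
    df = pd.read_csv(path, na_values=["NA", "NaN", ""], dtype={"rcb_class": str})
    if "sample_id" not in df.columns:
        raise ValueError("clinical table must have a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    unknown = set(df.columns) - set(CLINICAL_COLUMNS)
    if unknown:
        warnings.warn(f"ignoring unknown clinical columns: {sorted(unknown)}",
                      RuntimeWarning, stacklevel=2)
    if "time_years" in df.columns:
        t = pd.to_numeric(df["time_years"], errors="raise")
        if (t.dropna() < 0).any():
            raise ValueError("negative survival times")
        if "event" in df.columns:
            bad = t.isna() & df["event"].notna()
            if bad.any():
                raise ValueError("event defined without time for some samples")
            df["event"] = df["event"].map(
                lambda v: None if _is_na(v) else bool(int(v)) if str(v) in "01" else bool(v)
            )
    if "ki67_post_pct" in df.columns:
        k = pd.to_numeric(df["ki67_post_pct"], errors="raise").dropna()
        if ((k < 0) | (k > 100)).any():
            raise ValueError("Ki67 percentages out of [0,100]")
    return df
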