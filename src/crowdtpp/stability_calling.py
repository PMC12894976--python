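"""ΔTm computation, per-treatment z-scores, significance calls, concordance.

A protein's stability shift under a crowding agent is ΔTm = Tm(treatment) −
Tm(control); positive means stabilized.  Within each treatment, ΔTm values
of all QC-passing proteins are standardized to z-scores (sample sd, n−1),
and |z| ≥ z_crit (default 1.96, the two-sided 5% normal quantile) calls a
protein significantly stabilized (z ≥ z_crit) or destabilized (z ≤ −z_crit),
boundary inclusive.  Because the standardization is within-treatment, the
method detects shifts relative to the treatment's own ΔTm distribution, not
absolute shifts.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .melt_model import MeltFit, QCCriteria, DEFAULT_QC, passes_qc, fit_from_row

log = logging.getLogger(__name__)

__all__ = [
    "StabilityCallError",
    "PairQCError",
    "DegenerateDistributionError",
    "CALL_STABILIZED",
    "CALL_DESTABILIZED",
    "CALL_NULL",
    "DEFAULT_Z_CRIT",
    "delta_tm",
    "z_scores",
    "call_stability",
    "build_stability_calls",
    "ConcordanceSummary",
    "concordance_summary",
]

CALL_STABILIZED = "stabilized"
CALL_DESTABILIZED = "destabilized"
CALL_NULL = "null"

DEFAULT_Z_CRIT = 1.96


class StabilityCallError(ValueError):
    """Invalid input to the stability-calling stage."""


class PairQCError(StabilityCallError):
    """A (control, treatment) fit pair failed quality control."""

    def __init__(self, reason: str):
        super().__init__(f"pair excluded: {reason}")
        self.reason = reason


class DegenerateDistributionError(StabilityCallError):
    """A ΔTm distribution has zero variance; z-scores are undefined."""


def delta_tm(fit_treatment: MeltFit, fit_control: MeltFit) -> float:
    """ΔTm = Tm(treatment) − Tm(control); positive = stabilized.

    Both fits must carry qc_pass; otherwise the pair is excluded via
    :class:`PairQCError` with reason ``control_qc`` or ``treatment_qc``.
    """
    if not fit_control.qc_pass:
        raise PairQCError("control_qc")
    if not fit_treatment.qc_pass:
        raise PairQCError("treatment_qc")
    return fit_treatment.tm - fit_control.tm


def z_scores(delta_tms) -> np.ndarray:
    """Standardize one treatment's ΔTm vector to mean 0, sample sd 1."""
    x = np.asarray(delta_tms, dtype=float)
    finite = np.isfinite(x)
    if int(finite.sum()) < 3:
        raise StabilityCallError("need at least 3 finite ΔTm values to standardize")
    mean = float(np.mean(x[finite]))
    sd = float(np.std(x[finite], ddof=1))
    if not sd > 0:
        raise DegenerateDistributionError("ΔTm distribution has zero variance")
    return (x - mean) / sd


def call_stability(z, z_crit: float = DEFAULT_Z_CRIT) -> np.ndarray:
    """Three-way classification of z-scores; |z| exactly at z_crit is significant."""
    z = np.asarray(z, dtype=float)
    calls = np.where(
        z >= z_crit,
        CALL_STABILIZED,
        np.where(z <= -z_crit, CALL_DESTABILIZED, CALL_NULL),
    )
    return calls.astype(object)


def build_stability_calls(
    fits: pd.DataFrame,
    control_condition: str = "control",
    criteria: QCCriteria = DEFAULT_QC,
    z_crit: float = DEFAULT_Z_CRIT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn a tidy fits table into per-treatment stability calls.

    ``fits`` has one row per (protein, condition) as produced by
    :func:`crowdtpp.melt_model.fit_condition`.  For each treatment, proteins
    whose (control, treatment) fit pair passes the pairwise stringency check
    form the standardization population.  Returns ``(calls, excluded)``:
    calls with columns protein, crowder, delta_tm, z, call; excluded with
    protein, crowder, reason for every pair that was gated out.
    """
    if control_condition not in set(fits["condition"]):
        raise StabilityCallError(f"control condition {control_condition!r} not in fits")
    control = {
        row["protein"]: fit_from_row(row)
        for _, row in fits[fits["condition"] == control_condition].iterrows()
    }
    call_rows: list[dict] = []
    excluded: list[dict] = []
    treatments = [c for c in pd.unique(fits["condition"]) if c != control_condition]
    for treatment in treatments:
        sub = fits[fits["condition"] == treatment]
        proteins: list[str] = []
        deltas: list[float] = []
        for _, row in sub.iterrows():
            protein = row["protein"]
            fit_t = fit_from_row(row)
            fit_c = control.get(protein)
            if fit_c is None:
                excluded.append(
                    {"protein": protein, "crowder": treatment, "reason": "no_control_fit"}
                )
                continue
            ok, reasons = passes_qc(fit_c, fit_t, criteria)
            if not ok:
                excluded.append(
                    {
                        "protein": protein,
                        "crowder": treatment,
                        "reason": ";".join(reasons),
                    }
                )
                continue
            proteins.append(protein)
            deltas.append(fit_t.tm - fit_c.tm)
        if not proteins:
            log.warning("treatment %s: no QC-passing pairs", treatment)
            continue
        z = z_scores(np.asarray(deltas))
        calls = call_stability(z, z_crit=z_crit)
        for prot, d, zz, call in zip(proteins, deltas, z, calls):
            call_rows.append(
                {"protein": prot, "crowder": treatment, "delta_tm": d, "z": zz, "call": call}
            )
    calls_df = pd.DataFrame(call_rows, columns=["protein", "crowder", "delta_tm", "z", "call"])
    excluded_df = pd.DataFrame(excluded, columns=["protein", "crowder", "reason"])
    return calls_df, excluded_df


@dataclasses.dataclass
class ConcordanceSummary:
    """Cross-crowder concordance of significant stability calls.

    ``per_protein`` has one row per protein with ≥ 1 significant call:
    protein, n_significant, direction_profile (all-stabilized /
    all-destabilized / mixed).  ``histogram`` maps crowder-count → number of
    proteins; ``direction_histogram`` breaks the same counts down by
    direction profile.
    """

    per_protein: pd.DataFrame
    histogram: dict[int, int]
    direction_histogram: dict[tuple[int, str], int]


def concordance_summary(calls: pd.DataFrame) -> ConcordanceSummary:
    """Summarize how many crowders affect each protein, and how concordantly."""
    if calls.empty:
        empty = pd.DataFrame(columns=["protein", "n_significant", "direction_profile"])
        return ConcordanceSummary(per_protein=empty, histogram={}, direction_histogram={})
    sig = calls[calls["call"] != CALL_NULL]
    rows = []
    for protein, grp in sig.groupby("protein", sort=True):
        n_stab = int((grp["call"] == CALL_STABILIZED).sum())
        n_destab = int((grp["call"] == CALL_DESTABILIZED).sum())
        if n_stab and n_destab:
            profile = "mixed"
        elif n_stab:
            profile = "all-stabilized"
        else:
            profile = "all-destabilized"
        rows.append(
            {"protein": protein, "n_significant": n_stab + n_destab, "direction_profile": profile}
        )
    per_protein = pd.DataFrame(rows, columns=["protein", "n_significant", "direction_profile"])
    histogram: dict[int, int] = {}
    direction_histogram: dict[tuple[int, str], int] = {}
    for _, row in per_protein.iterrows():
        k = int(row["n_significant"])
        histogram[k] = histogram.get(k, 0) + 1
        key = (k, row["direction_profile"])
        direction_histogram[key] = direction_histogram.get(key, 0) + 1
    return ConcordanceSummary(
        per_protein=per_protein,
        histogram=dict(sorted(histogram.items())),
        direction_histogram=dict(sorted(direction_histogram.items())),
    )
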