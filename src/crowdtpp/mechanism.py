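"""Crowder-property regressions: crowding/viscosity vs preferential exclusion.

The crowding (excluded-volume/viscosity) model predicts that stabilization
should track reagent size and solution viscosity; the preferential-exclusion
model predicts dependence on surface chemistry (polar atom fraction,
hydrophobicity).  Regressing a per-crowder stability summary on each
physico-chemical descriptor and comparing R² values discriminates the two.

Summaries are computed over the common set of proteins that pass QC in
every condition, so crowders are compared on identical support.  With only
six crowders, every regression carries a small-sample caveat flag.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MechanismError",
    "DegenerateDescriptorError",
    "MechanismResult",
    "SUMMARY_MODES",
    "stability_summary_per_crowder",
    "property_regression",
    "mechanism_table",
]

SUMMARY_MODES = ("mean_tm", "mean_delta_tm", "median_delta_tm")

SMALL_SAMPLE_N = 10  # below this the r2 is flagged as a small-sample estimate


class MechanismError(ValueError):
    """Invalid input to the mechanism regression stage."""


class DegenerateDescriptorError(MechanismError):
    """A descriptor has zero variance across crowders; regression undefined."""


@dataclasses.dataclass(frozen=True)
class MechanismResult:
    descriptor: str
    mode: str
    slope: float
    intercept: float
    r2: float
    n: int
    small_sample: bool


def stability_summary_per_crowder(
    fits: pd.DataFrame,
    control_condition: str = "control",
    mode: str = "mean_tm",
) -> pd.Series:
    """One stability scalar per crowder over the common QC-passing protein set.

    Modes: ``mean_tm`` (mean melting temperature in the crowder),
    ``mean_delta_tm`` / ``median_delta_tm`` (shift relative to control).
    Proteins missing or failing QC in any condition are dropped everywhere;
    an empty intersection raises an error naming the offending condition.
    """
    if mode not in SUMMARY_MODES:
        raise MechanismError(f"unknown summary mode {mode!r}; use one of {SUMMARY_MODES}")
    ok = fits[fits["qc_pass"].astype(bool)]
    conditions = list(pd.unique(fits["condition"]))
    if control_condition not in conditions:
        raise MechanismError(f"control condition {control_condition!r} not in fits")
    common: set[str] | None = None
    for cond in conditions:
        present = set(ok.loc[ok["condition"] == cond, "protein"])
        if not present:
            raise MechanismError(f"no QC-passing proteins in condition {cond!r}")
        common = present if common is None else common & present
        if not common:
            raise MechanismError(
                f"common protein set became empty after intersecting condition {cond!r}"
            )
    tm = ok[ok["protein"].isin(common)].pivot(
        index="protein", columns="condition", values="tm"
    )
    crowders = [c for c in conditions if c != control_condition]
    if mode == "mean_tm":
        summary = tm[crowders].mean(axis=0)
    else:
        delta = tm[crowders].sub(tm[control_condition], axis=0)
        summary = delta.mean(axis=0) if mode == "mean_delta_tm" else delta.median(axis=0)
    summary.name = mode
    return summary


def property_regression(
    summaries: pd.Series,
    properties: pd.DataFrame,
    descriptor: str,
) -> MechanismResult:
    """OLS of a per-crowder stability summary on one physico-chemical descriptor.

    ``properties`` is indexed by reagent (see
    :func:`crowdtpp.quant_io.read_crowder_properties`).  Reports slope,
    intercept, R² (the squared Pearson correlation) and the number of
    crowders with both values.
    """
    if descriptor not in properties.columns:
        raise MechanismError(f"descriptor {descriptor!r} not in property table")
    x = pd.to_numeric(properties[descriptor], errors="coerce")
    joined = pd.DataFrame({"x": x, "y": summaries}).dropna()
    n = len(joined)
    if n < 3:
        raise MechanismError(
            f"need ≥ 3 crowders with descriptor and summary; got {n} for {descriptor!r}"
        )
    if float(np.var(joined["x"].to_numpy())) == 0.0:
        raise DegenerateDescriptorError(
            f"descriptor {descriptor!r} is constant across crowders"
        )
    res = stats.linregress(joined["x"], joined["y"])
    return MechanismResult(
        descriptor=descriptor,
        mode=str(summaries.name or ""),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=n,
        small_sample=n < SMALL_SAMPLE_N,
    )


def mechanism_table(
    fits: pd.DataFrame,
    properties: pd.DataFrame,
    control_condition: str = "control",
    modes: tuple[str, ...] = SUMMARY_MODES,
    descriptors: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """All mode × descriptor regressions, exported side by side."""
    if descriptors is None:
        descriptors = tuple(
            c
            for c in properties.columns
            if pd.api.types.is_numeric_dtype(properties[c])
        )
    rows = []
    for mode in modes:
        summary = stability_summary_per_crowder(fits, control_condition, mode)
        for descriptor in descriptors:
            try:
                res = property_regression(summary, properties, descriptor)
            except DegenerateDescriptorError:
                log.warning("descriptor %s constant; regression skipped", descriptor)
                continue
            rows.append(dataclasses.asdict(res))
    return pd.DataFrame(
        rows,
        columns=["descriptor", "mode", "slope", "intercept", "r2", "n", "small_sample"],
    )
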