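"""Synthetic TPP experiments with known ground truth.

Emulates the study design end to end: a 10-point thermal gradient (30–70 °C),
one control plus six crowder treatments, per-protein sigmoid melting with a
post-transition plateau, treatment-specific Tm shifts in a small minority of
proteins, and multiplicative log-normal intensity noise.  Shifts are
injected exactly by re-solving the sigmoid offset b for the shifted Tm while
holding a and the plateau fixed, so the true ΔTm of every (protein, crowder)
pair is known analytically.

Identifiability constraints built into the generator (they emulate the
subset of proteins a TPP analysis can actually quantify):

* every condition's Tm stays inside the measured gradient, away from both
  ends — shift magnitudes are clipped to the available headroom;
* every curve is fully folded at the 30 °C reference (soluble fraction
  within ~1e-5 of 1), since reference-normalized data cannot constrain a
  curve already melting at the reference temperature;
* slopes at Tm are at least 0.10 /°C in magnitude, comfortably beyond the
  stringency threshold, as for real QC-passing melting curves.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os

import numpy as np
import pandas as pd

from .melt_model import MeltParams, melt_eval, melt_slope
from .quant_io import (
    DEFAULT_TEMPERATURES,
    ProteomeQuant,
    write_quant_table,
    write_channel_map,
    write_table,
)
from .stability_calling import CALL_STABILIZED, CALL_DESTABILIZED, CALL_NULL

log = logging.getLogger(__name__)

__all__ = [
    "SimConfigError",
    "SimConfig",
    "SyntheticExperiment",
    "generate_experiment",
    "write_experiment",
    "truth_evaluation",
    "DEFAULT_CROWDERS",
]

DEFAULT_CROWDERS = ("ficoll70", "ficoll400", "dextran40", "dextran86", "peg1", "peg8")

# reference-temperature headroom: ln-odds of the soluble fraction at the
# lowest gradient temperature is kept below -12 (fraction ≥ 1 - 6e-6)
_REFERENCE_LOGIT_MARGIN = 12.0
_MIN_SHIFT_C = 2.5


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one synthetic TPP experiment.

    Defaults mirror the emulated design: 300 proteins, the 10-point
    30–70 °C gradient, six crowder treatments plus a control, 3% of proteins
    stabilized and 3% destabilized with shifts of 5 ± 1 °C, melting
    temperatures centred at 52 ± 5 °C, plateaus up to 0.25, and 5%
    multiplicative (log-normal) intensity noise.
    """

    n_proteins: int = 300
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    crowders: tuple[str, ...] = DEFAULT_CROWDERS
    control_name: str = "control"
    fraction_stabilized: float = 0.03
    fraction_destabilized: float = 0.03
    shift_mean: float = 5.0
    shift_sd: float = 1.0
    tm_mean: float = 52.0
    tm_sd: float = 5.0
    tm_range: tuple[float, float] = (44.0, 58.0)
    plateau_range: tuple[float, float] = (0.0, 0.25)
    slope_range: tuple[float, float] = (0.10, 0.22)
    noise_cv: float = 0.05
    missing_rate: float = 0.0
    abundance_range: tuple[float, float] = (1e7, 1e10)
    crowders_affected_p: float = 0.25
    left_skew: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SimConfigError("n_proteins must be ≥ 1")
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.size < 5 or not np.all(np.diff(temps) > 0):
            raise SimConfigError("temperatures must be ≥ 5 strictly increasing values")
        if self.fraction_stabilized + self.fraction_destabilized >= 1:
            raise SimConfigError("class fractions must sum to < 1")
        if min(self.fraction_stabilized, self.fraction_destabilized) < 0:
            raise SimConfigError("class fractions must be ≥ 0")
        if self.noise_cv < 0:
            raise SimConfigError("noise_cv must be ≥ 0")
        if not 0 <= self.missing_rate < 1:
            raise SimConfigError("missing_rate must be in [0, 1)")
        lo, hi = self.plateau_range
        if not (0 <= lo <= hi < 0.5):
            raise SimConfigError("plateau_range must lie within [0, 0.5)")
        if self.control_name in self.crowders:
            raise SimConfigError("control_name must not appear among crowders")

    @property
    def n_crowders(self) -> int:
        return len(self.crowders)

    @property
    def tm_bounds(self) -> tuple[float, float]:
        """Admissible Tm window for any condition: inside the gradient."""
        temps = self.temperatures
        return (float(temps[1]) + 2.0, float(temps[-1]) - 6.0)


@dataclasses.dataclass
class SyntheticExperiment:
    """Generated experiment: truth tables plus one ProteomeQuant per condition."""

    config: SimConfig
    protein_table: pd.DataFrame
    truth: pd.DataFrame
    quants: dict[str, ProteomeQuant]


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_experiment(config: SimConfig = SimConfig()) -> SyntheticExperiment:
    """Draw a complete synthetic experiment, fully reproducible given the seed.

    Control melting parameters are drawn from the config distributions;
    affected proteins get exact Tm shifts in a random subset of crowders
    (count 1 + Binomial(n_crowders − 1, crowders_affected_p), concerted in
    direction, matching the observed cross-crowder concordance).  Shift
    magnitudes that would push a Tm outside the observable gradient are
    shrunk to the headroom with a warning.
    """
    rng = np.random.default_rng(config.seed)
    temps = np.asarray(config.temperatures, dtype=float)
    t_ref = float(temps[0])
    tm_lo, tm_hi = config.tm_bounds
    n = config.n_proteins
    width = len(str(max(n, 1)))
    proteins = [f"SYN{(i + 1):0{width}d}" for i in range(n)]

    frac_s, frac_d = config.fraction_stabilized, config.fraction_destabilized
    if config.left_skew:
        # small excess of destabilizing shifts
        shifted = 0.25 * frac_s
        frac_s, frac_d = frac_s - shifted, frac_d + shifted

    sigma = math.sqrt(math.log1p(config.noise_cv**2))
    log_lo, log_hi = (math.log(v) for v in config.abundance_range)

    protein_rows: list[dict] = []
    truth_rows: list[dict] = []
    cond_params: dict[str, list[MeltParams]] = {
        c: [] for c in (config.control_name, *config.crowders)
    }
    abundances = np.empty(n)

    for i, protein in enumerate(proteins):
        r = rng.random()
        if r < frac_s:
            protein_class = CALL_STABILIZED
        elif r < frac_s + frac_d:
            protein_class = CALL_DESTABILIZED
        else:
            protein_class = CALL_NULL

        tm = _truncated_normal(
            rng, config.tm_mean, config.tm_sd,
            max(config.tm_range[0], tm_lo), min(config.tm_range[1], tm_hi),
        )
        plateau = float(rng.uniform(*config.plateau_range))
        target_slope = float(rng.uniform(*config.slope_range))
        abundances[i] = math.exp(rng.uniform(log_lo, log_hi))

        deltas = np.zeros(config.n_crowders)
        if protein_class != CALL_NULL:
            k = 1 + int(rng.binomial(config.n_crowders - 1, config.crowders_affected_p))
            which = rng.choice(config.n_crowders, size=k, replace=False)
            sign = 1.0 if protein_class == CALL_STABILIZED else -1.0
            headroom = (tm_hi - tm) if sign > 0 else (tm - tm_lo)
            for j in which:
                mag = float(rng.normal(config.shift_mean, config.shift_sd))
                if mag > headroom:
                    log.warning(
                        "%s: shift %.2f °C exceeds gradient headroom; shrunk to %.2f",
                        protein, mag, headroom,
                    )
                mag = float(np.clip(mag, _MIN_SHIFT_C, headroom))
                deltas[j] = sign * mag

        # a from the target slope at Tm, raised if needed so every condition
        # is fully folded at the reference temperature
        L = math.log1p(-2.0 * plateau)
        a_slope = target_slope * (1.0 - plateau) * tm**2 / (0.5 * (0.5 - plateau))
        tm_min_cond = tm + min(0.0, float(deltas.min()))
        a_ref = (_REFERENCE_LOGIT_MARGIN - L) / (1.0 / t_ref - 1.0 / tm_min_cond)
        a = max(a_slope, a_ref)
        b = a / tm - L
        control_params = MeltParams(a=a, b=b, plateau=plateau)
        cond_params[config.control_name].append(control_params)

        for crowder, delta in zip(config.crowders, deltas):
            if delta == 0.0:
                params = control_params
            else:
                params = MeltParams(a=a, b=a / (tm + delta) - L, plateau=plateau)
            cond_params[crowder].append(params)
            truth_rows.append(
                {
                    "protein": protein,
                    "crowder": crowder,
                    "true_delta_tm": float(delta),
                    "true_class": (
                        CALL_NULL
                        if delta == 0.0
                        else (CALL_STABILIZED if delta > 0 else CALL_DESTABILIZED)
                    ),
                    "tm_control": tm,
                    "tm_treatment": tm + float(delta),
                }
            )
        protein_rows.append(
            {
                "protein": protein,
                "true_class": protein_class,
                "tm": tm,
                "a": a,
                "b": b,
                "plateau": plateau,
                "slope": melt_slope(control_params),
                "abundance": abundances[i],
            }
        )

    quants: dict[str, ProteomeQuant] = {}
    for cond, params_list in cond_params.items():
        clean = np.vstack(
            [abundances[i] * melt_eval(p, temps) for i, p in enumerate(params_list)]
        )
        noise = rng.standard_normal(clean.shape)
        intensities = clean * np.exp(sigma * noise - 0.5 * sigma**2)
        if config.missing_rate > 0:
            mask = rng.random(clean.shape) < config.missing_rate
            intensities = np.where(mask, np.nan, intensities)
        quants[cond] = ProteomeQuant(
            protein_ids=list(proteins),
            intensities=intensities,
            temperatures=temps.copy(),
            condition=cond,
            abundance=abundances.copy(),
        )

    protein_table = pd.DataFrame(protein_rows)
    truth = pd.DataFrame(truth_rows)
    return SyntheticExperiment(
        config=config, protein_table=protein_table, truth=truth, quants=quants
    )


def write_experiment(exp: SyntheticExperiment, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the experiment in the TSV dialect quant_io reads, plus truth tables.

    Emits quant_<condition>.tsv per condition, channel_map.tsv,
    conditions.tsv (condition → file), truth.tsv and protein_params.tsv.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    cond_rows = []
    channel_map = None
    for cond, quant in exp.quants.items():
        fname = f"quant_{cond}.tsv"
        path = os.path.join(outdir, fname)
        channel_map = write_quant_table(quant, path)
        paths[cond] = path
        cond_rows.append({"condition": cond, "file": fname})
    assert channel_map is not None
    write_channel_map(channel_map, os.path.join(outdir, "channel_map.tsv"))
    write_table(pd.DataFrame(cond_rows), os.path.join(outdir, "conditions.tsv"))
    write_table(exp.truth, os.path.join(outdir, "truth.tsv"))
    write_table(exp.protein_table, os.path.join(outdir, "protein_params.tsv"))
    paths["channel_map"] = os.path.join(outdir, "channel_map.tsv")
    paths["conditions"] = os.path.join(outdir, "conditions.tsv")
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    return paths


def truth_evaluation(calls: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Confusion-matrix rates of stability calls against the generator truth.

    Pairs present in the truth but absent from the calls (QC-excluded) are
    treated as called null.  Returns sensitivity (true shifted pairs called
    significant), specificity (true null pairs called null), sign accuracy
    (true shifted pairs whose call matches the true direction), overall
    three-way class accuracy, and the underlying counts.
    """
    truth_keys = set(zip(truth["protein"], truth["crowder"]))
    call_keys = set(zip(calls["protein"], calls["crowder"]))
    stray = call_keys - truth_keys
    if stray:
        raise ValueError(
            f"{len(stray)} call pair(s) missing from the truth table, e.g. {sorted(stray)[:3]}"
        )
    merged = truth.merge(
        calls[["protein", "crowder", "call"]], on=["protein", "crowder"], how="left"
    )
    merged["call"] = merged["call"].fillna(CALL_NULL)

    is_shifted = merged["true_class"] != CALL_NULL
    called_sig = merged["call"] != CALL_NULL
    n_shifted = int(is_shifted.sum())
    n_null = int((~is_shifted).sum())
    sensitivity = float((is_shifted & called_sig).sum() / n_shifted) if n_shifted else math.nan
    specificity = float((~is_shifted & ~called_sig).sum() / n_null) if n_null else math.nan
    sign_accuracy = (
        float((merged.loc[is_shifted, "call"] == merged.loc[is_shifted, "true_class"]).sum() / n_shifted)
        if n_shifted
        else math.nan
    )
    class_accuracy = float((merged["call"] == merged["true_class"]).mean())
    return {
        "n_pairs": float(len(merged)),
        "n_true_shifted": float(n_shifted),
        "n_true_null": float(n_null),
        "n_called_significant": float(called_sig.sum()),
        "n_uncalled": float(len(truth_keys) - len(call_keys)),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "sign_accuracy": sign_accuracy,
        "class_accuracy": class_accuracy,
    }
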