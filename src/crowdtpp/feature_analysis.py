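"""Sequence-level biophysics and annotation-keyword enrichment.

Links stability classes (stabilized / destabilized / null) to protein
features: GRAVY hydropathy, molecular weight, and Fisher-exact keyword
enrichment with Benjamini–Hochberg FDR control.  The background for
enrichment is the set of TPP-analyzable proteins (those with QC-passing
fits), not the whole proteome.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles_qc import compare_param_distributions

log = logging.getLogger(__name__)

__all__ = [
    "FeatureAnalysisError",
    "KYTE_DOOLITTLE",
    "AVERAGE_RESIDUE_MASS",
    "MONOISOTOPIC_RESIDUE_MASS",
    "gravy",
    "protein_mw",
    "sequence_properties",
    "keyword_enrichment",
    "compare_sets_property",
]


class FeatureAnalysisError(ValueError):
    """Invalid sequence or set input to feature analysis."""


# Kyte & Doolittle (1982) J Mol Biol 157:105 hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "E": -3.5, "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Average residue masses (Da), IUPAC 1997 atomic weights as tabulated by ExPASy.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_AVERAGE = 18.0153

# Monoisotopic residue masses (Da).
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694, "C": 103.00919,
    "E": 129.04259, "Q": 128.05858, "G": 57.02146, "H": 137.05891, "I": 113.08406,
    "L": 113.08406, "K": 128.09496, "M": 131.04049, "F": 147.06841, "P": 97.05276,
    "S": 87.03203, "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}
WATER_MONOISOTOPIC = 18.0105646863

_AROMATIC = frozenset("FWY")


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value over residues.

    Non-standard residues are skipped with a warning; an empty or fully
    non-standard sequence is an error.
    """
    seq = sequence.upper()
    values = [KYTE_DOOLITTLE[c] for c in seq if c in KYTE_DOOLITTLE]
    skipped = len(seq) - len(values)
    if skipped:
        log.warning("gravy: skipped %d non-standard residue(s)", skipped)
    if not values:
        raise FeatureAnalysisError("sequence has no standard residues")
    return float(np.mean(values))


def protein_mw(
    sequence: str, monoisotopic: bool = False, skip_unknown: bool = False
) -> float:
    """Protein mass in Da: sum of residue masses plus one water.

    Average masses by default; set ``monoisotopic`` for monoisotopic.
    Non-standard residues raise unless ``skip_unknown``.
    """
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    water = WATER_MONOISOTOPIC if monoisotopic else WATER_AVERAGE
    seq = sequence.upper()
    total = 0.0
    counted = 0
    for c in seq:
        if c in table:
            total += table[c]
            counted += 1
        elif skip_unknown:
            log.warning("protein_mw: skipping non-standard residue %r", c)
        else:
            raise FeatureAnalysisError(f"non-standard residue {c!r} in sequence")
    if counted == 0:
        raise FeatureAnalysisError("sequence has no standard residues")
    return total + water


def sequence_properties(sequence: str) -> dict[str, float]:
    """Bundle of per-sequence biophysical descriptors.

    GRAVY and molecular weight use the tables above; aromaticity is the
    mole fraction of F/W/Y; the aliphatic index follows Ikai (1980); the
    instability index delegates to Biopython's ProtParam implementation.
    Aromaticity, aliphaticity and instability are optional descriptors that
    showed no stability association and carry no acceptance checks.
    """
    from Bio.SeqUtils.ProtParam import ProteinAnalysis

    seq = "".join(c for c in sequence.upper() if c in KYTE_DOOLITTLE)
    if not seq:
        raise FeatureAnalysisError("sequence has no standard residues")
    n = len(seq)
    frac = {aa: seq.count(aa) / n for aa in "AVIL"}
    return {
        "length": float(n),
        "gravy": gravy(seq),
        "molecular_weight": protein_mw(seq),
        "aromaticity": sum(seq.count(a) for a in _AROMATIC) / n,
        "aliphatic_index": 100.0
        * (frac["A"] + 2.9 * frac["V"] + 3.9 * (frac["I"] + frac["L"])),
        "instability_index": float(ProteinAnalysis(seq).instability_index()),
    }


def keyword_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-keyword Fisher exact enrichment of a foreground within a background.

    For every keyword annotated on ≥ 1 foreground protein, builds the 2×2
    table (in/out of foreground × has/lacks keyword), computes the Fisher
    exact p (two-sided by default) and the odds ratio, then applies
    Benjamini–Hochberg across tested keywords.  Returns a DataFrame with
    columns keyword, fg_count, bg_count, odds_ratio, p, q sorted by p.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise FeatureAnalysisError("foreground must be a subset of the background")
    out = bg - fg
    kw_fg: dict[str, int] = {}
    kw_bg: dict[str, int] = {}
    for prot in bg:
        for kw in annotations.get(prot, ()):
            kw_bg[kw] = kw_bg.get(kw, 0) + 1
            if prot in fg:
                kw_fg[kw] = kw_fg.get(kw, 0) + 1
    rows = []
    for kw, fg_count in sorted(kw_fg.items()):
        bg_count = kw_bg[kw]
        table = [
            [fg_count, len(fg) - fg_count],
            [bg_count - fg_count, len(out) - (bg_count - fg_count)],
        ]
        odds, p = stats.fisher_exact(table, alternative=alternative)
        rows.append(
            {"keyword": kw, "fg_count": fg_count, "bg_count": bg_count,
             "odds_ratio": float(odds), "p": float(p)}
        )
    df = pd.DataFrame(rows, columns=["keyword", "fg_count", "bg_count", "odds_ratio", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df.sort_values(["p", "keyword"], kind="mergesort").reset_index(drop=True)


def compare_sets_property(
    stabilized: Iterable[str],
    destabilized: Iterable[str],
    null_set: Iterable[str],
    property_values: Mapping[str, float],
) -> pd.DataFrame:
    """Pairwise Mann–Whitney comparisons of one property across the three
    stability classes, with the effect direction as a difference of medians.

    Comparisons involving an empty set (or a set with no property values)
    are skipped with a warning.
    """
    sets = {
        "stabilized": set(stabilized),
        "destabilized": set(destabilized),
        "null": set(null_set),
    }
    values = {
        name: np.asarray(
            [property_values[p] for p in members if p in property_values], dtype=float
        )
        for name, members in sets.items()
    }
    pairs = [("stabilized", "null"), ("destabilized", "null"), ("stabilized", "destabilized")]
    rows = []
    for name_a, name_b in pairs:
        a, b = values[name_a], values[name_b]
        if a.size == 0 or b.size == 0:
            log.warning("comparison %s vs %s skipped: empty set", name_a, name_b)
            continue
        res = compare_param_distributions(a, b)
        rows.append(
            {
                "set_a": name_a,
                "set_b": name_b,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "u": res.u,
                "p": res.p,
                "median_difference": float(np.median(a) - np.median(b)),
            }
        )
    return pd.DataFrame(
        rows, columns=["set_a", "set_b", "n_a", "n_b", "u", "p", "median_difference"]
    )
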