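"""Reading and writing the pipeline's tabular artifacts.

Quantification tables are tab-separated UTF-8 with a header row, one row per
protein group and one reporter-intensity column per TMT channel (MaxQuant
proteinGroups style).  Column names are never hard-coded: a channel→
temperature map supplied by the user (YAML or TSV) selects and orders the
intensity columns.  Rows flagged as reverse-database or contaminant matches
("+" in the conventional columns) are dropped and counted.  Missing
intensities stay missing (NaN) — zero is a valid measured intensity.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import re
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "QuantIOError",
    "QuantFormatError",
    "ValidationError",
    "ProteomeQuant",
    "DEFAULT_TEMPERATURES",
    "default_channel_map",
    "read_channel_map",
    "write_channel_map",
    "read_quant_table",
    "write_quant_table",
    "read_crowder_properties",
    "read_fasta",
    "read_annotations",
    "write_table",
    "read_table",
    "write_results",
]


class QuantIOError(Exception):
    """Base class for artifact I/O failures."""


class QuantFormatError(QuantIOError):
    """A file does not have the expected structure (columns, dtypes, keys)."""


class ValidationError(QuantIOError):
    """A table parsed but violates a domain invariant."""


#: The 10-point thermal gradient used throughout (°C).
DEFAULT_TEMPERATURES = (30.0, 34.0, 38.0, 43.0, 47.0, 52.0, 56.0, 60.0, 66.0, 70.0)

_ID_COLUMN_CANDIDATES = ("protein_id", "Protein IDs", "Majority protein IDs", "Accession")
_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Contaminant")
_REPORTER_RE = re.compile(r"reporter intensity", re.IGNORECASE)

CROWDER_DESCRIPTORS = (
    "molecular_weight",
    "intrinsic_viscosity",
    "polar_atom_fraction",
    "hydrophobicity_index",
    "topology",
)


@dataclasses.dataclass
class ProteomeQuant:
    """One condition's proteins × temperatures reporter-intensity matrix.

    Channels are ordered by ascending temperature and rows sorted by
    accession, so the in-memory layout never depends on input file order.
    """

    protein_ids: list[str]
    intensities: np.ndarray
    temperatures: np.ndarray
    condition: str
    abundance: np.ndarray | None = None
    n_flagged_dropped: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        n, k = self.intensities.shape
        if len(self.protein_ids) != n:
            raise ValidationError("protein_ids length must match intensity rows")
        if len(self.temperatures) != k:
            raise ValidationError("temperatures length must equal channel count")
        if len(set(self.protein_ids)) != n:
            dupes = pd.Series(self.protein_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate protein accessions: {dupes}")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValidationError("temperatures must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise ValidationError("intensities must be ≥ 0 or missing")
        if self.abundance is not None:
            self.abundance = np.asarray(self.abundance, dtype=float)
            if self.abundance.shape != (n,):
                raise ValidationError("abundance length must match protein count")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


def default_channel_map(
    temperatures=DEFAULT_TEMPERATURES,
    prefix: str = "Reporter intensity corrected",
) -> dict[str, float]:
    """MaxQuant-style channel→temperature map for the default gradient."""
    return {f"{prefix} {i + 1}": float(t) for i, t in enumerate(temperatures)}


def read_channel_map(path: str | os.PathLike) -> dict[str, float]:
    """Read a channel→temperature map from YAML (mapping) or TSV (two columns)."""
    path = os.fspath(path)
    if path.endswith((".yaml", ".yml")):
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping) or not raw:
            raise QuantFormatError("channel map YAML must be a non-empty mapping")
        return {str(k): float(v) for k, v in raw.items()}
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for chan_col, temp_col in (("channel", "temperature_c"), ("channel", "temperature")):
        if chan_col in df.columns and temp_col in df.columns:
            return dict(zip(df[chan_col].astype(str), df[temp_col].astype(float)))
    raise QuantFormatError(
        "channel map TSV needs columns 'channel' and 'temperature_c'"
    )


def write_channel_map(channel_map: Mapping[str, float], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"channel": list(channel_map), "temperature_c": list(channel_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_quant_table(
    path: str | os.PathLike,
    channel_map: Mapping[str, float],
    condition: str,
    id_column: str | None = None,
    abundance_column: str | None = None,
) -> ProteomeQuant:
    """Read one condition's protein-level quantification TSV.

    Every channel named in ``channel_map`` must be a column; temperatures
    must be distinct.  Reporter-intensity-like columns not covered by the
    map are ignored with a warning.  Flagged decoy/contaminant rows are
    dropped and counted in ``n_flagged_dropped``.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty:
        raise QuantFormatError(f"empty quantification table: {path}")

    if id_column is None:
        for cand in _ID_COLUMN_CANDIDATES:
            if cand in df.columns:
                id_column = cand
                break
        else:
            raise QuantFormatError(
                f"no accession column among {_ID_COLUMN_CANDIDATES} in {path}"
            )
    elif id_column not in df.columns:
        raise QuantFormatError(f"missing accession column {id_column!r} in {path}")

    missing = [c for c in channel_map if c not in df.columns]
    if missing:
        raise QuantFormatError(f"missing channel column(s) {missing} in {path}")

    temps = [float(channel_map[c]) for c in channel_map]
    if len(set(temps)) != len(temps):
        raise ValidationError("channel map temperatures must be distinct")

    unmapped = [
        c for c in df.columns if _REPORTER_RE.search(str(c)) and c not in channel_map
    ]
    if unmapped:
        log.warning("ignoring unmapped reporter column(s): %s", unmapped)

    n_flagged = 0
    for col in _FLAG_COLUMNS:
        if col in df.columns:
            flagged = df[col].astype(str).str.strip() == "+"
            n_flagged += int(flagged.sum())
            df = df.loc[~flagged]

    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise QuantFormatError(f"duplicate accession(s) in {path}: {dupes}")

    df = df.assign(**{id_column: ids}).sort_values(id_column, kind="mergesort")
    order = sorted(channel_map, key=lambda c: channel_map[c])
    intensities = df[order].to_numpy(dtype=float)
    abundance = None
    if abundance_column is not None:
        if abundance_column not in df.columns:
            raise QuantFormatError(f"missing abundance column {abundance_column!r}")
        abundance = df[abundance_column].to_numpy(dtype=float)
    return ProteomeQuant(
        protein_ids=df[id_column].tolist(),
        intensities=intensities,
        temperatures=np.array(sorted(temps)),
        condition=condition,
        abundance=abundance,
        n_flagged_dropped=n_flagged,
    )


def write_quant_table(
    quant: ProteomeQuant,
    path: str | os.PathLike,
    channel_prefix: str = "Reporter intensity corrected",
    abundance_column: str = "LFQ intensity",
) -> dict[str, float]:
    """Write a ProteomeQuant in the dialect :func:`read_quant_table` reads.

    Returns the channel map describing the written columns.
    """
    channel_map = default_channel_map(quant.temperatures, prefix=channel_prefix)
    data = {"protein_id": quant.protein_ids}
    for j, chan in enumerate(channel_map):
        data[chan] = quant.intensities[:, j]
    if quant.abundance is not None:
        data[abundance_column] = quant.abundance
    # no float_format: shortest exact repr, so write→read is lossless and
    # stage-wise runs reproduce in-memory runs bit for bit
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    return channel_map


def read_crowder_properties(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-reagent physico-chemical descriptor table.

    Requires a ``reagent`` column plus the five descriptors (molecular
    weight in kDa, intrinsic viscosity in mL/g, polar atom fraction,
    hydrophobicity index, topology).  Extra columns are preserved untouched.
    Returns a DataFrame indexed by reagent.
    """
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise QuantFormatError(f"empty crowder property table: {path}") from None
    if df.empty:
        raise QuantFormatError(f"crowder property table has no rows: {path}")
    required = ("reagent",) + CROWDER_DESCRIPTORS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise QuantFormatError(f"missing crowder property column(s): {missing}")
    if df["reagent"].duplicated().any():
        raise ValidationError("reagent names must be unique")
    paf = df["polar_atom_fraction"].astype(float)
    if ((paf < 0) | (paf > 1)).any():
        bad = df.loc[(paf < 0) | (paf > 1), "reagent"].tolist()
        raise ValidationError(f"polar_atom_fraction outside [0, 1] for {bad}")
    return df.set_index("reagent")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Protein sequences keyed by accession (UniProt ``sp|ACC|NAME`` headers unwrapped)."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(os.fspath(path), "fasta"):
        acc = record.id
        parts = acc.split("|")
        if len(parts) == 3:
            acc = parts[1]
        seqs[acc] = str(record.seq)
    return seqs


def read_annotations(path: str | os.PathLike) -> dict[str, set[str]]:
    """Long-format TSV (protein, keyword) → accession → set of keywords."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    prot_col = cols.get("protein") or cols.get("protein_id")
    kw_col = cols.get("keyword")
    if prot_col is None or kw_col is None:
        raise QuantFormatError("annotation table needs 'protein' and 'keyword' columns")
    out: dict[str, set[str]] = {}
    for prot, kw in zip(df[prot_col].astype(str), df[kw_col].astype(str)):
        kw = kw.strip()
        if not kw:
            raise ValidationError(f"empty keyword for protein {prot}")
        out.setdefault(prot, set()).add(kw)
    return out


# ---------------------------------------------------------------------------
# generic results tables


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table as TSV with ≥ 10 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# pandas' default NA tokens minus "null", which is a stability-call class
_NA_TOKENS = [
    "", "#N/A", "#N/A N/A", "#NA", "-1.#IND", "-1.#QNAN", "-NaN", "-nan",
    "1.#IND", "1.#QNAN", "<NA>", "N/A", "NA", "NULL", "NaN", "None", "n/a", "nan",
]


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=_NA_TOKENS, keep_default_na=False,
        float_precision="round_trip",
    )


def write_results(
    fits: pd.DataFrame,
    calls: pd.DataFrame,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Write fits.tsv, calls.tsv and a per-condition summary.tsv.

    Column order is fixed; empty collections yield headers-only files.
    Returns the mapping of artifact name → written path.
    """
    os.makedirs(outdir, exist_ok=True)
    fit_cols = [
        "protein", "condition", "a", "b", "plateau", "tm", "slope", "r2",
        "converged", "qc_pass", "qc_reasons",
    ]
    call_cols = ["protein", "crowder", "delta_tm", "z", "call"]
    fits_out = fits.reindex(columns=fit_cols)
    calls_out = calls.reindex(columns=call_cols)
    bad = set(calls_out["call"].dropna()) - {"stabilized", "destabilized", "null"}
    if bad:
        raise ValidationError(f"unknown stability call class(es): {sorted(bad)}")

    paths = {
        "fits": os.path.join(outdir, "fits.tsv"),
        "calls": os.path.join(outdir, "calls.tsv"),
        "summary": os.path.join(outdir, "summary.tsv"),
    }
    write_table(fits_out, paths["fits"])
    write_table(calls_out, paths["calls"])

    if len(fits_out):
        summary = (
            fits_out.groupby("condition", sort=True)
            .agg(
                n_proteins=("protein", "size"),
                n_converged=("converged", "sum"),
                n_qc_pass=("qc_pass", "sum"),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["condition", "n_proteins", "n_converged", "n_qc_pass"])
    if len(calls_out):
        call_counts = (
            calls_out.pivot_table(
                index="crowder", columns="call", values="protein", aggfunc="count", fill_value=0
            )
            .reindex(columns=["stabilized", "destabilized", "null"], fill_value=0)
            .reset_index()
            .rename(columns={"crowder": "condition"})
        )
        summary = summary.merge(call_counts, on="condition", how="left")
    write_table(summary, paths["summary"])
    return paths
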