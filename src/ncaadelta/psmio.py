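"""PSM table I/O, quality filtering and ncAA observation extraction.

The pipeline's input atom is one peptide-spectrum match (PSM) from an open
(wildcard) database search: a peptide identified in a protein, optionally
carrying a localized mass offset ("delta mass") on one residue, plus the
search engine's quality scores.  This module reads the tab-separated dialect
produced by such searches (and by :mod:`ncaadelta.simdata`), applies the
score/FDR filters, and derives the non-coded amino acid (ncAA) observations:
residue-localized nonzero delta masses rounded to four decimal places.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

#: Canonical internal column names, in output order.
CANONICAL_COLUMNS = [
    "spectrum_id", "group", "bio_replicate", "tech_replicate",
    "peptide", "protein_id", "protein_start", "mod_site",
    "delta_mass", "peptide_mass",
    "score", "delta_mods_score", "fdr2d", "fdr_uniq2d",
]

#: Header-name synonym maps per dialect.  The "byonic" dialect mirrors the
#: wildcard-search export this pipeline consumes.
DIALECTS: dict[str, dict[str, str]] = {
    "byonic": {
        "Spectrum": "spectrum_id",
        "Group": "group",
        "BioReplicate": "bio_replicate",
        "TechReplicate": "tech_replicate",
        "Peptide": "peptide",
        "ProteinId": "protein_id",
        "ProteinStart": "protein_start",
        "ModSite": "mod_site",
        "DeltaMass": "delta_mass",
        "PeptideMass": "peptide_mass",
        "Score": "score",
        "DeltaModsScore": "delta_mods_score",
        "FDR2D": "fdr2d",
        "FDR_uniq.2D": "fdr_uniq2d",
    },
}
#: Identity dialect: file already uses canonical names.
DIALECTS["canonical"] = {c: c for c in CANONICAL_COLUMNS}

_NUMERIC = ["protein_start", "mod_site", "delta_mass", "peptide_mass",
            "score", "delta_mods_score", "fdr2d", "fdr_uniq2d"]
_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


@dataclass
class PsmFilterConfig:
    """Quality thresholds applied to PSM rows (all boundaries inclusive)."""

    min_score: float = 300.0
    min_delta_mods_score: float = 10.0
    max_fdr2d: float = 0.01
    max_fdr_uniq2d: float = 0.01
    #: ncAA cutoff: only |delta mass| strictly above this is a candidate.
    min_abs_delta: float = 0.01
    #: apply the delta cutoff to the signed value instead of |delta|
    signed_cutoff: bool = False

    def __post_init__(self):
        vals = [self.min_score, self.min_delta_mods_score,
                self.max_fdr2d, self.max_fdr_uniq2d, self.min_abs_delta]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("filter thresholds must be finite")
        if self.min_abs_delta < 0:
            raise ValueError("min_abs_delta must be >= 0")


def round4(x):
    """Round to 4 decimals, half away from zero (platform-stable)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) * 1e4 + 0.5) / 1e4


def read_psm_table(source, dialect: str = "byonic") -> pd.DataFrame:
    """Read a PSM TSV into the canonical frame.

    Rows violating the record invariants (non-numeric cells, mod_site outside
    the peptide, FDR outside [0, 1], non-residue characters, multi-site
    cells) are rejected with row-numbered diagnostics collected in
    ``df.attrs["diagnostics"]`` and logged; order of surviving rows is
    preserved.  A missing required column raises :class:`FormatError` naming
    it.
    """
    colmap = DIALECTS[dialect]
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    missing = [src for src in colmap if src not in df.columns]
    if missing:
        raise FormatError(f"PSM table missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=colmap)[CANONICAL_COLUMNS]
    diagnostics: list[str] = []
    bad = pd.Series(False, index=df.index)
    for col in _NUMERIC:
        num = pd.to_numeric(df[col], errors="coerce")
        nb = num.isna()
        for i in df.index[nb & ~bad]:
            diagnostics.append(f"row {i + 2}: unparseable {col!r} value {df.at[i, col]!r}")
        bad |= nb
        df[col] = num
    ok = ~bad
    pep_ok = df["peptide"].fillna("").str.match(_PEPTIDE_RE)
    for i in df.index[ok & ~pep_ok]:
        diagnostics.append(f"row {i + 2}: peptide is not an uppercase residue string")
    ok &= pep_ok
    plen = df["peptide"].str.len().fillna(0)
    site_ok = (df["mod_site"] >= 0) & (df["mod_site"] <= plen) & (df["mod_site"] % 1 == 0)
    for i in df.index[ok & ~site_ok]:
        diagnostics.append(f"row {i + 2}: mod_site {df.at[i, 'mod_site']} outside peptide")
    ok &= site_ok
    fdr_ok = df["fdr2d"].between(0, 1) & df["fdr_uniq2d"].between(0, 1)
    for i in df.index[ok & ~fdr_ok]:
        diagnostics.append(f"row {i + 2}: FDR value outside [0, 1]")
    ok &= fdr_ok
    out = df.loc[ok].reset_index(drop=True)
    out["protein_start"] = out["protein_start"].astype(int)
    out["mod_site"] = out["mod_site"].astype(int)
    for col in ("bio_replicate", "tech_replicate"):
        out[col] = pd.to_numeric(out[col], errors="coerce").fillna(0).astype(int)
    out.attrs["diagnostics"] = diagnostics
    if diagnostics:
        log.warning("read_psm_table rejected %d row(s); first: %s",
                    len(diagnostics), diagnostics[0])
    return out


def write_psm_table(df: pd.DataFrame, path, dialect: str = "byonic",
                    header_comment: str | None = None) -> None:
    """Write a canonical PSM frame back to the TSV dialect."""
    inv = {v: k for k, v in DIALECTS[dialect].items()}
    out = df[CANONICAL_COLUMNS].rename(columns=inv)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)


def filter_psms(df: pd.DataFrame, config: PsmFilterConfig | None = None) -> pd.DataFrame:
    """Retain rows passing all four quality gates (boundaries inclusive):
    score >= min_score, delta_mods_score >= min_delta_mods_score,
    fdr2d <= max_fdr2d, fdr_uniq2d <= max_fdr_uniq2d.
    """
    config = config or PsmFilterConfig()
    mask = (
        (df["score"] >= config.min_score)
        & (df["delta_mods_score"] >= config.min_delta_mods_score)
        & (df["fdr2d"] <= config.max_fdr2d)
        & (df["fdr_uniq2d"] <= config.max_fdr_uniq2d)
    )
    out = df.loc[mask].reset_index(drop=True)
    log.info("filter_psms: retained %d / %d rows (dropped %d)",
             len(out), len(df), len(df) - len(out))
    return out


OBSERVATION_COLUMNS = [
    "protein_id", "protein_position", "residue",
    "delta_mass_raw", "delta_mass_4dp", "peptide_mass",
    "group", "bio_replicate", "tech_replicate",
]


def extract_ncaa_observations(df: pd.DataFrame,
                              config: PsmFilterConfig | None = None) -> pd.DataFrame:
    """Derive ncAA observations from (already filtered) PSM rows.

    One observation per row with a localized site (mod_site > 0) and a delta
    mass strictly beyond the 0.01-Da noise floor; the site is mapped to
    protein coordinates (1-based) and the delta rounded to 4 decimals.  Rows
    claiming a site but carrying delta 0 are skipped with a warning.
    """
    config = config or PsmFilterConfig()
    sited = df["mod_site"] > 0
    n_zero_site = int((sited & (df["delta_mass"] == 0)).sum())
    if n_zero_site:
        log.warning("extract_ncaa_observations: %d row(s) with mod_site > 0 "
                    "but delta 0 skipped", n_zero_site)
    if config.signed_cutoff:
        beyond = df["delta_mass"] > config.min_abs_delta
    else:
        beyond = df["delta_mass"].abs() > config.min_abs_delta
    sel = df.loc[sited & beyond]
    pos = sel["protein_start"] + sel["mod_site"] - 1
    residues = [p[s - 1] for p, s in zip(sel["peptide"], sel["mod_site"])]
    obs = pd.DataFrame({
        "protein_id": sel["protein_id"].to_numpy(),
        "protein_position": pos.to_numpy(),
        "residue": residues,
        "delta_mass_raw": sel["delta_mass"].to_numpy(),
        "delta_mass_4dp": round4(sel["delta_mass"].to_numpy()),
        "peptide_mass": sel["peptide_mass"].to_numpy(),
        "group": sel["group"].to_numpy(),
        "bio_replicate": sel["bio_replicate"].to_numpy(),
        "tech_replicate": sel["tech_replicate"].to_numpy(),
    })
    return obs


def occurrence_frequencies(obs: pd.DataFrame) -> pd.Series:
    """Frequency of each rounded delta mass (redundancy count).

    Returns a Series indexed by delta_mass_4dp, sorted by descending count;
    counts sum to the number of observations.
    """
    if obs.empty:
        return pd.Series(dtype=int, name="frequency")
    counts = obs["delta_mass_4dp"].value_counts()
    counts.name = "frequency"
    counts.index.name = "delta_mass_4dp"
    return counts


def write_observations(obs: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        obs.to_csv(fh, sep="\t", index=False)


def replicate_totals(filtered: pd.DataFrame) -> pd.DataFrame:
    """Filtered-PSM count per (group, bio_replicate, tech_replicate) —
    the denominators for spectral-count normalization."""
    totals = (filtered.groupby(["group", "bio_replicate", "tech_replicate"])
              .size().rename("total").reset_index())
    return totals
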