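"""Annotation of clustered delta masses with known PTMs and substitutions.

A clustered delta mass (the fitted Gaussian peak of a 1-Da window component)
is matched against two sources of candidate explanations:

* a bundled snapshot of common post-translational modifications with their
  monoisotopic mass shifts (a small curated table, not a live UniMod dump —
  reproducibility over completeness), and
* the full matrix of 380 ordered single-residue substitutions, whose mass
  shifts follow directly from the residue monoisotopic masses.

A cluster that matches nothing within tolerance can still be *assigned* as a
real chemical event when its Gaussian fit is good (R^2 > 0.5) and/or when it
sits predominantly on a single amino acid (> 50% of members); otherwise it
stays unassigned.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

# Monoisotopic residue masses (Da) of the 20 standard amino acids.
# These are physical constants (sum of the residue's atomic monoisotopic
# masses); precision here is ~1e-5 Da, far below any tolerance in use.
AA_MONO: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Monoisotopic mass of water, added to the residue sum for a neutral peptide.
WATER_MONO: float = 18.010565

AA_THREE: dict[str, str] = {
    "G": "Gly", "A": "Ala", "S": "Ser", "P": "Pro", "V": "Val",
    "T": "Thr", "C": "Cys", "L": "Leu", "I": "Ile", "N": "Asn",
    "D": "Asp", "Q": "Gln", "K": "Lys", "E": "Glu", "M": "Met",
    "H": "His", "F": "Phe", "R": "Arg", "Y": "Tyr", "W": "Trp",
}

DB_COLUMNS = ["name", "source_db", "mono_delta", "kind", "targets"]


def peptide_mono_mass(peptide: str) -> float:
    """Neutral monoisotopic mass of an unmodified peptide."""
    return sum(AA_MONO[a] for a in peptide) + WATER_MONO


def load_mod_database(path=None) -> pd.DataFrame:
    """Load a modification-mass table (TSV: name, source_db, mono_delta,
    kind, targets).

    With no ``path`` the bundled PTM snapshot is used.  Duplicate rows are
    collapsed; a malformed mass raises :class:`FormatError` naming the row.
    An empty file yields an empty table (with a warning via the return
    value's length — callers log it).
    """
    if path is None:
        ref = importlib.resources.files("ncaadelta.data") / "modifications.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_mod_database(p)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in DB_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"modification table missing column(s): {', '.join(missing)}")
    if df.empty:
        return df.assign(mono_delta=pd.Series(dtype=float))[DB_COLUMNS]
    mono = pd.to_numeric(df["mono_delta"], errors="coerce")
    bad = df.index[mono.isna() | ~np.isfinite(mono.fillna(np.inf))]
    if len(bad):
        raise FormatError(f"malformed mono_delta in modification table row(s): {list(bad + 2)}")
    df = df.assign(mono_delta=mono.astype(float))
    df = df.drop_duplicates(subset=DB_COLUMNS).reset_index(drop=True)
    return df[DB_COLUMNS]


def build_substitution_masses() -> pd.DataFrame:
    """All 380 ordered single-residue substitution deltas.

    Every ordered pair X -> Y of distinct standard residues contributes one
    entry with delta = mass(Y) - mass(X).  Pairs with delta exactly zero
    (Leu <-> Ile isomers) are retained but flagged indistinguishable in the
    ``note`` column, since no mass measurement can separate them.
    """
    rows = []
    for x, mx in AA_MONO.items():
        for y, my in AA_MONO.items():
            if x == y:
                continue
            delta = my - mx
            rows.append({
                "name": f"{AA_THREE[x]}->{AA_THREE[y]}",
                "source_db": "substitution",
                "mono_delta": delta,
                "kind": "substitution",
                "targets": x,
                "note": "indistinguishable-isomer" if delta == 0.0 else "",
            })
    return pd.DataFrame(rows)


def full_annotation_database(ptm_path=None) -> pd.DataFrame:
    """Bundled PTM snapshot plus the substitution matrix, one table."""
    ptm = load_mod_database(ptm_path).assign(note="")
    sub = build_substitution_masses()
    return pd.concat([ptm, sub], ignore_index=True)


@dataclass
class ClusterAnnotation:
    """Annotation outcome for one delta-mass cluster.

    ``matches`` holds every database entry within the mass tolerance, sorted
    by absolute error, with the error expressed both in Da and as ppm of the
    cluster members' median peptide mass.
    """

    cluster_id: str
    peak: float
    status: str  # matched | assigned_unmatched | unassigned
    substitution_flag: bool
    matches: pd.DataFrame = field(repr=False)
    best_match: str = ""

    def as_row(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "peak": self.peak,
            "status": self.status,
            "substitution_flag": self.substitution_flag,
            "n_matches": len(self.matches),
            "best_match": self.best_match,
            "all_matches": ";".join(self.matches["name"]) if len(self.matches) else "",
        }


def annotate_cluster(cluster, db: pd.DataFrame, tolerance_da: float = 0.005) -> ClusterAnnotation:
    """Match one cluster's peak against the modification database.

    status is ``matched`` when at least one entry lies within
    ``tolerance_da`` of the peak; an unmatched cluster is
    ``assigned_unmatched`` when R^2 > 0.5 and/or its dominant residue
    fraction exceeds 0.5, else ``unassigned``.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be positive")
    err = (db["mono_delta"] - cluster.peak).abs() if len(db) else pd.Series(dtype=float)
    hits = db.loc[err <= tolerance_da].copy() if len(db) else db.copy()
    if len(hits):
        hits["err_da"] = hits["mono_delta"] - cluster.peak
        med = getattr(cluster, "median_peptide_mass", np.nan)
        hits["err_ppm"] = hits["err_da"] / med * 1e6 if np.isfinite(med) and med > 0 else np.nan
        hits = hits.reindex(hits["err_da"].abs().sort_values(kind="stable").index)
        hits = hits.reset_index(drop=True)
        status = "matched"
    elif cluster.r2 > 0.5 or cluster.dominant_fraction > 0.5:
        status = "assigned_unmatched"
    else:
        status = "unassigned"
    return ClusterAnnotation(
        cluster_id=cluster.cluster_id,
        peak=cluster.peak,
        status=status,
        substitution_flag=bool(len(hits) and (hits["kind"] == "substitution").any()),
        matches=hits,
        best_match=hits["name"].iloc[0] if len(hits) else "",
    )


def annotate_clusters(clusters, db: pd.DataFrame, tolerance_da: float = 0.005):
    """Annotate a list of clusters; returns (annotations, summary table)."""
    anns = [annotate_cluster(c, db, tolerance_da) for c in clusters]
    table = pd.DataFrame([a.as_row() for a in anns]) if anns else pd.DataFrame(
        columns=["cluster_id", "peak", "status", "substitution_flag",
                 "n_matches", "best_match", "all_matches"])
    return anns, table
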