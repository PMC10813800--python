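"""Model/Results interface tying the pipeline stages together.

:class:`DeltaMassModel` is constructed from a PSM table (a pandas frame in
the canonical dialect, or a TSV via :meth:`DeltaMassModel.from_tsv`) plus the
analysis parameters; :meth:`DeltaMassModel.fit` runs

    filter -> extract -> window -> mixture/BIC -> constraints/regression
           -> annotate -> quantify -> differential -> reports

and returns a :class:`DeltaMassResults` carrying every intermediate table,
the accepted clusters with their uncertainties (SD, R^2), the differential
statistics, and a ``summary()`` text table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_clusters, full_annotation_database
from .cluster import ClusterParams, cluster_observations, cluster_table
from .diffmod import (differential_clusters, differential_residues,
                      protein_frequency_table, residue_level_report,
                      table1_layout)
from .psmio import (PsmFilterConfig, extract_ncaa_observations, filter_psms,
                    occurrence_frequencies, read_psm_table, replicate_totals,
                    write_observations)


class DeltaMassModel:
    """Clustered delta-mass analysis of an open-search PSM table.

    Parameters
    ----------
    psms : pandas.DataFrame
        Canonical PSM frame (see :mod:`ncaadelta.psmio`).
    filter_config : PsmFilterConfig
        Score/FDR/delta thresholds.
    cluster_params : ClusterParams
        Windowing, mixture and constraint settings.
    tolerance_da : float
        Annotation match tolerance in Da.
    pseudocount : float
        Added to both group means before the ratio.
    test : {"student", "welch"}
        t-test variant for the group comparison.
    mod_database : pandas.DataFrame, optional
        PTM + substitution table; defaults to the bundled snapshot plus the
        380-entry substitution matrix.
    """

    def __init__(self, psms: pd.DataFrame, *,
                 filter_config: PsmFilterConfig | None = None,
                 cluster_params: ClusterParams | None = None,
                 tolerance_da: float = 0.005,
                 pseudocount: float = 0.5,
                 test: str = "student",
                 fdr_correct: bool = False,
                 mod_database: pd.DataFrame | None = None):
        self.psms = psms
        self.filter_config = filter_config or PsmFilterConfig()
        self.cluster_params = cluster_params or ClusterParams()
        self.tolerance_da = tolerance_da
        self.pseudocount = pseudocount
        self.test = test
        self.fdr_correct = fdr_correct
        self.mod_database = (mod_database if mod_database is not None
                             else full_annotation_database())

    @classmethod
    def from_tsv(cls, path, dialect: str = "byonic", **kwargs) -> "DeltaMassModel":
        return cls(read_psm_table(path, dialect=dialect), **kwargs)

    def config_dict(self) -> dict:
        return {
            "version": __version__,
            "filter": asdict(self.filter_config),
            "cluster": asdict(self.cluster_params),
            "tolerance_da": self.tolerance_da,
            "pseudocount": self.pseudocount,
            "test": self.test,
            "fdr_correct": self.fdr_correct,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.config_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def fit(self, seed: int = 0) -> "DeltaMassResults":
        filtered = filter_psms(self.psms, self.filter_config)
        observations = extract_ncaa_observations(filtered, self.filter_config)
        totals = replicate_totals(filtered)
        occurrence = occurrence_frequencies(observations)
        clusters, window_report = cluster_observations(
            observations, self.cluster_params, seed=seed)
        annotations, annotation_table = annotate_clusters(
            clusters, self.mod_database, self.tolerance_da)
        differential = differential_clusters(
            clusters, observations, totals,
            self.pseudocount, self.test, self.fdr_correct)
        residue_diff = differential_residues(
            clusters, observations, totals,
            self.pseudocount, self.test, self.fdr_correct)
        points = residue_level_report(residue_diff)
        freq = protein_frequency_table(points)
        return DeltaMassResults(
            model=self, seed=seed, n_input=len(self.psms),
            filtered=filtered, observations=observations, totals=totals,
            occurrence=occurrence, clusters=clusters,
            window_report=window_report, annotations=annotations,
            annotation_table=annotation_table, differential=differential,
            residue_differential=residue_diff, points=points,
            protein_frequencies=freq)


class DeltaMassResults:
    """Fitted results: clusters, annotations and differential statistics."""

    def __init__(self, model, seed, n_input, filtered, observations, totals,
                 occurrence, clusters, window_report, annotations,
                 annotation_table, differential, residue_differential,
                 points, protein_frequencies):
        self.model = model
        self.seed = seed
        self.n_input = n_input
        self.filtered = filtered
        self.observations = observations
        self.totals = totals
        self.occurrence = occurrence
        self.clusters = clusters
        self.window_report = window_report
        self.annotations = annotations
        self.annotation_table = annotation_table
        self.differential = differential
        self.residue_differential = residue_differential
        self.points = points
        self.protein_frequencies = protein_frequencies

    @property
    def cluster_summary(self) -> pd.DataFrame:
        """Cluster table joined with annotation and differential columns."""
        base = cluster_table(self.clusters)
        if base.empty:
            return base
        ann = self.annotation_table[["cluster_id", "status", "best_match",
                                     "substitution_flag"]]
        diff = self.differential[["cluster_id", "mean_control", "mean_ischemia",
                                  "ratio", "p_value", "significant", "direction"]]
        return base.merge(ann, on="cluster_id").merge(diff, on="cluster_id")

    def summary(self) -> str:
        """Human-readable report of the fit."""
        lines = [
            "Clustered delta-mass analysis",
            "=" * 64,
            f"input PSMs:            {self.n_input}",
            f"filtered PSMs:         {len(self.filtered)}",
            f"ncAA observations:     {len(self.observations)}",
            f"distinct 4-dp deltas:  {len(self.occurrence)}",
            f"accepted clusters:     {len(self.clusters)}",
            f"significant clusters:  {int(self.differential['significant'].sum()) if len(self.differential) else 0}",
            f"seed: {self.seed}   config: {self.model.config_hash()}",
            "",
        ]
        cs = self.cluster_summary
        if len(cs):
            show = cs[["cluster_id", "window_n", "peak", "sd", "r2", "size",
                       "dominant_residue", "best_match", "ratio", "p_value",
                       "significant", "direction"]].copy()
            lines.append(show.to_string(
                index=False, float_format=lambda v: f"{v:.4f}"))
        else:
            lines.append("(no clusters passed the constraints)")
        return "\n".join(lines)

    def save(self, outdir) -> Path:
        """Write all report tables (TSV + JSON) into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = (f"ncaadelta {__version__} | seed={self.seed} "
                  f"| config={self.model.config_hash()}")
        write_observations(self.observations, outdir / "observations.tsv", header)

        def _tsv(df, name):
            with open(outdir / name, "w") as fh:
                fh.write(f"# {header}\n")
                df.to_csv(fh, sep="\t", index=False)

        _tsv(self.occurrence.reset_index(), "occurrence.tsv")
        _tsv(self.cluster_summary, "clusters.tsv")
        _tsv(self.annotation_table, "annotations.tsv")
        _tsv(self.differential, "differential.tsv")
        _tsv(self.residue_differential, "residue_differential.tsv")
        _tsv(self.points, "residue_points.tsv")
        _tsv(table1_layout(self.protein_frequencies), "protein_frequencies.tsv")
        members = pd.DataFrame(
            [(c.cluster_id, int(i)) for c in self.clusters for i in c.members],
            columns=["cluster_id", "observation_row"])
        _tsv(members, "cluster_members.tsv")
        with open(outdir / "window_report.json", "w") as fh:
            json.dump({"header": header, **self.window_report}, fh, indent=1)
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        return outdir
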