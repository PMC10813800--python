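"""Seeded synthetic proteomes and wildcard-search PSM tables.

The generator emulates the statistical structure of an open-search bottom-up
proteomics experiment on a two-group design (control vs ischemia, 3
biological samples per group, 3 technical LC-MS/MS replicates each): a small
random proteome is digested tryptically, peptides are "identified" as PSM
rows, and a chosen set of modification sites carries a planted delta mass at
a group-specific rate, perturbed by instrument-like ppm mass error.  Score
columns mimic the search engine's quality metadata so the downstream filters
have something to act on.

Nothing at the spectrum level is simulated (no peak lists): the pipeline's
input atom is the search-engine PSM row, and that is what is produced.
Ground truth (which site carries which delta at which rate) is recorded so
recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotate import AA_MONO, peptide_mono_mass
from .errors import ConfigurationError, GenerationError
from .psmio import CANONICAL_COLUMNS

STANDARD_AA = "".join(sorted(AA_MONO))

#: Score-column generators: location/scale for rows meant to pass the
#: downstream quality filters ("true") vs rows meant to fail ("decoy").
DEFAULT_SCORE_DISTRIBUTIONS = {
    "true": {"score": (650.0, 120.0), "delta_mods_score": (60.0, 18.0),
             "fdr_max": 0.009},
    "decoy": {"score": (150.0, 80.0), "delta_mods_score": (4.0, 4.0),
              "fdr_max": 0.08},
}


@dataclass
class SyntheticConfig:
    """Shape and noise parameters of one simulated experiment.

    Defaults are the package's reference study conditions: a 12-protein
    proteome, 3 vs 3 biological samples with 3 technical replicates each,
    3000 PSMs per technical replicate and 5 ppm mass error — enough depth
    that each planted site accrues several hundred observations, pinning
    its fitted peak to well under a milli-dalton.
    """

    n_proteins: int = 12
    protein_length_range: tuple[int, int] = (40, 60)
    n_bio_per_group: int = 3
    n_tech_per_bio: int = 3
    psms_per_tech: int = 3000
    mass_error_ppm_sd: float = 5.0
    #: probability a PSM is drawn from peptides with no planted site
    background_unmodified_fraction: float = 0.6
    #: fraction of rows whose score columns are drawn from the failing model
    decoy_fraction: float = 0.05
    score_distributions: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCORE_DISTRIBUTIONS.items()})
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.protein_length_range
        if lo > hi:
            raise ConfigurationError(
                f"protein_length_range min {lo} exceeds max {hi}")
        for name in ("n_proteins", "n_bio_per_group", "n_tech_per_bio", "psms_per_tech"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.mass_error_ppm_sd > 0:
            raise ConfigurationError("mass_error_ppm_sd must be > 0")
        for name in ("background_unmodified_fraction", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass
class PlantedModification:
    """One planted ncAA: a concrete residue site carrying a delta mass at a
    group-specific rate."""

    protein_id: str
    position: int  # 1-based within the protein
    residue: str
    true_delta_mass: float
    rate_control: float
    rate_ischemia: float

    @property
    def expected_ratio(self) -> float:
        if self.rate_control == 0:
            return float("inf") if self.rate_ischemia > 0 else 1.0
        return self.rate_ischemia / self.rate_control


@dataclass
class SyntheticGroundTruth:
    """The planted modification landscape plus the proteome it lives on."""

    proteome: dict[str, str]
    planted: list[PlantedModification]
    seed: int

    @property
    def expected_ratios(self) -> dict[tuple, float]:
        return {(m.protein_id, m.position): m.expected_ratio for m in self.planted}

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "proteome": self.proteome,
            "planted": [dict(asdict(m), expected_ratio=m.expected_ratio)
                        for m in self.planted],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticGroundTruth":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        planted = [PlantedModification(**{k: v for k, v in m.items()
                                          if k != "expected_ratio"})
                   for m in payload["planted"]]
        return cls(proteome=payload["proteome"], planted=planted,
                   seed=payload["seed"])


def make_proteome(config: SyntheticConfig) -> dict[str, str]:
    """Random proteome: n_proteins uniform sequences over the 20 residues."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(0,)))
    lo, hi = config.protein_length_range
    proteome = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(list(STANDARD_AA))[rng.integers(0, 20, size=length)])
        proteome[f"SYN{i + 1:04d}"] = seq
    return proteome


def tryptic_peptides(sequence: str, min_len: int = 6, max_len: int = 30):
    """Fully cleaved tryptic peptides (cut after K/R, not before P).

    Returns (start, peptide) pairs with 1-based starts, keeping peptides
    whose length lies in [min_len, max_len] — the observable range of a
    typical LC-MS/MS run.
    """
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    out = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if min_len <= b - a <= max_len:
            out.append((a + 1, sequence[a:b]))
    return out


def plant_modifications(proteome: dict[str, str], spec, seed: int = 0) -> SyntheticGroundTruth:
    """Assign each requested (delta_mass, residue, rate_control, rate_ischemia)
    a concrete site on a digestible peptide.

    Each entry lands on a distinct tryptic peptide (so sites do not compete
    for the same PSMs); a residue with no available site raises
    :class:`GenerationError` naming it.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    # candidate sites: (protein, 1-based position, residue, peptide key)
    candidates: list[tuple[str, int, str, tuple]] = []
    for pid, seq in proteome.items():
        for start, pep in tryptic_peptides(seq):
            for j, aa in enumerate(pep):
                candidates.append((pid, start + j, aa, (pid, start)))
    used_peptides: set[tuple] = set()
    planted = []
    for delta, residue, rate_c, rate_i in spec:
        if not np.isfinite(delta):
            raise GenerationError(f"non-finite delta mass {delta!r}")
        if residue not in AA_MONO:
            raise GenerationError(f"no standard residue {residue!r} to plant on")
        for r in (rate_c, rate_i):
            if not 0.0 <= r <= 1.0:
                raise GenerationError(f"modification rate {r} outside [0, 1]")
        avail = [c for c in candidates
                 if c[2] == residue and c[3] not in used_peptides]
        if not avail:
            raise GenerationError(
                f"no available site with residue {residue!r} in the proteome")
        pick = avail[int(rng.integers(0, len(avail)))]
        used_peptides.add(pick[3])
        planted.append(PlantedModification(
            protein_id=pick[0], position=pick[1], residue=residue,
            true_delta_mass=float(delta),
            rate_control=float(rate_c), rate_ischemia=float(rate_i)))
    return SyntheticGroundTruth(proteome=proteome, planted=planted, seed=seed)


def _draw_scores(rng, model, n):
    score = rng.normal(model["score"][0], model["score"][1], size=n)
    dms = rng.normal(model["delta_mods_score"][0], model["delta_mods_score"][1], size=n)
    fdr2d = rng.uniform(0.0, model["fdr_max"], size=n)
    fdru = rng.uniform(0.0, model["fdr_max"], size=n)
    return score, dms, fdr2d, fdru


def simulate_psms(truth: SyntheticGroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Emit the full PSM table for the two-group replicated design.

    For each group x biological x technical replicate, ``psms_per_tech`` rows
    are drawn.  A PSM either samples a background peptide (delta 0) with
    probability ``background_unmodified_fraction``, or a peptide covering a
    planted site; covering PSMs carry the site's delta with the group rate,
    perturbed by Gaussian ppm error scaled to the peptide monoisotopic mass.
    Score columns come from the passing model except for a ``decoy_fraction``
    of rows drawn from the failing model.  Each replicate uses a child seed
    derived from the global seed by a fixed spawn key, so adding replicates
    does not perturb earlier ones.
    """
    if not truth.proteome:
        raise GenerationError("empty proteome")
    digest = []  # (protein_id, start, peptide, mass)
    for pid, seq in truth.proteome.items():
        for start, pep in tryptic_peptides(seq):
            digest.append((pid, start, pep, peptide_mono_mass(pep)))
    if not digest:
        raise GenerationError("proteome produced no digestible peptides")
    site_by_peptide = {}
    for m in truth.planted:
        for k, (pid, start, pep, _) in enumerate(digest):
            if pid == m.protein_id and start <= m.position < start + len(pep):
                site_by_peptide[k] = m
    planted_idx = np.array(sorted(site_by_peptide), dtype=int)
    background_idx = np.array([k for k in range(len(digest))
                               if k not in site_by_peptide], dtype=int)

    frames = []
    groups = ["control", "ischemia"]
    for gi, group in enumerate(groups):
        for bio in range(1, config.n_bio_per_group + 1):
            for tech in range(1, config.n_tech_per_bio + 1):
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(2, gi, bio, tech)))
                n = config.psms_per_tech
                if len(planted_idx) == 0:
                    is_bg = np.ones(n, dtype=bool)
                elif len(background_idx) == 0:
                    is_bg = np.zeros(n, dtype=bool)
                else:
                    is_bg = rng.random(n) < config.background_unmodified_fraction
                pep_idx = np.empty(n, dtype=int)
                if is_bg.any():
                    pep_idx[is_bg] = rng.choice(background_idx, size=int(is_bg.sum()))
                if (~is_bg).any():
                    pep_idx[~is_bg] = rng.choice(planted_idx, size=int((~is_bg).sum()))
                delta = np.zeros(n)
                mod_site = np.zeros(n, dtype=int)
                carry = rng.random(n)
                ppm_noise = rng.normal(0.0, config.mass_error_ppm_sd, size=n)
                pep_mass = np.array([digest[k][3] for k in pep_idx])
                for i in np.nonzero(~is_bg)[0]:
                    m = site_by_peptide[pep_idx[i]]
                    rate = m.rate_ischemia if group == "ischemia" else m.rate_control
                    if carry[i] < rate:
                        start = digest[pep_idx[i]][1]
                        mod_site[i] = m.position - start + 1
                        delta[i] = (m.true_delta_mass
                                    + ppm_noise[i] * 1e-6 * pep_mass[i])
                is_decoy = rng.random(n) < config.decoy_fraction
                s_t = _draw_scores(rng, config.score_distributions["true"], n)
                s_d = _draw_scores(rng, config.score_distributions["decoy"], n)
                score, dms, fdr2d, fdru = (np.where(is_decoy, d, t)
                                           for t, d in zip(s_t, s_d))
                frames.append(pd.DataFrame({
                    "spectrum_id": [f"{group[0]}{bio}t{tech}_s{i:06d}" for i in range(n)],
                    "group": group,
                    "bio_replicate": bio,
                    "tech_replicate": tech,
                    "peptide": [digest[k][2] for k in pep_idx],
                    "protein_id": [digest[k][0] for k in pep_idx],
                    "protein_start": [digest[k][1] for k in pep_idx],
                    "mod_site": mod_site,
                    "delta_mass": delta,
                    "peptide_mass": pep_mass,
                    "score": score,
                    "delta_mods_score": dms,
                    "fdr2d": np.clip(fdr2d, 0.0, 1.0),
                    "fdr_uniq2d": np.clip(fdru, 0.0, 1.0),
                }))
    out = pd.concat(frames, ignore_index=True)
    return out[CANONICAL_COLUMNS]


#: The reference planted-modification landscape: oxidation (M), acetylation
#: (K), phosphorylation (S), deamidation (N, equal rates — a null site) and
#: dehydration (T), at group rates giving clear up/down regulation.
DEFAULT_PLANT_SPEC = [
    (15.9949, "M", 0.15, 0.40),
    (42.0106, "K", 0.40, 0.15),
    (79.9663, "S", 0.15, 0.45),
    (0.9840, "N", 0.25, 0.25),
    (-18.0106, "T", 0.15, 0.38),
]


def default_scenario(seed: int = 0, **config_overrides):
    """The reference end-to-end scenario: default config, reference plant
    spec.  Returns (truth, config, psm table)."""
    config = SyntheticConfig(seed=seed, **config_overrides)
    proteome = make_proteome(config)
    truth = plant_modifications(proteome, DEFAULT_PLANT_SPEC, seed=seed)
    psms = simulate_psms(truth, config)
    return truth, config, psms
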