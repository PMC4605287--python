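"""Information content of AM profiles and molecule filtering.

How much identifying power a barcode carries is quantified by two
components, both measured relative to the typical experimental noise level:

* **spatial component** (``space_score``) — the number of distinct
  features (peaks) along the profile that survive a prominence criterion;
* **contrast component** (``contrast_score``) — the accumulated
  peak-to-valley depths in noise units, with each step capped at
  ``contrast_cap``: beyond some depth, extra contrast no longer helps to
  tell neighbouring features apart, so its contribution saturates.

Features are extracted by classical persistence pruning: all strict local
extrema of the trace are listed in alternating max/min order (profile ends
included as run boundaries), then the adjacent extremum pair with the
smallest absolute depth is removed repeatedly while that depth is at most
``prominence_factor * noise_sd``. What survives is the alternating skeleton
of modulations that are detectable above noise.

The combined information score ``is_value`` ranks molecules for filtering:
profiles with few shallow features can be matched confidently to almost
anything and are discarded before classification.

The exact score definition here is this package's own concrete procedure;
it realises the stated qualitative properties (feature count, noise-relative
contrast, saturation) rather than reproducing any particular legacy
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcodes import (
    DEFAULT_BP_PER_PIXEL,
    DEFAULT_MOTIF,
    find_motif_sites,
    theoretical_enzymatic_profile,
    theoretical_intercalation_profile,
)
from .core import AMProfile, GenomeSequence, PSFModel
from .matching import PairedTTest, paired_cc_test

__all__ = [
    "InfoConfig",
    "InfoScores",
    "Extremum",
    "detect_features",
    "information_content",
    "compare_labelling_schemes",
    "SchemeComparison",
    "filter_molecules",
]


@dataclass(frozen=True)
class InfoConfig:
    """Scoring parameters, all relative to the experimental noise level.

    ``noise_sd`` is in the intensity units of the profiles being scored.
    A peak-valley step counts as a feature only if deeper than
    ``prominence_factor * noise_sd``; each step's contrast contribution is
    capped at ``contrast_cap`` noise units.
    """

    noise_sd: float
    prominence_factor: float = 2.0
    contrast_cap: float = 5.0
    is_threshold: float = 0.0
    space_weight: float = 1.0
    contrast_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not self.prominence_factor > 0 or not self.contrast_cap > 0:
            raise ValueError("prominence_factor and contrast_cap must be positive")
        if self.contrast_cap < self.prominence_factor:
            raise ValueError("contrast_cap must be >= prominence_factor")
        if self.is_threshold < 0:
            raise ValueError("is_threshold must be non-negative")


@dataclass(frozen=True)
class InfoScores:
    space_score: int
    contrast_score: float
    is_value: float


@dataclass(frozen=True)
class Extremum:
    index: int
    value: float
    kind: str  # 'max' or 'min'


def _alternating_extrema(v: np.ndarray) -> list[Extremum]:
    """All strict local extrema in alternating order, ends included.

    Runs of equal values are compressed to their first sample; a constant
    profile yields an empty list.
    """
    if np.ptp(v) == 0.0:
        return []
    keep = np.concatenate(([True], np.diff(v) != 0.0))
    idx = np.flatnonzero(keep)
    w = v[idx]
    m = w.size
    ext: list[Extremum] = []
    ext.append(Extremum(int(idx[0]), float(w[0]), "min" if w[1] > w[0] else "max"))
    for j in range(1, m - 1):
        if w[j] > w[j - 1] and w[j] > w[j + 1]:
            ext.append(Extremum(int(idx[j]), float(w[j]), "max"))
        elif w[j] < w[j - 1] and w[j] < w[j + 1]:
            ext.append(Extremum(int(idx[j]), float(w[j]), "min"))
    ext.append(Extremum(int(idx[-1]), float(w[-1]), "max" if w[-1] > w[-2] else "min"))
    return ext


def detect_features(profile: AMProfile, cfg: InfoConfig) -> list[Extremum]:
    """Alternating extrema surviving persistence pruning.

    The adjacent max/min pair with the smallest absolute depth is removed
    repeatedly while that depth <= ``prominence_factor * noise_sd``
    (smallest pair first; earliest pair on ties). A constant profile gives
    an empty list.
    """
    if len(profile) < 3:
        raise ValueError("profile must have at least 3 pixels")
    ext = _alternating_extrema(profile.values)
    floor = cfg.prominence_factor * cfg.noise_sd
    while len(ext) >= 2:
        depths = [abs(ext[i + 1].value - ext[i].value) for i in range(len(ext) - 1)]
        j = int(np.argmin(depths))
        if depths[j] <= floor:
            del ext[j : j + 2]
        else:
            break
    return ext


def information_content(profile: AMProfile, cfg: InfoConfig) -> InfoScores:
    """Spatial and saturated-contrast scores of one profile.

    ``space_score`` counts surviving maxima; ``contrast_score`` sums
    ``min(depth / noise_sd, contrast_cap)`` over adjacent surviving
    extremum pairs, so an isolated peak is scored symmetrically on both
    flanks. Scores are computed on the raw (non z-scored) trace.
    """
    ext = detect_features(profile, cfg)
    space = sum(1 for e in ext if e.kind == "max")
    contrast = 0.0
    for i in range(len(ext) - 1):
        depth = abs(ext[i + 1].value - ext[i].value) / cfg.noise_sd
        contrast += min(depth, cfg.contrast_cap)
    if space == 0:
        contrast = 0.0
    return InfoScores(
        space_score=space,
        contrast_score=contrast,
        is_value=cfg.space_weight * space + cfg.contrast_weight * contrast,
    )


def _unit_mean(profile: AMProfile) -> AMProfile | None:
    """Rescale a profile to unit mean intensity; None for an empty profile.

    Modulation depth is then measured relative to the overall signal level,
    which is the scale experimental noise (shot noise, background) lives
    on, so one ``noise_sd`` is meaningful for chemistries with different
    native intensity units.
    """
    m = float(profile.values.mean())
    if m <= 0.0:
        return None
    return profile.copy_with(profile.values / m)


@dataclass(frozen=True)
class SchemeComparison:
    """Per-genome information scores of both labelling schemes.

    Ratios are enzymatic over intercalation means; ``space_test`` and
    ``contrast_test`` are paired t-tests across genomes.
    """

    table: pd.DataFrame
    space_ratio: float
    contrast_ratio: float
    space_test: PairedTTest | None
    contrast_test: PairedTTest | None


def compare_labelling_schemes(
    genomes: list[GenomeSequence],
    psf: PSFModel = PSFModel(),
    bp_per_pixel: float = DEFAULT_BP_PER_PIXEL,
    cfg: InfoConfig = InfoConfig(noise_sd=0.1),
    motif: str = DEFAULT_MOTIF,
) -> SchemeComparison:
    """Score motif-directed vs intercalation barcodes on the same genomes.

    Each theoretical profile is rescaled to unit mean intensity before
    scoring, so a single ``noise_sd`` (a fraction of the typical signal
    level) is comparable across chemistries with different native
    intensity units. Per-genome scores are reported both per genome and
    per kbp; a scheme with an empty profile (e.g. zero motif sites) scores
    zero and its ratio entry is undefined (NaN).
    """
    if not genomes:
        raise ValueError("genome list must be non-empty")
    rows = []
    for genome in genomes:
        sites = find_motif_sites(genome, motif)
        enz = theoretical_enzymatic_profile(sites, psf, bp_per_pixel)
        inter = theoretical_intercalation_profile(genome, psf, bp_per_pixel)
        kbp = genome.length_bp / 1000.0
        row: dict[str, float | str | int] = {
            "genome_id": genome.id,
            "length_kbp": kbp,
            "n_sites": len(sites),
        }
        for name, prof in (("enzymatic", enz), ("intercalation", inter)):
            scaled = _unit_mean(prof)
            if scaled is None:
                scores = InfoScores(0, 0.0, 0.0)
            else:
                scores = information_content(scaled, cfg)
            row[f"{name}_space"] = scores.space_score
            row[f"{name}_contrast"] = scores.contrast_score
            row[f"{name}_space_per_kbp"] = scores.space_score / kbp
            row[f"{name}_contrast_per_kbp"] = scores.contrast_score / kbp
        rows.append(row)
    table = pd.DataFrame(rows)

    def ratio(col: str) -> float:
        denom = table[f"intercalation_{col}"].mean()
        if denom == 0:
            return float("nan")
        return float(table[f"enzymatic_{col}"].mean() / denom)

    def ttest(col: str) -> PairedTTest | None:
        if len(table) < 2:
            return None
        return paired_cc_test(
            list(table[f"enzymatic_{col}"]), list(table[f"intercalation_{col}"])
        )

    return SchemeComparison(
        table=table,
        space_ratio=ratio("space"),
        contrast_ratio=ratio("contrast"),
        space_test=ttest("space"),
        contrast_test=ttest("contrast"),
    )


def filter_molecules(
    molecules: list[AMProfile], cfg: InfoConfig
) -> tuple[list[AMProfile], list[AMProfile]]:
    """Partition molecules by information score.

    Keeps molecules with ``is_value >= cfg.is_threshold``; the partition is
    exhaustive and disjoint.
    """
    kept: list[AMProfile] = []
    discarded: list[AMProfile] = []
    for mol in molecules:
        scores = information_content(mol, cfg)
        (kept if scores.is_value >= cfg.is_threshold else discarded).append(mol)
    return kept, discarded
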