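"""Forward simulation of noisy single-molecule AM profiles.

Stands in for experimental nanochannel snapshots: each simulated molecule
carries a known ground-truth genome, orientation and stretch, so that
classification experiments can be scored exactly.

The noise model decomposes the experimental variability named for this kind
of assay — labelling efficiency, degree of DNA stretching and dye
photophysics — into four independent components:

1. per-site Bernoulli labelling with probability ``label_efficiency``;
2. a global linear stretch factor ``s ~ Normal(stretch_mean, stretch_sd)``
   applied to label coordinates (the PSF width is optical in origin and
   stays fixed on the pixel grid);
3. per-label lognormal brightness with mean 1 and coefficient of variation
   ``brightness_cv``;
4. an additive background offset plus zero-mean Gaussian camera noise per
   pixel, both expressed in units of a single label's peak intensity, with
   the result clipped at zero (camera counts are non-negative).

Finally the profile is reversed with probability ``flip_prob`` — molecules
enter the nanochannel in either orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .barcodes import DEFAULT_BP_PER_PIXEL, find_motif_sites, gaussian_mixture_profile
from .core import AMProfile, GenomeSequence, LabelSiteTrain, PSFModel

__all__ = [
    "SimulationParams",
    "SimulatedMolecule",
    "simulate_molecule",
    "simulate_library",
    "random_genome",
]


@dataclass(frozen=True)
class SimulationParams:
    """Noise-model parameters; see module docstring for the model.

    Intensity-like parameters (``background_level``, ``noise_sd``) are in
    units of one label's peak height, so their meaning does not depend on
    the PSF width or pixel scale.
    """

    label_efficiency: float = 0.8
    stretch_mean: float = 1.0
    stretch_sd: float = 0.02
    brightness_cv: float = 0.3
    background_level: float = 0.05
    noise_sd: float = 0.05
    flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_efficiency <= 1.0:
            raise ValueError("label_efficiency must be in [0, 1]")
        if not self.stretch_mean > 0:
            raise ValueError("stretch_mean must be positive")
        if self.stretch_sd < 0 or self.brightness_cv < 0:
            raise ValueError("stretch_sd and brightness_cv must be non-negative")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be non-negative")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if not self.stretch_mean - 3.0 * self.stretch_sd > 0:
            raise ValueError("stretch_mean - 3*stretch_sd must stay positive")


@dataclass(frozen=True)
class SimulatedMolecule:
    """A simulated profile together with its ground truth."""

    profile: AMProfile
    truth_genome_id: str
    truth_orientation: str  # '+' or '-'
    truth_stretch: float
    labelled_site_count: int


def simulate_molecule(
    genome: GenomeSequence,
    sites: LabelSiteTrain,
    psf: PSFModel = PSFModel(),
    params: SimulationParams = SimulationParams(),
    bp_per_pixel: float = DEFAULT_BP_PER_PIXEL,
    rng: np.random.Generator | None = None,
) -> SimulatedMolecule:
    """Simulate one noisy molecule from a genome and its label-site train.

    With all noise terms switched off (full efficiency, zero stretch/
    brightness variation, zero background and noise, no flip) the output
    equals the theoretical enzymatic profile exactly. A fixed seed gives
    bit-identical output.
    """
    if sites.genome_id != genome.id or sites.genome_length_bp != genome.length_bp:
        raise ValueError(
            f"site train ({sites.genome_id!r}, {sites.genome_length_bp} bp) does "
            f"not belong to genome ({genome.id!r}, {genome.length_bp} bp)"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n_sites = len(sites)
    keep = rng.random(n_sites) < params.label_efficiency
    stretch = float(rng.normal(params.stretch_mean, params.stretch_sd))
    n_kept = int(keep.sum())
    if params.brightness_cv > 0 and n_kept:
        s2 = math.log1p(params.brightness_cv**2)
        brightness = rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=n_kept)
    else:
        brightness = np.ones(n_kept)

    centres = sites.centres_bp[keep] * stretch
    values = gaussian_mixture_profile(
        centres, brightness, genome.length_bp * stretch, psf, bp_per_pixel
    )
    # one unit-brightness label peaks at the Gaussian density maximum
    peak = 1.0 / (psf.sigma_bp * math.sqrt(2.0 * math.pi))
    values = values + params.background_level * peak
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd * peak, size=values.size)
        np.clip(values, 0.0, None, out=values)
    flipped = bool(rng.random() < params.flip_prob)
    if flipped:
        values = values[::-1]
    orientation = "-" if flipped else "+"

    profile = AMProfile(
        values,
        bp_per_pixel,
        genome_id=genome.id,
        kind="simulated",
        meta={
            "truth_genome_id": genome.id,
            "truth_orientation": orientation,
            "truth_stretch": stretch,
            "labelled_site_count": n_kept,
            "motif": sites.motif,
            "fwhm_bp": psf.fwhm_bp,
            **{f"sim_{k}": v for k, v in asdict(params).items()},
        },
    )
    return SimulatedMolecule(
        profile=profile,
        truth_genome_id=genome.id,
        truth_orientation=orientation,
        truth_stretch=stretch,
        labelled_site_count=n_kept,
    )


def simulate_library(
    genomes: list[GenomeSequence],
    n_per_genome: int,
    psf: PSFModel = PSFModel(),
    params: SimulationParams = SimulationParams(),
    bp_per_pixel: float = DEFAULT_BP_PER_PIXEL,
    motif: str = "TCGA",
) -> list[SimulatedMolecule]:
    """Simulate ``n_per_genome`` molecules from each genome.

    Per-molecule random streams are derived deterministically from
    ``(params.seed, genome index, replicate index)``, so the library is
    reproducible and individual molecules can be regenerated in isolation.
    """
    if not genomes:
        raise ValueError("genome list must be non-empty")
    if n_per_genome < 1:
        raise ValueError("n_per_genome must be >= 1")
    molecules: list[SimulatedMolecule] = []
    for gi, genome in enumerate(genomes):
        sites = find_motif_sites(genome, motif)
        for ri in range(n_per_genome):
            rng = np.random.default_rng([params.seed, gi, ri])
            mol = simulate_molecule(genome, sites, psf, params, bp_per_pixel, rng=rng)
            mol.profile.meta["molecule_id"] = f"{genome.id}/{ri}"
            mol.profile.meta["seed_key"] = f"{params.seed}.{gi}.{ri}"
            molecules.append(mol)
    return molecules


def random_genome(
    length_bp: int,
    gc: float = 0.5,
    rng: np.random.Generator | int | None = None,
    id: str = "random",
) -> GenomeSequence:
    """An i.i.d. random genome with the given GC fraction."""
    if length_bp < 1:
        raise ValueError("length_bp must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length_bp, p=p)
    return GenomeSequence(id=id, seq="".join(bases))
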