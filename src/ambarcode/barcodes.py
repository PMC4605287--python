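"""Theoretical amplitude-modulation barcodes from genome sequence.

Two labelling chemistries are modelled:

* **Enzymatic (motif-directed) labelling** — a methyltransferase such as
  M.TaqI deposits one fluorophore per occurrence of its recognition motif
  (TCGA). The expected image intensity is the sum of one Gaussian PSF per
  site, so the theoretical barcode is a Gaussian mixture evaluated on the
  camera pixel grid.
* **Intercalation labelling** — sequence-dependent staining whose local
  intensity tracks the GC fraction; the theoretical barcode is the per-base
  G/C indicator convolved with the PSF.

Profiles live on a common pixel grid extending three PSF sigmas beyond both
genome ends, so that terminal peaks are fully represented; the molecule is
treated as linear (no circular wrap-around).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import fftconvolve

from .core import AMProfile, GenomeSequence, LabelSiteTrain, PSFModel, reverse_complement

__all__ = [
    "DEFAULT_BP_PER_PIXEL",
    "DEFAULT_MOTIF",
    "find_motif_sites",
    "pixel_grid",
    "theoretical_enzymatic_profile",
    "theoretical_intercalation_profile",
]

#: Default pixel scale: a 65 nm camera pixel at 100x magnification over DNA
#: stretched to ~0.29 nm/bp in a nanochannel corresponds to ~225 bp/pixel.
DEFAULT_BP_PER_PIXEL = 225.0

#: M.TaqI recognition sequence.
DEFAULT_MOTIF = "TCGA"

#: The pixel grid extends this many PSF sigmas past both genome ends.
GRID_PAD_SIGMAS = 3.0

_MOTIF_ALPHABET = frozenset("ACGT")


def _scan(seq: str, motif: str) -> list[int]:
    """All 0-based start positions of exact (overlapping) motif matches."""
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(start)
        start = seq.find(motif, start + 1)
    return hits


def find_motif_sites(
    genome: GenomeSequence, motif: str, both_strands: bool = False
) -> LabelSiteTrain:
    """Locate every occurrence of a labelling motif on a genome.

    Matches are exact; N never matches. With ``both_strands`` the reverse
    complement of the motif is also searched on the forward strand and hits
    are reported as the forward-strand start of the matched window. For
    palindromic motifs (e.g. TCGA, ATCGAT) each duplex site is reported
    exactly once whichever flag is used. Overlapping occurrences are all
    reported.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    bad = set(motif) - _MOTIF_ALPHABET
    if bad:
        raise ValueError(f"motif contains characters outside A/C/G/T: {sorted(bad)}")
    if genome.length_bp < len(motif):
        raise ValueError("genome shorter than motif")

    positions = set(_scan(genome.seq, motif))
    if both_strands:
        rc = reverse_complement(motif)
        if rc != motif:
            positions.update(_scan(genome.seq, rc))
    return LabelSiteTrain(
        genome_id=genome.id,
        motif=motif,
        positions_bp=tuple(sorted(positions)),
        genome_length_bp=genome.length_bp,
    )


def pixel_grid(genome_length_bp: float, sigma_bp: float, bp_per_pixel: float) -> np.ndarray:
    """Pixel-centre coordinates (bp) of the profile grid for one molecule.

    The grid covers ``[-3 sigma, genome_length + 3 sigma]``; pixel ``i`` is
    centred at ``-3 sigma + (i + 1/2) * bp_per_pixel``.
    """
    if not bp_per_pixel > 0:
        raise ValueError("bp_per_pixel must be positive")
    start = -GRID_PAD_SIGMAS * sigma_bp
    span = genome_length_bp + 2.0 * GRID_PAD_SIGMAS * sigma_bp
    n = max(2, int(math.ceil(span / bp_per_pixel)))
    return start + (np.arange(n) + 0.5) * bp_per_pixel


def gaussian_mixture_profile(
    centres_bp: np.ndarray,
    weights: np.ndarray | float,
    genome_length_bp: float,
    psf: PSFModel,
    bp_per_pixel: float,
) -> np.ndarray:
    """Sum of weighted unit-integral Gaussians sampled on the pixel grid.

    Each label contributes a Gaussian of integral ``weight`` (in label
    units), expressed as a per-bp density, so that
    ``profile.sum() * bp_per_pixel`` equals the total label weight.
    """
    x = pixel_grid(genome_length_bp, psf.sigma_bp, bp_per_pixel)
    centres_bp = np.atleast_1d(np.asarray(centres_bp, dtype=float))
    if centres_bp.size == 0:
        return np.zeros_like(x)
    w = np.broadcast_to(np.atleast_1d(np.asarray(weights, dtype=float)), centres_bp.shape)
    sigma = psf.sigma_bp
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    # sites x pixels; profiles are short (~hundreds of px), sites ~hundreds
    d = (x[None, :] - centres_bp[:, None]) / sigma
    return norm * (w[:, None] * np.exp(-0.5 * d * d)).sum(axis=0)


def theoretical_enzymatic_profile(
    sites: LabelSiteTrain,
    psf: PSFModel = PSFModel(),
    bp_per_pixel: float = DEFAULT_BP_PER_PIXEL,
) -> AMProfile:
    """Expected AM barcode of a fully labelled molecule.

    One unit-integral Gaussian PSF is placed at the centre of each motif
    occurrence and the mixture is sampled at pixel centres. Intensity is a
    per-bp label density: the pixel sum times ``bp_per_pixel`` recovers the
    number of sites (to discretisation accuracy).
    """
    values = gaussian_mixture_profile(
        sites.centres_bp, 1.0, sites.genome_length_bp, psf, bp_per_pixel
    )
    return AMProfile(
        values,
        bp_per_pixel,
        genome_id=sites.genome_id,
        kind="theoretical_enzymatic",
        meta={
            "motif": sites.motif,
            "n_sites": len(sites),
            "fwhm_bp": psf.fwhm_bp,
            "genome_length_bp": sites.genome_length_bp,
        },
    )


_GC_INDICATOR = {"G": 1.0, "C": 1.0, "A": 0.0, "T": 0.0, "N": 0.5}


def theoretical_intercalation_profile(
    genome: GenomeSequence,
    psf: PSFModel = PSFModel(),
    bp_per_pixel: float = DEFAULT_BP_PER_PIXEL,
) -> AMProfile:
    """Expected AM barcode of GC-highlighting intercalation staining.

    The per-base indicator (1 for G/C, 0 for A/T, 0.5 for N) is convolved
    with a unit-sum Gaussian kernel at 1 bp resolution and sampled on the
    same pixel-grid convention as the enzymatic profile. Interior values are
    a smoothed local GC fraction in [0, 1].
    """
    if genome.length_bp == 0:
        raise ValueError("genome must be non-empty")
    sigma = psf.sigma_bp
    ind = np.array([_GC_INDICATOR[b] for b in genome.seq], dtype=float)
    pad = int(math.ceil(GRID_PAD_SIGMAS * sigma)) + 1
    padded = np.concatenate([np.zeros(pad), ind, np.zeros(pad)])
    # 5-sigma truncation keeps the all-G interior flat to < 1e-6
    radius = int(math.ceil(5.0 * sigma))
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    smooth = fftconvolve(padded, kernel, mode="same")
    # bp coordinate of padded sample j is (j - pad + 0.5)
    bp_coords = np.arange(padded.size) - pad + 0.5
    x = pixel_grid(genome.length_bp, sigma, bp_per_pixel)
    values = np.interp(x, bp_coords, smooth, left=0.0, right=0.0)
    np.clip(values, 0.0, None, out=values)  # FFT round-off can dip ~ -1e-15
    return AMProfile(
        values,
        bp_per_pixel,
        genome_id=genome.id,
        kind="theoretical_intercalation",
        meta={"fwhm_bp": psf.fwhm_bp, "genome_length_bp": genome.length_bp},
    )
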