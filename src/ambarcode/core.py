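"""Core domain types for amplitude-modulation (AM) optical mapping.

An AM barcode is the continuous fluorescence-intensity trace read along a
stretched DNA molecule whose labels are too dense to resolve individually:
the diffraction-limited point spread functions (PSFs) of neighbouring
fluorophores overlap and the *modulation* of the summed intensity, rather
than a pattern of isolated spots, carries the sequence fingerprint.

This module defines the shared value types: genome sequences, trains of
labelling-motif sites, the Gaussian PSF model, and the 1-D intensity
profile container used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

__all__ = [
    "GenomeSequence",
    "LabelSiteTrain",
    "PSFModel",
    "AMProfile",
    "PROFILE_KINDS",
    "DegenerateProfileError",
    "NoValidAlignmentError",
    "FastaFormatError",
    "ProfileFormatError",
]

_GENOME_ALPHABET = frozenset("ACGTN")
_MOTIF_ALPHABET = frozenset("ACGT")

#: Allowed provenance tags for an :class:`AMProfile`.
PROFILE_KINDS = ("theoretical_enzymatic", "theoretical_intercalation", "simulated")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class DegenerateProfileError(ValueError):
    """A profile is degenerate for the requested operation (e.g. zero variance)."""


class NoValidAlignmentError(ValueError):
    """No shift satisfies the overlap constraint between query and reference."""


class FastaFormatError(ValueError):
    """Malformed FASTA input; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class ProfileFormatError(ValueError):
    """Malformed profile TSV input; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T,N}, stored upper-case."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _GENOME_ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.id!r} contains characters outside A/C/G/T/N: "
                f"{sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.seq)

    @property
    def gc_fraction(self) -> float:
        """Fraction of G/C bases; N counts half (unknown base, unbiased)."""
        if not self.seq:
            return float("nan")
        gc = self.seq.count("G") + self.seq.count("C") + 0.5 * self.seq.count("N")
        return gc / len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LabelSiteTrain:
    """Ordered 0-based forward-strand start positions of a labelling motif.

    Positions use a 0-based, half-open coordinate convention: a site at
    position ``p`` occupies ``[p, p + len(motif))``.
    """

    genome_id: str
    motif: str
    positions_bp: tuple[int, ...]
    genome_length_bp: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions_bp", tuple(int(p) for p in self.positions_bp))
        lim = self.genome_length_bp - len(self.motif)
        prev = -1
        for p in self.positions_bp:
            if p <= prev:
                raise ValueError("site positions must be strictly increasing")
            if not 0 <= p <= lim:
                raise ValueError(
                    f"site position {p} outside [0, {lim}] for motif "
                    f"{self.motif!r} on a {self.genome_length_bp} bp genome"
                )
            prev = p

    def __len__(self) -> int:
        return len(self.positions_bp)

    @property
    def centres_bp(self) -> np.ndarray:
        """Label positions at the centre of each motif occurrence, in bp."""
        return np.asarray(self.positions_bp, dtype=float) + len(self.motif) / 2.0


@dataclass(frozen=True)
class PSFModel:
    """Gaussian point spread function, width in base pairs along the molecule.

    ``fwhm_bp`` is the full width at half maximum; the paper-scale default of
    1500 bp corresponds to a diffraction-limited spot imaged over DNA
    stretched in a nanochannel.
    """

    fwhm_bp: float = 1500.0

    def __post_init__(self) -> None:
        if not self.fwhm_bp > 0:
            raise ValueError("fwhm_bp must be positive")

    @property
    def sigma_bp(self) -> float:
        return self.fwhm_bp / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class AMProfile:
    """A 1-D intensity trace sampled on a uniform pixel grid.

    Parameters
    ----------
    values
        Intensity per pixel, arbitrary units. Must be finite, length >= 2,
        and non-negative unless ``normalized`` is set (z-scored copies are an
        explicitly marked separate state).
    bp_per_pixel
        Base pairs spanned by one pixel along the stretched molecule.
    genome_id
        Identifier of the underlying genome, or "" when unknown.
    kind
        One of ``theoretical_enzymatic``, ``theoretical_intercalation``,
        ``simulated``.
    meta
        Free-form provenance (parameters, seed, truth labels for simulated
        molecules).
    """

    __slots__ = ("values", "bp_per_pixel", "genome_id", "kind", "meta", "normalized")

    def __init__(
        self,
        values: np.ndarray,
        bp_per_pixel: float,
        genome_id: str = "",
        kind: str = "simulated",
        meta: Mapping[str, Any] | None = None,
        normalized: bool = False,
    ):
        values = np.ascontiguousarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("profile must be a 1-D array with at least 2 pixels")
        if not np.all(np.isfinite(values)):
            raise ValueError("profile values must be finite")
        if not normalized and np.any(values < 0):
            raise ValueError("raw profile values must be non-negative")
        if not bp_per_pixel > 0:
            raise ValueError("bp_per_pixel must be positive")
        if kind not in PROFILE_KINDS:
            raise ValueError(f"kind must be one of {PROFILE_KINDS}, got {kind!r}")
        self.values = values
        self.bp_per_pixel = float(bp_per_pixel)
        self.genome_id = genome_id
        self.kind = kind
        self.meta: dict[str, Any] = dict(meta or {})
        self.normalized = bool(normalized)

    def __len__(self) -> int:
        return self.values.size

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AMProfile(n={len(self)}, bp_per_pixel={self.bp_per_pixel:g}, "
            f"genome_id={self.genome_id!r}, kind={self.kind!r}, "
            f"normalized={self.normalized})"
        )

    def copy_with(self, values: np.ndarray, *, normalized: bool | None = None) -> "AMProfile":
        """New profile with replaced values, same scale and provenance."""
        return AMProfile(
            values,
            self.bp_per_pixel,
            genome_id=self.genome_id,
            kind=self.kind,
            meta=dict(self.meta),
            normalized=self.normalized if normalized is None else normalized,
        )
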