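"""File formats: FASTA input, the profile TSV dialect, site-train BED.

The profile TSV dialect is one intensity value per line preceded by
``# key=value`` header lines carrying provenance (genome_id, kind,
bp_per_pixel, seed, truth labels, ...). Round-trips are lossless: floats
are written with 17 significant digits, which is exact for IEEE doubles.
All coordinates in outputs are 0-based, half-open.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Any

import numpy as np
from Bio import SeqIO

from .core import AMProfile, FastaFormatError, GenomeSequence, LabelSiteTrain, ProfileFormatError

__all__ = [
    "read_fasta",
    "read_profile_tsv",
    "write_profile_tsv",
    "write_site_train_bed",
]

_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = set("RYSWKMBDHV")


def _first_bad_line(path: Path, record_id: str, bad_chars: set[str]) -> int | None:
    """1-based line number of the first offending character in a record."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].split() else False
                continue
            if in_record and (set(line.strip().upper()) & bad_chars):
                return lineno
    return None


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Parse a (multi-record) FASTA file into genome sequences.

    The id is the first whitespace-delimited token of the header. Sequences
    are upper-cased; U is mapped to T and IUPAC ambiguity codes to N, each
    with a warning. Characters outside the IUPAC nucleotide alphabet raise
    a :class:`FastaFormatError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty FASTA file", line_number=1)
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        raise FastaFormatError(f"{path}: does not start with a '>' header", line_number=1)

    genomes: list[GenomeSequence] = []
    for record in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            lineno = None
            with open(path) as fh:
                for i, line in enumerate(fh, start=1):
                    if line.startswith(">") and line[1:].split() and line[1:].split()[0] == record.id:
                        lineno = i
                        break
            raise FastaFormatError(
                f"{path}: record {record.id!r} has an empty sequence", line_number=lineno
            )
        bad = set(seq) - _IUPAC
        if bad:
            lineno = _first_bad_line(path, record.id, bad)
            raise FastaFormatError(
                f"{path}: record {record.id!r} contains non-IUPAC characters "
                f"{sorted(bad)}",
                line_number=lineno,
            )
        if "U" in seq:
            warnings.warn(f"record {record.id!r}: U mapped to T", stacklevel=2)
            seq = seq.replace("U", "T")
        amb = set(seq) & _AMBIGUOUS
        if amb:
            warnings.warn(
                f"record {record.id!r}: ambiguity codes {sorted(amb)} mapped to N",
                stacklevel=2,
            )
            seq = seq.translate(str.maketrans({c: "N" for c in amb}))
        genomes.append(GenomeSequence(id=record.id, seq=seq))
    if not genomes:
        raise FastaFormatError(f"{path}: no FASTA records found", line_number=1)
    return genomes


def _format_meta_value(v: Any) -> str:
    if isinstance(v, float):
        return f"{v:.17g}"
    return str(v)


def _parse_meta_value(s: str) -> Any:
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    if s in ("True", "False"):
        return s == "True"
    return s


def write_profile_tsv(profile: AMProfile, path: str | Path) -> None:
    """Write a profile in the package TSV dialect (see module docstring)."""
    path = Path(path)
    lines = [
        f"# genome_id={profile.genome_id}",
        f"# kind={profile.kind}",
        f"# bp_per_pixel={profile.bp_per_pixel:.17g}",
        f"# normalized={profile.normalized}",
    ]
    for key in sorted(profile.meta):
        lines.append(f"# {key}={_format_meta_value(profile.meta[key])}")
    lines.extend(f"{v:.17g}" for v in profile.values)
    path.write_text("\n".join(lines) + "\n")


def read_profile_tsv(path: str | Path) -> AMProfile:
    """Read a profile written by :func:`write_profile_tsv`.

    Raises :class:`ProfileFormatError` (with line number) for non-numeric
    value lines and when the mandatory ``bp_per_pixel`` header is missing.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ProfileFormatError(
                        f"{path}: malformed header (expected key=value)", lineno
                    )
                key, _, val = body.partition("=")
                meta[key.strip()] = _parse_meta_value(val.strip())
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ProfileFormatError(
                    f"{path}: non-numeric profile value {line!r}", lineno
                ) from None
    if "bp_per_pixel" not in meta:
        raise ProfileFormatError(f"{path}: missing required header key bp_per_pixel")
    if len(values) < 2:
        raise ProfileFormatError(f"{path}: profile needs at least 2 values")
    bp_per_pixel = float(meta.pop("bp_per_pixel"))
    genome_id = str(meta.pop("genome_id", ""))
    kind = str(meta.pop("kind", "simulated"))
    normalized = bool(meta.pop("normalized", False))
    return AMProfile(
        np.asarray(values),
        bp_per_pixel,
        genome_id=genome_id,
        kind=kind,
        meta=meta,
        normalized=normalized,
    )


def write_site_train_bed(sites: LabelSiteTrain, path: str | Path) -> None:
    """Write motif sites as BED-like 3-column TSV (0-based, half-open)."""
    path = Path(path)
    width = len(sites.motif)
    lines = [f"# motif={sites.motif} genome_length_bp={sites.genome_length_bp} coords=0-based-half-open"]
    lines.extend(
        f"{sites.genome_id}\t{p}\t{p + width}" for p in sites.positions_bp
    )
    path.write_text("\n".join(lines) + "\n")
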