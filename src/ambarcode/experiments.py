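"""Reusable synthetic benchmark experiments.

Desk-scale stand-ins for the wet-lab validation experiments: a reference
library of random genomes is simulated, noisy molecules are drawn from each
and classified back against the library, and detection is judged by the
histogram mean + 1 SD rule. These experiments quantify what the method can
achieve under the package's own noise model; they do not reproduce any
particular experimental data set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .barcodes import DEFAULT_BP_PER_PIXEL, find_motif_sites, theoretical_enzymatic_profile
from .core import GenomeSequence, PSFModel
from .matching import (
    Assignment,
    ClassificationReport,
    MatchConfig,
    classification_report,
    classify,
)
from .simulate import SimulationParams, random_genome, simulate_library

__all__ = ["LibraryTypingResult", "make_reference_panel", "library_typing_experiment"]


@dataclass(frozen=True)
class LibraryTypingResult:
    """Outcome of one synthetic library-typing experiment."""

    report: ClassificationReport
    accuracy: float  # correctly assigned / total molecules
    per_genome_accuracy: dict[str, float]
    detected: dict[str, bool]  # see library_typing_experiment docstring
    confusion: np.ndarray  # rows: truth, cols: assigned (+ last col unclassified)
    reference_ids: tuple[str, ...]


def make_reference_panel(
    n_genomes: int,
    genome_length_bp: int,
    gc: float = 0.5,
    seed: int = 0,
) -> list[GenomeSequence]:
    """A panel of i.i.d. random genomes emulating a phage reference library."""
    rng = np.random.default_rng([seed, 0xA11])
    return [
        random_genome(genome_length_bp, gc=gc, rng=rng, id=f"panel{i:02d}")
        for i in range(n_genomes)
    ]


def library_typing_experiment(
    genomes: list[GenomeSequence],
    n_per_genome: int,
    params: SimulationParams,
    psf: PSFModel = PSFModel(),
    bp_per_pixel: float = DEFAULT_BP_PER_PIXEL,
    match_cfg: MatchConfig = MatchConfig(),
    motif: str = "TCGA",
) -> LibraryTypingResult:
    """Simulate molecules from every genome and classify them back.

    Returns overall and per-genome accuracy (fraction of molecules assigned
    to their true genome, unclassified counting as errors), the mean + 1 SD
    detection outcome per genome, and the full confusion matrix.

    Detection follows the single-strain screening design: for each truth
    genome, the assignment histogram of *its own* molecules across all
    references is examined, and the genome counts as detected when its own
    count exceeds that histogram's mean plus one sample SD. (In a pooled
    balanced experiment at least one reference count always sits at or
    below the mean, so the pooled histogram cannot flag every strain; the
    screening question is per sample, one strain against the library.)
    """
    references = [
        theoretical_enzymatic_profile(find_motif_sites(g, motif), psf, bp_per_pixel)
        for g in genomes
    ]
    ref_ids = [g.id for g in genomes]
    molecules = simulate_library(genomes, n_per_genome, psf, params, bp_per_pixel, motif)

    idx = {rid: j for j, rid in enumerate(ref_ids)}
    confusion = np.zeros((len(ref_ids), len(ref_ids) + 1), dtype=int)
    assignments: dict[str, Assignment] = {}
    for mol in molecules:
        mol_id = str(mol.profile.meta["molecule_id"])
        a = classify(mol.profile, references, match_cfg)
        assignments[mol_id] = a
        i = idx[mol.truth_genome_id]
        j = idx.get(a.reference_id, len(ref_ids))  # last column: unclassified
        confusion[i, j] += 1

    report = classification_report(assignments, ref_ids)
    diag = confusion[np.arange(len(ref_ids)), np.arange(len(ref_ids))]
    per_genome = {
        rid: diag[i] / n_per_genome for i, rid in enumerate(ref_ids)
    }
    detected = {}
    for i, rid in enumerate(ref_ids):
        row = confusion[i, : len(ref_ids)].astype(float)
        thresh = row.mean() + (row.std(ddof=1) if row.size > 1 else 0.0)
        detected[rid] = bool(row[i] > thresh)
    return LibraryTypingResult(
        report=report,
        accuracy=float(diag.sum() / confusion.sum()),
        per_genome_accuracy=per_genome,
        detected=detected,
        confusion=confusion,
        reference_ids=tuple(ref_ids),
    )
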