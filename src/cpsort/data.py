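"""Packaged default training windows and the matrices built from them.

The package ships two training-window FASTA files mirroring the sizes of the
published diatom training sets: a 166-window plastid set and a 31-window PPC
set.  Both are synthetic stand-ins sampled from the default cleavage-site
profiles in :mod:`cpsort.fixtures` (seeds recorded in the record headers);
the real training sequences are experimentally localised diatom proteins and
are not redistributed here.  Default matrices are rebuilt from these windows
at load time, in corrected or uncorrected form.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .io_formats import read_fasta
from .matrixlib import ScoringMatrix, WindowSet, build_scoring_matrix

PLASTID_WINDOWS_FILE = "plastid_windows_synthetic.fasta"
PPC_WINDOWS_FILE = "ppc_windows_synthetic.fasta"


def _packaged_windows(filename: str) -> WindowSet:
    ref = resources.files("cpsort").joinpath("data", filename)
    with resources.as_file(ref) as path:
        records = read_fasta(path)
    return WindowSet.from_sequences([r.sequence for r in records], [r.id for r in records])


@lru_cache(maxsize=None)
def plastid_training_windows() -> WindowSet:
    """166 packaged plastid cleavage-site windows (synthetic stand-ins)."""
    return _packaged_windows(PLASTID_WINDOWS_FILE)


@lru_cache(maxsize=None)
def ppc_training_windows() -> WindowSet:
    """31 packaged periplastidic-compartment windows (synthetic stand-ins)."""
    return _packaged_windows(PPC_WINDOWS_FILE)


@lru_cache(maxsize=None)
def default_plastid_matrix(corrected: bool = True) -> ScoringMatrix:
    label = "plastid-166" + ("" if corrected else "-uncorrected")
    return build_scoring_matrix(plastid_training_windows(), corrected=corrected, label=label)


@lru_cache(maxsize=None)
def default_ppc_matrix(corrected: bool = True) -> ScoringMatrix:
    label = "PPC-31" + ("" if corrected else "-uncorrected")
    return build_scoring_matrix(ppc_training_windows(), corrected=corrected, label=label)
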