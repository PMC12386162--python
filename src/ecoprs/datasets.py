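"""Paths to the packaged example data.

The package ships the seven-variant Sjogren's syndrome score PGS001308,
1000 Genomes Phase 3 effect-allele frequencies for the five European
populations CEU, TSI, FIN, GBR and IBS, and published prevalence estimates
for the matching countries. Together they form the worked example every
pipeline stage is demonstrated on.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

_FILES = {
    "scores": "PGS001308.txt",
    "freqs": "frequencies_1kg_phase3_eur.tsv",
    "prev": "prevalence_sjogren_europe.tsv",
}


def example_path(which: str) -> Path:
    """Return the path of one packaged input: 'scores', 'freqs' or 'prev'."""
    try:
        name = _FILES[which]
    except KeyError:
        raise KeyError(f"unknown example file {which!r}; choose from {sorted(_FILES)}")
    return Path(resources.files("ecoprs.data") / name)


def example_paths() -> tuple[Path, Path, Path]:
    """Paths of the packaged scoring file, frequency table and prevalence table."""
    return example_path("scores"), example_path("freqs"), example_path("prev")
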